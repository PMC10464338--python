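"""Elution statistics over the hexanediol gradient.

For each protein the raw replicate-mean abundance in the isotonic-buffer
control (IB) and in each hexanediol concentration group (2%, 5%, 10%)
yields:

* the HD ratio — pooled HD abundance over total (IB + HD) abundance, a
  per-protein measure of hexanediol sensitivity;
* concentration shares — each HD group's fraction of the summed HD
  abundance;
* a representative/common classification — a protein whose share in one
  concentration exceeds 50% of its summed HD abundance is representative
  of that concentration; a protein whose maximal share lies between 20%
  and 50% is common.

Ratio statistics deliberately use raw replicate means with undetected
groups at zero, not imputed or normalized values: imputation serves
normalization and Z-scoring, and would inflate the apparent abundance of
groups where a protein was never observed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .quant_io import GROUPS, HD_GROUPS, QuantTable

log = logging.getLogger(__name__)

REP_CLASSES = (
    "representative_HD2",
    "representative_HD5",
    "representative_HD10",
    "common",
    "minor",
    "undefined",
)


@dataclass(frozen=True)
class ElutionProfile:
    protein_id: str
    a_ib: float
    a_hd2: float
    a_hd5: float
    a_hd10: float
    hd_ratio: float | None
    shares: tuple[float, float, float] | None
    rep_class: str

    @property
    def hd_abundances(self) -> tuple[float, float, float]:
        return (self.a_hd2, self.a_hd5, self.a_hd10)

    def abundance_in(self, group: str) -> float:
        return {
            "IB": self.a_ib,
            "HD2": self.a_hd2,
            "HD5": self.a_hd5,
            "HD10": self.a_hd10,
        }[group]


def hd_vs_ib_ratio(a_ib: float, a_hd_total: float) -> float | None:
    """HD-eluted abundance over total (IB + HD) abundance, in [0, 1].

    Returns None when both abundances are zero (the protein carries no
    signal and is excluded).
    """
    if a_ib < 0 or a_hd_total < 0:
        raise ValidationError("abundances must be non-negative")
    total = a_ib + a_hd_total
    if total == 0:
        return None
    return a_hd_total / total


def concentration_shares(
    a_hd2: float, a_hd5: float, a_hd10: float
) -> tuple[float, float, float] | None:
    """Each concentration's fraction of the summed HD abundance; None if all zero."""
    if min(a_hd2, a_hd5, a_hd10) < 0:
        raise ValidationError("abundances must be non-negative")
    total = a_hd2 + a_hd5 + a_hd10
    if total == 0:
        return None
    return (a_hd2 / total, a_hd5 / total, a_hd10 / total)


def classify_representative(
    shares: tuple[float, float, float] | None,
    rep_threshold: float = 0.5,
    common_low: float = 0.2,
) -> str:
    """Classify a protein by its concentration shares.

    ``representative_<conc>`` iff that share strictly exceeds
    ``rep_threshold`` (at most one can); otherwise ``common`` iff the
    maximal share lies in [``common_low``, ``rep_threshold``]; otherwise
    ``minor``. Undefined shares give ``undefined``.
    """
    if not (0 < rep_threshold < 1) or not (0 < common_low < 1):
        raise ValidationError("thresholds must lie in (0, 1)")
    if common_low >= rep_threshold:
        raise ValidationError(
            f"common_low ({common_low}) must be below rep_threshold ({rep_threshold})"
        )
    if shares is None:
        return "undefined"
    for share, group in zip(shares, HD_GROUPS):
        if share > rep_threshold:
            return f"representative_{group}"
    if max(shares) >= common_low:
        return "common"
    return "minor"


def build_profiles(
    table: QuantTable,
    rep_threshold: float = 0.5,
    common_low: float = 0.2,
    hd_pooling: Literal["sum", "max"] = "sum",
) -> list[ElutionProfile]:
    """Compute ElutionProfiles from a raw (unimputed) quant table.

    Group abundance is the mean of the observed replicate values in that
    group, or 0 when the protein was not detected in any replicate of the
    group. ``hd_pooling`` controls how the three concentration groups are
    pooled into a single HD abundance for the HD ratio: their sum
    (sequential elution fractions are distinct material) or their max.
    """
    if hd_pooling not in ("sum", "max"):
        raise ValidationError(f"unknown hd_pooling {hd_pooling!r}")
    group_cols = {g: table.samples_in_group(g) for g in GROUPS}
    for g, cols in group_cols.items():
        if not cols:
            raise ValidationError(f"quant table has no samples in group {g!r}")
    means = {
        g: table.abundance[cols].mean(axis=1, skipna=True).fillna(0.0)
        for g, cols in group_cols.items()
    }
    profiles = []
    n_undefined = 0
    for pid in table.protein_ids:
        a_ib = float(means["IB"][pid])
        a_hd = tuple(float(means[g][pid]) for g in HD_GROUPS)
        pooled = sum(a_hd) if hd_pooling == "sum" else max(a_hd)
        ratio = hd_vs_ib_ratio(a_ib, pooled)
        shares = concentration_shares(*a_hd)
        rep_class = classify_representative(shares, rep_threshold, common_low)
        if ratio is None or shares is None:
            n_undefined += 1
        profiles.append(
            ElutionProfile(pid, a_ib, *a_hd, hd_ratio=ratio, shares=shares, rep_class=rep_class)
        )
    if n_undefined:
        log.info("elution profiles: %d protein(s) with undefined ratio or shares", n_undefined)
    return profiles


def setwise_abundance_ratio(
    profiles: Sequence[ElutionProfile],
    members: Iterable[str],
    group: str,
    include_ib: bool = False,
) -> float:
    """Summed abundance of a protein set in one group over its summed total.

    The denominator sums the three HD concentration groups, plus IB when
    ``include_ib`` is set (needed for HD-vs-IB comparisons).
    """
    if group not in GROUPS:
        raise ValidationError(f"unknown group {group!r}")
    members = set(members)
    selected = [p for p in profiles if p.protein_id in members]
    if not selected:
        raise ValidationError(f"no profiled protein belongs to the set ({len(members)} members)")
    numerator = sum(p.abundance_in(group) for p in selected)
    denominator = sum(
        p.a_hd2 + p.a_hd5 + p.a_hd10 + (p.a_ib if include_ib else 0.0)
        for p in selected
    )
    if denominator == 0:
        raise ValidationError("set has zero total abundance")
    return numerator / denominator


def profiles_to_frame(profiles: Sequence[ElutionProfile]) -> pd.DataFrame:
    """Tabulate profiles: abundances, HD ratio, shares and class per protein."""
    rows = []
    for p in profiles:
        s2, s5, s10 = p.shares if p.shares is not None else (np.nan, np.nan, np.nan)
        rows.append(
            {
                "protein_id": p.protein_id,
                "a_IB": p.a_ib,
                "a_HD2": p.a_hd2,
                "a_HD5": p.a_hd5,
                "a_HD10": p.a_hd10,
                "hd_ratio": np.nan if p.hd_ratio is None else p.hd_ratio,
                "s2": s2,
                "s5": s5,
                "s10": s10,
                "rep_class": p.rep_class,
            }
        )
    return pd.DataFrame(rows)
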