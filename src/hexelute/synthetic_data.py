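"""Synthetic gradient-elution proteomics experiments with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
four-group label-free quant table (isotonic-buffer control plus 2%, 5%
and 10% hexanediol elutions) with replicates, log-normal total
abundances, abundance-dependent missingness, and three planted protein
classes:

* ``llps_like`` — condensate-prone proteins: most of their material
  elutes at low hexanediol concentration, and their sequences carry
  S/G/Q/P-rich low-complexity blocks with matching disorder intervals;
* ``structured`` — folded chromatin- or cytoplasm-associated proteins:
  eluted mostly by the isotonic buffer, near-uniform residue usage,
  little disorder;
* ``background`` — intermediate on both axes.

Sequence composition is block-structured rather than i.i.d. so the
low-complexity detector has realistic contiguous targets, and missing
cells concentrate at low abundance (left-censored-like) so minimum
imputation is exercised meaningfully. Everything is deterministic given
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .quant_io import (
    AMINO_ACIDS,
    GROUPS,
    DisorderAnnotation,
    PeptideEvidence,
    QuantTable,
    SampleMeta,
)

CLASSES = ("llps_like", "structured", "background")

#: Residue pool and weights for planted low-complexity blocks.
_LC_RESIDUES = np.array(list("SGQP"))
_LC_WEIGHTS = np.array([0.50, 0.25, 0.15, 0.10])

_ALL_RESIDUES = np.array(list(AMINO_ACIDS))

_REPLICATE_NOISE_SIGMA = 0.2  # multiplicative log-normal noise per replicate
_HIGH_CONFIDENCE_PASS_RATE = 0.97


@dataclass
class SimConfig:
    """Study conditions for one simulated experiment.

    ``elution_profiles`` gives each class's mean abundance share over
    (IB, HD2, HD5, HD10); ``abundance_lognormal`` is the (mu, sigma) of
    the natural-log total peak area.
    """

    n_proteins: int = 2000
    replicates: Mapping[str, int] = field(
        default_factory=lambda: {"IB": 2, "HD2": 2, "HD5": 2, "HD10": 2}
    )
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"llps_like": 0.25, "structured": 0.35, "background": 0.40}
    )
    elution_profiles: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "llps_like": (0.10, 0.60, 0.20, 0.10),
            "structured": (0.70, 0.05, 0.10, 0.15),
            "background": (0.40, 0.15, 0.20, 0.25),
        }
    )
    abundance_lognormal: tuple[float, float] = (18.0, 1.5)
    missing_rate: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValidationError("n_proteins must be >= 1")
        if set(self.replicates) != set(GROUPS) or any(
            r < 1 for r in self.replicates.values()
        ):
            raise ValidationError(f"replicates must cover groups {GROUPS} with counts >= 1")
        if set(self.class_fractions) != set(CLASSES):
            raise ValidationError(f"class_fractions must cover classes {CLASSES}")
        if abs(sum(self.class_fractions.values()) - 1.0) > 1e-9:
            raise ValidationError("class fractions must sum to 1")
        if any(f < 0 for f in self.class_fractions.values()):
            raise ValidationError("class fractions must be non-negative")
        for cls, profile in self.elution_profiles.items():
            if len(profile) != 4 or abs(sum(profile) - 1.0) > 1e-9 or min(profile) < 0:
                raise ValidationError(
                    f"elution profile for {cls!r} must be 4 non-negative shares summing to 1"
                )
        if not (0 <= self.missing_rate < 1):
            raise ValidationError("missing_rate must lie in [0, 1)")

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimConfig":
        kwargs = dict(data)
        if "elution_profiles" in kwargs:
            kwargs["elution_profiles"] = {
                k: tuple(v) for k, v in kwargs["elution_profiles"].items()
            }
        if "abundance_lognormal" in kwargs:
            kwargs["abundance_lognormal"] = tuple(kwargs["abundance_lognormal"])
        return cls(**kwargs)


def _class_counts(config: SimConfig) -> dict[str, int]:
    counts = {
        cls: round(config.n_proteins * config.class_fractions[cls]) for cls in CLASSES
    }
    # fix rounding drift on the largest class
    drift = config.n_proteins - sum(counts.values())
    if drift:
        largest = max(CLASSES, key=lambda c: counts[c])
        counts[largest] += drift
    return counts


def _split_lengths(rng: np.random.Generator, total: int, parts: int, minimum: int = 0) -> list[int]:
    """Split ``total`` into ``parts`` non-negative lengths, each >= minimum."""
    if parts <= 0:
        return []
    spare = total - minimum * parts
    if spare < 0:
        raise ValidationError("cannot split length with the requested minimum")
    extra = rng.multinomial(spare, np.full(parts, 1.0 / parts))
    return [minimum + int(e) for e in extra]


def _blocky_sequence(
    rng: np.random.Generator, length: int, lc_fraction: float
) -> tuple[str, list[tuple[int, int]]]:
    """A sequence with planted low-complexity blocks covering ~lc_fraction."""
    lc_total = int(round(lc_fraction * length))
    if lc_total < 15:
        seq = "".join(rng.choice(_ALL_RESIDUES, size=length))
        return seq, []
    n_blocks = max(1, lc_total // 50)
    block_lengths = _split_lengths(rng, lc_total, n_blocks, minimum=15)
    gap_lengths = _split_lengths(rng, length - lc_total, n_blocks + 1)
    parts: list[str] = []
    blocks: list[tuple[int, int]] = []
    pos = 0
    for i, block_len in enumerate(block_lengths):
        gap = gap_lengths[i]
        parts.append("".join(rng.choice(_ALL_RESIDUES, size=gap)))
        pos += gap
        parts.append("".join(rng.choice(_LC_RESIDUES, size=block_len, p=_LC_WEIGHTS)))
        blocks.append((pos, pos + block_len))
        pos += block_len
    parts.append("".join(rng.choice(_ALL_RESIDUES, size=gap_lengths[-1])))
    return "".join(parts), blocks


def simulate_proteome(
    config: SimConfig,
) -> tuple[dict[str, str], list[DisorderAnnotation], pd.DataFrame]:
    """Generate sequences, disorder intervals and the ground-truth table.

    Ground truth columns: protein_id, class_label, the true abundance
    share per group, and the planted low-complexity target fraction.
    """
    rng = np.random.default_rng(config.seed)
    counts = _class_counts(config)
    sequences: dict[str, str] = {}
    disorder: list[DisorderAnnotation] = []
    records = []
    index = 0
    for cls in CLASSES:
        for _ in range(counts[cls]):
            pid = f"P{index:05d}"
            index += 1
            length = int(rng.integers(300, 801))
            if cls == "llps_like":
                lc_target = float(rng.uniform(0.30, 0.60))
            elif cls == "background":
                lc_target = float(rng.uniform(0.05, 0.20))
            else:
                lc_target = 0.0
            seq, blocks = _blocky_sequence(rng, length, lc_target)
            if cls == "llps_like":
                # disorder tracks the planted blocks, slightly widened
                intervals = [
                    (max(0, s - 10), min(length, e + 10)) for s, e in blocks
                ]
            elif cls == "structured":
                span = int(round(float(rng.uniform(0.02, 0.08)) * length))
                start = int(rng.integers(0, max(1, length - span)))
                intervals = [(start, start + max(1, span))]
            else:
                span = int(round(float(rng.uniform(0.05, 0.25)) * length))
                start = int(rng.integers(0, max(1, length - span)))
                intervals = [(start, start + max(1, span))]
            sequences[pid] = seq
            if intervals:
                disorder.append(DisorderAnnotation.from_intervals(pid, intervals))
            shares = config.elution_profiles[cls]
            records.append(
                {
                    "protein_id": pid,
                    "class_label": cls,
                    "share_IB": shares[0],
                    "share_HD2": shares[1],
                    "share_HD5": shares[2],
                    "share_HD10": shares[3],
                    "lcd_target": lc_target,
                }
            )
    truth = pd.DataFrame(records).set_index("protein_id")
    return sequences, disorder, truth


def simulate_elution(
    config: SimConfig, truth: pd.DataFrame
) -> tuple[QuantTable, list[PeptideEvidence]]:
    """Generate the quant table and peptide evidence for a ground truth.

    Per protein: total abundance ~ LogNormal(mu, sigma); each replicate
    measurement is total x group share x LogNormal(0, 0.2) noise. Cells
    are masked missing at ``missing_rate``, rank-weighted toward low
    abundance; every sample column keeps at least one observed value.
    Peptide evidence is sampled so ~97% of proteins pass the
    high-confidence filter.
    """
    rng = np.random.default_rng([config.seed, 104729])
    protein_ids = list(truth.index)
    n = len(protein_ids)
    mu, sigma = config.abundance_lognormal
    total = rng.lognormal(mu, sigma, size=n)
    samples = [
        SampleMeta(f"{group}_r{rep}", group, rep)
        for group in GROUPS
        for rep in range(1, config.replicates[group] + 1)
    ]
    share_cols = {g: truth[f"share_{g}"].to_numpy() for g in GROUPS}
    columns = {}
    for meta in samples:
        noise = rng.lognormal(0.0, _REPLICATE_NOISE_SIGMA, size=n)
        columns[meta.sample_id] = total * share_cols[meta.group] * noise
    values = pd.DataFrame(columns, index=pd.Index(protein_ids, name="protein_id"))

    if config.missing_rate > 0:
        flat = values.to_numpy().ravel()
        order = np.argsort(np.argsort(flat, kind="stable"), kind="stable")
        # weight 2 -> 0, linear in ascending abundance rank
        weights = 2.0 * (1.0 - order / max(1, flat.size - 1))
        mask = rng.random(flat.size) < config.missing_rate * weights
        mask = mask.reshape(values.shape)
        for j in range(mask.shape[1]):  # keep >= 1 observed value per column
            if mask[:, j].all():
                col = values.iloc[:, j].to_numpy()
                mask[int(np.argmax(col)), j] = False
        masked = values.to_numpy()
        masked[mask] = np.nan
        values = pd.DataFrame(masked, index=values.index, columns=values.columns)

    table = QuantTable(abundance=values, samples=samples)

    passing = rng.random(n) < _HIGH_CONFIDENCE_PASS_RATE
    unique = np.where(passing, 1 + rng.poisson(3, size=n), rng.integers(0, 3, size=n))
    strict = np.where(passing, 2 + rng.poisson(4, size=n), rng.integers(0, 2, size=n))
    evidence = [
        PeptideEvidence(pid, int(u), int(s))
        for pid, u, s in zip(protein_ids, unique, strict)
    ]
    return table, evidence
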