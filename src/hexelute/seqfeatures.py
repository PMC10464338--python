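"""Sequence features associated with liquid-liquid phase separation.

Per protein: the fraction of residues in low-complexity segments found by
an entropy-based two-threshold sliding-window detector, the fraction in
externally predicted disordered regions, the fraction of charged residues
(D, E, K, R), and the mean Kyte-Doolittle hydropathy rescaled to [0, 1]
(the Uversky convention).

The low-complexity detector follows the classic two-threshold scheme:
every length-W window whose Shannon compositional entropy is at or below
``locut`` triggers a segment, which is extended over contiguous windows
at or below ``hicut``; overlapping extended regions are merged. The
optimal-subsegment refinement stage of the original SEG program is
deliberately omitted: the downstream statistic is a per-protein length
fraction, for which boundary refinement is second-order. Reported
segment boundaries may therefore differ slightly from original SEG
output.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .quant_io import AMINO_ACIDS, DisorderAnnotation, merge_intervals

log = logging.getLogger(__name__)

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

CHARGED_RESIDUES = frozenset("DEKR")  # histidine excluded by convention

#: Entropy of a uniform 20-letter composition; used for all-X windows.
MAX_COMPLEXITY = math.log2(20)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class LowComplexitySegment:
    """A merged low-complexity region, 0-based half-open, with its overall
    compositional entropy in bits per residue."""

    start: int
    end: int
    complexity: float


def window_complexity(window: str) -> float:
    """Shannon compositional entropy of a window in bits per residue.

    X residues are excluded from the counts with the length reduced
    accordingly; an all-X window is treated as maximally complex.
    """
    if not window:
        raise ValidationError("empty window")
    counts = Counter(window.upper())
    counts.pop("X", None)
    length = sum(counts.values())
    if length == 0:
        log.warning("window of only X residues: treating as maximal complexity")
        return MAX_COMPLEXITY
    return -sum((n / length) * math.log2(n / length) for n in counts.values())


def _window_complexities(seq: str, W: int) -> np.ndarray:
    """Entropy of every length-W window, vectorized via cumulative counts."""
    codes = np.array([_AA_INDEX.get(c, -1) for c in seq], dtype=np.int64)  # X -> -1
    n = len(seq)
    onehot = np.zeros((n + 1, 20), dtype=np.int64)
    valid = codes >= 0
    onehot[1:][valid, codes[valid]] = 1
    cum = np.cumsum(onehot, axis=0)
    counts = cum[W:] - cum[:-W]  # (n-W+1, 20)
    lengths = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / lengths[:, None]
        logp = np.zeros_like(p)
        np.log2(p, out=logp, where=counts > 0)
    entropy = (-p * logp).sum(axis=1)
    entropy[lengths == 0] = MAX_COMPLEXITY
    return entropy


def seg_low_complexity(
    seq: str, W: int = 12, locut: float = 2.2, hicut: float = 2.5
) -> list[LowComplexitySegment]:
    """Detect low-complexity segments with the two-threshold window scheme.

    Windows with entropy <= ``locut`` trigger segments; triggers are
    extended over contiguous windows with entropy <= ``hicut``; the
    resulting residue intervals are merged. Defaults are the published
    SEG defaults (W=12, locut=2.2, hicut=2.5).
    """
    if W < 2:
        raise ValidationError(f"window length must be >= 2, got {W}")
    if locut <= 0:
        raise ValidationError(f"locut must be > 0, got {locut}")
    if locut > hicut:
        raise ValidationError(f"locut ({locut}) must not exceed hicut ({hicut})")
    seq = seq.upper()
    if len(seq) < W:
        raise ValidationError(
            f"sequence length {len(seq)} shorter than window length {W}"
        )
    entropy = _window_complexities(seq, W)
    extendable = entropy <= hicut
    triggers = entropy <= locut
    intervals: list[tuple[int, int]] = []
    n_windows = len(entropy)
    i = 0
    while i < n_windows:
        if not extendable[i]:
            i += 1
            continue
        j = i
        while j < n_windows and extendable[j]:
            j += 1
        if triggers[i:j].any():  # run of extendable windows containing a trigger
            intervals.append((i, j - 1 + W))
        i = j
    merged = merge_intervals(intervals)
    return [
        LowComplexitySegment(start, end, window_complexity(seq[start:end]))
        for start, end in merged
    ]


def lcd_fraction(seq: str, segments: Sequence[LowComplexitySegment]) -> float:
    """Fraction of the protein length covered by low-complexity segments."""
    if not seq:
        raise ValidationError("empty sequence")
    for s in segments:
        if s.start < 0 or s.end > len(seq) or s.start >= s.end:
            raise ValidationError(f"segment [{s.start}, {s.end}) out of bounds")
    union = merge_intervals((s.start, s.end) for s in segments)
    return sum(e - s for s, e in union) / len(seq)


def idr_fraction(seq: str, disorder: DisorderAnnotation) -> float:
    """Fraction of the protein length covered by disorder intervals."""
    if not seq:
        raise ValidationError("empty sequence")
    for start, end in disorder.intervals:
        if end > len(seq):
            raise ValidationError(
                f"protein {disorder.protein_id!r}: interval end {end} exceeds "
                f"length {len(seq)}"
            )
    return sum(e - s for s, e in disorder.intervals) / len(seq)


def fcr(seq: str) -> float:
    """Fraction of charged residues (D, E, K, R) over the full length."""
    if not seq:
        raise ValidationError("empty sequence")
    seq = seq.upper()
    return sum(1 for c in seq if c in CHARGED_RESIDUES) / len(seq)


def uversky_hydropathy(seq: str) -> float:
    """Mean Kyte-Doolittle hydropathy rescaled linearly to [0, 1].

    X residues are skipped with the length reduced accordingly; any other
    non-standard residue is a hard error.
    """
    if not seq:
        raise ValidationError("empty sequence")
    seq = seq.upper()
    total = 0.0
    counted = 0
    for c in seq:
        if c == "X":
            continue
        if c not in KYTE_DOOLITTLE:
            raise ValidationError(f"unknown residue {c!r}")
        total += (KYTE_DOOLITTLE[c] + 4.5) / 9.0
        counted += 1
    if counted == 0:
        raise ValidationError("sequence contains only X residues")
    return total / counted


def feature_table(
    sequences: Mapping[str, str],
    disorder: Iterable[DisorderAnnotation] = (),
    external_scores: pd.DataFrame | None = None,
    W: int = 12,
    locut: float = 2.2,
    hicut: float = 2.5,
) -> pd.DataFrame:
    """Per-protein feature vectors: lcd_fraction, idr_fraction, fcr, hydropathy.

    Proteins without a disorder record get idr_fraction 0. Optional
    external predictor scores (a DataFrame indexed by protein_id, e.g.
    PScore or catGRANULE analogues) are joined as extra columns.
    """
    disorder_by_id = {d.protein_id: d for d in disorder}
    rows = []
    for pid, seq in sequences.items():
        segments = seg_low_complexity(seq, W, locut, hicut) if len(seq) >= W else []
        ann = disorder_by_id.get(pid, DisorderAnnotation(pid, ()))
        rows.append(
            {
                "protein_id": pid,
                "lcd_fraction": lcd_fraction(seq, segments),
                "idr_fraction": idr_fraction(seq, ann),
                "fcr": fcr(seq),
                "hydropathy": uversky_hydropathy(seq),
            }
        )
    df = pd.DataFrame(rows).set_index("protein_id")
    if external_scores is not None:
        df = df.join(external_scores, how="left")
    return df
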