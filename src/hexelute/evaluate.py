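"""Ground-truth recovery metrics for synthetic studies.

Given a simulated study's ground truth and the elution profiles the
pipeline estimated from its quant table, these helpers measure how well
the analysis recovers the planted structure: the recall of planted
class-to-representative assignments, the AUROC of the HD ratio as a
separator of condensate-prone from structured proteins, and the Spearman
correlation between true and estimated concentration shares.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .elution_profile import ElutionProfile
from .errors import ValidationError
from .quant_io import HD_GROUPS


def auroc(positives: Sequence[float], negatives: Sequence[float]) -> float:
    """Probability that a random positive scores above a random negative
    (ties count half), via the rank-sum identity U / (n1 * n2)."""
    positives = np.asarray(positives, dtype=float)
    negatives = np.asarray(negatives, dtype=float)
    if len(positives) == 0 or len(negatives) == 0:
        raise ValidationError("need scores on both sides")
    pooled = np.concatenate([positives, negatives])
    ranks = sps.rankdata(pooled)
    u = ranks[: len(positives)].sum() - len(positives) * (len(positives) + 1) / 2
    return float(u / (len(positives) * len(negatives)))


def representative_recall(
    truth: pd.DataFrame,
    profiles: Sequence[ElutionProfile],
    class_label: str,
    rep_class: str,
) -> float:
    """Fraction of profiled proteins of a planted class assigned a
    representative class."""
    members = set(truth.index[truth["class_label"] == class_label])
    assigned = [p for p in profiles if p.protein_id in members]
    if not assigned:
        raise ValidationError(f"no profiled protein of class {class_label!r}")
    return sum(p.rep_class == rep_class for p in assigned) / len(assigned)


def hd_ratio_auroc(
    truth: pd.DataFrame,
    profiles: Sequence[ElutionProfile],
    positive_class: str = "llps_like",
    negative_class: str = "structured",
) -> float:
    """AUROC of the per-protein HD ratio separating two planted classes."""
    labels = truth["class_label"]
    pos_ids = set(labels.index[labels == positive_class])
    neg_ids = set(labels.index[labels == negative_class])
    pos = [p.hd_ratio for p in profiles if p.protein_id in pos_ids and p.hd_ratio is not None]
    neg = [p.hd_ratio for p in profiles if p.protein_id in neg_ids and p.hd_ratio is not None]
    return auroc(pos, neg)


def share_recovery_spearman(
    truth: pd.DataFrame, profiles: Sequence[ElutionProfile]
) -> float:
    """Spearman correlation between planted and estimated HD concentration
    shares, pooled over all (protein, concentration) pairs.

    Planted shares over (IB, HD2, HD5, HD10) are renormalized to the
    three HD groups to match the estimated share definition.
    """
    true_values = []
    est_values = []
    for p in profiles:
        if p.shares is None or p.protein_id not in truth.index:
            continue
        row = truth.loc[p.protein_id]
        hd = np.array([row[f"share_{g}"] for g in HD_GROUPS], dtype=float)
        if hd.sum() == 0:
            continue
        true_values.extend(hd / hd.sum())
        est_values.extend(p.shares)
    if not true_values:
        raise ValidationError("no overlapping proteins with defined shares")
    rho, _ = sps.spearmanr(true_values, est_values)
    return float(rho)
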