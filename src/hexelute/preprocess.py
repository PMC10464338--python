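"""Quantification processing: confidence filter, detection filter,
minimum-value imputation, quantile normalization and per-group Z-scoring.

The chain reproduces a standard label-free workflow: proteins are kept if
they have at least one unique peptide and two strict peptides, or more
than two strict peptides; proteins detected in at least one sample are
retained; missing peak areas are imputed with the minimum observed value
(per sample column by default); quantile normalization equalizes the
sample distributions; abundances are then log2-transformed and Z-scored
within each treatment group for cross-group comparison.

Stage order is enforced: each operation refuses to run unless its
predecessors have been applied, and records itself on the returned table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import PipelineOrderError, ValidationError
from .quant_io import PeptideEvidence, QuantTable

log = logging.getLogger(__name__)

STAGE_ORDER = ("high_confidence", "detected", "imputed", "quantile_normalized")


def _require_stages(table: QuantTable, *needed: str) -> None:
    for stage in needed:
        if stage not in table.stages:
            raise PipelineOrderError(
                f"stage {stage!r} has not been applied yet "
                f"(applied so far: {list(table.stages) or 'none'}; "
                f"required order: {' -> '.join(STAGE_ORDER)})"
            )


@dataclass
class NormalizedTable:
    """Quantile-normalized log2 abundances with per-cell provenance.

    ``provenance`` is a parallel DataFrame of {"observed", "imputed"}
    recording which cells were measured and which were filled in by
    minimum imputation.
    """

    values: pd.DataFrame
    provenance: pd.DataFrame
    samples: list

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValidationError("normalized table contains missing values")
        if self.values.shape != self.provenance.shape:
            raise ValidationError("provenance matrix shape mismatch")


def filter_high_confidence(
    table: QuantTable, evidence: Sequence[PeptideEvidence]
) -> QuantTable:
    """Keep proteins with (>=1 unique and >=2 strict) or >2 strict peptides."""
    if table.stages:
        raise PipelineOrderError(
            "high-confidence filter must run first "
            f"(stages already applied: {list(table.stages)})"
        )
    by_id = {e.protein_id: e for e in evidence}
    keep = []
    for pid in table.protein_ids:
        if pid not in by_id:
            raise ValidationError(f"no peptide evidence record for protein {pid!r}")
        e = by_id[pid]
        if (e.unique_peptides >= 1 and e.strict_peptides >= 2) or e.strict_peptides > 2:
            keep.append(pid)
    log.info("high-confidence filter: kept %d of %d proteins", len(keep), len(table.protein_ids))
    return table.subset(keep).with_stage("high_confidence")


def filter_detected(table: QuantTable, min_samples: int = 1) -> QuantTable:
    """Keep proteins observed (non-missing) in at least ``min_samples`` samples."""
    if min_samples < 1:
        raise ValidationError(f"min_samples must be >= 1, got {min_samples}")
    _require_stages(table, "high_confidence")
    counts = table.abundance.notna().sum(axis=1)
    keep = list(table.abundance.index[counts >= min_samples])
    log.info("detection filter: kept %d of %d proteins", len(keep), len(table.protein_ids))
    return table.subset(keep).with_stage("detected")


def impute_min(
    table: QuantTable, scope: Literal["column", "global"] = "column"
) -> tuple[QuantTable, pd.DataFrame]:
    """Replace missing cells with the minimum observed value.

    By default the minimum is taken per sample column, respecting
    sample-specific detection limits; ``scope="global"`` uses the matrix
    minimum. Returns the imputed table and a provenance DataFrame of
    {"observed", "imputed"}.
    """
    _require_stages(table, "high_confidence", "detected")
    values = table.abundance.copy()
    missing = values.isna()
    if scope == "column":
        all_missing = missing.all(axis=0)
        if all_missing.any():
            col = values.columns[all_missing][0]
            raise ValidationError(f"sample {col!r} has no observed values to impute from")
        fill = values.min(axis=0, skipna=True)
        values = values.fillna(fill)
    elif scope == "global":
        observed = values.to_numpy()[~missing.to_numpy()]
        if observed.size == 0:
            raise ValidationError("table has no observed values to impute from")
        values = values.fillna(float(observed.min()))
    else:
        raise ValidationError(f"unknown impute scope {scope!r}")
    provenance = pd.DataFrame(
        np.where(missing, "imputed", "observed"),
        index=values.index,
        columns=values.columns,
    )
    return table.with_stage("imputed", values), provenance


def quantile_normalize_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize a complete matrix so every column shares one distribution.

    Each column's rank r is replaced by the mean across columns of the
    r-th order statistics; ties within a column receive the mean of the
    reference values at their tied ranks.
    """
    X = values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValidationError("quantile normalization requires a complete matrix")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(len(col))
        normalized = reference[ranks]
        # average reference values over runs of tied input values
        sorted_col = col[order]
        boundaries = np.flatnonzero(np.r_[True, sorted_col[1:] != sorted_col[:-1], True])
        for a, b in zip(boundaries[:-1], boundaries[1:]):
            if b - a > 1:
                normalized[order[a:b]] = reference[a:b].mean()
        out[:, j] = normalized
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def quantile_normalize(table: QuantTable) -> QuantTable:
    _require_stages(table, "high_confidence", "detected", "imputed")
    normalized = quantile_normalize_matrix(table.abundance)
    return table.with_stage("quantile_normalized", normalized)


def log2_zscore_by_group(table: QuantTable, group: str) -> pd.Series:
    """Z-score log2 group abundance across proteins for one treatment group.

    Group abundance per protein is the arithmetic mean of its replicate
    columns on the raw (pre-log) scale. Z-scores use the sample (n-1)
    standard deviation across proteins.
    """
    _require_stages(table, *STAGE_ORDER)
    cols = table.samples_in_group(group)
    if not cols:
        raise ValidationError(f"no samples in group {group!r}")
    abundance = table.abundance[cols].mean(axis=1)
    if (abundance <= 0).any():
        bad = abundance.index[abundance <= 0][0]
        raise ValidationError(
            f"protein {bad!r} has non-positive abundance in group {group!r}"
        )
    if len(abundance) < 2:
        raise ValidationError(
            f"group {group!r}: need >= 2 proteins to Z-score, got {len(abundance)}"
        )
    logged = np.log2(abundance)
    sd = logged.std(ddof=1)
    if sd == 0:
        raise ValidationError(f"group {group!r}: zero standard deviation, Z-score undefined")
    return (logged - logged.mean()) / sd


def normalize_pipeline(
    table: QuantTable,
    evidence: Sequence[PeptideEvidence],
    min_detected_samples: int = 1,
    impute_scope: Literal["column", "global"] = "column",
) -> tuple[QuantTable, NormalizedTable]:
    """Run the full chain; returns the detection-filtered raw table (used for
    ratio statistics) and the normalized table with provenance."""
    hc = filter_high_confidence(table, evidence)
    detected = filter_detected(hc, min_samples=min_detected_samples)
    imputed, provenance = impute_min(detected, scope=impute_scope)
    normalized = quantile_normalize(imputed)
    log2_values = np.log2(normalized.abundance)
    return detected, NormalizedTable(
        values=log2_values, provenance=provenance, samples=list(table.samples)
    )
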