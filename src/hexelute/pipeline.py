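"""End-to-end orchestration: inputs -> preprocessing -> elution profiles ->
sequence features -> comparison statistics -> tabular reports.

``run_pipeline`` executes the stages in order and writes one TSV per
report: a per-protein master table, a protein-type chi-square table, a
set-wise abundance-ratio table, feature comparisons (high- vs
low-abundance proteins per treatment group, and representative classes
against each other) with Mann-Whitney p-values, per-class enrichment
tables, and a run log echoing the configuration. Stages communicate only
through their return values; the master table is assembled by joins on
protein_id.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import pandas as pd
import yaml

from . import __version__
from .errors import ValidationError
from .quant_io import (
    GROUPS,
    HD_GROUPS,
    read_disorder,
    read_fasta,
    read_gmt,
    read_peptide_evidence,
    read_quant_table,
    write_table,
)
from .preprocess import log2_zscore_by_group, normalize_pipeline
from .elution_profile import build_profiles, profiles_to_frame, setwise_abundance_ratio
from .seqfeatures import feature_table
from .stats import (
    chi_square_independence,
    hypergeometric_enrichment,
    mann_whitney_u,
    quartile_split,
)

log = logging.getLogger(__name__)

FEATURE_COLUMNS = ("lcd_fraction", "idr_fraction", "fcr", "hydropathy")


@dataclass
class RunConfig:
    """Paths and options for one pipeline run; loadable from flat YAML.

    Every analysis choice the method leaves open is an explicit key here
    so a replication attempt can toggle each one.
    """

    quant_table: str
    sample_sheet: str
    peptide_evidence: str
    out_dir: str
    fasta: str | None = None
    disorder: str | None = None
    external_scores: str | None = None
    type_sets: str | None = None
    annotation_sets: str | None = None
    min_detected_samples: int = 1
    impute_scope: Literal["column", "global"] = "column"
    hd_pooling: Literal["sum", "max"] = "sum"
    rep_threshold: float = 0.5
    common_low: float = 0.2
    include_ib: bool = False
    abundance_split: Literal["quartile", "median"] = "quartile"
    seg_window: int = 12
    seg_locut: float = 2.2
    seg_hicut: float = 2.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def validate_paths(self) -> None:
        required = {
            "quant_table": self.quant_table,
            "sample_sheet": self.sample_sheet,
            "peptide_evidence": self.peptide_evidence,
        }
        optional = {
            "fasta": self.fasta,
            "disorder": self.disorder,
            "external_scores": self.external_scores,
            "type_sets": self.type_sets,
            "annotation_sets": self.annotation_sets,
        }
        for name, path in {**required, **{k: v for k, v in optional.items() if v}}.items():
            if not Path(path).exists():
                raise ValidationError(f"config key {name!r}: file {path} does not exist")


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, RuntimeError):
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def _abundance_split_bins(values: pd.Series, mode: str) -> tuple[list[str], list[str]]:
    """Protein ids in the high and low abundance bins."""
    mapping = dict(values.items())
    if mode == "quartile":
        bins = quartile_split(mapping)
        high = [p for p, b in bins.items() if b == "Q4"]
        low = [p for p, b in bins.items() if b == "Q1"]
    elif mode == "median":
        med = values.median()
        high = list(values.index[values > med])
        low = list(values.index[values <= med])
    else:
        raise ValidationError(f"unknown abundance_split {mode!r}")
    return high, low


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every stage and write the report bundle into ``config.out_dir``.

    Returns the report tables keyed by name. When no FASTA is configured
    the sequence-feature outputs are skipped and the run log says so.
    """
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"hexelute {__version__}", f"seed: {config.seed}", "config:"]
    log_lines += [f"  {k}: {v}" for k, v in dataclasses.asdict(config).items()]
    reports: dict[str, pd.DataFrame] = {}

    with _stage("quant_io"):
        table = read_quant_table(config.quant_table, config.sample_sheet)
        evidence = read_peptide_evidence(config.peptide_evidence)
        sequences = read_fasta(config.fasta) if config.fasta else None
        disorder = (
            read_disorder(config.disorder, sequences) if config.disorder else []
        )
        external = (
            pd.read_csv(config.external_scores, sep="\t", index_col="protein_id")
            if config.external_scores
            else None
        )
        type_sets = read_gmt(config.type_sets) if config.type_sets else {}
        annotation_sets = read_gmt(config.annotation_sets) if config.annotation_sets else {}
    log_lines.append(f"input proteins: {len(table.protein_ids)}")

    with _stage("preprocess"):
        detected, normalized = normalize_pipeline(
            table,
            evidence,
            min_detected_samples=config.min_detected_samples,
            impute_scope=config.impute_scope,
        )
        # raw-scale quantile-normalized table for group Z-scores
        qn_table = detected.with_stage("imputed", 2.0 ** normalized.values).with_stage(
            "quantile_normalized"
        )
        zscores = {g: log2_zscore_by_group(qn_table, g) for g in GROUPS}
    log_lines.append(f"high-confidence, detected proteins: {len(detected.protein_ids)}")
    detected_in = {
        g: set(
            detected.abundance.index[
                detected.abundance[detected.samples_in_group(g)].notna().any(axis=1)
            ]
        )
        for g in GROUPS
    }
    for g in GROUPS:
        log_lines.append(f"detected in {g}: {len(detected_in[g])}")

    with _stage("elution_profile"):
        profiles = build_profiles(
            detected,
            rep_threshold=config.rep_threshold,
            common_low=config.common_low,
            hd_pooling=config.hd_pooling,
        )
        profile_frame = profiles_to_frame(profiles)

    features = None
    if sequences is not None:
        with _stage("seqfeatures"):
            profiled = [p for p in profile_frame["protein_id"] if p in sequences]
            features = feature_table(
                {pid: sequences[pid] for pid in profiled},
                disorder,
                external_scores=external,
                W=config.seg_window,
                locut=config.seg_locut,
                hicut=config.seg_hicut,
            )
    else:
        log_lines.append("no FASTA configured: sequence-feature outputs skipped")

    # (1) master table
    master = profile_frame.set_index("protein_id")
    for g in GROUPS:
        master[f"zscore_{g}"] = zscores[g]
    if features is not None:
        master = master.join(features, how="left")
    master = master.reset_index()
    reports["master_table"] = master

    # (2) protein-type chi-square: in-set vs out-of-set counts among
    # HD-detected and IB-detected proteins, one test per type set
    if type_sets:
        with _stage("type_chisq"):
            hd_detected = set().union(*(detected_in[g] for g in HD_GROUPS))
            ib_detected = detected_in["IB"]
            rows = []
            for name, members in type_sets.items():
                counts = [
                    [len(hd_detected & members), len(hd_detected - members)],
                    [len(ib_detected & members), len(ib_detected - members)],
                ]
                chi2, df, p = chi_square_independence(counts)
                rows.append(
                    {
                        "set_name": name,
                        "hd_in_set": counts[0][0],
                        "hd_out_set": counts[0][1],
                        "ib_in_set": counts[1][0],
                        "ib_out_set": counts[1][1],
                        "chi2": chi2,
                        "df": df,
                        "p_value": p,
                    }
                )
            reports["protein_type_chisq"] = pd.DataFrame(rows)

    # (3) set-wise abundance ratios over the gradient, plus the HD-vs-IB ratio
    if annotation_sets:
        with _stage("setwise_ratios"):
            profiled_ids = set(profile_frame["protein_id"])
            rows = []
            for name, members in annotation_sets.items():
                present = members & profiled_ids
                if not present:
                    log.info("set %r has no profiled members; skipped", name)
                    continue
                row = {"set_name": name, "n_members": len(present)}
                for g in HD_GROUPS:
                    row[f"ratio_{g}"] = setwise_abundance_ratio(
                        profiles, present, g, include_ib=config.include_ib
                    )
                sub = profile_frame[profile_frame["protein_id"].isin(present)]
                hd_total = sub[["a_HD2", "a_HD5", "a_HD10"]].to_numpy().sum()
                grand = hd_total + sub["a_IB"].sum()
                row["hd_vs_ib_ratio"] = hd_total / grand if grand > 0 else float("nan")
                rows.append(row)
            reports["setwise_abundance_ratio"] = pd.DataFrame(rows)

    # (4) feature comparisons: high vs low abundance per group, and
    # representative classes pairwise
    if features is not None:
        with _stage("feature_comparison"):
            rows = []
            feature_cols = [c for c in features.columns]
            for g in GROUPS:
                z = zscores[g][zscores[g].index.isin(features.index)]
                high, low = _abundance_split_bins(z, config.abundance_split)
                for feat in feature_cols:
                    x = features.loc[high, feat].dropna()
                    y = features.loc[low, feat].dropna()
                    if len(x) < 1 or len(y) < 1:
                        continue
                    U, p = mann_whitney_u(x, y)
                    rows.append(
                        {
                            "comparison": f"{g}_high_vs_low_abundance",
                            "feature": feat,
                            "n_a": len(x),
                            "n_b": len(y),
                            "median_a": x.median(),
                            "median_b": y.median(),
                            "U": U,
                            "p_value": p,
                        }
                    )
            by_class = master.set_index("protein_id").groupby("rep_class").groups
            rep_classes = [f"representative_{g}" for g in HD_GROUPS]
            for i, cls_a in enumerate(rep_classes):
                for cls_b in rep_classes[i + 1 :]:
                    ids_a = [p for p in by_class.get(cls_a, []) if p in features.index]
                    ids_b = [p for p in by_class.get(cls_b, []) if p in features.index]
                    if not ids_a or not ids_b:
                        continue
                    for feat in feature_cols:
                        x = features.loc[ids_a, feat].dropna()
                        y = features.loc[ids_b, feat].dropna()
                        if len(x) < 1 or len(y) < 1:
                            continue
                        U, p = mann_whitney_u(x, y)
                        rows.append(
                            {
                                "comparison": f"{cls_a}_vs_{cls_b}",
                                "feature": feat,
                                "n_a": len(x),
                                "n_b": len(y),
                                "median_a": x.median(),
                                "median_b": y.median(),
                                "U": U,
                                "p_value": p,
                            }
                        )
            reports["feature_comparison"] = pd.DataFrame(rows)

    # (5) enrichment per representative class
    if annotation_sets:
        with _stage("enrichment"):
            universe = set(profile_frame["protein_id"])
            for g in HD_GROUPS:
                cls = f"representative_{g}"
                query = set(
                    profile_frame.loc[profile_frame["rep_class"] == cls, "protein_id"]
                )
                if not query:
                    log_lines.append(f"no {cls} proteins: enrichment skipped")
                    continue
                results = hypergeometric_enrichment(query, annotation_sets, universe)
                reports[f"enrichment_{cls}"] = pd.DataFrame(
                    [
                        {
                            "set_name": r.set_name,
                            "overlap": r.overlap,
                            "set_size": r.set_size,
                            "query_size": r.query_size,
                            "universe_size": r.universe_size,
                            "p_value": r.p_value,
                            "q_value": r.q_value,
                            "neg_log10_p": -math.log10(r.p_value),
                        }
                        for r in results
                    ]
                )

    for name, frame in reports.items():
        write_table(frame, out_dir / f"{name}.tsv")
    class_counts = master["rep_class"].value_counts().to_dict()
    log_lines.append(f"representative-class counts: {class_counts}")
    log_lines.append(f"reports written: {sorted(reports)}")
    (out_dir / "run_log.txt").write_text("\n".join(str(l) for l in log_lines) + "\n")
    return reports
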