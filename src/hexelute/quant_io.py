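"""Readers, writers and validated in-memory tables for every external format.

The quantification table is a protein x sample matrix of label-free peak
areas. Sample metadata (treatment group, replicate) comes from a separate
sample sheet so that group assignment is explicit and validated rather
than inferred from column names. Missing cells are encoded as an empty
field or the literal ``NA`` (case-insensitive); zeros are observed values.

Coordinates are 0-based half-open throughout, matching BED conventions,
so externally predicted disorder intervals are consumed as-is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ValidationError

#: Treatment groups, in elution order: isotonic-buffer control followed by
#: the 2%, 5% and 10% 1,6-hexanediol fractions.
GROUPS = ("IB", "HD2", "HD5", "HD10")

#: Hexanediol concentration groups only (the gradient), excluding the control.
HD_GROUPS = ("HD2", "HD5", "HD10")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

_NA_STRINGS = ("", "NA", "na", "Na", "nA")


@dataclass(frozen=True)
class SampleMeta:
    """One MS sample: its identifier, treatment group and replicate number."""

    sample_id: str
    group: str
    replicate: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown group {self.group!r} "
                f"(expected one of {GROUPS})"
            )
        if self.replicate < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: replicate must be >= 1, "
                f"got {self.replicate}"
            )


@dataclass
class QuantTable:
    """Protein x sample abundance matrix with sample metadata.

    ``abundance`` is a float DataFrame indexed by protein_id with one
    column per sample_id; missing measurements are NaN. ``stages`` records
    which processing stages have been applied, in order, and is used to
    enforce the processing chain.
    """

    abundance: pd.DataFrame
    samples: list[SampleMeta]
    stages: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = self.abundance.index
        if ids.has_duplicates:
            dup = ids[ids.duplicated()][0]
            raise ValidationError(f"duplicate protein_id {dup!r}")
        sample_ids = [s.sample_id for s in self.samples]
        if len(set(sample_ids)) != len(sample_ids):
            dup = next(s for s in sample_ids if sample_ids.count(s) > 1)
            raise ValidationError(f"duplicate sample_id {dup!r}")
        if list(self.abundance.columns) != sample_ids:
            raise ValidationError(
                "abundance columns do not match sample metadata: "
                f"{list(self.abundance.columns)} vs {sample_ids}"
            )
        values = self.abundance.to_numpy()
        if np.nanmin(values, initial=0.0) < 0:
            bad = self.abundance.lt(0).any(axis=1)
            raise ValidationError(
                f"negative abundance for protein {self.abundance.index[bad][0]!r}"
            )

    @property
    def protein_ids(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def samples_in_group(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise ValidationError(f"unknown group {group!r}")
        return [s.sample_id for s in self.samples if s.group == group]

    def with_stage(self, stage: str, abundance: pd.DataFrame | None = None) -> "QuantTable":
        return QuantTable(
            abundance=self.abundance if abundance is None else abundance,
            samples=list(self.samples),
            stages=self.stages + (stage,),
        )

    def subset(self, protein_ids: Sequence[str]) -> "QuantTable":
        return replace(self, abundance=self.abundance.loc[list(protein_ids)])


@dataclass(frozen=True)
class PeptideEvidence:
    """Peptide support for one protein.

    ``strict_peptides`` counts peptides with Mascot ion score >= 20; the
    high-confidence filter requires (>=1 unique and >=2 strict) or >2 strict.
    """

    protein_id: str
    unique_peptides: int
    strict_peptides: int

    def __post_init__(self) -> None:
        if self.unique_peptides < 0 or self.strict_peptides < 0:
            raise ValidationError(
                f"protein {self.protein_id!r}: peptide counts must be >= 0"
            )


@dataclass(frozen=True)
class DisorderAnnotation:
    """Externally predicted disorder intervals for one protein.

    Intervals are 0-based half-open residue coordinates, non-overlapping
    and sorted after construction (overlapping input intervals are merged).
    """

    protein_id: str
    intervals: tuple[tuple[int, int], ...]

    @staticmethod
    def from_intervals(protein_id: str, intervals: Iterable[tuple[int, int]]) -> "DisorderAnnotation":
        merged = merge_intervals(intervals)
        for start, end in merged:
            if start < 0 or start >= end:
                raise ValidationError(
                    f"protein {protein_id!r}: invalid interval [{start}, {end})"
                )
        return DisorderAnnotation(protein_id, merged)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Merge overlapping or touching half-open intervals; returns them sorted."""
    ordered = sorted(intervals)
    merged: list[list[int]] = []
    for start, end in ordered:
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return tuple((s, e) for s, e in merged)


# ---------------------------------------------------------------------------
# readers


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Read a TSV sample sheet with columns sample_id, group, replicate."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "group", "replicate"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"sample sheet {path} must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    samples = []
    for row in df.itertuples(index=False):
        try:
            rep = int(row.replicate)
        except ValueError as exc:
            raise ValidationError(
                f"sample {row.sample_id!r}: non-integer replicate {row.replicate!r}"
            ) from exc
        samples.append(SampleMeta(row.sample_id, row.group, rep))
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dup = next(s for s in ids if ids.count(s) > 1)
        raise ValidationError(f"sample sheet repeats sample_id {dup!r}")
    return samples


def read_quant_table(path: str | Path, sample_sheet: str | Path) -> QuantTable:
    """Read a protein x sample abundance TSV plus its sample sheet.

    The TSV has a ``protein_id`` first column and one column per sample.
    Empty cells and ``NA`` (any case) parse as missing; any other
    non-numeric cell is a hard error, so no row is ever silently dropped.
    """
    samples = read_sample_sheet(sample_sheet)
    raw = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, index_col=0
    )
    header = list(raw.columns)
    if len(set(header)) != len(header):
        dup = next(c for c in header if header.count(c) > 1)
        raise ValidationError(f"quant table header repeats sample_id {dup!r}")
    by_id = {s.sample_id: s for s in samples}
    missing_meta = [c for c in header if c not in by_id]
    if missing_meta:
        raise ValidationError(
            f"sample(s) {missing_meta} in quant table absent from sample sheet"
        )
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ValidationError(f"duplicate protein_id {dup!r}")

    def parse_cell(text: str, protein: str, sample: str) -> float:
        if text in _NA_STRINGS:
            return math.nan
        try:
            value = float(text)
        except ValueError as exc:
            raise ValidationError(
                f"protein {protein!r}, sample {sample!r}: "
                f"unparseable abundance {text!r}"
            ) from exc
        if value < 0:
            raise ValidationError(
                f"protein {protein!r}, sample {sample!r}: negative abundance {value}"
            )
        return value

    values = pd.DataFrame(
        {
            col: [parse_cell(v, pid, col) for pid, v in raw[col].items()]
            for col in header
        },
        index=raw.index,
        dtype=float,
    )
    # keep only sheet samples present in the table, in sheet order
    kept = [s for s in samples if s.sample_id in header]
    values = values[[s.sample_id for s in kept]]
    return QuantTable(abundance=values, samples=kept)


def read_peptide_evidence(path: str | Path) -> list[PeptideEvidence]:
    """Read a TSV with columns protein_id, unique_peptides, strict_peptides."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"protein_id", "unique_peptides", "strict_peptides"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"peptide evidence {path} must have columns {sorted(required)}"
        )
    records = []
    for row in df.itertuples(index=False):
        try:
            unique = int(row.unique_peptides)
            strict = int(row.strict_peptides)
        except ValueError as exc:
            raise ValidationError(
                f"protein {row.protein_id!r}: non-integer peptide count"
            ) from exc
        records.append(PeptideEvidence(row.protein_id, unique, strict))
    seen: set[str] = set()
    for rec in records:
        if rec.protein_id in seen:
            raise ValidationError(
                f"duplicate evidence record for protein {rec.protein_id!r}"
            )
        seen.add(rec.protein_id)
    return records


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences into a protein_id -> sequence map.

    Sequences are uppercased and restricted to the 20 amino acids plus X.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValidationError(f"duplicate FASTA record {record.id!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise ValidationError(f"empty sequence for {record.id!r}")
        bad = set(seq) - _VALID_RESIDUES
        if bad:
            raise ValidationError(
                f"sequence {record.id!r} contains invalid residue(s) {sorted(bad)}"
            )
        sequences[record.id] = seq
    return sequences


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT annotation sets: name <tab> description <tab> member...

    Duplicate set names and member-less sets are hard errors; the
    description column is ignored.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs name, description "
                    f"and at least one member"
                )
            name, _desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise ValidationError(f"{path}:{lineno}: set {name!r} has no members")
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = set(members)
    return sets


def read_disorder(
    path: str | Path, sequences: Mapping[str, str] | None = None
) -> list[DisorderAnnotation]:
    """Read BED-like disorder intervals: protein_id, start, end (0-based half-open).

    When ``sequences`` is supplied every interval is cross-checked against
    the sequence length.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["protein_id", "start", "end"],
        dtype={"protein_id": str},
    )
    grouped: dict[str, list[tuple[int, int]]] = {}
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if start < 0 or start >= end:
            raise ValidationError(
                f"protein {row.protein_id!r}: invalid interval [{start}, {end})"
            )
        if sequences is not None:
            if row.protein_id not in sequences:
                raise ValidationError(
                    f"disorder interval for unknown protein {row.protein_id!r}"
                )
            length = len(sequences[row.protein_id])
            if end > length:
                raise ValidationError(
                    f"protein {row.protein_id!r}: interval end {end} exceeds "
                    f"sequence length {length}"
                )
        grouped.setdefault(row.protein_id, []).append((start, end))
    return [
        DisorderAnnotation.from_intervals(pid, ivals)
        for pid, ivals in grouped.items()
    ]


# ---------------------------------------------------------------------------
# writers


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a TSV with header, missing as empty string, floats at full precision."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", na_rep="", index=index)


def write_quant_table(table: QuantTable, path: str | Path) -> None:
    out = table.abundance.copy()
    out.index.name = "protein_id"
    write_table(out, path, index=True)


def write_sample_sheet(samples: Sequence[SampleMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "group": [s.group for s in samples],
            "replicate": [s.replicate for s in samples],
        }
    )
    write_table(df, path)


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as handle:
        for pid, seq in sequences.items():
            handle.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as handle:
        for name, members in sets.items():
            handle.write("\t".join([name, name] + sorted(members)) + "\n")


def write_disorder(annotations: Sequence[DisorderAnnotation], path: str | Path) -> None:
    rows = [
        {"protein_id": ann.protein_id, "start": start, "end": end}
        for ann in annotations
        for start, end in ann.intervals
    ]
    df = pd.DataFrame(rows, columns=["protein_id", "start", "end"])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", header=False, index=False)
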