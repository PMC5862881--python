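"""Readers, writers and validation for the tabular and sequence formats
used across the pipeline.

Conventions
-----------
* Tab-separated UTF-8 text with ``.`` decimal separator is the canonical
  tabular dialect for every matrix and table.
* All genomic intervals are 0-based half-open internally; conversions
  to/from 1-based formats (SAM) happen only at the read/write boundary.
* Expression matrices are strict: duplicate identifiers, non-numeric or
  missing cells are errors, matching a dataset quantified in all samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Literal, Optional

import numpy as np
import pandas as pd
import pysam

GROUPS = ("BPH", "PC", "CRPC")

Layer = Literal["protein", "mrna", "mirna_counts"]
Scale = Literal["linear", "log2"]


class FormatError(ValueError):
    """A file violated the expected dialect or an invariant."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A genes/miRNAs x samples quantitative layer.

    Parameters
    ----------
    values : pandas.DataFrame
        Features in rows (index = feature ids), samples in columns.
    layer : {"protein", "mrna", "mirna_counts"}
    scale : {"linear", "log2"}
    """

    values: pd.DataFrame
    layer: Layer = "protein"
    scale: Scale = "linear"

    def __post_init__(self) -> None:
        df = self.values
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dups[:5]}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if not np.isfinite(arr).all():
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(
                f"non-finite value at ({df.index[r]!r}, {df.columns[c]!r})"
            )
        if self.layer == "mirna_counts":
            if self.scale != "linear":
                raise FormatError("mirna_counts layer must be linear scale")
            if (arr < 0).any():
                raise FormatError("mirna_counts must be non-negative")
            if not np.allclose(arr, np.round(arr)):
                raise FormatError("mirna_counts must be integers")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        missing = set(sample_ids) - set(self.values.columns)
        if missing:
            raise KeyError(f"samples not in matrix: {sorted(missing)}")
        return replace(self, values=self.values[list(sample_ids)])

    def subset_features(self, feature_ids: list[str]) -> "ExpressionMatrix":
        missing = set(feature_ids) - set(self.values.index)
        if missing:
            raise KeyError(f"features not in matrix: {sorted(missing)[:5]}")
        return replace(self, values=self.values.loc[list(feature_ids)])


def read_expression_matrix(path: str | Path, layer: Layer = "protein",
                           scale: Scale = "linear") -> ExpressionMatrix:
    """Read a feature x sample TSV (header = sample ids, first column =
    feature ids) into a validated :class:`ExpressionMatrix`."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: header must name at least one sample")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: {exc}") from exc
    df.index = df.index.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise FormatError(
                f"{path}: non-numeric cell at (row {bad[0]!r}, column {col!r})"
            )
        if df[col].isna().any():
            row = df.index[df[col].isna()][0]
            raise FormatError(
                f"{path}: empty cell at (row {row!r}, column {col!r})"
            )
    try:
        return ExpressionMatrix(df, layer=layer, scale=scale)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

@dataclass
class SampleSheet:
    """Cohort design: sample ids, disease group, replicate links.

    ``replicate_of`` marks a column that is a technical replicate MS run
    of another sample; downstream analysis averages such pairs.
    """

    table: pd.DataFrame  # columns: sample_id, group, replicate_of

    def __post_init__(self) -> None:
        t = self.table
        required = {"sample_id", "group", "replicate_of"}
        if not required.issubset(t.columns):
            raise FormatError(f"sample sheet needs columns {sorted(required)}")
        if t["sample_id"].duplicated().any():
            raise FormatError("duplicate sample_id in sample sheet")
        bad = set(t["group"]) - set(GROUPS)
        if bad:
            raise FormatError(f"unknown group label(s): {sorted(bad)}")
        known = set(t["sample_id"])
        links = t["replicate_of"].dropna()
        links = links[links.astype(str).str.len() > 0]
        dangling = set(links) - known
        if dangling:
            raise FormatError(f"replicate_of points to missing sample(s): "
                              f"{sorted(dangling)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def group_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return row["group"].iloc[0]

    def samples_in_group(self, group: str, primary_only: bool = True) -> list[str]:
        if group not in GROUPS:
            raise KeyError(f"unknown group {group!r}")
        t = self.table
        sel = t["group"] == group
        if primary_only:
            sel &= t["replicate_of"].isna() | (t["replicate_of"].astype(str) == "")
        return list(t.loc[sel, "sample_id"])

    def group_counts(self) -> dict[str, int]:
        return {g: len(self.samples_in_group(g)) for g in GROUPS}

    def replicate_pairs(self) -> list[tuple[str, str]]:
        """(original, replicate) pairs of technical MS runs."""
        t = self.table
        out = []
        for _, row in t.iterrows():
            rep = row["replicate_of"]
            if isinstance(rep, str) and rep:
                out.append((rep, row["sample_id"]))
        return out


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df = df.replace({"replicate_of": {"": None}})
    if "group" in df.columns and (df["group"].astype(str) == "").any():
        raise FormatError(f"{path}: empty group label")
    try:
        return SampleSheet(df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# Copy number, mutation, miRNA-target tables
# ---------------------------------------------------------------------------

def read_copy_number_table(path: str | Path) -> pd.DataFrame:
    """Gene-level dosage table: columns gene_id, sample_id, copy_number
    and optional integer_cn; one row per (gene, sample)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "sample_id", "copy_number"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if (df["copy_number"] < 0).any():
        raise FormatError(f"{path}: negative copy number")
    if df.duplicated(["gene_id", "sample_id"]).any():
        raise FormatError(f"{path}: duplicate (gene, sample) row")
    return df


def copy_number_matrix(cn: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long-form copy-number table to genes x samples."""
    return cn.pivot(index="gene_id", columns="sample_id", values="copy_number")


def read_mutation_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "sample_id", "origin"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    bad = set(df["origin"]) - {"somatic", "germline"}
    if bad:
        raise FormatError(f"{path}: origin must be somatic/germline, got {bad}")
    return df


def read_mirna_target_table(path: str | Path) -> pd.DataFrame:
    """miRNA-target predictions with one boolean flag per database."""
    df = pd.read_csv(path, sep="\t")
    flag_cols = [c for c in df.columns if c.startswith("db_")]
    if len(flag_cols) != 3:
        raise FormatError(f"{path}: expected 3 db_* flag columns")
    df[flag_cols] = df[flag_cols].astype(bool)
    if not df[flag_cols].any(axis=1).all():
        raise FormatError(f"{path}: row with no supporting database")
    return df


# ---------------------------------------------------------------------------
# DMR tables (BED3+N dialect)
# ---------------------------------------------------------------------------

def read_dmr_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ DMR file.

    Expected dialect: a ``#``-prefixed header line naming the columns
    ``chrom start end dmr_id`` followed by one column per sample holding
    normalized fragment counts. Coordinates are 0-based half-open.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
    if not header.startswith("#"):
        raise FormatError(f"{path}: missing '#'-prefixed header line")
    names = header[1:].split()
    df = pd.read_csv(path, sep="\t", comment=None, skiprows=1, names=names)
    for col in ("chrom", "start", "end", "dmr_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if (df["start"] < 0).any():
        raise FormatError(f"{path}: negative coordinate")
    if (df["start"] >= df["end"]).any():
        bad = df.loc[df["start"] >= df["end"], "dmr_id"].iloc[0]
        raise FormatError(f"{path}: start >= end for DMR {bad!r}")
    sample_cols = [c for c in names if c not in
                   ("chrom", "start", "end", "dmr_id")]
    if sample_cols and (df[sample_cols] < 0).to_numpy().any():
        raise FormatError(f"{path}: negative fragment count")
    return df


def write_dmr_bed(dmrs: pd.DataFrame, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("#" + "\t".join(dmrs.columns) + "\n")
        dmrs.to_csv(fh, sep="\t", index=False, header=False)


def dmr_sample_columns(dmrs: pd.DataFrame) -> list[str]:
    return [c for c in dmrs.columns
            if c not in ("chrom", "start", "end", "dmr_id",
                         "assigned_gene", "tss_distance")]


def read_tss_table(path: str | Path) -> pd.DataFrame:
    """Transcription start sites: gene_id, chrom, position (0-based), strand."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "chrom", "position", "strand"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if not set(df["strand"]).issubset({"+", "-"}):
        raise FormatError(f"{path}: strand must be '+' or '-'")
    return df


# ---------------------------------------------------------------------------
# Alignments (SAM)
# ---------------------------------------------------------------------------

@dataclass
class AlignmentRecord:
    """Minimal view of one mate: 0-based position, or unmapped."""

    read_id: str
    chrom: Optional[str]
    pos: Optional[int]          # 0-based leftmost, None if unmapped
    mapq: int
    is_reverse: bool
    is_unmapped: bool
    sequence: str


@dataclass
class MatePair:
    read_id: str
    mate1: AlignmentRecord
    mate2: AlignmentRecord


def _to_record(aln: "pysam.AlignedSegment") -> AlignmentRecord:
    return AlignmentRecord(
        read_id=aln.query_name,
        chrom=None if aln.is_unmapped else aln.reference_name,
        pos=None if aln.is_unmapped else aln.reference_start,
        mapq=aln.mapping_quality,
        is_reverse=bool(aln.is_reverse),
        is_unmapped=bool(aln.is_unmapped),
        sequence=aln.query_sequence or "",
    )


def read_alignments(path: str | Path) -> Iterator[MatePair]:
    """Stream mate-joined records from a name-sorted SAM file.

    SAM's 1-based coordinates are converted to 0-based here (via pysam).
    Mates of a pair must be adjacent; otherwise the input is treated as
    unsorted and an error is raised. Records without a sequence are
    skipped with a warning.
    """
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        pending: Optional[pysam.AlignedSegment] = None
        seen: set[str] = set()
        for aln in sam:
            if not aln.query_sequence:
                warnings.warn(f"record {aln.query_name} has no sequence; skipped")
                continue
            if pending is None:
                pending = aln
                continue
            if aln.query_name != pending.query_name:
                raise FormatError(
                    f"{path}: mates not adjacent (is the SAM name-sorted?): "
                    f"{pending.query_name!r} unpaired"
                )
            if aln.query_name in seen:
                raise FormatError(f"{path}: read id {aln.query_name!r} repeats")
            seen.add(aln.query_name)
            first, second = ((pending, aln) if pending.is_read1
                             else (aln, pending))
            yield MatePair(aln.query_name, _to_record(first), _to_record(second))
            pending = None
        if pending is not None:
            raise FormatError(f"{path}: trailing unpaired record "
                              f"{pending.query_name!r}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (small) FASTA file into a name -> sequence dict."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with Path(path).open("w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
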