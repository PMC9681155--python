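"""Annotation and tabular IO with a single coordinate convention.

All intervals are stored 0-based half-open (BED convention). The two
annotation dialects differ only at the reader:

* ``bed6+3`` — BED6 plus three extra columns (subfamily, family, class);
  as a convenience the BED ``name`` field may instead carry the three
  labels joined by ``:`` (``RLTR45-int:ERVK:LTR``).
* ``repeatmasker_out`` — RepeatMasker ``.out``, whose 1-based inclusive
  start is converted by ``start - 1``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_SEX_CHROM_NAMES = frozenset({"chrX", "X", "chrY", "Y"})


class AnnotationParseError(ValueError):
    """A line of an annotation file could not be parsed."""


@dataclass(frozen=True)
class TELocus:
    """One annotated repeat interval; the unit of all locus-level analysis.

    Coordinates are 0-based half-open. ``subfamily`` and ``family`` carry
    RepeatMasker-style names verbatim (e.g. ``RLTR45-int`` / ``ERVK``).
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    subfamily: str = ""
    family: str = ""
    class_label: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"locus {self.locus_id!r}: end ({self.end}) must exceed start ({self.start})"
            )
        if not self.subfamily:
            raise ValueError(f"locus {self.locus_id!r}: subfamily must be nonempty")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"locus {self.locus_id!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene record: id, chromosome, TSS and gene body span.

    The TSS is 0-based: for a ``+``-strand gene it equals ``gene_start``,
    for a ``-``-strand gene ``gene_end - 1``.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str
    gene_start: int
    gene_end: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")
        if not (self.gene_start <= self.tss < self.gene_end):
            raise ValueError(
                f"gene {self.gene_id!r}: TSS {self.tss} outside gene body "
                f"[{self.gene_start}, {self.gene_end})"
            )


@dataclass
class SampleSheet:
    """Sample ids with condition labels (IVF / SCNT / KO groupings)."""

    table: pd.DataFrame  # columns: sample_id, condition, replicate

    def __post_init__(self) -> None:
        required = {"sample_id", "condition"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"sample sheet needs columns {sorted(required)}")
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample id {dup!r}")
        if "replicate" not in self.table.columns:
            self.table = self.table.assign(
                replicate=self.table.groupby("condition").cumcount() + 1
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def condition_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id, "condition"]
        if row.empty:
            raise KeyError(sample_id)
        return row.iloc[0]

    def samples_in(self, condition: str) -> list[str]:
        return list(self.table.loc[self.table["condition"] == condition, "sample_id"])

    def require_groups(self, a: str, b: str, min_per_group: int = 2) -> tuple[list[str], list[str]]:
        ga, gb = self.samples_in(a), self.samples_in(b)
        for name, grp in ((a, ga), (b, gb)):
            if len(grp) < min_per_group:
                raise ValueError(
                    f"condition {name!r} has {len(grp)} samples; need >= {min_per_group}"
                )
        return ga, gb


@dataclass
class CountMatrix:
    """Features x samples non-negative integer counts with feature lengths."""

    counts: pd.DataFrame  # index: feature ids; columns: sample ids; dtype int
    lengths: pd.Series  # bp per feature, aligned to counts.index

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r}")
        if not self.counts.index.equals(self.lengths.index):
            self.lengths = self.lengths.reindex(self.counts.index)
            if self.lengths.isna().any():
                missing = self.lengths.index[self.lengths.isna()][0]
                raise ValueError(f"no length for feature {missing!r}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(np.mod(vals, 1) == 0):
                bad = np.argwhere(np.mod(vals, 1) != 0)[0]
                raise ValueError(
                    f"non-integer count at feature {self.counts.index[bad[0]]!r}, "
                    f"sample {self.counts.columns[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts are not allowed")
        if (self.lengths <= 0).any():
            bad = self.lengths.index[self.lengths <= 0][0]
            raise ValueError(f"non-positive length for feature {bad!r}")
        self.lengths = self.lengths.astype(np.int64)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_features(self, feature_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(feature_ids)], self.lengths.loc[list(feature_ids)])

    def write(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "length", self.lengths)
        out.to_csv(path, sep="\t", index_label="feature_id")


def _parse_bed63_line(line: str, lineno: int, index: int) -> TELocus:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 6:
        raise AnnotationParseError(f"line {lineno}: expected >= 6 tab-separated fields")
    chrom, start_s, end_s, name, _score, strand = fields[:6]
    try:
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise AnnotationParseError(f"line {lineno}: non-integer coordinate") from exc
    if len(fields) >= 9:
        subfamily, family, class_label = fields[6], fields[7], fields[8]
        locus_id = name
    else:
        parts = name.split(":")
        if len(parts) != 3:
            raise AnnotationParseError(
                f"line {lineno}: name field must be subfamily:family:class when columns 7-9 absent"
            )
        subfamily, family, class_label = parts
        locus_id = f"{subfamily}|{chrom}:{start}-{end}|{index}"
    try:
        return TELocus(locus_id, chrom, start, end, strand, subfamily, family, class_label)
    except ValueError as exc:
        raise AnnotationParseError(f"line {lineno}: {exc}") from exc


def _parse_repeatmasker_line(line: str, lineno: int, index: int) -> TELocus | None:
    fields = line.split()
    if not fields:
        return None
    if fields[0] in {"SW", "score"}:  # header
        return None
    if len(fields) < 11:
        raise AnnotationParseError(f"line {lineno}: expected >= 11 whitespace fields")
    chrom = fields[4]
    try:
        begin, end = int(fields[5]), int(fields[6])
    except ValueError as exc:
        raise AnnotationParseError(f"line {lineno}: non-integer coordinate") from exc
    strand = "+" if fields[8] == "+" else "-"
    subfamily = fields[9]
    cls_fam = fields[10]
    if "/" in cls_fam:
        class_label, family = cls_fam.split("/", 1)
    else:
        class_label, family = cls_fam, cls_fam
    locus_id = f"{subfamily}|{chrom}:{begin - 1}-{end}|{index}"
    try:
        # RepeatMasker start is 1-based inclusive: convert to 0-based half-open.
        return TELocus(locus_id, chrom, begin - 1, end, strand, subfamily, family, class_label)
    except ValueError as exc:
        raise AnnotationParseError(f"line {lineno}: {exc}") from exc


def read_te_annotation(path: str | Path, dialect: str = "bed6+3") -> list[TELocus]:
    """Read a TE annotation as a list of :class:`TELocus`.

    Parameters
    ----------
    path : file path
    dialect : {"bed6+3", "repeatmasker_out"}

    Raises
    ------
    AnnotationParseError
        On a malformed line (the error names the line number).
    """
    if dialect not in {"bed6+3", "repeatmasker_out"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    loci: list[TELocus] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            if dialect == "bed6+3":
                locus = _parse_bed63_line(line, lineno, len(loci))
            else:
                locus = _parse_repeatmasker_line(line, lineno, len(loci))
            if locus is None:
                continue
            if locus.locus_id in seen:
                raise AnnotationParseError(f"line {lineno}: duplicate locus id {locus.locus_id!r}")
            seen.add(locus.locus_id)
            loci.append(locus)
    if not loci:
        warnings.warn(f"annotation file {path} contains no records", stacklevel=2)
    return loci


def write_te_annotation(loci: Iterable[TELocus], path: str | Path) -> None:
    """Write loci as BED6+3 (cols 7-9: subfamily, family, class)."""
    with open(path, "w") as fh:
        for lc in loci:
            fh.write(
                f"{lc.chrom}\t{lc.start}\t{lc.end}\t{lc.locus_id}\t0\t{lc.strand}"
                f"\t{lc.subfamily}\t{lc.family}\t{lc.class_label}\n"
            )


def filter_autosomes(features: Sequence) -> list:
    """Drop features on sex chromosomes (chrX/X/chrY/Y), keeping input order.

    IVF embryo pools mix sexes while SCNT embryos are clonal, so X/Y dosage
    differs systematically between conditions; sex chromosomes are removed
    before any group comparison.
    """
    return [f for f in features if f.chrom not in _SEX_CHROM_NAMES]


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read the minimal gene table (TSV: gene_id, chrom, tss, strand, start, end)."""
    df = pd.read_csv(path, sep="\t")
    required = ["gene_id", "chrom", "tss", "strand", "gene_start", "gene_end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"gene table missing columns {missing}")
    return [
        GeneModel(
            gene_id=str(r.gene_id),
            chrom=str(r.chrom),
            tss=int(r.tss),
            strand=str(r.strand),
            gene_start=int(r.gene_start),
            gene_end=int(r.gene_end),
        )
        for r in df.itertuples()
    ]


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        [
            (g.gene_id, g.chrom, g.tss, g.strand, g.gene_start, g.gene_end)
            for g in genes
        ],
        columns=["gene_id", "chrom", "tss", "strand", "gene_start", "gene_end"],
    ).to_csv(path, sep="\t", index=False)


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a TSV count matrix (feature_id, length, then one column per sample)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "length" not in df.columns:
        raise ValueError("count matrix must have a 'length' second column")
    lengths = df["length"]
    counts = df.drop(columns=["length"])
    if counts.isna().any().any():
        raise ValueError("count matrix has missing cells (ragged rows?)")
    return CountMatrix(counts, lengths)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)
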