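"""Readers and writers for the tabular and interval formats used by the pipeline.

Coordinate conventions
----------------------
Everything in memory is 0-based, half-open ``[start, end)``.  Conversion to
and from the 1-based conventions of GFF3 and cytosine reports happens here,
at the I/O boundary, and nowhere else.

Formats handled:

* sample sheets (TSV: sample_id, genotype, replicate),
* feature x sample integer count matrices (TSV, first column = feature id),
* per-sample cytosine reports in the Bismark ``CX`` dialect
  (chrom, 1-based pos, strand, methylated count, unmethylated count,
  context, trinucleotide — the trinucleotide column is optional and ignored),
* GFF3 gene tracks (1-based closed) and BED3/BED6 tracks (0-based half-open).

Parsers never drop rows silently: malformed input raises :class:`ParseError`
carrying the offending line number.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GENOTYPES = ("female", "male", "hybrid")
CONTEXTS = ("CG", "CHG", "CHH")
FEATURE_KINDS = ("miRNA", "sirna_cluster", "gene")
INTERVAL_KINDS = ("gene", "TE", "sirna_cluster", "dmr_bin", "other")

#: columns of the canonical in-memory cytosine table
CYTOSINE_COLUMNS = ("chrom", "pos0", "strand", "context", "meth_reads", "total_reads")


class ParseError(ValueError):
    """Malformed input; carries the 1-based line number when known."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.line = line


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleSheet:
    """Maps sample ids to genotype (female / male / hybrid) and replicate."""

    sample_ids: tuple[str, ...]
    genotypes: tuple[str, ...]
    replicates: tuple[int, ...]

    def __post_init__(self):
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_id in sample sheet")
        for g in self.genotypes:
            if g not in GENOTYPES:
                raise ValueError(f"unknown genotype {g!r}")
        for r in self.replicates:
            if r < 1:
                raise ValueError("replicate numbers must be positive")
        if not (len(self.sample_ids) == len(self.genotypes) == len(self.replicates)):
            raise ValueError("sample sheet columns have unequal lengths")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def samples_of(self, genotype: str) -> list[str]:
        if genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {genotype!r}")
        return [s for s, g in zip(self.sample_ids, self.genotypes) if g == genotype]

    def require_trio(self) -> None:
        for g in GENOTYPES:
            if not self.samples_of(g):
                raise ValueError(f"sample sheet has no {g} sample")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "genotype": self.genotypes,
             "replicate": self.replicates}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleSheet":
        return cls(
            tuple(str(s) for s in df["sample_id"]),
            tuple(str(g) for g in df["genotype"]),
            tuple(int(r) for r in df["replicate"]),
        )


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.lstrip("#") for c in df.columns]
    missing = {"sample_id", "genotype", "replicate"} - set(df.columns)
    if missing:
        raise ParseError(f"sample sheet missing columns {sorted(missing)}", path)
    df["replicate"] = df["replicate"].astype(int)
    return SampleSheet.from_frame(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    with open(path, "w") as fh:
        fh.write("#" )
        sheet.to_frame().to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

@dataclass
class TrioCountMatrix:
    """Integer counts for features across female/male/hybrid replicates.

    ``counts`` is a feature x sample DataFrame whose columns follow the
    sample-sheet order.  ``feature_kind`` records what the rows are
    (miRNAs, siRNA clusters or genes); it does not change any computation.
    """

    counts: pd.DataFrame
    samples: SampleSheet
    feature_kind: str = "sirna_cluster"

    def __post_init__(self):
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature_kind {self.feature_kind!r}")
        if list(self.counts.columns) != list(self.samples.sample_ids):
            raise ValueError("count matrix columns do not match sample sheet")
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r}")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    def genotype_columns(self, genotype: str) -> pd.DataFrame:
        return self.counts[self.samples.samples_of(genotype)]


def read_counts(path, sample_sheet: SampleSheet,
                feature_kind: str = "sirna_cluster") -> TrioCountMatrix:
    """Read a TSV count matrix (first column feature ids, header sample ids).

    The matrix is re-ordered to the sample-sheet column order.  Samples in
    the header that are absent from the sheet, duplicate feature ids and
    non-integer or negative cells are errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = (df.index.name or "feature_id").lstrip("#")
    unknown = [c for c in df.columns if c not in sample_sheet.sample_ids]
    if unknown:
        raise ParseError(f"unknown sample {unknown[0]!r} in header", path)
    absent = [s for s in sample_sheet.sample_ids if s not in df.columns]
    if absent:
        raise ParseError(f"sample {absent[0]!r} missing from matrix", path)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"duplicate feature id {dup!r}", path)
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        frac, _ = np.modf(values.astype(float))
        if np.any(frac != 0):
            bad = df.index[np.where(frac != 0)[0][0]]
            raise ParseError(f"non-integer count for feature {bad!r}", path)
        df = df.astype(np.int64)
    if (df.to_numpy() < 0).any():
        bad = df.index[np.where((df.to_numpy() < 0).any(axis=1))[0][0]]
        raise ParseError(f"negative count for feature {bad!r}", path)
    df = df[list(sample_sheet.sample_ids)]
    df.index = df.index.astype(str)
    df.index.name = "feature_id"
    return TrioCountMatrix(df, sample_sheet, feature_kind)


def write_counts(matrix: TrioCountMatrix, path) -> None:
    """Write a count matrix in the canonical formatting read_counts accepts."""
    with open(path, "w") as fh:
        fh.write("#feature_id\t" + "\t".join(matrix.counts.columns) + "\n")
        for fid, row in zip(matrix.counts.index, matrix.counts.to_numpy()):
            fh.write(fid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# genomic intervals (GFF3 / BED)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval with a feature kind and stable id.

    Strand '.' is allowed for clusters, DMR bins and TEs but not for genes:
    flank annotation needs gene orientation.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    kind: str = "other"
    id: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.id!r}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.kind not in INTERVAL_KINDS:
            raise ValueError(f"unknown interval kind {self.kind!r}")
        if self.kind == "gene" and self.strand == ".":
            raise ValueError(f"gene {self.id!r} must be stranded")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


def _check_unique_ids(intervals: Sequence[GenomicInterval], path) -> None:
    seen: set[str] = set()
    for iv in intervals:
        if iv.id in seen:
            raise ParseError(f"duplicate interval id {iv.id!r}", path)
        seen.add(iv.id)


def read_gff3_genes(path) -> list[GenomicInterval]:
    """Extract ``gene`` records from a GFF3 file as 0-based half-open intervals.

    GFF3 coordinates are 1-based closed; start becomes ``start - 1``.  The
    gene id is taken from the ``ID=`` attribute (the raw attribute column if
    absent).
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ParseError(f"GFF3 line has {len(parts)} columns", path, lineno)
            chrom, _, ftype, start, end, _, strand, _, attrs = parts[:9]
            if ftype != "gene":
                continue
            try:
                start0, end0 = int(start) - 1, int(end)
            except ValueError:
                raise ParseError("non-integer coordinates", path, lineno) from None
            if end0 <= start0:
                raise ParseError(f"empty interval after conversion "
                                 f"({start}..{end})", path, lineno)
            gid = attrs
            for chunk in attrs.split(";"):
                if chunk.startswith("ID="):
                    gid = chunk[3:]
                    break
            try:
                out.append(GenomicInterval(chrom, start0, end0, strand, "gene", gid))
            except ValueError as exc:
                raise ParseError(str(exc), path, lineno) from None
    _check_unique_ids(out, path)
    return out


def write_gff3_genes(genes: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\tsrnaheterosis\tgene\t{g.start + 1}\t{g.end}\t."
                     f"\t{g.strand}\t.\tID={g.id}\n")


def read_bed(path, kind: str = "other") -> list[GenomicInterval]:
    """Read BED3/BED6 (0-based half-open).  BED3 rows get strand '.' and a
    positional id ``<kind>_<n>``."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError("BED line needs >=3 columns", path, lineno)
            chrom, start, end = parts[0], parts[1], parts[2]
            try:
                start0, end0 = int(start), int(end)
            except ValueError:
                raise ParseError("non-integer coordinates", path, lineno) from None
            name = parts[3] if len(parts) >= 4 and parts[3] != "." \
                else f"{kind}_{lineno}"
            strand = parts[5] if len(parts) >= 6 else "."
            try:
                out.append(GenomicInterval(chrom, start0, end0, strand, kind, name))
            except ValueError as exc:
                raise ParseError(str(exc), path, lineno) from None
    _check_unique_ids(out, path)
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# cytosine reports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CytosineCall:
    """One cytosine in one sample: context, strand and read support."""

    sample_id: str
    chrom: str
    pos0: int
    strand: str
    context: str
    meth_reads: int
    total_reads: int

    def __post_init__(self):
        if self.context not in CONTEXTS:
            raise ValueError(f"invalid context {self.context!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.meth_reads < 0 or self.meth_reads > self.total_reads:
            raise ValueError("meth_reads must be in [0, total_reads]")


def read_cytosine_report(path, sample_id: str) -> pd.DataFrame:
    """Read a Bismark-style cytosine report for one sample.

    Expected columns: chrom, 1-based position, strand (+/-), methylated
    count, unmethylated count, context (CG/CHG/CHH); a seventh trinucleotide
    column is tolerated and ignored.  Positions are converted to 0-based;
    total_reads = methylated + unmethylated, so rows with zero coverage are
    retained (the >=5-read filter is applied downstream, never here).

    Returns a DataFrame with :data:`CYTOSINE_COLUMNS` and
    ``df.attrs["sample_id"]`` set.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "pos", "strand", "meth", "unmeth", "context", "tri"],
            usecols=range(7), dtype={"chrom": str},
            engine="c",
        )
    except pd.errors.ParserError:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "pos", "strand", "meth", "unmeth", "context"],
            dtype={"chrom": str},
        )
    bad_ctx = ~df["context"].isin(CONTEXTS)
    if bad_ctx.any():
        i = int(np.where(bad_ctx)[0][0])
        raise ParseError(f"malformed context {df['context'].iloc[i]!r}",
                         path, i + 1)
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        i = int(np.where(bad_strand)[0][0])
        raise ParseError(f"invalid strand {df['strand'].iloc[i]!r}", path, i + 1)
    meth = df["meth"].to_numpy()
    unmeth = df["unmeth"].to_numpy()
    if (meth < 0).any() or (unmeth < 0).any():
        i = int(np.where((meth < 0) | (unmeth < 0))[0][0])
        raise ParseError("negative counts", path, i + 1)
    out = pd.DataFrame({
        "chrom": df["chrom"].astype(str),
        "pos0": df["pos"].astype(np.int64) - 1,
        "strand": df["strand"],
        "context": df["context"],
        "meth_reads": meth.astype(np.int64),
        "total_reads": (meth + unmeth).astype(np.int64),
    })
    out.attrs["sample_id"] = sample_id
    return out


def write_cytosine_report(calls: pd.DataFrame, path) -> None:
    """Write the in-memory cytosine table back to the 1-based report dialect."""
    with open(path, "w") as fh:
        for row in calls.itertuples(index=False):
            unmeth = row.total_reads - row.meth_reads
            fh.write(f"{row.chrom}\t{row.pos0 + 1}\t{row.strand}\t"
                     f"{row.meth_reads}\t{unmeth}\t{row.context}\tNNN\n")


def cytosine_table(calls: Iterable[CytosineCall]) -> pd.DataFrame:
    """Build the canonical cytosine DataFrame from CytosineCall records."""
    calls = list(calls)
    df = pd.DataFrame(
        {
            "chrom": [c.chrom for c in calls],
            "pos0": np.array([c.pos0 for c in calls], dtype=np.int64),
            "strand": [c.strand for c in calls],
            "context": [c.context for c in calls],
            "meth_reads": np.array([c.meth_reads for c in calls], dtype=np.int64),
            "total_reads": np.array([c.total_reads for c in calls], dtype=np.int64),
        }
    )
    if calls:
        df.attrs["sample_id"] = calls[0].sample_id
    return df


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a result table as TSV with a '#'-prefixed header line."""
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=index)
    text = buf.getvalue()
    with open(path, "w") as fh:
        fh.write("#" + text)
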