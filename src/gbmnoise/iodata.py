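"""Readers and writers for the on-disk formats the pipeline touches.

All genomic coordinates are 1-based inclusive internally (GFF3 convention);
BED input is converted on read.  Parsers validate strictly and raise
:class:`FormatError` with a line number rather than silently coercing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

VALID_CONTEXTS = ("CG", "CHG", "CHH")
VALID_STRANDS = ("+", "-")

#: Column layouts for cytosine reports.  "cx" is the 7-column per-cytosine
#: report (chrom, pos, strand, meth, unmeth, context, trinucleotide); the
#: 6-column "coverage" layout (chrom, start, end, fraction, meth, unmeth)
#: carries no context column, so a fixed context must be supplied.
CYTOSINE_DIALECTS = ("cx", "coverage")


class FormatError(ValueError):
    """A malformed record in an input file."""


@dataclass(frozen=True)
class CytosineRecord:
    """Methylation evidence at one cytosine."""

    chrom: str
    pos: int  # 1-based
    strand: str
    context: str
    meth_count: int
    unmeth_count: int

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise FormatError(f"bad strand {self.strand!r}")
        if self.context not in VALID_CONTEXTS:
            raise FormatError(f"unknown context {self.context!r}")
        if self.meth_count < 0 or self.unmeth_count < 0:
            raise FormatError("negative count")
        if self.pos < 1:
            raise FormatError("position must be >= 1")


@dataclass
class GeneModel:
    """A gene span with its exon/UTR intervals; introns are derived.

    ``exons`` and ``utrs`` are lists of 1-based inclusive ``(start, end)``
    tuples.  Exons are merged on construction.  Introns are the parts of
    ``[start, end]`` covered by neither exon nor UTR.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    utrs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise FormatError(f"{self.gene_id}: end < start")
        self.exons = merge_intervals(self.exons)
        self.utrs = merge_intervals(self.utrs)
        for s, e in self.exons + self.utrs:
            if s < self.start or e > self.end:
                raise FormatError(
                    f"{self.gene_id}: feature {s}..{e} outside gene span "
                    f"{self.start}..{self.end}"
                )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def introns(self) -> list[tuple[int, int]]:
        covered = merge_intervals(self.exons + self.utrs)
        return subtract_intervals((self.start, self.end), covered)

    @property
    def exonic(self) -> list[tuple[int, int]]:
        """Exon ∪ UTR intervals (the annotated transcribed, spliced part)."""
        return merge_intervals(self.exons + self.utrs)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent 1-based inclusive intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if e < s:
            raise FormatError(f"interval end < start: {s}..{e}")
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract_intervals(
    span: tuple[int, int], remove: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Parts of ``span`` not covered by the (merged, sorted) ``remove`` set."""
    out = []
    cursor = span[0]
    for s, e in remove:
        if s > cursor:
            out.append((cursor, min(s - 1, span[1])))
        cursor = max(cursor, e + 1)
        if cursor > span[1]:
            break
    if cursor <= span[1]:
        out.append((cursor, span[1]))
    return [(s, e) for s, e in out if s <= e]


def interval_length(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s + 1 for s, e in intervals)


# ---------------------------------------------------------------------------
# cytosine reports
# ---------------------------------------------------------------------------

def parse_cytosine_report(
    path: str | os.PathLike,
    dialect: str = "cx",
    context: str | None = None,
) -> Iterator[CytosineRecord]:
    """Stream validated :class:`CytosineRecord` from a per-cytosine report.

    Parameters
    ----------
    dialect
        ``"cx"`` for the 7-column per-cytosine layout or ``"coverage"`` for
        the 6-column coverage layout (which requires ``context``).
    context
        Fixed context assigned to every record of a ``coverage`` file.
    """
    if dialect not in CYTOSINE_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    if dialect == "coverage" and context not in VALID_CONTEXTS:
        raise ValueError("coverage dialect requires an explicit context")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if dialect == "cx":
                    if len(parts) < 6:
                        raise FormatError("expected >= 6 columns")
                    chrom, pos, strand, meth, unmeth, ctx = parts[:6]
                else:
                    if len(parts) < 6:
                        raise FormatError("expected 6 columns")
                    chrom, pos, _end, _frac, meth, unmeth = parts[:6]
                    strand, ctx = "+", context
                yield CytosineRecord(
                    chrom=chrom,
                    pos=int(pos),
                    strand=strand,
                    context=ctx,
                    meth_count=int(meth),
                    unmeth_count=int(unmeth),
                )
            except (FormatError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc


def read_cytosine_table(
    path: str | os.PathLike, dialect: str = "cx", context: str | None = None
) -> pd.DataFrame:
    """Read a whole cytosine report into a DataFrame (bulk, vectorised
    counterpart of :func:`parse_cytosine_report`; same validation)."""
    if dialect not in CYTOSINE_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    if dialect == "coverage" and context not in VALID_CONTEXTS:
        raise ValueError("coverage dialect requires an explicit context")
    names = (
        ["chrom", "pos", "strand", "meth", "unmeth", "context", "tri"]
        if dialect == "cx"
        else ["chrom", "pos", "end", "frac", "meth", "unmeth"]
    )
    try:
        tab = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=names, usecols=range(len(names)),
            dtype={"chrom": str, "pos": np.int64, "meth": np.int64,
                   "unmeth": np.int64},
        )
    except (ValueError, pd.errors.ParserError):
        # slow path pinpoints the offending line
        return cytosine_frame(
            parse_cytosine_report(path, dialect=dialect, context=context)
        )
    if dialect == "coverage":
        tab["strand"] = "+"
        tab["context"] = context
    bad = (
        ~tab["context"].isin(VALID_CONTEXTS)
        | ~tab["strand"].isin(VALID_STRANDS)
        | (tab["meth"] < 0)
        | (tab["unmeth"] < 0)
        | (tab["pos"] < 1)
    )
    if bad.any():
        # re-parse through the streaming validator for a line-numbered error
        list(parse_cytosine_report(path, dialect=dialect, context=context))
        raise FormatError(f"{path}: malformed record")  # pragma: no cover
    return tab[["chrom", "pos", "strand", "context", "meth", "unmeth"]]


def cytosine_frame(records: Iterable[CytosineRecord]) -> pd.DataFrame:
    rows = [
        (r.chrom, r.pos, r.strand, r.context, r.meth_count, r.unmeth_count)
        for r in records
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "meth", "unmeth"]
    )


def write_cytosine_report(path: str | os.PathLike, table: pd.DataFrame) -> None:
    """Write a cytosine table in the 7-column ``cx`` layout."""
    out = table.copy()
    out["tri"] = out["context"]
    out[["chrom", "pos", "strand", "meth", "unmeth", "context", "tri"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_UTR_TYPES = {"five_prime_UTR", "three_prime_UTR", "UTR"}


def parse_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from GFF3, one primary transcript per gene.

    When a gene has several mRNAs the longest (genomic span) one provides the
    exon/UTR structure.  Exons are merged; coordinates stay 1-based inclusive.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if mrnas:
            tx = max(mrnas, key=lambda m: m.end - m.start)
            exon_parent = tx
        else:
            exon_parent = gene
        exons = [
            (f.start, f.end) for f in db.children(exon_parent, featuretype="exon")
        ]
        utrs = [
            (f.start, f.end)
            for t in _UTR_TYPES
            for f in db.children(exon_parent, featuretype=t)
        ]
        for s, e in exons + utrs:
            if s < gene.start or e > gene.end:
                raise FormatError(
                    f"{gene.id}: exon/UTR {s}..{e} outside gene span "
                    f"{gene.start}..{gene.end}"
                )
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                start=gene.start,
                end=gene.end,
                exons=exons,
                utrs=utrs,
            )
        )
    return genes


def write_gff3(path: str | os.PathLike, genes: Sequence[GeneModel]) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/UTR features), in the
    canonical (chrom, start) order the parser also returns."""
    genes = sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tgbmnoise\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            mrna_id = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\tgbmnoise\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tgbmnoise\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"Parent={mrna_id}\n"
                )
            for s, e in g.utrs:
                at_start = abs(s - g.start) <= abs(g.end - e)
                five = at_start == (g.strand == "+")
                utype = "five_prime_UTR" if five else "three_prime_UTR"
                fh.write(
                    f"{g.chrom}\tgbmnoise\t{utype}\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"Parent={mrna_id}\n"
                )


# ---------------------------------------------------------------------------
# expression matrices / plain tables
# ---------------------------------------------------------------------------

def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a genes x cells FPKM matrix from TSV (header = cell ids, first
    column = gene ids).  Validates uniqueness, numeric dtype, non-negativity.
    """
    mat = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if mat.index.duplicated().any():
        dup = mat.index[mat.index.duplicated()][0]
        raise FormatError(f"duplicated gene id {dup!r}")
    if mat.columns.duplicated().any():
        raise FormatError("duplicated cell id")
    try:
        mat = mat.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric cell: {exc}") from exc
    if mat.isna().any().any():
        raise FormatError("missing entries in matrix")
    if (mat.values < 0).any():
        raise FormatError("negative FPKM")
    return mat


def write_matrix(path: str | os.PathLike, matrix: pd.DataFrame) -> None:
    # default float repr round-trips float64 exactly
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a per-gene table (features, ground truth, ...) indexed by gene_id."""
    tab = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if tab.index.duplicated().any():
        raise FormatError("duplicated gene id in table")
    return tab


def write_table(path: str | os.PathLike, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# BED reads
# ---------------------------------------------------------------------------

def read_bed_reads(path: str | os.PathLike) -> pd.DataFrame:
    """Read BED6 read intervals; converts to 1-based inclusive coordinates.

    Returns columns chrom, start, end (1-based inclusive), name (cell id),
    strand.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise FormatError(f"{path}:{lineno}: read end <= start")
            name = parts[3] if len(parts) > 3 else "."
            strand = parts[5] if len(parts) > 5 else "+"
            rows.append((chrom, start + 1, end, name, strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])


def write_bed_reads(path: str | os.PathLike, reads: pd.DataFrame) -> None:
    """Write reads (1-based inclusive) as BED6 (0-based half-open)."""
    out = pd.DataFrame(
        {
            "chrom": reads["chrom"],
            "start": reads["start"] - 1,
            "end": reads["end"],
            "name": reads["name"],
            "score": 0,
            "strand": reads["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)
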