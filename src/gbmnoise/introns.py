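"""Intron derivation, intron/exon read counting, and intron FPKM.

Introns of a non-overlapping gene are the positions of its span covered by
neither exon nor UTR.  Reads are counted in two independent passes — once
against the intron set, once against the annotated exon set — so a
junction-spanning read increments both tallies.  FPKM uses pooled counts
across cells and the pooled library size.
"""

from __future__ import annotations

import math
import os
from typing import Sequence

import numpy as np
import pandas as pd

from .iodata import GeneModel, interval_length


# ---------------------------------------------------------------------------
# gene-level interval work
# ---------------------------------------------------------------------------

def flag_overlapping_genes(genes: Sequence[GeneModel]) -> list[GeneModel]:
    """Drop every gene whose span intersects another gene's span on either
    strand; both members of an overlapping pair are removed."""
    bad: set[str] = set()
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for glist in by_chrom.values():
        glist.sort(key=lambda g: (g.start, g.end))
        max_end = -1
        max_end_gene = None
        for g in glist:
            if max_end_gene is not None and g.start <= max_end:
                bad.add(g.gene_id)
                bad.add(max_end_gene.gene_id)
            if g.end > max_end:
                max_end, max_end_gene = g.end, g
    return [g for g in genes if g.gene_id not in bad]


def derive_introns(gene: GeneModel) -> list[tuple[int, int]]:
    """Intron intervals: the gene span minus merged exon and UTR intervals."""
    return gene.introns


def modified_annotation_records(gene: GeneModel) -> list[tuple]:
    """gene/mRNA/"exon" records where the *introns* are the features typed
    "exon" — the relabelling trick that lets exon-counting tools count
    intronic reads against the modified annotation."""
    mrna_id = f"{gene.gene_id}.1"
    recs = [
        (gene.chrom, "gene", gene.start, gene.end, gene.strand,
         f"ID={gene.gene_id}"),
        (gene.chrom, "mRNA", gene.start, gene.end, gene.strand,
         f"ID={mrna_id};Parent={gene.gene_id}"),
    ]
    for s, e in gene.introns:
        recs.append((gene.chrom, "exon", s, e, gene.strand, f"Parent={mrna_id}"))
    return recs


def write_modified_annotation(path: str | os.PathLike,
                              genes: Sequence[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            for chrom, ftype, s, e, strand, attrs in modified_annotation_records(g):
                fh.write(
                    f"{chrom}\tgbmnoise\t{ftype}\t{s}\t{e}\t.\t{strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# read counting
# ---------------------------------------------------------------------------

class _DisjointIntervals:
    """Per-chromosome sorted, pairwise-disjoint intervals tagged by gene."""

    def __init__(self, per_gene: list[tuple[int, list[tuple[int, int]]]],
                 chroms: list[str]):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        buf: dict[str, list[tuple[int, int, int]]] = {}
        for (gidx, ivs), chrom in zip(per_gene, chroms):
            for s, e in ivs:
                buf.setdefault(chrom, []).append((s, e, gidx))
        for chrom, triples in buf.items():
            triples.sort()
            starts = np.array([t[0] for t in triples])
            ends = np.array([t[1] for t in triples])
            gidx = np.array([t[2] for t in triples])
            if np.any(starts[1:] <= ends[:-1]):
                raise ValueError(
                    "feature intervals overlap; run flag_overlapping_genes first"
                )
            self.by_chrom[chrom] = (starts, ends, gidx)


def _count_pass(
    reads: pd.DataFrame, index: _DisjointIntervals, n_genes: int, min_overlap: int
) -> np.ndarray:
    counts = np.zeros(n_genes, dtype=int)
    for chrom, sub in reads.groupby("chrom", sort=False):
        if chrom not in index.by_chrom:
            continue
        starts, ends, gidx = index.by_chrom[chrom]
        rs = sub["start"].to_numpy()
        re_ = sub["end"].to_numpy()
        if np.any(re_ < rs):
            raise ValueError("read with end < start")
        lo = np.searchsorted(ends, rs, side="left")
        hi = np.searchsorted(starts, re_, side="right")
        span = hi - lo
        one = span == 1
        if one.any():
            j = lo[one]
            ov = (np.minimum(ends[j], re_[one])
                  - np.maximum(starts[j], rs[one]) + 1)
            ok = ov >= min_overlap
            np.add.at(counts, gidx[j[ok]], 1)
        for i in np.flatnonzero(span >= 2):
            per_gene: dict[int, int] = {}
            for j in range(lo[i], hi[i]):
                ov = min(ends[j], re_[i]) - max(starts[j], rs[i]) + 1
                if ov > 0:
                    per_gene[gidx[j]] = per_gene.get(gidx[j], 0) + ov
            for g, o in per_gene.items():
                if o >= min_overlap:
                    counts[g] += 1
    return counts


def count_reads(
    reads: pd.DataFrame,
    genes: Sequence[GeneModel],
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Intron and exon read counts per (non-overlapping) gene.

    A read increments a gene's intron tally when its total overlap with the
    gene's intron set is >= ``min_overlap`` bp; the exon tally is counted in
    a separate pass against the annotated exon/UTR set, so junction reads
    count toward both.  Reads use 1-based inclusive coordinates.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    chroms = [g.chrom for g in genes]
    intron_idx = _DisjointIntervals(
        [(i, g.introns) for i, g in enumerate(genes)], chroms
    )
    exon_idx = _DisjointIntervals(
        [(i, g.exonic) for i, g in enumerate(genes)], chroms
    )
    n = len(genes)
    intron_reads = _count_pass(reads, intron_idx, n, min_overlap)
    exon_reads = _count_pass(reads, exon_idx, n, min_overlap)
    out = pd.DataFrame(
        {
            "intron_reads": intron_reads,
            "exon_reads": exon_reads,
            "total_reads": intron_reads + exon_reads,
            "total_intron_length": [interval_length(g.introns) for g in genes],
            "intron_number": [len(g.introns) for g in genes],
            "gene_length": [g.length for g in genes],
        },
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
    )
    return out


# ---------------------------------------------------------------------------
# FPKM
# ---------------------------------------------------------------------------

def compute_fpkm(count: float, feature_length_bp: float,
                 library_fragments: float) -> float:
    """FPKM = count / ((length/1e3) * (library/1e6))."""
    if feature_length_bp <= 0:
        raise ValueError("zero-length feature")
    if library_fragments <= 0:
        raise ValueError("empty library")
    return count / ((feature_length_bp / 1e3) * (library_fragments / 1e6))


def add_fpkm(rows: pd.DataFrame, library_fragments: int | None = None) -> pd.DataFrame:
    """Attach intron FPKM (over total intron length) and total FPKM (over
    gene length).  Genes without introns get intron FPKM 0."""
    out = rows.copy()
    if library_fragments is None:
        library_fragments = int(out["total_reads"].sum())
    if library_fragments <= 0:
        raise ValueError("library has no fragments")
    denom = library_fragments / 1e6
    out["intron_fpkm"] = [
        (r.intron_reads / ((r.total_intron_length / 1e3) * denom))
        if r.intron_number > 0
        else 0.0
        for r in out.itertuples()
    ]
    out["total_fpkm"] = out["total_reads"] / ((out["gene_length"] / 1e3) * denom)
    return out


def filter_intron_genes(
    rows: pd.DataFrame, threshold: float = 1.5, log_base: float = 2.0
) -> pd.DataFrame:
    """Keep genes with log(total FPKM + 1) > threshold, the same filter the
    expression-noise analysis applies."""
    score = np.log(rows["total_fpkm"] + 1.0) / math.log(log_base)
    return rows.loc[score > threshold]
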