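"""Binomial-tail classification of genes into gbM / unmethylated /
ambiguous / highly-methylated-non-gbM.

A gene's per-context methylation level (methylated calls k over total calls
n, pooled over all covered cytosines in the gene body, both strands) is
compared with the genomic background — the pooled average level over all
genes — via the upper tail of Binomial(n, background).  Decision rules:

* P_CHG < alpha or P_CHH < alpha        -> highly methylated non-gbM
* else P_CG < alpha                     -> gbM
* else P_CG > 1 - alpha                 -> unmethylated
* else                                  -> ambiguous

Only genes called gbM or unmethylated in both replicates keep a consensus
label.  A context with no covered cytosine gets P = 1 (it cannot be
significantly *higher* than background).  The raw 0.05/0.95 thresholds are
applied without multiple-testing correction, and the upper tail includes the
observed count, P(X >= k), so the two thresholds are symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from .config import AMBIGUOUS, GBM, HIGHLY_METHYLATED, NO_CONSENSUS, UNMETHYLATED
from .iodata import GeneModel

CONTEXTS = ("CG", "CHG", "CHH")
REGION_MODES = ("gene_body", "exons_only")


@dataclass(frozen=True)
class GeneMethylationSummary:
    """Per-context (k, n) counts for one gene."""

    gene_id: str
    k: dict  # context -> methylated calls
    n: dict  # context -> total calls

    def level(self, context: str) -> float:
        n = self.n[context]
        return self.k[context] / n if n > 0 else float("nan")


@dataclass(frozen=True)
class MethylationCall:
    gene_id: str
    label: str
    p: dict  # context -> upper-tail probability


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

class _ContextIndex:
    """Sorted position index with prefix sums, per (chrom, context)."""

    def __init__(self, cytosines: pd.DataFrame):
        self.by_key: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for (chrom, ctx), sub in cytosines.groupby(
            ["chrom", "context"], sort=False, observed=True
        ):
            pos = sub["pos"].to_numpy()
            order = np.argsort(pos, kind="stable")
            pos = pos[order]
            meth = sub["meth"].to_numpy()[order]
            total = meth + sub["unmeth"].to_numpy()[order]
            # pool calls on either strand at the same position
            self.by_key[(chrom, ctx)] = (
                pos,
                np.concatenate([[0], np.cumsum(meth)]),
                np.concatenate([[0], np.cumsum(total)]),
            )

    def sums(self, chrom: str, ctx: str, intervals) -> tuple[int, int]:
        key = (chrom, ctx)
        if key not in self.by_key:
            return 0, 0
        pos, cmeth, ctot = self.by_key[key]
        k = n = 0
        for s, e in intervals:
            lo = np.searchsorted(pos, s, side="left")
            hi = np.searchsorted(pos, e, side="right")
            k += int(cmeth[hi] - cmeth[lo])
            n += int(ctot[hi] - ctot[lo])
        return k, n


def summarize_gene(
    cytosines: pd.DataFrame, gene: GeneModel, region_mode: str = "gene_body"
) -> GeneMethylationSummary:
    """(k, n) per context over the gene body or its exons only."""
    index = _ContextIndex(cytosines)
    return _summarize_one(index, gene, region_mode)


def _summarize_one(
    index: _ContextIndex, gene: GeneModel, region_mode: str
) -> GeneMethylationSummary:
    if region_mode not in REGION_MODES:
        raise ValueError(f"region_mode must be one of {REGION_MODES}")
    intervals = (
        [(gene.start, gene.end)] if region_mode == "gene_body" else gene.exonic
    )
    k, n = {}, {}
    for ctx in CONTEXTS:
        k[ctx], n[ctx] = index.sums(gene.chrom, ctx, intervals)
    return GeneMethylationSummary(gene_id=gene.gene_id, k=k, n=n)


def summarize_genes(
    cytosines: pd.DataFrame, genes: list[GeneModel], region_mode: str = "gene_body"
) -> pd.DataFrame:
    """Bulk summary: one row per gene with k_/n_ columns per context."""
    index = _ContextIndex(cytosines)
    rows = []
    for g in genes:
        s = _summarize_one(index, g, region_mode)
        rows.append(
            [s.k["CG"], s.n["CG"], s.k["CHG"], s.n["CHG"], s.k["CHH"], s.n["CHH"]]
        )
    return pd.DataFrame(
        rows,
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
        columns=["k_CG", "n_CG", "k_CHG", "n_CHG", "k_CHH", "n_CHH"],
    )


# ---------------------------------------------------------------------------
# background and tails
# ---------------------------------------------------------------------------

def compute_background(summaries: pd.DataFrame, method: str = "mean_of_levels") -> dict:
    """Genomic-average methylation level per context.

    ``mean_of_levels`` (default) averages per-gene levels k/n over genes
    with coverage, weighting every gene equally; ``pooled`` uses the
    read-weighted ratio sum(k)/sum(n).  The two coincide under equal
    coverage.  Pooled weighting lets long genes dominate, which inflates the
    CG background whenever methylation covaries with length (as it does for
    gbM genes), so the equal-weight form is the default.
    """
    if method not in ("mean_of_levels", "pooled"):
        raise ValueError(f"unknown background method {method!r}")
    bg = {}
    for ctx in CONTEXTS:
        k = summaries[f"k_{ctx}"].to_numpy(dtype=float)
        n = summaries[f"n_{ctx}"].to_numpy(dtype=float)
        covered = n > 0
        if not covered.any():
            raise ValueError(f"no covered cytosines in context {ctx}")
        if method == "pooled":
            bg[ctx] = float(k.sum() / n.sum())
        else:
            bg[ctx] = float(np.mean(k[covered] / n[covered]))
    return bg


def binom_upper_tail(k, n, p):
    """P(X >= k) for X ~ Binomial(n, p); accepts scalars or arrays.

    Uses the survival function, numerically stable for n up to >= 1e6.
    """
    k = np.asarray(k)
    n = np.asarray(n)
    p_arr = np.asarray(p, dtype=float)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("require 0 <= k <= n")
    if np.any(p_arr < 0) or np.any(p_arr > 1):
        raise ValueError("require p in [0, 1]")
    out = binom.sf(k - 1, n, p_arr)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_gene(
    summary: GeneMethylationSummary, background: dict, alpha: float = 0.05
) -> MethylationCall:
    """Classify one gene from its (k, n) counts and the genomic background."""
    p = {}
    for ctx in CONTEXTS:
        n = summary.n[ctx]
        p[ctx] = binom_upper_tail(summary.k[ctx], n, background[ctx]) if n > 0 else 1.0
    label = _decide(p["CG"], p["CHG"], p["CHH"], alpha)
    return MethylationCall(gene_id=summary.gene_id, label=label, p=p)


def _decide(p_cg: float, p_chg: float, p_chh: float, alpha: float) -> str:
    if p_chg < alpha or p_chh < alpha:
        return HIGHLY_METHYLATED
    if p_cg < alpha:
        return GBM
    if p_cg > 1.0 - alpha:
        return UNMETHYLATED
    return AMBIGUOUS


def classify_genes(
    summaries: pd.DataFrame, background: dict | None = None, alpha: float = 0.05
) -> pd.DataFrame:
    """Vectorised classification of a summary table.

    Returns a frame with per-context tail probabilities and the class label.
    When ``background`` is omitted it is pooled from ``summaries`` itself.
    """
    if background is None:
        background = compute_background(summaries)
    out = pd.DataFrame(index=summaries.index.copy())
    for ctx in CONTEXTS:
        k = summaries[f"k_{ctx}"].to_numpy()
        n = summaries[f"n_{ctx}"].to_numpy()
        p = np.ones(len(summaries))
        covered = n > 0
        p[covered] = binom.sf(k[covered] - 1, n[covered], background[ctx])
        out[f"P_{ctx}"] = p
    label = np.full(len(out), AMBIGUOUS, dtype=object)
    p_cg = out["P_CG"].to_numpy()
    high = (out["P_CHG"].to_numpy() < alpha) | (out["P_CHH"].to_numpy() < alpha)
    label[(~high) & (p_cg < alpha)] = GBM
    label[(~high) & (p_cg > 1 - alpha)] = UNMETHYLATED
    label[high] = HIGHLY_METHYLATED
    out["label"] = label
    return out


def consensus_call(label_rep1: str, label_rep2: str) -> str:
    """Replicate consensus: a final gbM/unmethylated label needs agreement in
    both replicates; anything else gets no label."""
    if label_rep1 == label_rep2 and label_rep1 in (GBM, UNMETHYLATED):
        return label_rep1
    return NO_CONSENSUS


def consensus_calls(calls1: pd.DataFrame, calls2: pd.DataFrame) -> pd.Series:
    common = calls1.index.intersection(calls2.index)
    l1 = calls1.loc[common, "label"]
    l2 = calls2.loc[common, "label"]
    agree = (l1 == l2) & l1.isin([GBM, UNMETHYLATED])
    out = pd.Series(NO_CONSENSUS, index=common, name="consensus", dtype=object)
    out[agree] = l1[agree]
    return out


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

_STRICT = (GBM, UNMETHYLATED, HIGHLY_METHYLATED)


def concordance_report(
    calls_a: pd.DataFrame, calls_b: pd.DataFrame, reference_label: str
) -> dict:
    """Cross-dataset concordance for the genes dataset A calls
    ``reference_label`` (gbM or unmethylated).

    Fractions over genes present in both call sets:
    ``identical`` (same class in B), ``strictly_conflicting`` (B assigns a
    different one of gbM/unmethylated/highly-methylated), ``intermediate``
    (B says ambiguous).  The three sum to 1.
    """
    ref = calls_a.index[calls_a["label"] == reference_label]
    common = ref.intersection(calls_b.index)
    if len(common) == 0:
        raise ValueError("no shared genes with the reference label")
    b = calls_b.loc[common, "label"]
    identical = (b == reference_label).mean()
    conflicting = (b.isin(_STRICT) & (b != reference_label)).mean()
    intermediate = (b == AMBIGUOUS).mean()
    return {
        "n": int(len(common)),
        "identical": float(identical),
        "strictly_conflicting": float(conflicting),
        "intermediate": float(intermediate),
    }
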