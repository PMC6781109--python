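"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the statistical structure the downstream analysis
assumes: a gene census split into gbM / unmethylated / highly-methylated /
ambiguous classes, two replicate methylomes with CG-specific enrichment in
gbM genes, a 20-cell FPKM matrix whose log-variance follows a cubic
polynomial in log-mean, genomic covariates collinear with gbM through a
Gaussian copula, and class-specific intron-read fractions.

Expression consistency is planted by moment-preserving zero inflation: each
gene gets a per-cell detection probability ``pi``; a cell is zero with
probability 1 - pi and the nonzero draws are compensated (mean M/pi,
variance adjusted) so the gene's marginal mean and variance equal the
planted (M, V) regardless of pi.  A direct gbM effect on detection
therefore moves consistency without moving measured noise to first order.

Every stage draws from an RNG derived from ``(config.seed, stage name)``, so
stages are independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import (
    AMBIGUOUS,
    FEATURE_COLUMNS,
    GBM,
    HIGHLY_METHYLATED,
    UNMETHYLATED,
    SimConfig,
)
from .iodata import GeneModel


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible RNG stream for one pipeline stage."""
    tag = zlib.crc32(stage.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig) -> list[GeneModel]:
    """Gene models with 1..max_exons exons, terminal UTRs, and a configurable
    fraction of overlapping gene pairs (to exercise the overlap filter)."""
    config.validate()
    rng = stage_rng(config.seed, "genome")
    n = config.n_genes
    lengths = np.exp(
        rng.normal(config.gene_length_meanlog, config.gene_length_sdlog, size=n)
    )
    lengths = np.maximum(lengths.astype(int), config.min_gene_length)
    chroms = np.array(
        [f"Chr{1 + i % config.n_chromosomes}" for i in range(n)]
    )
    order = np.argsort(chroms, kind="stable")
    genes: list[GeneModel] = []
    cursor: dict[str, int] = {}
    prev: dict[str, tuple[int, int]] = {}
    for idx in order:
        chrom = chroms[idx]
        length = int(lengths[idx])
        pos = cursor.get(chrom, 1)
        if chrom in prev and rng.random() < config.overlap_fraction:
            ps, pe = prev[chrom]
            start = int(ps + rng.integers(1, max(pe - ps, 2)))
        else:
            start = pos + int(rng.exponential(config.intergenic_mean)) + 50
        end = start + length - 1
        strand = "+" if rng.random() < 0.5 else "-"
        exons = _random_exons(rng, start, end, config.max_exons)
        utrs = _terminal_utrs(exons)
        gid = f"SG{idx + 1:05d}"
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                start=start,
                end=end,
                exons=exons,
                utrs=utrs,
            )
        )
        cursor[chrom] = max(pos, end + 1)
        prev[chrom] = (start, end)
    genes.sort(key=lambda g: int(g.gene_id[2:]))
    return genes


def _random_exons(
    rng: np.random.Generator, start: int, end: int, max_exons: int
) -> list[tuple[int, int]]:
    length = end - start + 1
    # cap exon count so every exon/intron segment is >= ~30 bp
    n_ex = int(rng.integers(1, max_exons + 1))
    n_ex = max(1, min(n_ex, length // 60))
    if n_ex == 1:
        return [(start, end)]
    n_seg = 2 * n_ex - 1
    cuts = np.sort(rng.choice(np.arange(1, length), size=n_seg - 1, replace=False))
    bounds = np.concatenate([[0], cuts, [length]])
    exons = []
    for i in range(n_seg):
        if i % 2 == 0:  # exon segments alternate, first and last are exons
            s = start + int(bounds[i])
            e = start + int(bounds[i + 1]) - 1
            exons.append((s, e))
    return exons


def _terminal_utrs(exons: list[tuple[int, int]]) -> list[tuple[int, int]]:
    utrs = []
    s, e = exons[0]
    utr_len = min(100, max((e - s + 1) * 3 // 10, 1))
    utrs.append((s, s + utr_len - 1))
    s, e = exons[-1]
    utr_len = min(100, max((e - s + 1) * 3 // 10, 1))
    utrs.append((e - utr_len + 1, e))
    return utrs


# ---------------------------------------------------------------------------
# classes and methylomes
# ---------------------------------------------------------------------------

def _point_biserial_factor(p: float) -> float:
    """corr(indicator(Z>t), Z) for standard normal Z thresholded at quantile
    1-p; used to convert planted indicator-feature correlations to latent
    correlations."""
    t = norm.ppf(1.0 - p)
    return float(norm.pdf(t) / np.sqrt(p * (1.0 - p)))


def assign_classes(config: SimConfig, genes: list[GeneModel]) -> pd.DataFrame:
    """Assign a planted methylation class per gene.

    gbM status is thresholded from a latent correlated with (standardised)
    log gene length so that the planted gbM-length correlation is realised;
    the remaining classes are drawn by their renormalised proportions.
    """
    rng = stage_rng(config.seed, "methylome")
    n = len(genes)
    lengths = np.array([g.length for g in genes], dtype=float)
    z_len = (np.log(lengths) - config.gene_length_meanlog) / config.gene_length_sdlog
    p_gbm = config.class_proportions[GBM]
    c = _point_biserial_factor(p_gbm)
    a = np.clip(config.gbm_feature_corr["gene_length"] / c, -config.correlation_cap,
                config.correlation_cap)
    latent = a * z_len + np.sqrt(1.0 - a**2) * rng.standard_normal(n)
    n_gbm = int(round(p_gbm * n))
    gbm_idx = np.argsort(latent)[::-1][:n_gbm]
    is_gbm = np.zeros(n, dtype=bool)
    is_gbm[gbm_idx] = True

    cls = np.empty(n, dtype=object)
    cls[is_gbm] = GBM
    rest = np.flatnonzero(~is_gbm)
    others = [UNMETHYLATED, HIGHLY_METHYLATED, AMBIGUOUS]
    probs = np.array([config.class_proportions[c_] for c_ in others])
    probs = probs / probs.sum()
    cls[rest] = rng.choice(others, size=rest.size, p=probs)

    truth = pd.DataFrame(
        {
            "class": cls,
            "is_gbm": is_gbm.astype(int),
            "gene_length": lengths.astype(int),
            "z_length": z_len,
            "class_latent": latent,
        },
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
    )
    # per-gene true CG rate (ambiguous genes straddle the background)
    lo, hi = config.ambiguous_cg_range
    cg = np.empty(n)
    chg = np.empty(n)
    chh = np.empty(n)
    for i, c_ in enumerate(cls):
        if c_ == AMBIGUOUS:
            cg[i] = rng.uniform(lo, hi)
            chg[i] = chh[i] = config.ambiguous_non_cg_rate
        else:
            rates = config.meth_rates[c_]
            cg[i], chg[i], chh[i] = rates["CG"], rates["CHG"], rates["CHH"]
    truth["cg_rate"] = cg
    truth["chg_rate"] = chg
    truth["chh_rate"] = chh
    return truth


def simulate_methylomes(
    config: SimConfig, genes: list[GeneModel], truth: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Two replicate per-cytosine count sets plus ground truth.

    Site positions are shared between replicates (one genome); coverage and
    methylated-read counts are drawn independently per replicate:
    meth ~ Binomial(Poisson coverage, class-and-context rate).
    """
    if truth is None:
        truth = assign_classes(config, genes)
    rng = stage_rng(config.seed, "methylome-counts")
    contexts = ("CG", "CHG", "CHH")
    chrom_names = sorted({g.chrom for g in genes})
    chrom_code = {c: i for i, c in enumerate(chrom_names)}
    pos_arr, ctx_arr, gene_idx = [], [], []
    for gi, g in enumerate(genes):
        for ci, ctx in enumerate(contexts):
            dens = config.site_density[ctx]
            n_sites = rng.binomial(g.length, dens)
            if n_sites == 0:
                continue
            # uniform draw with dedup; collision loss is O(density) and
            # irrelevant to the planted rates
            pos = np.unique(rng.integers(g.start, g.end + 1, size=n_sites))
            pos_arr.append(pos)
            ctx_arr.append(np.full(len(pos), ci, dtype=np.int8))
            gene_idx.append(np.full(len(pos), gi, dtype=np.int32))
    pos_all = np.concatenate(pos_arr)
    ctx_all = np.concatenate(ctx_arr)
    gidx = np.concatenate(gene_idx)
    chrom_all = np.array(
        [chrom_code[g.chrom] for g in genes], dtype=np.int16
    )[gidx]
    rate_by_ctx = np.column_stack(
        [truth[c].to_numpy() for c in ("cg_rate", "chg_rate", "chh_rate")]
    )
    rates = rate_by_ctx[gidx, ctx_all]
    strands = (rng.random(len(pos_all)) < 0.5).astype(np.int8)

    reps = []
    for _rep in range(2):
        cov = rng.poisson(config.coverage_mean, size=len(pos_all))
        meth = rng.binomial(cov, rates)
        keep = cov > 0
        reps.append(
            pd.DataFrame(
                {
                    "chrom": pd.Categorical.from_codes(
                        chrom_all[keep], categories=chrom_names
                    ),
                    "pos": pos_all[keep],
                    "strand": pd.Categorical.from_codes(
                        strands[keep], categories=["+", "-"]
                    ),
                    "context": pd.Categorical.from_codes(
                        ctx_all[keep], categories=list(contexts)
                    ),
                    "meth": meth[keep],
                    "unmeth": (cov - meth)[keep],
                }
            )
        )
    return reps[0], reps[1], truth


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def simulate_features(config: SimConfig, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-gene genomic feature table from a Gaussian copula conditioned on
    the gbM class latent.

    Planted correlations in ``config.gbm_feature_corr`` are between the gbM
    0/1 indicator and each feature's latent; they are converted to latent
    correlations via the point-biserial factor of the thresholding.  Binary
    features are thresholded latents, so their realised correlations are
    approximate.  Adds the latents used downstream (``z_breadth``,
    ``z_alpha``) to ``truth`` in place.
    """
    rng = stage_rng(config.seed, "features")
    n = len(truth)
    p_gbm = config.class_proportions[GBM]
    c = _point_biserial_factor(p_gbm)
    g_lat = truth["class_latent"].to_numpy()
    # re-standardise: latent was built standard normal
    feats = pd.DataFrame(index=truth.index.copy())
    feats["gene_length"] = truth["gene_length"].to_numpy()

    def latent_for(name: str) -> np.ndarray:
        rho = np.clip(config.gbm_feature_corr[name] / c,
                      -config.correlation_cap, config.correlation_cap)
        return rho * g_lat + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)

    z_lethal = latent_for("lethal")
    feats["lethal"] = (z_lethal > norm.ppf(1 - config.lethal_prop)).astype(int)

    z_kaks = latent_for("ka_ks")
    feats["ka_ks"] = np.exp(config.ka_ks_meanlog + config.ka_ks_sdlog * z_kaks)

    z_mod = latent_for("module_size")
    feats["module_size"] = np.maximum(
        1, np.round(np.exp(config.module_size_meanlog
                           + config.module_size_sdlog * z_mod))
    ).astype(int)

    z_alpha = latent_for("alpha_wgd")
    feats["alpha_wgd"] = (z_alpha > norm.ppf(1 - config.alpha_wgd_prop)).astype(int)

    z_bg = latent_for("betagamma_wgd")
    feats["betagamma_wgd"] = (
        z_bg > norm.ppf(1 - config.betagamma_wgd_prop)
    ).astype(int)

    z_breadth = latent_for("expression_breadth")
    bmax = config.breadth_max
    feats["expression_breadth"] = np.minimum(
        bmax, np.round((bmax * 9 / 8) * norm.cdf(z_breadth + 1.0))
    ).astype(int)

    z_tandem = latent_for("tandem_duplicate")
    feats["tandem_duplicate"] = (z_tandem > norm.ppf(1 - config.tandem_prop)).astype(int)

    truth["z_breadth"] = z_breadth
    truth["z_alpha"] = z_alpha
    return feats[list(FEATURE_COLUMNS)]


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _polyval(coeffs: tuple, x: np.ndarray) -> np.ndarray:
    """Evaluate c0 + c1 x + c2 x^2 + ... (ascending coefficients)."""
    out = np.zeros_like(x, dtype=float)
    for k, ck in enumerate(coeffs):
        out += ck * x**k
    return out


def simulate_expression(config: SimConfig, truth: pd.DataFrame) -> pd.DataFrame:
    """Genes x cells FPKM matrix with the planted cubic mean-variance law.

    Per gene: a class-specific lognormal mean, variance from the cubic trend
    in log-mean times the gene's noise multiplier, 20 lognormal cell values,
    then lower-tail censoring at the quantile matching the gene's detection
    probability.  Adds true means, multipliers and detection probabilities
    to ``truth`` in place.
    """
    rng = stage_rng(config.seed, "expression")
    n = len(truth)
    cls = truth["class"].to_numpy()
    L = np.array(
        [
            rng.normal(config.expr_meanlog[c_], config.expr_sdlog[c_])
            for c_ in cls
        ]
    )
    M = np.exp(L)

    if config.noise_multiplier_mode == "covariate":
        if "z_breadth" not in truth.columns:
            raise ValueError(
                "covariate noise multipliers need simulate_features first"
            )
        p = config.class_proportions[GBM]
        g_std = (truth["is_gbm"].to_numpy() - p) / np.sqrt(p * (1 - p))
        logm = (
            config.noise_beta_length * truth["z_length"].to_numpy()
            + config.noise_beta_breadth * truth["z_breadth"].to_numpy()
            + config.noise_beta_alpha_wgd * truth["z_alpha"].to_numpy()
            + config.noise_beta_gbm * g_std
            + rng.normal(0.0, config.noise_sigma, size=n)
        )
    elif config.noise_multiplier_mode == "fixed_groups":
        logm = np.zeros(n)
        n_high = int(round(config.multiplier_high_fraction * n))
        high = rng.choice(n, size=n_high, replace=False)
        logm[high] = np.log(config.multiplier_high_value)
    else:
        raise ValueError(f"unknown noise_multiplier_mode "
                         f"{config.noise_multiplier_mode!r}")

    log_var = _polyval(config.variance_trend, L) + logm
    V = np.exp(log_var)

    if config.dropout_enabled:
        z_mu = (L - L.mean()) / max(L.std(), 1e-12)
        z_m = (logm - logm.mean()) / max(logm.std(), 1e-12)
        eta = (
            config.detect_b0
            + config.detect_b_mu * z_mu
            + config.detect_b_len * truth["z_length"].to_numpy()
            - config.detect_b_noise * z_m
            + config.detect_b_gbm * truth["is_gbm"].to_numpy()
        )
        with np.errstate(over="ignore"):  # eta -> -inf means pi = 0 exactly
            pi = 1.0 / (1.0 + np.exp(-eta))
        # moment-preserving zero inflation: zeros occur with prob 1 - pi and
        # the nonzero (burst) distribution is compensated so the marginal
        # mean and variance stay exactly (M, V); feasibility bounds pi from
        # below at M^2/(M^2 + V)
        pi_min = M**2 / (M**2 + V) * (1.0 + 1e-6)
        pi = np.where(pi == 0.0, 0.0, np.maximum(pi, np.minimum(pi_min, 1.0)))
    else:
        pi = np.ones(n)

    safe_pi = np.where(pi > 0, pi, 1.0)
    M_nz = M / safe_pi
    V_nz = np.maximum((V - ((1.0 - safe_pi) / safe_pi) * M**2) / safe_pi, 0.0)
    s2 = np.log1p(V_nz / M_nz**2)
    mu_ln = np.log(M_nz) - s2 / 2.0
    sd_ln = np.sqrt(s2)
    cells = rng.lognormal(
        mean=mu_ln[:, None], sigma=sd_ln[:, None], size=(n, config.n_cells)
    )
    detected = rng.random((n, config.n_cells)) < pi[:, None]
    cells = np.where(detected, cells, 0.0)

    truth["true_log_mean"] = L
    truth["true_mean"] = M
    truth["noise_multiplier"] = np.exp(logm)
    truth["detect_prob"] = pi
    return pd.DataFrame(
        cells,
        index=truth.index.copy(),
        columns=[f"cell{j + 1:02d}" for j in range(config.n_cells)],
    )


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def simulate_reads(
    config: SimConfig,
    genes: list[GeneModel],
    matrix: pd.DataFrame,
    truth: pd.DataFrame,
) -> pd.DataFrame:
    """Fixed-length read intervals per cell.

    Per cell, reads are multinomial across genes with weights FPKM x gene
    length; each read lands fully inside an intron with the gene's planted
    retention fraction (when an intron can hold it), else inside an exon.
    Adds ``retention_fraction`` to ``truth`` in place.
    """
    for c_, r in config.retention_fraction.items():
        if not 0.0 <= r <= 1.0:
            raise ValueError("retention fraction outside [0,1]")
    rng = stage_rng(config.seed, "reads")
    rl = config.read_length
    gene_by_id = {g.gene_id: g for g in genes}
    ids = list(matrix.index)
    lengths = np.array([gene_by_id[i].length for i in ids], dtype=float)
    retention = np.array(
        [config.retention_fraction[c_] for c_ in truth.loc[ids, "class"]]
    )
    truth.loc[ids, "retention_fraction"] = retention

    # per-gene usable intervals (long enough to hold a read), as arrays of
    # start positions and placement widths
    def _usable(ivs):
        ok = [(s, e - s + 1 - rl + 1) for s, e in ivs if e - s + 1 >= rl]
        if not ok:
            return None
        return (np.array([s for s, _ in ok]), np.array([w for _, w in ok], float))

    introns_ok = [_usable(gene_by_id[i].introns) for i in ids]
    exons_ok = [_usable(gene_by_id[i].exonic) for i in ids]

    counts = np.zeros((len(ids), config.n_cells), dtype=int)
    for j, cell in enumerate(matrix.columns):
        w = matrix[cell].to_numpy() * lengths
        total = w.sum()
        if total <= 0:
            continue
        counts[:, j] = rng.multinomial(config.reads_per_cell, w / total)

    out_chrom, out_start, out_end, out_cell = [], [], [], []
    cell_names = list(matrix.columns)
    for gi, gid in enumerate(ids):
        n_reads = int(counts[gi].sum())
        if n_reads == 0:
            continue
        g = gene_by_id[gid]
        intr, exn = introns_ok[gi], exons_ok[gi]
        if intr is None and exn is None:
            continue
        go_intron = rng.random(n_reads) < retention[gi]
        if intr is None:
            go_intron[:] = False
        elif exn is None:
            go_intron[:] = True
        starts = np.empty(n_reads, dtype=int)
        for flag, ivs in ((True, intr), (False, exn)):
            mask = go_intron == flag
            k = int(mask.sum())
            if k == 0 or ivs is None:
                continue
            s_arr, widths = ivs
            pick = rng.choice(s_arr.size, size=k, p=widths / widths.sum())
            offs = (rng.random(k) * widths[pick]).astype(int)
            starts[mask] = s_arr[pick] + offs
        out_chrom.append(np.full(n_reads, g.chrom, dtype=object))
        out_start.append(starts)
        out_end.append(starts + rl - 1)
        out_cell.append(np.repeat(np.arange(config.n_cells), counts[gi]))

    if not out_chrom:
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "strand"])
    cell_arr = np.array(cell_names, dtype=object)
    reads = pd.DataFrame(
        {
            "chrom": np.concatenate(out_chrom),
            "start": np.concatenate(out_start),
            "end": np.concatenate(out_end),
            "name": cell_arr[np.concatenate(out_cell)],
            "strand": "+",
        }
    )
    return reads.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# one-call convenience
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """Everything one simulated study produces."""

    config: SimConfig
    genes: list[GeneModel]
    truth: pd.DataFrame
    cytosines_rep1: pd.DataFrame
    cytosines_rep2: pd.DataFrame
    features: pd.DataFrame
    matrix: pd.DataFrame
    reads: pd.DataFrame


def simulate_all(config: SimConfig, with_reads: bool = True) -> SimulatedDataset:
    """Run every generator stage in dependency order."""
    genes = simulate_genome(config)
    rep1, rep2, truth = simulate_methylomes(config, genes)
    features = simulate_features(config, truth)
    matrix = simulate_expression(config, truth)
    if with_reads:
        reads = simulate_reads(config, genes, matrix, truth)
    else:
        reads = pd.DataFrame(columns=["chrom", "start", "end", "name", "strand"])
    return SimulatedDataset(
        config=config,
        genes=genes,
        truth=truth,
        cytosines_rep1=rep1,
        cytosines_rep2=rep2,
        features=features,
        matrix=matrix,
        reads=reads,
    )
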