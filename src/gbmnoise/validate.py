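"""Planted-truth recovery experiments.

Each function runs one validation question end to end on a named scenario:
generate synthetic data, run the relevant pipeline stages, and measure how
well the known planted structure is recovered.  Tests and the acceptance
script both call these, so the measured regimes are identical everywhere.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import introns as intr, methylation as meth, models, noise, scenarios
from .config import GBM, NO_CONSENSUS, UNMETHYLATED, SimConfig
from .pipeline import fit_intron_model, fit_response_model
from .simulate import (
    assign_classes,
    simulate_expression,
    simulate_features,
    simulate_genome,
    simulate_methylomes,
    simulate_reads,
    stage_rng,
)


def _truth_labels(truth: pd.DataFrame) -> pd.Series:
    """gbM/unmethylated labels from planted classes (other classes: none)."""
    lab = truth["class"].where(truth["class"].isin([GBM, UNMETHYLATED]),
                               NO_CONSENSUS)
    return lab.rename("label")


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

def classifier_recovery(seed: int, n_genes: int = 2000) -> dict:
    """Fraction of planted gbM / unmethylated genes recovered by the
    two-replicate consensus classification."""
    cfg = scenarios.classifier_recovery(seed, n_genes)
    genes = simulate_genome(cfg)
    rep1, rep2, truth = simulate_methylomes(cfg, genes)
    calls = []
    for rep in (rep1, rep2):
        summaries = meth.summarize_genes(rep, genes)
        calls.append(meth.classify_genes(summaries, alpha=cfg.alpha))
    consensus = meth.consensus_calls(calls[0], calls[1])
    out = {}
    for cls, key in ((GBM, "gbm_recall"), (UNMETHYLATED, "unmethylated_recall")):
        planted = truth.index[truth["class"] == cls]
        out[key] = float((consensus.loc[planted] == cls).mean())
    out["n_genes"] = n_genes
    return out


def region_mode_agreement(seed: int, n_genes: int = 2000) -> dict:
    """Fraction of genes labelled identically when methylation is summarised
    over the whole gene body vs exons only (methylation uniform within the
    gene, well-separated classes)."""
    cfg = scenarios.uniform_agreement(seed, n_genes)
    genes = simulate_genome(cfg)
    rep1, _rep2, _truth = simulate_methylomes(cfg, genes)
    calls = {}
    for mode in ("gene_body", "exons_only"):
        summaries = meth.summarize_genes(rep1, genes, region_mode=mode)
        calls[mode] = meth.classify_genes(summaries, alpha=cfg.alpha)
    agree = (calls["gene_body"]["label"] == calls["exons_only"]["label"]).mean()
    return {"agreement": float(agree), "n_genes": n_genes}


# ---------------------------------------------------------------------------
# F* behaviour
# ---------------------------------------------------------------------------

def fstar_recovery(seed: int, n_genes: int = 5000) -> dict:
    """Degree selection, decorrelation and multiplier recovery on the
    planted cubic trend with a 2x-noise gene subset."""
    cfg = scenarios.multiplier_recovery(seed, n_genes)
    genes = simulate_genome(cfg)
    truth = assign_classes(cfg, genes)
    simulate_features(cfg, truth)
    matrix = simulate_expression(cfg, truth)
    table, model = noise.build_noise_table(
        matrix, threshold=cfg.expression_threshold, log_base=cfg.log_base,
        max_degree=cfg.max_degree, alpha=cfg.alpha,
    )
    joined = table.join(truth["noise_multiplier"])
    high = joined["noise_multiplier"] > 1.5
    return {
        "degree": model.degree,
        "tau": model.tau,
        "tau_p": model.pvalue,
        "median_fstar_high": float(joined.loc[high, "F_star"].median()),
        "median_fstar_base": float(joined.loc[~high, "F_star"].median()),
        "n_genes": n_genes,
    }


# ---------------------------------------------------------------------------
# headline regime
# ---------------------------------------------------------------------------

def headline_recovery(seed: int, n_genes: int = 5000) -> dict:
    """The central direct-vs-indirect contrast, on planted labels.

    Measures, per seed: the BH-adjusted marginal Mann-Whitney P for F*
    between gbM and unmethylated genes; whether gbM enters the BIC-best F*
    model and its relative importance; whether gbM enters the BIC-best
    consistency model and its averaged coefficient; and the gbM coefficient
    in the intron-FPKM model.
    """
    cfg = scenarios.headline_regime(seed, n_genes)
    genes = simulate_genome(cfg)
    truth = assign_classes(cfg, genes)
    features = simulate_features(cfg, truth)
    matrix = simulate_expression(cfg, truth)
    table, _model = noise.build_noise_table(
        matrix, threshold=cfg.expression_threshold, log_base=cfg.log_base,
        max_degree=cfg.max_degree, alpha=cfg.alpha,
    )
    labels = _truth_labels(truth)
    contrast = labels[labels != NO_CONSENSUS]
    data = table.join(features, how="inner").join(contrast, how="inner")
    data["gbM"] = (data["label"] == GBM).astype(float)

    marg = models.group_comparison(
        data[["F_star", "F_prime", "consistency", "mu", "gene_length",
              "expression_breadth", "alpha_wgd"]],
        data["label"], GBM, UNMETHYLATED,
    )
    fstar_fit = fit_response_model(data, "F_star", vif_max=cfg.vif_max)
    cons_fit = fit_response_model(data, "consistency", vif_max=cfg.vif_max)

    reads = simulate_reads(cfg, genes, matrix, truth)
    keep = intr.flag_overlapping_genes(genes)
    rows = intr.add_fpkm(intr.count_reads(reads, keep),
                         library_fragments=len(reads))
    intron_fit = fit_intron_model(
        rows, features, labels, threshold=cfg.expression_threshold,
        log_base=cfg.log_base, vif_max=cfg.vif_max,
    )
    return {
        "mw_fstar_padj": float(marg.loc["F_star", "P_adj"]),
        "gbm_in_best_fstar": "gbM" in fstar_fit["avg"].best_predictors,
        "gbm_importance_fstar": float(fstar_fit["avg"].importance["gbM"]),
        "gbm_in_best_consistency": "gbM" in cons_fit["avg"].best_predictors,
        "gbm_coef_consistency": float(cons_fit["avg"].coefficients["gbM"]),
        "gbm_coef_intron": float(intron_fit["avg"].coefficients["gbM"]),
        "gbm_importance_intron": float(intron_fit["avg"].importance["gbM"]),
        "n_genes": n_genes,
    }


def headline_seed_fractions(seeds: list[int], n_genes: int = 5000) -> dict:
    """Fraction of seeds reproducing each headline outcome."""
    runs = [headline_recovery(s, n_genes) for s in seeds]
    return {
        "frac_marginal_mw_significant": float(
            np.mean([r["mw_fstar_padj"] < 0.05 for r in runs])
        ),
        "frac_gbm_excluded_from_noise_model": float(
            np.mean(
                [
                    (not r["gbm_in_best_fstar"])
                    and r["gbm_importance_fstar"] < 0.5
                    for r in runs
                ]
            )
        ),
        "frac_gbm_kept_positive_consistency": float(
            np.mean(
                [
                    r["gbm_in_best_consistency"] and r["gbm_coef_consistency"] > 0
                    for r in runs
                ]
            )
        ),
        "frac_gbm_negative_intron": float(
            np.mean([r["gbm_coef_intron"] < 0 for r in runs])
        ),
        "n_seeds": len(seeds),
        "n_genes": n_genes,
    }


# ---------------------------------------------------------------------------
# statistical-layer calibration
# ---------------------------------------------------------------------------

def pcr_type1_error(
    seed: int, n_sims: int = 200, n_genes: int = 5000, alpha: float = 0.05
) -> dict:
    """Type-I error of the gbM term in principal-component regression when
    the response depends on the observed features but not on gbM."""
    cfg = SimConfig(seed=seed, n_genes=n_genes)
    genes = simulate_genome(cfg)
    rejections = 0
    rng = stage_rng(seed, "pcr-null")
    for i in range(n_sims):
        cfg_i = cfg.replace(seed=int(rng.integers(0, 2**31 - 1)))
        truth = assign_classes(cfg_i, genes)
        features = simulate_features(cfg_i, truth)
        z_len = models.standardize(features[["gene_length"]])["gene_length"]
        z_breadth = models.standardize(features[["expression_breadth"]])[
            "expression_breadth"
        ]
        y = 0.3 * z_len + 0.2 * z_breadth + rng.normal(0, 1, len(features))
        fit = models.pcr_fit(features, truth["is_gbm"], y)
        if fit.anova.loc["gbM", "P"] < alpha:
            rejections += 1
    return {"type1_rate": rejections / n_sims, "n_sims": n_sims,
            "n_genes": n_genes}


def bic_active_set_recovery(
    seeds: list[int], n: int = 5000, n_predictors: int = 10, beta: float = 0.15
) -> dict:
    """How often all-subsets BIC averaging pins exactly the 3-of-10 planted
    active predictors as the best model."""
    exact = 0
    for seed in seeds:
        rng = stage_rng(seed, "bic-recovery")
        X = pd.DataFrame(
            rng.standard_normal((n, n_predictors)),
            columns=[f"x{j + 1}" for j in range(n_predictors)],
        )
        y = beta * (X["x1"] + X["x2"] + X["x3"]) + rng.standard_normal(n)
        avg = models.bic_model_average(X, y)
        if sorted(avg.best_predictors) == ["x1", "x2", "x3"]:
            exact += 1
    return {"exact_recovery_rate": exact / len(seeds), "n_seeds": len(seeds),
            "n": n}
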