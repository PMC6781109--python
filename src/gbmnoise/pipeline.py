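"""Orchestrate simulate -> classify -> noise -> introns -> models as one
reproducible run.

Each stage reads its inputs from and writes its outputs to one run
directory; ``run_all`` executes them in order and records a manifest with
SHA-256 digests of every output, so a rerun with the same config and seed
can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, introns as intr, iodata, methylation as meth, models, noise
from .config import GBM, NO_CONSENSUS, UNMETHYLATED, SimConfig
from .simulate import simulate_all

log = logging.getLogger("gbmnoise")

FILES = {
    "gff": "genes.gff3",
    "cx1": "methylome_rep1.cx.tsv",
    "cx2": "methylome_rep2.cx.tsv",
    "matrix": "fpkm_matrix.tsv",
    "reads": "reads.bed",
    "features": "features.tsv",
    "truth": "ground_truth.tsv",
    "calls1": "calls_rep1.tsv",
    "calls2": "calls_rep2.tsv",
    "consensus": "calls_consensus.tsv",
    "noise": "noise_table.tsv",
    "variance_model": "variance_model.json",
    "modified_gff": "genes_introns_as_exons.gff3",
    "intron_counts": "intron_counts.tsv",
    "table1": "table1_comparison.tsv",
    "consistency_hist": "consistency_histogram.tsv",
    "gbm_prediction": "gbm_prediction.tsv",
    "manifest": "manifest.json",
}

#: genomic covariates entering the ANCOVA models alongside gbM
COVARIATES = [
    "gene_length",
    "mu",
    "lethal",
    "ka_ks",
    "module_size",
    "alpha_wgd",
    "betagamma_wgd",
    "expression_breadth",
    "tandem_duplicate",
]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_simulate(config: SimConfig, outdir: Path) -> None:
    log.info("simulate: n_genes=%d n_cells=%d seed=%d",
             config.n_genes, config.n_cells, config.seed)
    ds = simulate_all(config)
    iodata.write_gff3(outdir / FILES["gff"], ds.genes)
    iodata.write_cytosine_report(outdir / FILES["cx1"], ds.cytosines_rep1)
    iodata.write_cytosine_report(outdir / FILES["cx2"], ds.cytosines_rep2)
    iodata.write_matrix(outdir / FILES["matrix"], ds.matrix)
    iodata.write_bed_reads(outdir / FILES["reads"], ds.reads)
    iodata.write_table(outdir / FILES["features"], ds.features)
    iodata.write_table(outdir / FILES["truth"], ds.truth)


def run_classify(config: SimConfig, outdir: Path, region_mode: str = "gene_body") -> None:
    genes = iodata.parse_gff3(outdir / FILES["gff"])
    calls = []
    for key, out_key in (("cx1", "calls1"), ("cx2", "calls2")):
        cyt = iodata.read_cytosine_table(outdir / FILES[key])
        summaries = meth.summarize_genes(cyt, genes, region_mode=region_mode)
        c = meth.classify_genes(summaries, alpha=config.alpha)
        iodata.write_table(outdir / FILES[out_key], c)
        calls.append(c)
    consensus = meth.consensus_calls(calls[0], calls[1])
    iodata.write_table(outdir / FILES["consensus"], consensus.to_frame())
    log.info("classify: %s", consensus.value_counts().to_dict())


def run_noise(config: SimConfig, outdir: Path) -> None:
    matrix = iodata.read_matrix(outdir / FILES["matrix"])
    table, model = noise.build_noise_table(
        matrix,
        threshold=config.expression_threshold,
        log_base=config.log_base,
        max_degree=config.max_degree,
        alpha=config.alpha,
    )
    iodata.write_table(outdir / FILES["noise"], table)
    with open(outdir / FILES["variance_model"], "w") as fh:
        json.dump(
            {
                "degree": model.degree,
                "coefficients": list(model.coefficients),
                "kendall_tau": model.tau,
                "kendall_p": model.pvalue,
                "exhausted": model.exhausted,
                "n_genes": int(len(table)),
            },
            fh,
            indent=2,
        )
    log.info("noise: %d genes pass filter, trend degree %d (tau=%.4f)",
             len(table), model.degree, model.tau)


def run_introns(config: SimConfig, outdir: Path) -> None:
    genes = iodata.parse_gff3(outdir / FILES["gff"])
    keep = intr.flag_overlapping_genes(genes)
    intr.write_modified_annotation(outdir / FILES["modified_gff"], keep)
    reads = iodata.read_bed_reads(outdir / FILES["reads"])
    rows = intr.count_reads(reads, keep)
    rows = intr.add_fpkm(rows, library_fragments=len(reads))
    iodata.write_table(outdir / FILES["intron_counts"], rows)
    log.info("introns: %d non-overlapping genes, %d reads counted",
             len(keep), len(reads))


def run_models(config: SimConfig, outdir: Path) -> dict:
    noise_table = iodata.read_table(outdir / FILES["noise"])
    features = iodata.read_table(outdir / FILES["features"])
    consensus = iodata.read_table(outdir / FILES["consensus"])["consensus"]
    data = noise_table.join(features, how="inner")
    contrast = consensus[consensus != NO_CONSENSUS]
    data = data.join(contrast.rename("label"), how="inner")
    data["gbM"] = (data["label"] == GBM).astype(float)

    # Table-1-shaped marginal contrasts
    table1 = models.group_comparison(
        data[["F_star", "F_prime", "consistency", "mu"] + COVARIATES[2:]
             + ["gene_length"]],
        data["label"], GBM, UNMETHYLATED,
    )
    iodata.write_table(outdir / FILES["table1"], table1)

    # consistency histogram (Fig-1-shaped): class proportions per cell count
    hist = _consistency_histogram(noise_table, consensus)
    iodata.write_table(outdir / FILES["consistency_hist"], hist)

    results = {"table1": table1, "consistency_hist": hist}
    for response in ("F_star", "F_prime", "consistency"):
        fitted = fit_response_model(data, response, vif_max=config.vif_max)
        results[response] = fitted
        _write_model(outdir, response, fitted)

    # intron-retention model
    intron_rows = iodata.read_table(outdir / FILES["intron_counts"])
    fitted = fit_intron_model(
        intron_rows, features, consensus,
        threshold=config.expression_threshold,
        log_base=config.log_base,
        vif_max=config.vif_max,
    )
    results["intron_fpkm"] = fitted
    _write_model(outdir, "intron_fpkm", fitted)

    # which features predict gbM?
    pred = data[["gene_length", "mu", "lethal", "ka_ks", "module_size",
                 "alpha_wgd", "betagamma_wgd", "expression_breadth",
                 "tandem_duplicate", "F_star", "F_prime", "consistency"]].dropna()
    avg, dropped = models.predict_gbm_model(
        pred, data.loc[pred.index, "gbM"], vif_max=config.vif_max
    )
    gbm_pred = pd.DataFrame(
        {"avg_coefficient": avg.coefficients, "importance": avg.importance}
    )
    gbm_pred["in_best_model"] = gbm_pred.index.isin(avg.best_predictors)
    gbm_pred["dropped_by_vif"] = gbm_pred.index.isin(dropped)
    iodata.write_table(outdir / FILES["gbm_prediction"], gbm_pred)
    results["gbm_prediction"] = (avg, dropped)
    return results


def fit_response_model(
    data: pd.DataFrame, response: str, vif_max: float = 4.0
) -> dict:
    """Transform selection, vif screen, ANCOVA and BIC averaging for one
    response over gbM plus the genomic covariates."""
    predictors = ["gbM"] + [c for c in COVARIATES if c != response]
    exempt = {"mu"} if response == "F_star" else set()
    spec = models.ModelSpec(response=response, predictors=predictors,
                            log_exempt=exempt)
    spec = models.choose_transforms(data, spec)
    y, X = models.build_design(data, spec)
    X, dropped = models.vif_screen(X, vif_max=vif_max)
    avg = models.bic_model_average(X, y)
    return {"spec": spec, "avg": avg, "dropped": dropped, "n": len(y)}


def fit_intron_model(
    intron_rows: pd.DataFrame,
    features: pd.DataFrame,
    consensus: pd.Series,
    threshold: float = 1.5,
    log_base: float = 2.0,
    vif_max: float = 4.0,
) -> dict:
    """ANCOVA of log intron FPKM on gbM, the genomic covariates and the two
    intron geometry covariates, on expressed non-overlapping genes."""
    rows = intr.filter_intron_genes(intron_rows, threshold=threshold,
                                    log_base=log_base)
    contrast = consensus[consensus != NO_CONSENSUS]
    data = rows.join(features.drop(columns=["gene_length"]), how="inner")
    data = data.join(contrast.rename("label"), how="inner")
    data["gbM"] = (data["label"] == GBM).astype(float)
    data["log_intron_fpkm"] = np.log1p(data["intron_fpkm"])
    predictors = ["gbM", "total_fpkm", "gene_length", "total_intron_length",
                  "intron_number", "lethal", "ka_ks", "module_size",
                  "alpha_wgd", "betagamma_wgd", "expression_breadth",
                  "tandem_duplicate"]
    spec = models.ModelSpec(response="log_intron_fpkm", predictors=predictors)
    spec = models.choose_transforms(data, spec)
    y, X = models.build_design(data, spec)
    X, dropped = models.vif_screen(X, vif_max=vif_max)
    avg = models.bic_model_average(X, y)
    return {"spec": spec, "avg": avg, "dropped": dropped, "n": len(y)}


def _write_model(outdir: Path, name: str, fitted: dict) -> None:
    avg: models.AveragedModel = fitted["avg"]
    table = pd.DataFrame(
        {"avg_coefficient": avg.coefficients, "importance": avg.importance}
    )
    table["in_best_model"] = table.index.isin(avg.best_predictors)
    table.index.name = "term"
    table.to_csv(outdir / f"model_{name}_averaged.tsv", sep="\t")
    best = avg.best_fit
    anova = best.anova.copy()
    anova.insert(0, "response", name)
    anova.to_csv(outdir / f"model_{name}_best_anova.tsv", sep="\t")


def _consistency_histogram(noise_table: pd.DataFrame,
                           consensus: pd.Series) -> pd.DataFrame:
    lab = consensus.reindex(noise_table.index).fillna("other")
    lab = lab.where(lab.isin([GBM, UNMETHYLATED]), "other")
    counts = (
        pd.crosstab(noise_table["consistency"], lab)
        .reindex(columns=[GBM, UNMETHYLATED, "other"], fill_value=0)
    )
    props = counts.div(counts.sum(axis=1), axis=0)
    props.columns = [f"prop_{c}" for c in props.columns]
    out = pd.concat([counts, props], axis=1)
    out.index.name = "n_cells_expressed"
    return out


# ---------------------------------------------------------------------------
# run_all and reporting
# ---------------------------------------------------------------------------

_STAGE_FUNCS = [
    ("simulate", run_simulate),
    ("classify", run_classify),
    ("noise", run_noise),
    ("introns", run_introns),
    ("models", run_models),
]


def run_all(config: SimConfig, outdir: str | os.PathLike) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for stage, func in _STAGE_FUNCS:
        try:
            func(config, out)
        except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
            raise StageError(stage, exc) from exc
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "digests": {
            p.name: _digest(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != FILES["manifest"]
        },
    }
    with open(out / FILES["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def summarize_run(outdir: str | os.PathLike) -> str:
    """Human-readable report of a completed (possibly partial) run."""
    out = Path(outdir)
    lines = [f"gbmnoise run summary: {out}", "=" * 60]

    def section(title: str, path: Path, render) -> None:
        lines.append("")
        lines.append(f"## {title}")
        if not path.exists():
            lines.append("  (stage output absent)")
            return
        render(path)

    def _classes(path: Path) -> None:
        cons = iodata.read_table(path)["consensus"]
        for label, n in cons.value_counts().items():
            lines.append(f"  {label}: {n}")

    def _hist(path: Path) -> None:
        hist = pd.read_csv(path, sep="\t", index_col=0)
        lines.append(hist.to_string())

    def _table1(path: Path) -> None:
        lines.append(pd.read_csv(path, sep="\t", index_col=0).to_string())

    def _models_section(_: Path) -> None:
        for name in ("F_star", "F_prime", "consistency", "intron_fpkm"):
            p = out / f"model_{name}_averaged.tsv"
            if not p.exists():
                lines.append(f"  model {name}: absent")
                continue
            t = pd.read_csv(p, sep="\t", index_col=0)
            best = t.index[t["in_best_model"]].tolist()
            lines.append(f"  {name}: best model = {best}")

    def _variance(path: Path) -> None:
        vm = json.loads(path.read_text())
        lines.append(
            f"  degree {vm['degree']}, Kendall tau(F*, mu) = "
            f"{vm['kendall_tau']:.4f} (P = {vm['kendall_p']:.3g})"
        )

    section("Gene classes (replicate consensus)", out / FILES["consensus"], _classes)
    section("Variance trend", out / FILES["variance_model"], _variance)
    section("Expression-consistency histogram", out / FILES["consistency_hist"], _hist)
    section("gbM vs unmethylated contrasts", out / FILES["table1"], _table1)
    section("Covariate models", out / FILES["manifest"], _models_section)
    return "\n".join(lines)
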