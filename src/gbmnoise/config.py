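"""Simulation configuration.

:class:`SimConfig` gathers every knob of the synthetic-data generator.  The
defaults encode the study conditions the pipeline is designed for: 20 root
quiescent-centre cells, a gene census split into gbM / unmethylated /
highly-methylated / ambiguous classes, CG-specific methylation enrichment in
gbM genes, a cubic log-mean/log-variance expression trend, covariates
collinear with gbM, and class-specific intron-retention fractions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

GBM = "gbM"
UNMETHYLATED = "unmethylated"
HIGHLY_METHYLATED = "highly_methylated_non_gbM"
AMBIGUOUS = "ambiguous"
NO_CONSENSUS = "none"

CLASSES = (GBM, UNMETHYLATED, HIGHLY_METHYLATED, AMBIGUOUS)

#: Feature columns of the per-gene genomic feature table.  ``gene_length`` is
#: taken from the simulated annotation; the rest are drawn from a Gaussian
#: copula conditioned on the gbM indicator.
FEATURE_COLUMNS = (
    "gene_length",
    "lethal",
    "ka_ks",
    "module_size",
    "alpha_wgd",
    "betagamma_wgd",
    "expression_breadth",
    "tandem_duplicate",
)


def _d(**kw: Any) -> Any:
    return field(default_factory=lambda: dict(kw))


@dataclass
class SimConfig:
    """All generator parameters; every stage of the pipeline reads from here.

    Randomness is controlled by ``seed``; each stage derives an independent
    stream from it, so stages are reproducible in isolation.
    """

    seed: int = 0
    n_genes: int = 2000
    n_cells: int = 20

    # ---- genome geometry -------------------------------------------------
    n_chromosomes: int = 5
    gene_length_meanlog: float = 7.6  # median ~2 kb
    gene_length_sdlog: float = 0.6
    min_gene_length: int = 300
    max_exons: int = 12
    intergenic_mean: float = 600.0
    overlap_fraction: float = 0.05  # fraction of genes planted overlapping

    # ---- methylation -----------------------------------------------------
    # per-class, per-context binomial success rates
    meth_rates: dict = _d(
        gbM={"CG": 0.25, "CHG": 0.02, "CHH": 0.02},
        unmethylated={"CG": 0.02, "CHG": 0.02, "CHH": 0.02},
        highly_methylated_non_gbM={"CG": 0.50, "CHG": 0.30, "CHH": 0.20},
    )
    # ambiguous genes draw a per-gene CG rate uniformly from this range,
    # straddling the pooled genomic background
    ambiguous_cg_range: tuple = (0.10, 0.22)
    ambiguous_non_cg_rate: float = 0.02
    # mean per-site read coverage (Poisson)
    coverage_mean: float = 20.0
    # cytosine site densities (sites per bp) per context
    site_density: dict = _d(CG=0.04, CHG=0.033, CHH=0.083)

    # ---- gene classes and covariates ------------------------------------
    class_proportions: dict = _d(
        gbM=0.35,
        unmethylated=0.45,
        highly_methylated_non_gbM=0.12,
        ambiguous=0.08,
    )
    # planted point-biserial correlation between the gbM indicator and each
    # covariate's latent; signs follow the observed contrasts (gbM genes
    # longer, broader expression, more lethal, larger modules, less often
    # WGD-retained or tandem-duplicated)
    gbm_feature_corr: dict = _d(
        gene_length=0.40,
        lethal=0.15,
        ka_ks=0.0,
        module_size=0.20,
        alpha_wgd=-0.25,
        betagamma_wgd=-0.12,
        expression_breadth=0.30,
        tandem_duplicate=-0.10,
    )
    correlation_cap: float = 0.9
    # marginal parameters for covariates
    lethal_prop: float = 0.17
    alpha_wgd_prop: float = 0.30
    betagamma_wgd_prop: float = 0.12
    tandem_prop: float = 0.09
    ka_ks_meanlog: float = -1.9
    ka_ks_sdlog: float = 0.5
    module_size_meanlog: float = 2.7
    module_size_sdlog: float = 0.6
    breadth_max: int = 64

    # ---- expression ------------------------------------------------------
    # per-class log-mean FPKM distributions (natural log)
    expr_meanlog: dict = _d(
        gbM=1.6,
        unmethylated=1.2,
        highly_methylated_non_gbM=0.5,
        ambiguous=1.0,
    )
    expr_sdlog: dict = _d(
        gbM=0.8,
        unmethylated=1.4,
        highly_methylated_non_gbM=1.2,
        ambiguous=1.2,
    )
    # cubic trend: log(sigma^2) = c0 + c1 L + c2 L^2 + c3 L^3, L = log(mu)
    variance_trend: tuple = (2.0, 1.9, 0.08, -0.012)
    # gene-level noise multipliers: either driven by covariates ("covariate")
    # or a planted high-multiplier subset ("fixed_groups")
    noise_multiplier_mode: str = "covariate"
    noise_beta_length: float = -0.25
    noise_beta_breadth: float = -0.30
    noise_beta_alpha_wgd: float = -0.15
    noise_beta_gbm: float = 0.0  # direct gbM -> noise effect (zero by design)
    noise_sigma: float = 0.35
    multiplier_high_fraction: float = 0.1
    multiplier_high_value: float = 2.0

    # ---- detection / consistency ----------------------------------------
    # per-cell detection probability pi = sigmoid(b0 + b_mu z_mu + b_len z_len
    # - b_noise z_logm + b_gbm gbM); cells below the matching lognormal
    # quantile are censored to 0
    dropout_enabled: bool = True
    detect_b0: float = 1.3
    detect_b_mu: float = 1.2
    detect_b_len: float = 0.3
    detect_b_noise: float = 0.7
    detect_b_gbm: float = 0.6  # direct gbM -> consistency effect

    # ---- reads / intron retention ----------------------------------------
    reads_per_cell: int = 20000
    read_length: int = 50
    retention_fraction: dict = _d(
        gbM=0.05,
        unmethylated=0.10,
        highly_methylated_non_gbM=0.08,
        ambiguous=0.08,
    )

    # ---- analysis thresholds (the published defaults) --------------------
    alpha: float = 0.05
    expression_threshold: float = 1.5
    log_base: float = 2.0
    max_degree: int = 6
    vif_max: float = 4.0  # sqrt(vif) < 2

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")
        props = self.class_proportions
        if set(props) != set(CLASSES):
            raise ValueError(f"class_proportions must cover {CLASSES}")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        for cls, rates in self.meth_rates.items():
            for ctx, r in rates.items():
                if not 0.0 <= r <= 1.0:
                    raise ValueError(f"methylation rate {cls}/{ctx} outside [0,1]")
        lo, hi = self.ambiguous_cg_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("ambiguous_cg_range outside [0,1]")
        for cls, r in self.retention_fraction.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"retention fraction {cls} outside [0,1]")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction outside [0,1)")
        for name, r in self.gbm_feature_corr.items():
            if abs(r) > self.correlation_cap:
                raise ValueError(f"gbM-feature correlation {name} exceeds cap")

    # ---- (de)serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["variance_trend"] = list(self.variance_trend)
        d["ambiguous_cg_range"] = list(self.ambiguous_cg_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("variance_trend", "ambiguous_cg_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **kw: Any) -> "SimConfig":
        return dataclasses.replace(self, **kw)
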