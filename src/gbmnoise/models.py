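"""Group tests, correlations, ANCOVA with BIC all-subsets model averaging,
vif screening, transform selection, and principal-component regression.

Conventions
-----------
* Predictors (binary ones included) are centred and scaled by their sample
  standard deviation before fitting; the response stays on its own scale.
* Per-term sums of squares are Type II (each term adjusted for all others).
* BIC = n ln(RSS/n) + k ln(n) with k = number of coefficients including the
  intercept; only BIC differences are ever used, so the dropped constant is
  irrelevant.
* Model averaging is "full": a predictor absent from a model contributes a
  zero coefficient; a predictor's relative importance is the summed BIC
  weight of the models containing it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

MAX_SUBSET_PREDICTORS = 20


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------

def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact null distribution when the smaller
    sample has <= 8 observations and there are no ties, tie-corrected normal
    approximation otherwise.  Returns (U of the first sample, P)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("P values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with t-approximation P value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rho undefined for a constant vector")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# model specification and design building
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Which columns predict which response, and how they are transformed.

    ``transforms`` maps predictor name to "identity", "log" (requires
    strictly positive values) or "log1p" (the recorded fallback when zeros
    are present).  ``log_exempt`` lists predictors that must never be logged
    for this response (the mean expression level when the response is F*).
    """

    response: str
    predictors: list[str]
    transforms: dict[str, str] = field(default_factory=dict)
    standardize: bool = True
    log_exempt: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.response in self.predictors:
            raise ValueError("response cannot be among the predictors")
        for name in self.transforms:
            if name not in self.predictors:
                raise ValueError(f"transform for unknown predictor {name!r}")


def _apply_transform(x: pd.Series, how: str) -> pd.Series:
    if how == "identity":
        return x
    if how == "log":
        if (x <= 0).any():
            raise ValueError(f"log of non-positive column {x.name!r}")
        return np.log(x)
    if how == "log1p":
        if (x < 0).any():
            raise ValueError(f"log1p of negative column {x.name!r}")
        return np.log1p(x)
    raise ValueError(f"unknown transform {how!r}")


def standardize(table: pd.DataFrame, spec: ModelSpec | None = None) -> pd.DataFrame:
    """Centre each column and scale by its sample standard deviation."""
    cols = spec.predictors if spec is not None else list(table.columns)
    out = pd.DataFrame(index=table.index)
    for c in cols:
        x = table[c].astype(float)
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"zero-variance column {c!r}")
        out[c] = (x - x.mean()) / sd
    return out


def build_design(table: pd.DataFrame, spec: ModelSpec) -> tuple[pd.Series, pd.DataFrame]:
    """Apply transforms and (optionally) standardisation; rows with missing
    values in the response or any predictor are dropped listwise."""
    cols = [spec.response] + spec.predictors
    data = table[cols].astype(float).dropna()
    y = data[spec.response]
    X = pd.DataFrame(index=data.index)
    for c in spec.predictors:
        X[c] = _apply_transform(data[c], spec.transforms.get(c, "identity"))
    if spec.standardize:
        X = standardize(X)
    return y, X


def default_log_transform(x: pd.Series) -> str:
    """"log" when strictly positive, "log1p" when zeros are present."""
    return "log" if (x > 0).all() else "log1p"


def choose_transforms(table: pd.DataFrame, spec: ModelSpec) -> ModelSpec:
    """Greedy single pass over predictors in declared order: keep the log
    transform of a (continuous) predictor iff it increases the R^2 of the
    full additive model; ``log_exempt`` predictors are never logged."""
    spec = ModelSpec(
        response=spec.response,
        predictors=list(spec.predictors),
        transforms=dict(spec.transforms),
        standardize=spec.standardize,
        log_exempt=set(spec.log_exempt),
    )
    for name in spec.predictors:
        if name in spec.log_exempt:
            continue
        col = table[name].dropna()
        if col.nunique() <= 2:  # binary: transform is meaningless
            continue
        if (col < 0).any():  # negatives: no log candidate exists
            spec.transforms[name] = "identity"
            continue
        base = dict(spec.transforms)
        base[name] = "identity"
        logged = dict(spec.transforms)
        logged[name] = default_log_transform(col)
        r2_base = _full_model_r2(table, spec, base)
        r2_log = _full_model_r2(table, spec, logged)
        spec.transforms[name] = logged[name] if r2_log > r2_base else "identity"
    return spec


def _full_model_r2(table: pd.DataFrame, spec: ModelSpec, transforms: dict) -> float:
    trial = ModelSpec(
        response=spec.response,
        predictors=list(spec.predictors),
        transforms=transforms,
        standardize=spec.standardize,
        log_exempt=set(spec.log_exempt),
    )
    y, X = build_design(table, trial)
    return _ols_r2(np.asarray(y, dtype=float), X.to_numpy())


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    Xc = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    resid = y - Xc @ beta
    tss = np.sum((y - y.mean()) ** 2)
    return 1.0 - np.sum(resid**2) / tss


# ---------------------------------------------------------------------------
# vif
# ---------------------------------------------------------------------------

def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor: 1 / (1 - R^2 of that
    predictor regressed on all the others).  Raises on rank deficiency."""
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("vif needs at least two predictors")
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < p + 1:
        raise ValueError("rank-deficient design (duplicated or collinear column)")
    out = {}
    for j, name in enumerate(design.columns):
        others = np.delete(X, j, axis=1)
        r2 = _ols_r2(X[:, j], others)
        out[name] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def vif_screen(design: pd.DataFrame, vif_max: float = 4.0) -> tuple[pd.DataFrame, list[str]]:
    """Iteratively drop the predictor with the largest vif until all satisfy
    sqrt(vif) < 2 (vif < ``vif_max``).  Returns (kept design, dropped names).

    Perfectly collinear columns (e.g. a duplicated predictor), for which the
    vif itself is undefined, are removed first, keeping the earlier column.
    """
    design = design.copy()
    dropped: list[str] = []
    # pre-drop exact collinearity so vif is computable
    n = len(design)
    kept_cols: list[str] = []
    X_kept = np.ones((n, 1))
    for c in design.columns:
        cand = np.column_stack([X_kept, design[c].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(cand) > X_kept.shape[1]:
            kept_cols.append(c)
            X_kept = cand
        else:
            dropped.append(c)
    design = design[kept_cols]
    while design.shape[1] >= 2:
        v = vif(design)
        worst = v.idxmax()
        if v[worst] < vif_max:
            break
        design = design.drop(columns=[worst])
        dropped.append(worst)
    return design, dropped


# ---------------------------------------------------------------------------
# ANCOVA fits
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    """One fitted covariate model with its ANCOVA table."""

    predictors: list[str]
    coefficients: pd.Series  # includes "Intercept"
    anova: pd.DataFrame  # per-term: coefficient, sum_sq, F, P (Type II)
    r2: float
    bic: float
    rss: float
    n: int
    vif: pd.Series | None = None


def bic_from_rss(rss: float, n: int, n_coef: int) -> float:
    return n * np.log(rss / n) + n_coef * np.log(n)


def fit_ancova(design: pd.DataFrame, response: pd.Series) -> ModelFit:
    """OLS with intercept; per-term Type II sums of squares and F tests."""
    import statsmodels.api as sm

    y = np.asarray(response, dtype=float)
    X = sm.add_constant(design.to_numpy(dtype=float), has_constant="add")
    n, k = X.shape
    if n <= k:
        raise ValueError("need n > number of coefficients")
    full = sm.OLS(y, X).fit()
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("singular design")
    rss_full = float(full.ssr)
    df_resid = n - k
    mse = rss_full / df_resid
    rows = []
    for j, name in enumerate(design.columns):
        Xr = np.delete(X, j + 1, axis=1)
        rss_r = float(sm.OLS(y, Xr).fit().ssr)
        ss = rss_r - rss_full
        F = ss / mse if mse > 0 else np.inf
        P = float(stats.f.sf(F, 1, df_resid)) if np.isfinite(F) else 0.0
        rows.append((name, full.params[j + 1], ss, F, P))
    anova = pd.DataFrame(
        rows, columns=["term", "coefficient", "sum_sq", "F", "P"]
    ).set_index("term")
    coefs = pd.Series(full.params, index=["Intercept"] + list(design.columns))
    return ModelFit(
        predictors=list(design.columns),
        coefficients=coefs,
        anova=anova,
        r2=float(full.rsquared),
        bic=bic_from_rss(rss_full, n, k),
        rss=rss_full,
        n=n,
    )


# ---------------------------------------------------------------------------
# BIC all-subsets model averaging
# ---------------------------------------------------------------------------

@dataclass
class AveragedModel:
    """BIC-weighted average over all predictor subsets."""

    coefficients: pd.Series  # full averaging: zero when absent
    importance: pd.Series  # summed weight of models containing the predictor
    best_predictors: list[str]
    best_fit: ModelFit
    weights: pd.Series  # indexed by frozenset-as-string model key
    always_keep: list[str]


def bic_model_average(
    design: pd.DataFrame,
    response: pd.Series,
    always_keep: list[str] | None = None,
) -> AveragedModel:
    """Fit every subset of predictors (2^p enumeration), weight by
    exp(-dBIC/2), and average coefficients across all models.

    ``always_keep`` predictors are forced into every candidate model.
    Implemented on precomputed Gram matrices so the enumeration cost does not
    scale with the number of observations.
    """
    always_keep = list(always_keep or [])
    names = list(design.columns)
    free = [c for c in names if c not in always_keep]
    if len(free) > MAX_SUBSET_PREDICTORS:
        raise ValueError(
            f"too many candidate predictors for all-subsets enumeration "
            f"({len(free)} > {MAX_SUBSET_PREDICTORS})"
        )
    y = np.asarray(response, dtype=float)
    n = len(y)
    X = np.column_stack([np.ones(n), design.to_numpy(dtype=float)])
    G = X.T @ X
    Xy = X.T @ y
    yy = float(y @ y)
    keep_idx = [names.index(c) + 1 for c in always_keep]

    records = []
    for subset in itertools.chain.from_iterable(
        itertools.combinations(range(len(free)), r) for r in range(len(free) + 1)
    ):
        cols = [0] + keep_idx + [names.index(free[j]) + 1 for j in subset]
        cols = sorted(cols)
        Gs = G[np.ix_(cols, cols)]
        try:
            beta = np.linalg.solve(Gs, Xy[cols])
        except np.linalg.LinAlgError:
            continue
        rss = max(yy - float(Xy[cols] @ beta), 1e-300)
        bic = bic_from_rss(rss, n, len(cols))
        records.append((cols, beta, bic))
    if not records:
        raise ValueError("no estimable model")
    bics = np.array([r[2] for r in records])
    w = np.exp(-0.5 * (bics - bics.min()))
    w /= w.sum()

    coef = pd.Series(0.0, index=names)
    importance = pd.Series(0.0, index=names)
    for (cols, beta, _), wm in zip(records, w):
        for c, b in zip(cols, beta):
            if c == 0:
                continue
            name = names[c - 1]
            coef[name] += wm * b
            importance[name] += wm
    best = records[int(np.argmin(bics))]
    best_names = [names[c - 1] for c in best[0] if c != 0]
    best_fit = fit_ancova(design[best_names], response) if best_names else _intercept_fit(y)
    keys = pd.Series(
        w, index=["+".join(names[c - 1] for c in cols if c != 0) or "(intercept)"
                  for cols, _, _ in records]
    )
    return AveragedModel(
        coefficients=coef,
        importance=importance,
        best_predictors=best_names,
        best_fit=best_fit,
        weights=keys,
        always_keep=always_keep,
    )


def _intercept_fit(y: np.ndarray) -> ModelFit:
    n = len(y)
    rss = float(np.sum((y - y.mean()) ** 2))
    return ModelFit(
        predictors=[],
        coefficients=pd.Series({"Intercept": float(y.mean())}),
        anova=pd.DataFrame(columns=["coefficient", "sum_sq", "F", "P"]),
        r2=0.0,
        bic=bic_from_rss(rss, n, 1),
        rss=rss,
        n=n,
    )


# ---------------------------------------------------------------------------
# principal-component regression
# ---------------------------------------------------------------------------

def pcr_fit(
    features: pd.DataFrame, gbm_indicator: pd.Series, response: pd.Series
) -> ModelFit:
    """Regress the response on the gbM indicator plus *all* principal
    components of the other (standardised) features.

    Because the components span the same space as the features, the gbM term
    is tested net of every other feature, with multicollinearity confined to
    the single gbM-vs-components block.
    """
    from sklearn.decomposition import PCA

    Xs = standardize(features)
    if Xs.isna().any().any():
        raise ValueError("degenerate feature matrix")
    pca = PCA(n_components=Xs.shape[1])
    scores = pca.fit_transform(Xs.to_numpy())
    design = pd.DataFrame(
        scores, index=features.index,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    g = gbm_indicator.astype(float)
    sd = g.std(ddof=1)
    if sd == 0:
        raise ValueError("gbM indicator is constant")
    design.insert(0, "gbM", (g - g.mean()) / sd)
    return fit_ancova(design, response)


# ---------------------------------------------------------------------------
# gbM-prediction model
# ---------------------------------------------------------------------------

def predict_gbm_model(
    predictors: pd.DataFrame,
    gbm_indicator: pd.Series,
    vif_max: float = 4.0,
) -> tuple[AveragedModel, list[str]]:
    """Which genomic features predict gbM?  Ordinary least squares on the
    0/1 indicator: vif screening first (sqrt(vif) < 2 required), then BIC
    all-subsets averaging over the surviving predictors.

    Returns (averaged model, predictors dropped by the vif screen).
    """
    design = standardize(predictors)
    design, dropped = vif_screen(design, vif_max=vif_max)
    avg = bic_model_average(design, gbm_indicator.astype(float))
    return avg, dropped


# ---------------------------------------------------------------------------
# marginal group comparison (Table-1-shaped)
# ---------------------------------------------------------------------------

def group_comparison(
    data: pd.DataFrame, labels: pd.Series, group_a: str, group_b: str
) -> pd.DataFrame:
    """Per-column contrast between two gene groups: medians (proportions for
    binary columns), Mann-Whitney P and its BH adjustment."""
    ia = labels.index[labels == group_a].intersection(data.index)
    ib = labels.index[labels == group_b].intersection(data.index)
    rows = []
    for col in data.columns:
        a = data.loc[ia, col].dropna()
        b = data.loc[ib, col].dropna()
        binary = data[col].dropna().nunique() <= 2
        stat_a = float(a.mean() if binary else a.median())
        stat_b = float(b.mean() if binary else b.median())
        _, p = mann_whitney(a, b)
        rows.append((col, "proportion" if binary else "median", stat_a, stat_b, p))
    out = pd.DataFrame(
        rows, columns=["feature", "summary", group_a, group_b, "P"]
    ).set_index("feature")
    out["P_adj"] = bh_adjust(out["P"].to_numpy())
    return out
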