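"""Per-gene expression noise (F*, F') and expression consistency.

F* divides each gene's observed cross-cell variance by the variance expected
at its mean, where the expectation comes from the lowest-degree polynomial
regression of log(sigma^2) on log(mu) that leaves the residual ratio
uncorrelated with the mean (Kendall rank test).  F' is the plain coefficient
of variation.  Consistency is the number of cells with FPKM > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class VarianceModel:
    """Polynomial fit of log variance on log mean, plus the decorrelation
    check on the data it was fitted to."""

    degree: int
    coefficients: np.ndarray  # ascending powers
    tau: float
    pvalue: float
    exhausted: bool = False  # no degree <= max_degree decorrelated F* from mu

    def predict_log_var(self, mu: np.ndarray) -> np.ndarray:
        L = np.log(np.asarray(mu, dtype=float))
        return sum(c * L**k for k, c in enumerate(self.coefficients))


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def filter_expressed(
    matrix: pd.DataFrame, threshold: float = 1.5, log_base: float = 2.0
) -> pd.DataFrame:
    """Keep genes with log(FPKM + 1) > threshold in at least one cell."""
    if log_base <= 0 or log_base == 1:
        raise ValueError("invalid log base")
    if matrix.empty:
        raise ValueError("empty matrix")
    score = np.log(matrix.max(axis=1) + 1.0) / np.log(log_base)
    return matrix.loc[score > threshold]


def mean_variance(matrix: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Arithmetic mean and sample (n-1) variance over all cells, zeros
    included."""
    if matrix.shape[1] < 2:
        raise ValueError("need at least two cells")
    mu = matrix.mean(axis=1)
    var = matrix.var(axis=1, ddof=1)
    return mu, var


def fit_variance_trend(mu: pd.Series, var: pd.Series, degree: int) -> VarianceModel:
    """Least squares of log(sigma^2) on powers of log(mu) up to ``degree``.

    Genes with sigma^2 = 0 or mu <= 0 cannot enter the log-log fit and must
    be excluded by the caller.
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    mu_a = np.asarray(mu, dtype=float)
    var_a = np.asarray(var, dtype=float)
    if np.any(mu_a <= 0) or np.any(var_a <= 0):
        raise ValueError("trend fit requires mu > 0 and sigma^2 > 0")
    if len(mu_a) < degree + 1:
        raise ValueError("fewer genes than coefficients")
    L = np.log(mu_a)
    X = np.vander(L, degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(X, np.log(var_a), rcond=None)
    return VarianceModel(degree=degree, coefficients=coef, tau=np.nan, pvalue=np.nan)


def compute_Fstar(var: pd.Series, expected_var: pd.Series) -> pd.Series:
    """F* = observed variance / variance expected at the gene's mean."""
    ev = np.asarray(expected_var, dtype=float)
    if np.any(ev <= 0):
        raise ValueError("expected variance must be positive")
    return pd.Series(np.asarray(var, dtype=float) / ev, index=var.index, name="F_star")


def compute_Fprime(matrix: pd.DataFrame) -> pd.Series:
    """F' = coefficient of variation (sample sd / mean) across cells."""
    mu = matrix.mean(axis=1)
    if (mu <= 0).any():
        raise ValueError("F' undefined for genes with zero mean")
    sd = matrix.std(axis=1, ddof=1)
    return (sd / mu).rename("F_prime")


def expression_consistency(matrix: pd.DataFrame) -> pd.Series:
    """Number of cells in which the gene is detected (FPKM strictly > 0)."""
    return (matrix > 0).sum(axis=1).rename("consistency")


def kendall_tau(x, y) -> tuple[float, float]:
    """Tie-corrected Kendall tau-b; exact P by enumeration for n <= 8
    without ties, normal approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("tau undefined for a constant vector")
    ties = len(np.unique(x)) < len(x) or len(np.unique(y)) < len(y)
    method = "exact" if (len(x) <= 8 and not ties) else "asymptotic"
    res = stats.kendalltau(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# degree selection and the full table
# ---------------------------------------------------------------------------

def select_degree(
    mu: pd.Series,
    var: pd.Series,
    max_degree: int = 6,
    alpha: float = 0.05,
) -> VarianceModel:
    """Smallest polynomial degree whose residual ratio F* is uncorrelated
    with the mean (Kendall P >= alpha) on the fitted genes.

    If no degree up to ``max_degree`` decorrelates, the max-degree model is
    returned with ``exhausted=True``.
    """
    if max_degree < 1:
        raise ValueError("max_degree must be >= 1")
    if len(mu) < max_degree + 2:
        raise ValueError("too few genes for degree search")
    last = None
    for degree in range(1, max_degree + 1):
        model = fit_variance_trend(mu, var, degree)
        fstar = np.asarray(var) / np.exp(model.predict_log_var(np.asarray(mu)))
        tau, p = kendall_tau(fstar, np.asarray(mu))
        model.tau, model.pvalue = tau, p
        last = model
        if p >= alpha:
            return model
    last.exhausted = True
    return last


def build_noise_table(
    matrix: pd.DataFrame,
    threshold: float = 1.5,
    log_base: float = 2.0,
    max_degree: int = 6,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, VarianceModel]:
    """Filter, fit the variance trend, and assemble the per-gene noise table.

    Returns (table, model).  The table has mu, var, F_star, F_prime and
    consistency for every gene passing the expression filter; genes with
    zero variance (flat rows) keep NaN F* and are excluded from the trend
    fit.
    """
    expressed = filter_expressed(matrix, threshold=threshold, log_base=log_base)
    mu, var = mean_variance(expressed)
    usable = (mu > 0) & (var > 0)
    model = select_degree(mu[usable], var[usable], max_degree=max_degree, alpha=alpha)
    fstar = pd.Series(np.nan, index=expressed.index, name="F_star")
    fstar[usable] = compute_Fstar(
        var[usable], pd.Series(np.exp(model.predict_log_var(mu[usable])),
                               index=mu[usable].index)
    )
    table = pd.DataFrame(
        {
            "mu": mu,
            "var": var,
            "F_star": fstar,
            "F_prime": compute_Fprime(expressed),
            "consistency": expression_consistency(expressed),
        }
    )
    table.index.name = "gene_id"
    return table, model
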