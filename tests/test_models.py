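import itertools
import math

import numpy as np
import pandas as pd
import pytest

from gbmnoise import models
from gbmnoise.models import (
    ModelSpec,
    bh_adjust,
    bic_model_average,
    choose_transforms,
    fit_ancova,
    mann_whitney,
    pcr_fit,
    predict_gbm_model,
    spearman_rho,
    standardize,
    vif,
    vif_screen,
)


class TestMannWhitney:
    def test_exact_enumeration_example(self):
        # all C(4,2)=6 rank splits; only one as extreme each side -> P = 1/3
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0 and p == pytest.approx(1 / 3)

    def test_identical_samples_p_one(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_swap_symmetry(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=9)
        u1, p1 = mann_whitney(x, y)
        u2, p2 = mann_whitney(y, x)
        assert u1 + u2 == pytest.approx(len(x) * len(y))
        assert p1 == pytest.approx(p2)

    def test_exact_matches_permutation_enumeration(self, rng):
        x = np.array([0.3, 1.7, 2.9])
        y = np.array([0.9, 2.2, 3.5, 4.1, 5.0])
        u_obs, p_obs = mann_whitney(x, y)
        pooled = np.concatenate([x, y])
        stats = []
        for idx in itertools.combinations(range(8), 3):
            xs = pooled[list(idx)]
            ys = np.delete(pooled, list(idx))
            u = sum((xi > ys).sum() for xi in xs)
            stats.append(u)
        stats = np.array(stats, dtype=float)
        mean_u = len(x) * len(y) / 2
        p_exact = np.mean(np.abs(stats - mean_u) >= abs(u_obs - mean_u) - 1e-12)
        assert p_obs == pytest.approx(p_exact)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestBH:
    def test_hand_worked_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_equal_unchanged(self):
        assert np.allclose(bh_adjust([0.4, 0.4, 0.4]), 0.4)

    def test_monotone_and_never_below_raw(self, rng):
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_domain_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestSpearman:
    def test_monotone_pairs(self):
        assert spearman_rho([1, 2, 3], [10, 20, 30])[0] == 1.0
        assert spearman_rho([1, 2, 3], [3, 1, 0])[0] == -1.0

    def test_matches_rank_then_pearson_with_ties(self, rng):
        x = rng.integers(0, 3, 6).astype(float)
        x[0] = 9  # ensure non-constant
        y = rng.integers(0, 3, 6).astype(float)
        y[1] = -4
        rho, _ = spearman_rho(x, y)
        rx = pd.Series(x).rank().to_numpy()
        ry = pd.Series(y).rank().to_numpy()
        assert rho == pytest.approx(np.corrcoef(rx, ry)[0, 1])

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1], [1, 2, 3])


class TestStandardize:
    def test_sample_sd_scaling(self):
        out = standardize(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        assert np.allclose(out["x"], [-1, 0, 1])

    def test_already_standardized_unchanged(self, rng):
        x = rng.normal(size=40)
        x = (x - x.mean()) / x.std(ddof=1)
        out = standardize(pd.DataFrame({"x": x}))
        assert np.allclose(out["x"], x, atol=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            standardize(pd.DataFrame({"x": [2.0, 2.0, 2.0]}))


class TestVif:
    def test_orthogonal_predictors_unit_vif(self, rng):
        z = rng.normal(size=(50, 3))
        z -= z.mean(axis=0)  # orthogonal to the intercept as well
        q, _ = np.linalg.qr(z)
        design = pd.DataFrame(q, columns=list("abc"))
        assert np.allclose(vif(design), 1.0)

    def test_closed_form_at_correlation_half(self, rng):
        # construct exact sample correlation 0.5 -> vif = 1/(1-0.25) = 4/3
        z = rng.normal(size=(100, 2))
        z -= z.mean(axis=0)
        q, _ = np.linalg.qr(z)
        x, w = q[:, 0], q[:, 1]
        y = 0.5 * x + math.sqrt(0.75) * w
        v = vif(pd.DataFrame({"x": x, "y": y}))
        assert np.allclose(v, 4 / 3)

    def test_duplicated_column_rejected(self, rng):
        x = rng.normal(size=30)
        with pytest.raises(ValueError, match="rank"):
            vif(pd.DataFrame({"a": x, "b": x}))

    def test_screen_drops_duplicate_then_passes(self, rng):
        x = rng.normal(size=60)
        w = rng.normal(size=60)
        design = pd.DataFrame({"a": x, "a_dup": x, "b": w})
        kept, dropped = vif_screen(design)
        assert dropped == ["a_dup"]
        assert list(kept.columns) == ["a", "b"]


class TestAncova:
    def test_exact_linear_fit(self, rng):
        x = rng.normal(size=30)
        y = pd.Series(3.0 + 2.0 * x)
        fit = fit_ancova(pd.DataFrame({"x": x}), y)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)
        assert fit.coefficients["x"] == pytest.approx(2.0)

    def test_single_predictor_type2_equals_regression_ss(self, rng):
        x = rng.normal(size=40)
        y = pd.Series(1.0 + 0.8 * x + rng.normal(0, 0.5, 40))
        fit = fit_ancova(pd.DataFrame({"x": x}), y)
        tss = ((y - y.mean()) ** 2).sum()
        assert fit.anova.loc["x", "sum_sq"] == pytest.approx(tss - fit.rss)

    def test_coefficient_matches_closed_form_slope(self, rng):
        x = rng.normal(2.0, 3.0, size=200)
        y = pd.Series(2.0 * x)
        xs = (x - x.mean()) / x.std(ddof=1)
        fit = fit_ancova(pd.DataFrame({"x": xs}), y)
        # slope on standardized x = raw slope * sd(x)
        assert fit.coefficients["x"] == pytest.approx(2.0 * x.std(ddof=1))

    def test_singular_design_rejected(self, rng):
        x = rng.normal(size=20)
        with pytest.raises(ValueError):
            fit_ancova(pd.DataFrame({"a": x, "b": x}), pd.Series(x))


class TestBicAveraging:
    def test_cross_checked_against_per_subset_ancova(self, rng):
        """Gram-matrix enumeration must agree with statsmodels-based fits of
        every subset (weights, averaged coefficients, importance, best)."""
        n, p = 80, 3
        X = pd.DataFrame(rng.normal(size=(n, p)), columns=list("abc"))
        y = pd.Series(0.7 * X["a"] - 0.4 * X["c"] + rng.normal(0, 1, n))
        avg = bic_model_average(X, y)

        subsets = [list(s) for r in range(p + 1)
                   for s in itertools.combinations(list("abc"), r)]
        bics, coefs = [], []
        for s in subsets:
            if s:
                fit = fit_ancova(X[s], y)
                bics.append(fit.bic)
                coefs.append(fit.coefficients.drop("Intercept"))
            else:
                rss = ((y - y.mean()) ** 2).sum()
                bics.append(n * np.log(rss / n) + np.log(n))
                coefs.append(pd.Series(dtype=float))
        bics = np.array(bics)
        w = np.exp(-0.5 * (bics - bics.min()))
        w /= w.sum()
        expect_coef = pd.Series(0.0, index=list("abc"))
        expect_imp = pd.Series(0.0, index=list("abc"))
        for s, wi, c in zip(subsets, w, coefs):
            for name in s:
                expect_coef[name] += wi * c[name]
                expect_imp[name] += wi
        assert np.allclose(avg.coefficients, expect_coef)
        assert np.allclose(avg.importance, expect_imp)
        assert sorted(avg.best_predictors) == sorted(
            subsets[int(np.argmin(bics))]
        )
        assert avg.weights.sum() == pytest.approx(1.0)

    def test_delta_bic_two_gives_weight_ratio_e(self):
        w = np.exp(-0.5 * np.array([0.0, 2.0]))
        w /= w.sum()
        assert w[0] / w[1] == pytest.approx(math.e)

    def test_always_keep_has_importance_one(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        y = pd.Series(rng.normal(size=60))
        avg = bic_model_average(X, y, always_keep=["b"])
        assert avg.importance["b"] == pytest.approx(1.0)

    def test_too_many_predictors_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 21)))
        X.columns = [f"x{i}" for i in range(21)]
        with pytest.raises(ValueError, match="too many"):
            bic_model_average(X, pd.Series(rng.normal(size=30)))


class TestTransformSelection:
    def _table(self, rng, log_linear: bool):
        x = np.exp(rng.uniform(0, 4, 300))
        w = rng.normal(size=300)
        y = (np.log(x) if log_linear else x) + 0.5 * w + rng.normal(0, 0.3, 300)
        return pd.DataFrame({"y": y, "x": x, "w": w})

    def test_log_kept_when_response_log_linear(self, rng):
        tab = self._table(rng, log_linear=True)
        spec = choose_transforms(tab, ModelSpec("y", ["x", "w"]))
        assert spec.transforms["x"] == "log"

    def test_identity_kept_when_response_linear(self, rng):
        tab = self._table(rng, log_linear=False)
        spec = choose_transforms(tab, ModelSpec("y", ["x", "w"]))
        assert spec.transforms["x"] == "identity"

    def test_exempt_variable_never_logged(self, rng):
        tab = self._table(rng, log_linear=True)
        spec = choose_transforms(
            tab, ModelSpec("y", ["x", "w"], log_exempt={"x"})
        )
        assert spec.transforms.get("x", "identity") == "identity"

    def test_log1p_fallback_recorded_for_zeros(self, rng):
        tab = self._table(rng, log_linear=True)
        tab.loc[tab.index[:5], "x"] = 0.0
        tab["y"] = np.log1p(tab["x"]) + rng.normal(0, 0.1, len(tab))
        spec = choose_transforms(tab, ModelSpec("y", ["x", "w"]))
        assert spec.transforms["x"] == "log1p"

    def test_response_cannot_be_predictor(self):
        with pytest.raises(ValueError):
            ModelSpec("y", ["y", "x"])


class TestPcr:
    def test_orthonormal_features_match_plain_ancova(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(200, 4)))
        feats = pd.DataFrame(q * math.sqrt(199), columns=list("abcd"))
        g = pd.Series((rng.uniform(size=200) < 0.4).astype(float))
        y = pd.Series(0.5 * g + q @ [1.0, -1.0, 0.5, 0.0] + rng.normal(0, 1, 200))
        pcr = pcr_fit(feats, g, y)
        gs = (g - g.mean()) / g.std(ddof=1)
        direct = fit_ancova(
            pd.concat([gs.rename("gbM"), standardize(feats)], axis=1), y
        )
        assert pcr.coefficients["gbM"] == pytest.approx(
            direct.coefficients["gbM"]
        )
        assert pcr.anova.loc["gbM", "P"] == pytest.approx(
            direct.anova.loc["gbM", "P"]
        )

    def test_zero_variance_feature_rejected(self, rng):
        feats = pd.DataFrame({"a": rng.normal(size=50), "b": np.ones(50)})
        g = pd.Series((rng.uniform(size=50) < 0.5).astype(float))
        with pytest.raises(ValueError):
            pcr_fit(feats, g, pd.Series(rng.normal(size=50)))


class TestPredictGbm:
    def test_duplicated_predictor_screened_before_averaging(self, rng):
        x = rng.normal(size=300)
        w = rng.normal(size=300)
        g = pd.Series((x + rng.normal(0, 1, 300) > 0).astype(float))
        table = pd.DataFrame({"x": x, "x_copy": x, "w": w})
        avg, dropped = predict_gbm_model(table, g)
        assert dropped == ["x_copy"]
        assert "x" in avg.best_predictors and "w" not in avg.best_predictors


class TestGroupComparison:
    def test_medians_proportions_and_bh(self, rng):
        n = 60
        labels = pd.Series(["A"] * 30 + ["B"] * 30,
                           index=[f"g{i}" for i in range(n)])
        data = pd.DataFrame(
            {
                "cont": np.r_[rng.normal(0, 1, 30), rng.normal(3, 1, 30)],
                "bin": np.r_[np.ones(30), np.zeros(30)],
            },
            index=labels.index,
        )
        out = models.group_comparison(data, labels, "A", "B")
        assert out.loc["bin", "summary"] == "proportion"
        assert out.loc["bin", "A"] == 1.0 and out.loc["bin", "B"] == 0.0
        assert out.loc["cont", "summary"] == "median"
        assert (out["P_adj"] >= out["P"] - 1e-15).all()
        assert out.loc["cont", "P"] < 1e-6
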