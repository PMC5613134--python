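import numpy as np
import pandas as pd
import pytest

from hybridgs.kinship import KinshipMatrix
from hybridgs.mixed_model import (
    RandomTerm,
    assemble_model,
    parts_of_variance,
    predict_hybrids,
    reml_fit,
    zratio,
)


def oracle_restricted_loglik(theta, grams, y, X=None):
    """Restricted log-likelihood from the definition (independent code path)."""
    n = len(y)
    if X is None:
        X = np.ones((n, 1))
    V = theta[-1] * np.eye(n)
    for t, G in zip(theta[:-1], grams):
        V = V + t * G
    Vi = np.linalg.inv(V)
    XtVX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtVX) @ X.T @ Vi
    return -0.5 * (
        np.linalg.slogdet(V)[1] + np.linalg.slogdet(XtVX)[1] + float(y @ P @ y)
    )


def one_way_anova_reml(y, g, r):
    """Closed-form REML for the balanced one-way random-effects layout."""
    Y = y.reshape(g, r)
    ybar = Y.mean(axis=1)
    msb = r * np.sum((ybar - y.mean()) ** 2) / (g - 1)
    msw = np.sum((Y - ybar[:, None]) ** 2) / (g * (r - 1))
    s2g = max((msb - msw) / r, 0.0)
    s2e = msw if s2g > 0 else np.sum((y - y.mean()) ** 2) / (len(y) - 1)
    return s2g, s2e


class TestRemlOracles:
    @pytest.mark.parametrize("seed,s_g,s_e", [(0, 1.5, 1.0), (1, 0.3, 2.0), (2, 0.0, 1.0)])
    def test_balanced_one_way_matches_closed_form(self, seed, s_g, s_e):
        rng = np.random.default_rng(seed)
        g, r = 10, 4
        y = np.repeat(rng.normal(0, np.sqrt(s_g), g), r) + rng.normal(0, np.sqrt(s_e), g * r)
        term = RandomTerm("grp", list(range(g)), np.repeat(np.arange(g), r))
        fit = reml_fit(y, [term])
        s2g, s2e = one_way_anova_reml(y, g, r)
        assert fit.var_components["grp"] == pytest.approx(s2g, abs=1e-6)
        assert fit.resid_variance == pytest.approx(s2e, rel=1e-5)
        if s2g == 0.0:
            assert fit.boundary["grp"]

    def test_loglik_beats_grid_on_kinship_toy(self):
        rng = np.random.default_rng(4)
        n = 18
        M = rng.normal(size=(n, 25))
        K = KinshipMatrix(list(range(n)), M @ M.T / 25)
        y = rng.normal(size=n)
        term = RandomTerm("gen", list(range(n)), np.arange(n), kinship=K)
        fit = reml_fit(y, [term])
        grid = np.exp(np.linspace(np.log(1e-3), np.log(20), 20))
        best = max(
            oracle_restricted_loglik((a, b), [K.values], y) for a in grid for b in grid
        )
        assert fit.loglik >= best - 1e-9

    def test_permutation_null_drives_genetic_variance_to_boundary(self):
        rng = np.random.default_rng(8)
        n = 60
        M = rng.normal(size=(n, 40))
        K = KinshipMatrix(list(range(n)), M @ M.T / 40)
        term = RandomTerm("gen", list(range(n)), np.arange(n), kinship=K)
        L = np.linalg.cholesky(K.values + 1e-8 * np.eye(n))
        hits = 0
        reps = 20
        for _ in range(reps):
            y = L @ rng.normal(size=n) * 1.5 + rng.normal(size=n)
            y_perm = rng.permutation(y)
            fit = reml_fit(y_perm, [term])
            hits += fit.var_components["gen"] < 0.1 * np.var(y_perm)
        assert hits >= 0.7 * reps


class TestZRatio:
    def test_strong_term_gives_large_ratio_and_scale_invariance(self):
        rng = np.random.default_rng(2)
        g, r = 40, 5
        y = np.repeat(rng.normal(0, 2.0, g), r) + rng.normal(0, 1.0, g * r)
        K = KinshipMatrix(list(range(g)), np.eye(g))
        inc = np.repeat(np.arange(g), r)
        fit = reml_fit(y, [RandomTerm("grp", list(range(g)), inc, kinship=K)])
        z = zratio(fit, "grp")
        assert z > 2
        K2 = KinshipMatrix(list(range(g)), 2.0 * np.eye(g))
        fit2 = reml_fit(y, [RandomTerm("grp", list(range(g)), inc, kinship=K2)])
        assert zratio(fit2, "grp") == pytest.approx(z, rel=1e-4)

    def test_boundary_component_is_flagged_undefined(self):
        rng = np.random.default_rng(3)
        g, r = 10, 3
        y = rng.normal(size=g * r)  # pure noise
        term = RandomTerm("grp", list(range(g)), np.repeat(np.arange(g), r))
        fit = reml_fit(y, [term])
        if fit.boundary["grp"]:
            with pytest.warns(UserWarning, match="boundary"):
                assert np.isnan(zratio(fit, "grp"))
        else:
            pytest.skip("estimate did not land on the boundary for this draw")


class TestPrediction:
    def test_explicit_matrix_oracle_on_toy(self):
        rng = np.random.default_rng(9)
        females = ["F1", "F2", "F3"]
        males = ["M1", "M2", "M3"]
        Mf = rng.normal(size=(3, 10))
        Mm = rng.normal(size=(3, 10))
        Kf = KinshipMatrix(females, Mf @ Mf.T / 10)
        Km = KinshipMatrix(males, Mm @ Mm.T / 10)
        obs = [("F1", "M1"), ("F1", "M2"), ("F2", "M1"), ("F2", "M2"),
               ("F3", "M1"), ("F3", "M2"), ("F1", "M3"), ("F2", "M3")]
        y = rng.normal(45, 2, len(obs))
        fit = reml_fit(y, assemble_model("FM", obs, {"Kf": Kf, "Km": Km}))
        target = [("F3", "M3"), ("F1", "M1")]
        preds = predict_hybrids(fit, target)
        # oracle: mu + sum_k s2_k K_k[*, obs] V^-1 (y - mu)
        s2f = fit.var_components["female"]
        s2m = fit.var_components["male"]
        fi = [females.index(f) for f, _ in obs]
        mi = [males.index(m) for _, m in obs]
        V = (
            s2f * Kf.values[np.ix_(fi, fi)]
            + s2m * Km.values[np.ix_(mi, mi)]
            + fit.resid_variance * np.eye(len(obs))
        )
        r = np.linalg.solve(V, y - fit.intercept)
        for t, (f, m) in enumerate(target):
            want = (
                fit.intercept
                + s2f * Kf.values[females.index(f), fi] @ r
                + s2m * Km.values[males.index(m), mi] @ r
            )
            assert preds[t] == pytest.approx(want, abs=1e-8)

    def test_identity_gca_unobserved_parent_predicts_zero_blup(self):
        rng = np.random.default_rng(10)
        Kf = KinshipMatrix(["F1", "F2", "F3"], np.eye(3))
        Km = KinshipMatrix(["M1", "M2"], np.eye(2))
        obs = [("F1", "M1"), ("F1", "M2"), ("F2", "M1"), ("F2", "M2")] * 3
        y = rng.normal(size=len(obs))
        fit = reml_fit(y, assemble_model("GCA", obs, {"Kf": Kf, "Km": Km}))
        assert fit.blups["gca_female"].loc["F3"] == 0.0
        pred = predict_hybrids(fit, [("F3", "M1")])[0]
        assert pred == pytest.approx(fit.intercept + fit.blups["gca_male"].loc["M1"])

    def test_zero_kinship_parent_contributes_zero(self):
        rng = np.random.default_rng(11)
        vals = np.eye(3)
        vals[2, :2] = vals[:2, 2] = 0.0  # F3 unrelated to trained parents
        Kf = KinshipMatrix(["F1", "F2", "F3"], vals)
        Km = KinshipMatrix(["M1", "M2"], np.eye(2))
        obs = [("F1", "M1"), ("F1", "M2"), ("F2", "M1"), ("F2", "M2")] * 3
        y = rng.normal(size=len(obs))
        fit = reml_fit(y, assemble_model("FM", obs, {"Kf": Kf, "Km": Km}))
        assert fit.blups["female"].loc["F3"] == pytest.approx(0.0, abs=1e-12)

    def test_missing_parent_raises(self):
        Kf = KinshipMatrix(["F1", "F2"], np.eye(2))
        Km = KinshipMatrix(["M1", "M2"], np.eye(2))
        obs = [("F1", "M1"), ("F2", "M2"), ("F1", "M2"), ("F2", "M1")]
        y = np.array([1.0, 2.0, 3.0, 2.5])
        fit = reml_fit(y, assemble_model("FM", obs, {"Kf": Kf, "Km": Km}))
        with pytest.raises(KeyError):
            predict_hybrids(fit, [("F9", "M1")])


class TestModelAssembly:
    def test_term_counts_per_family(self, small_kernels, obs_crosses):
        assert len(assemble_model("GCA", obs_crosses, small_kernels)) == 2
        assert len(assemble_model("FM", obs_crosses, small_kernels)) == 2
        assert len(assemble_model("FMI", obs_crosses, small_kernels)) == 3
        kern = dict(small_kernels)
        kern["Kf_oil"], kern["Km_oil"] = kern["Kf_oil"], kern["Km_oil"]
        assert len(assemble_model("mk_oil", obs_crosses, kern)) == 4
        assert len(assemble_model("mk_epi", obs_crosses, small_kernels)) == 4
        with pytest.raises(ValueError, match="unknown model kind"):
            assemble_model("XX", obs_crosses, small_kernels)

    def test_gca_equals_fm_with_identity_kernels(self, small_study, obs_crosses):
        ident = {
            "Kf": KinshipMatrix(small_study.females.parent_ids, np.eye(10)),
            "Km": KinshipMatrix(small_study.males.parent_ids, np.eye(10)),
        }
        y = small_study.truth.hybrid_phenotypes.query("environment == 'E01'")[
            "value"
        ].to_numpy()
        fit_gca = reml_fit(y, assemble_model("GCA", obs_crosses, ident))
        fit_fm = reml_fit(y, assemble_model("FM", obs_crosses, ident))
        assert fit_gca.loglik == pytest.approx(fit_fm.loglik, abs=1e-6)
        np.testing.assert_allclose(
            predict_hybrids(fit_gca, obs_crosses),
            predict_hybrids(fit_fm, obs_crosses),
            atol=1e-6,
        )

    def test_non_psd_kernel_rejected(self):
        bad = KinshipMatrix(["a", "b"], np.array([[1.0, 2.0], [2.0, 1.0]]))
        term = RandomTerm("t", ["a", "b"], [0, 1, 0, 1], kinship=bad)
        with pytest.raises(ValueError, match="not PSD"):
            reml_fit(np.array([1.0, 2.0, 1.5, 2.5]), [term])


class TestInvariances:
    def test_kernel_scale_invariance_of_fit_and_predictions(self, small_study, small_kernels, obs_crosses):
        y = small_study.truth.hybrid_phenotypes.query("environment == 'E02'")[
            "value"
        ].to_numpy()
        fit1 = reml_fit(y, assemble_model("FM", obs_crosses, small_kernels))
        c = 7.5
        scaled = {
            "Kf": KinshipMatrix(small_kernels["Kf"].entities, c * small_kernels["Kf"].values),
            "Km": KinshipMatrix(small_kernels["Km"].entities, small_kernels["Km"].values),
        }
        fit2 = reml_fit(y, assemble_model("FM", obs_crosses, scaled))
        assert fit2.loglik == pytest.approx(fit1.loglik, abs=1e-6)
        assert fit2.var_components["female"] * c == pytest.approx(
            fit1.var_components["female"], rel=1e-5
        )
        np.testing.assert_allclose(
            predict_hybrids(fit1, obs_crosses), predict_hybrids(fit2, obs_crosses), atol=1e-6
        )

    def test_gblup_equals_rrblup_predictions(self):
        rng = np.random.default_rng(12)
        n, L = 25, 40
        M = rng.normal(size=(n, L))
        y = M @ rng.normal(0, 0.3, L) + rng.normal(size=n)
        K = KinshipMatrix(list(range(n)), M @ M.T)
        fit = reml_fit(y, [RandomTerm("gen", list(range(n)), np.arange(n), kinship=K)])
        s2g, s2e = fit.var_components["gen"], fit.resid_variance
        V = s2g * (M @ M.T) + s2e * np.eye(n)
        Vi = np.linalg.inv(V)
        ones = np.ones(n)
        mu = (ones @ Vi @ y) / (ones @ Vi @ ones)
        marker_effects = s2g * M.T @ Vi @ (y - mu)  # ridge solution, matched penalty
        pred_rr = mu + M @ marker_effects
        pred_gb = fit.intercept + fit.blups["gen"].to_numpy()
        np.testing.assert_allclose(pred_gb, pred_rr, atol=1e-8)

    def test_null_interaction_leaves_other_components_unchanged(
        self, small_study, small_kernels, obs_crosses
    ):
        # no simulated interaction in this study: FM and FMI should agree
        diffs = []
        for env in ("E01", "E02", "E03"):
            y = small_study.truth.hybrid_phenotypes.query("environment == @env")[
                "value"
            ].to_numpy()
            fm = reml_fit(y, assemble_model("FM", obs_crosses, small_kernels))
            fmi = reml_fit(y, assemble_model("FMI", obs_crosses, small_kernels))
            denom = fm.var_components["female"] + fm.var_components["male"]
            diffs.append(
                abs(fmi.var_components["female"] - fm.var_components["female"]) / denom
                + abs(fmi.var_components["male"] - fm.var_components["male"]) / denom
            )
        assert np.mean(diffs) < 0.15


class TestPartsOfVariance:
    def test_equal_components_give_symmetric_shares(self):
        pv = parts_of_variance({"a": 1.0, "b": 1.0, "residual": 2.0})
        assert pv.shares["a"] == pytest.approx(0.25)
        assert pv.shares["b"] == pytest.approx(0.25)
        assert sum(pv.shares.values()) == pytest.approx(1.0)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError, match="zero"):
            parts_of_variance({"a": 0.0, "residual": 0.0})
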