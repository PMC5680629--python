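"""Tests of trait standardization, the logistic survival models, AICc ranking
and the gradient transformations, each against an independent oracle where
one exists (grid search, statsmodels, lme4-verified constants, finite
differences)."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from anglesel import selection
from anglesel.selection import (
    FitResult,
    PondLogisticRegression,
    aicc,
    akaike_weights,
    assign_fitness,
    fit_logistic,
    growth_residuals,
    janzen_stern,
    mean_standardized_gradients,
    nagelkerke_r2,
    zstandardize,
)


def toy_raw(n=40, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "fish_id": [f"F{i}" for i in range(n)],
            "pond": rng.integers(1, 4, n),
            "BP": rng.normal(4.6, 1.5, n),
            "TL": rng.normal(199, 9.2, n),
            "G": rng.normal(0, 5, n),
            "SB": rng.normal(0, 1, n),
            "SH": rng.normal(0, 1, n),
            "SP": rng.normal(6.3, 2.6, n),
        }
    )


class TestGrowthResiduals:
    def test_uncorrelated_inputs_centered(self, rng):
        bp = rng.normal(5, 1, 2000)
        inc = rng.normal(8, 5, 2000)
        resid = growth_residuals(inc, bp)
        assert abs(resid.mean()) < 1e-10
        assert np.allclose(resid, inc - inc.mean(), atol=1.0)

    def test_exact_linear_gives_zero(self):
        bp = np.linspace(2, 8, 30)
        assert np.max(np.abs(growth_residuals(1 + 2 * bp, bp))) < 1e-10

    def test_residuals_orthogonal_to_bp(self, rng):
        bp = rng.normal(5, 1, 100)
        inc = 2 * bp + rng.normal(0, 3, 100)
        assert abs(np.corrcoef(growth_residuals(inc, bp), bp)[0, 1]) < 1e-12


class TestZStandardize:
    def test_columns_standardized(self):
        tm = zstandardize(toy_raw())
        for t in selection.BASE_TRAITS:
            assert abs(tm.z[t].mean()) < 1e-10
            assert tm.z[t].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_hand_computed_example(self):
        raw = toy_raw(3)
        raw["BP"] = [1.0, 2.0, 3.0]
        tm = zstandardize(raw)
        assert np.allclose(tm.z["BP"], [-1, 0, 1])
        assert tm.means["BP"] == 2.0 and tm.sds["BP"] == 1.0

    def test_quadratics_are_squares_of_z(self):
        tm = zstandardize(toy_raw())
        assert np.allclose(tm.z["G2"], tm.z["G"] ** 2)
        assert np.allclose(tm.z["BP2"], tm.z["BP"] ** 2)

    def test_zero_variance_trait_named(self):
        raw = toy_raw()
        raw["SH"] = 1.0
        with pytest.raises(ValueError, match="SH"):
            zstandardize(raw)


class TestAssignFitness:
    ROSTER = pd.DataFrame({"fish_id": ["A", "B", "C"]})

    def test_empty_log_all_survive(self):
        caps = pd.DataFrame(columns=["fish_id", "day", "session"])
        assert assign_fitness(caps, 7, self.ROSTER).eq(1).all()

    def test_first_capture_day_vs_horizon(self):
        caps = pd.DataFrame({"fish_id": ["A", "A"], "day": [9, 12], "session": [1, 1]})
        assert assign_fitness(caps, 7, self.ROSTER)["A"] == 1
        assert assign_fitness(caps, 20, self.ROSTER)["A"] == 0

    def test_printed_counts(self):
        roster = pd.DataFrame({"fish_id": [f"F{i}" for i in range(94)]})
        caps = pd.DataFrame({"fish_id": [f"F{i}" for i in range(38)], "day": 3, "session": 1})
        s = assign_fitness(caps, 7, roster)
        assert (s == 0).sum() == 38

    def test_unknown_capture_raises(self):
        caps = pd.DataFrame({"fish_id": ["Z"], "day": [1], "session": [1]})
        with pytest.raises(ValueError, match="Z"):
            assign_fitness(caps, 7, self.ROSTER)

    @pytest.mark.parametrize("seed", range(3))
    def test_horizon_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        roster = pd.DataFrame({"fish_id": [f"F{i}" for i in range(30)]})
        caps = pd.DataFrame(
            {
                "fish_id": rng.choice(roster["fish_id"], 40),
                "day": rng.integers(1, 21, 40),
                "session": 1,
            }
        )
        s7 = assign_fitness(caps, 7, roster)
        s20 = assign_fitness(caps, 20, roster)
        assert (s7 >= s20).all()


class TestLogisticFit:
    def test_intercept_only_closed_form(self):
        X = pd.DataFrame(index=range(100))
        y = np.array([1] * 60 + [0] * 40)
        est = PondLogisticRegression(terms=(), pond_mode="none").fit(X, y)
        assert est.coef_["(Intercept)"] == pytest.approx(np.log(60 / 40), abs=1e-6)

    def test_matches_two_stage_grid_search(self):
        x = np.array([-1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5, 2.0])
        y = np.array([0, 0, 1, 0, 1, 1, 1, 1])
        est = PondLogisticRegression(terms=("x",), pond_mode="none").fit(
            pd.DataFrame({"x": x}), y
        )

        def ll(a, b):
            eta = a + b * x
            return np.sum(y * eta - np.logaddexp(0, eta))

        # independent oracle: coarse grid then local refinement
        grid = np.arange(-5, 5, 0.05)
        best = max(((ll(a, b), a, b) for a in grid for b in grid))[1:]
        fine_a = np.arange(best[0] - 0.1, best[0] + 0.1, 0.001)
        fine_b = np.arange(best[1] - 0.1, best[1] + 0.1, 0.001)
        _, a_hat, b_hat = max((ll(a, b), a, b) for a in fine_a for b in fine_b)
        assert est.coef_["(Intercept)"] == pytest.approx(a_hat, abs=1e-3)
        assert est.coef_["x"] == pytest.approx(b_hat, abs=1e-3)

    def test_matches_statsmodels_logit(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 3)), columns=["a", "b", "c"])
        eta = -0.2 + X["a"] - 0.8 * X["b"]
        y = (rng.random(200) < expit(eta)).astype(int)
        est = PondLogisticRegression(terms=("a", "b", "c"), pond_mode="none").fit(X, y)
        sm_fit = sm.Logit(y, sm.add_constant(X[["a", "b", "c"]])).fit(disp=0)
        assert np.allclose(est.coef_.to_numpy(), sm_fit.params.to_numpy(), atol=1e-6)
        assert np.allclose(est.se_.to_numpy(), sm_fit.bse.to_numpy(), atol=1e-5)
        assert est.loglik_ == pytest.approx(sm_fit.llf, abs=1e-8)

    def test_constant_predictor_rank_failure(self):
        X = pd.DataFrame({"x": np.zeros(50)})
        y = np.tile([0, 1], 25)
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            PondLogisticRegression(terms=("x",), pond_mode="none").fit(X, y)

    def test_separation_reported(self):
        X = pd.DataFrame({"x": np.linspace(-2, 2, 40)})
        y = (X["x"] > 0).astype(int).to_numpy()
        with pytest.raises(RuntimeError, match="separation"):
            PondLogisticRegression(terms=("x",), pond_mode="none").fit(X, y)

    def test_random_intercept_matches_lme4(self):
        # identical dataset fitted with lme4::glmer (nAGQ=1, Laplace) gives
        # fixef (-0.1847997, 1.365536), tau 0.3234527, logLik -35.44852
        rng = np.random.default_rng(42)
        n = 60
        pond = np.repeat([1, 2, 3], 20)
        x = rng.standard_normal(n).round(4)
        u_true = {1: -0.8, 2: 0.1, 3: 0.9}
        eta = -0.3 + 0.9 * x + np.array([u_true[p] for p in pond])
        y = (rng.random(n) < expit(eta)).astype(int)
        est = PondLogisticRegression(terms=("x",), pond_mode="random").fit(
            pd.DataFrame({"x": x, "pond": pond}), y
        )
        assert est.coef_["(Intercept)"] == pytest.approx(-0.1847997, abs=1e-3)
        assert est.coef_["x"] == pytest.approx(1.365536, abs=1e-3)
        assert est.tau_ == pytest.approx(0.3234527, abs=1e-3)
        assert est.loglik_ == pytest.approx(-35.44852, abs=1e-4)

    def test_fixed_mode_counts_pond_dummies(self):
        raw = toy_raw(60, seed=3)
        tm = zstandardize(raw)
        y = pd.Series((np.arange(60) % 2), index=tm.fish_id)
        fr = fit_logistic(("BP",), tm, y, pond_mode="fixed")
        assert fr.k == 2 + 2  # intercept + BP + two pond dummies

    def test_random_mode_k_counts_fixed_effects_only(self):
        raw = toy_raw(60, seed=4)
        tm = zstandardize(raw)
        y = pd.Series((np.arange(60) % 2), index=tm.fish_id)
        assert fit_logistic((), tm, y, pond_mode="random").k == 1
        assert fit_logistic(("BP", "G"), tm, y, pond_mode="random").k == 3


class TestInformationCriteria:
    def test_aicc_arithmetic(self):
        assert aicc(-64.5, 1, 94) == pytest.approx(131.043, abs=5e-4)

    def test_correction_term_k9_n94(self):
        assert aicc(0.0, 9, 94) - (0.0 + 2 * 9) == pytest.approx(2 * 9 * 10 / 84)

    def test_aicc_tends_to_aic(self):
        assert aicc(-100.0, 5, 10**6) - (200 + 10) < 1e-3

    def test_single_model_weight_one(self):
        assert akaike_weights([123.4]) == pytest.approx([1.0])

    def test_equal_aicc_split_evenly(self):
        assert akaike_weights([100.0, 100.0]) == pytest.approx([0.5, 0.5])

    def test_shift_invariance_and_normalization(self, rng):
        v = rng.uniform(100, 150, 9)
        w1 = akaike_weights(v)
        w2 = akaike_weights(v + 37.5)
        assert np.allclose(w1, w2, atol=1e-12)
        assert w1.sum() == pytest.approx(1.0, abs=1e-12)


@pytest.fixture(scope="module")
def fitted():
    raw = toy_raw(94, seed=5)
    tm = zstandardize(raw)
    rng = np.random.default_rng(6)
    eta = (0.3 - 1.0 * tm.z["BP"] - 0.9 * tm.z["G"]).to_numpy()
    y = pd.Series((rng.random(94) < expit(eta)).astype(int).tolist(), index=tm.fish_id)
    return selection.run_model_set(tm, y, horizon="long", pond_mode="none")


class TestModelSet:

    def test_null_has_k1_and_weights_sum_to_one(self, fitted):
        comp, _ = fitted
        assert comp.loc[comp.model_no == 9, "k"].item() == 1
        assert comp["weight"].sum() == pytest.approx(1.0)

    def test_generative_terms_attract_weight(self, fitted):
        comp, _ = fitted
        bp_g = comp[comp["terms"].str.contains("BP")]["weight"].sum()
        assert bp_g > 0.8

    def test_final_model_is_richest_within_delta1(self, fitted):
        comp, fits = fitted
        final = selection.select_final_model(comp, fits)
        cand = comp[comp["best"]]
        assert final.k == cand["k"].max()

    def test_short_and_long_sets_have_nine_models(self):
        for key in ("short", "long"):
            ms = selection.MODEL_SETS[key]
            assert sorted(ms) == list(range(1, 10))
            assert ms[9] == ()
            assert len(ms[1]) == 8


def _manual_fit(terms=("x",), n=50, seed=8):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({"x": rng.normal(size=n)})
    y = (rng.random(n) < expit(0.4 + 0.9 * X["x"])).astype(int).to_numpy()
    est = PondLogisticRegression(terms=terms, pond_mode="none").fit(X, y)
    return est.result_, X, y


class TestGradients:
    def test_half_probability_factor(self):
        fr = FitResult(
            terms=("x",),
            coef=pd.Series({"(Intercept)": 0.0, "x": 0.8}),
            se=pd.Series({"(Intercept)": 1.0, "x": 1.0}),
            p_values=pd.Series({"(Intercept)": 1.0, "x": 1.0}),
            loglik=-10.0, k=2, n=20,
            fitted=np.full(20, 0.5), mean_fitness=0.5, pond_mode="none",
        )
        beta = janzen_stern(fr)
        assert beta["x"] == pytest.approx(0.5 * 0.8)

    def test_zero_coefficient_zero_gradient(self):
        fr, _, _ = _manual_fit()
        fr.coef["x"] = 0.0
        assert janzen_stern(fr)["x"] == 0.0

    def test_matches_numerical_derivative_of_mean_relative_fitness(self):
        fr, X, y = _manual_fit(n=10, seed=9)
        beta_sd = janzen_stern(fr)["x"]
        a, b = fr.coef["(Intercept)"], fr.coef["x"]
        wbar = y.mean()

        def mean_rel_fitness(delta):
            return np.mean(expit(a + b * (X["x"] + delta))) / wbar

        h = 1e-5
        oracle = (mean_rel_fitness(h) - mean_rel_fitness(-h)) / (2 * h)
        assert beta_sd == pytest.approx(oracle, abs=1e-4)

    def test_mean_standardization(self):
        beta_sd = pd.Series({"TL": -0.151})
        mu = pd.Series({"TL": 199.0})
        sd = pd.Series({"TL": 9.2})
        bmu = mean_standardized_gradients(beta_sd, mu, sd)
        assert bmu["TL"] == pytest.approx(-0.151 * 199 / 9.2)
        assert bmu["TL"] == pytest.approx(-3.27, abs=0.005)

    def test_unit_invariance(self):
        beta_sd = pd.Series({"TL": -0.151})
        one = mean_standardized_gradients(beta_sd, pd.Series({"TL": 199.0}), pd.Series({"TL": 9.2}))
        two = mean_standardized_gradients(beta_sd, pd.Series({"TL": 398.0}), pd.Series({"TL": 18.4}))
        assert one["TL"] == pytest.approx(two["TL"])

    def test_quadratic_terms_have_no_mean_standardization(self):
        beta_sd = pd.Series({"G2": 0.2})
        out = mean_standardized_gradients(beta_sd, pd.Series({"G": 7.8}), pd.Series({"G": 5.4}))
        assert np.isnan(out["G2"])


class TestNagelkerke:
    def _fr(self, ll, n=50):
        return FitResult(
            terms=(), coef=pd.Series(dtype=float), se=pd.Series(dtype=float),
            p_values=pd.Series(dtype=float), loglik=ll, k=1, n=n,
            fitted=np.full(n, 0.5), mean_fitness=0.5, pond_mode="none",
        )

    def test_equal_likelihoods_zero(self):
        assert nagelkerke_r2(self._fr(-30.0), self._fr(-30.0)) == 0.0

    def test_perfect_fit_approaches_one(self):
        n = 50
        l0 = n * np.log(0.5)
        assert nagelkerke_r2(self._fr(-1e-9, n), self._fr(l0, n)) == pytest.approx(1.0, abs=1e-6)

    def test_matches_hand_formula(self):
        l0, l1, n = -60.0, -45.0, 94
        r2_cs = 1 - np.exp(2 * (l0 - l1) / n)
        expected = r2_cs / (1 - np.exp(2 * l0 / n))
        assert nagelkerke_r2(self._fr(l1, n), self._fr(l0, n)) == pytest.approx(expected, abs=1e-10)

    def test_decreasing_likelihood_raises(self):
        with pytest.raises(ValueError):
            nagelkerke_r2(self._fr(-50.0), self._fr(-40.0))


class TestDescriptives:
    def test_identical_groups_equal_means(self):
        raw = toy_raw(40)
        fitness = pd.Series(np.tile([0, 1], 20), index=raw["fish_id"])
        raw2 = pd.concat([raw[::2], raw[::2]], ignore_index=True)
        raw2["fish_id"] = [f"X{i}" for i in range(len(raw2))]
        f2 = pd.Series([0] * 20 + [1] * 20, index=raw2["fish_id"])
        desc, corr = selection.trait_descriptives(raw2, f2)
        piv = desc.pivot(index="trait", columns="group", values="mean")
        assert np.allclose(piv["captured"], piv["not_captured"])
        assert np.allclose(np.diag(corr), 1.0)
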