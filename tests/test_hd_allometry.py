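import itertools
import math

import numpy as np
import pytest

import allomkit as ak
from allomkit.data_model_io import DataError
from allomkit.hd_allometry import FitOptions, get_model, model_registry
from conftest import make_dataset

# representative parameters in physiological range, one set per model
TRUE_PARAMS = {
    "quadratic": (0.633, 1.112, -0.095),
    "michaelis_menten": (33.09, 18.43),
    "weibull": (30.0, 0.07, 0.85),
    "exp3": (39.0, 37.8, 0.042),
    "exp2": (37.8, 0.0465),
    "gompertz": (34.7, 2.285, 0.0863),
    "power": (4.15, 0.543),
    "mod_exp2": (39.4, -9.876),
    "logistic": (32.8, 6.25, 0.138),
    "log_linear": (-2.71, 8.65),
}


class TestRegistry:
    def test_ten_models_in_canonical_order(self):
        reg = model_registry()
        assert [m.name for m in reg] == list(ak.hd_allometry.MODEL_ORDER)
        assert [m.arity for m in reg] == [3, 2, 3, 3, 2, 3, 2, 2, 3, 2]

    def test_michaelis_menten_half_saturation(self):
        mm = get_model("michaelis_menten")
        a, b = 33.0, 18.0
        assert mm((a, b), b) == pytest.approx(a / 2)

    def test_weibull_asymptote(self):
        w = get_model("weibull")
        a = 30.0
        assert abs(w((a, 0.07, 0.85), 1e6) - a) < 1e-6 * a

    def test_forms_finite_on_domain(self):
        D = np.geomspace(0.5, 499, 50)
        for spec in model_registry():
            H = spec(TRUE_PARAMS[spec.name], D)
            assert np.all(np.isfinite(H)), spec.name

    def test_monotone_on_domain(self):
        """Every model with positive-range parameters is non-decreasing in D
        on its declared monotone domain."""
        for spec in model_registry():
            p = np.asarray(TRUE_PARAMS[spec.name], dtype=float)
            lo, hi = spec.monotone_domain(p)
            if not (lo < hi):
                continue
            D = np.linspace(max(lo, 0.5), min(hi, 400.0), 300)
            H = spec(p, D)
            assert np.all(np.diff(H) >= -1e-9), spec.name

    def test_quadratic_turning_point(self):
        spec = get_model("quadratic")
        p = np.array([0.633, 1.112, -0.095])
        lo, hi = spec.monotone_domain(p)
        assert hi == pytest.approx(math.exp(-p[1] / (2 * p[2])))


class TestFitModel:
    @pytest.mark.parametrize("name", list(TRUE_PARAMS))
    def test_zero_noise_recovery(self, name):
        spec = get_model(name)
        D = np.geomspace(2, 100, 60)
        H = spec(TRUE_PARAMS[name], D)
        ds = make_dataset(D, H)
        fit = ak.fit_model(ds, spec)
        assert fit.converged
        rel = np.abs(fit.params - np.asarray(TRUE_PARAMS[name])) / \
            np.abs(np.asarray(TRUE_PARAMS[name]))
        assert np.all(rel < 1e-4), (name, fit.params)

    def test_rse_squared_times_df_equals_sse(self, vz_stand):
        ds, _ = vz_stand
        fit = ak.fit_model(ds, "michaelis_menten")
        assert fit.rse**2 * (fit.n - fit.spec.arity) == pytest.approx(fit.sse)

    def test_residuals_in_record_order(self):
        D = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        H = np.array([10.0, 15.0, 18.0, 20.0, 21.0])
        ds = make_dataset(D, H)
        fit = ak.fit_model(ds, "log_linear")
        np.testing.assert_allclose(fit.residuals, fit.predict(D) - H)

    def test_constant_heights_degenerate(self):
        ds = make_dataset([10, 20, 30, 40, 50], [15, 15, 15, 15, 15])
        with pytest.raises(DataError, match="constant"):
            ak.fit_model(ds, "michaelis_menten")

    def test_too_few_trees(self):
        ds = make_dataset([10, 20, 30, 40], [5, 9, 12, 14])
        with pytest.raises(DataError):
            ak.fit_model(ds, "weibull")  # arity 3 needs >= 5

    def test_min_dbh_filter(self, tf_stand):
        ds, _ = tf_stand
        fit_all = ak.fit_model(ds, "log_linear")
        fit_5 = ak.fit_model(ds, "log_linear", FitOptions(min_dbh=5.0))
        n5 = sum(1 for r in ds.records if r.dbh >= 5.0)
        assert fit_5.n == n5 < fit_all.n

    def test_log_linear_matches_closed_form_ols(self, vz_stand):
        """The nonlinear path on the log-linear model reproduces OLS on
        (lnD, H) to 1e-8 — an internal closed-form oracle."""
        ds, _ = vz_stand
        fit = ak.fit_model(ds, "log_linear")
        D = np.array([r.dbh for r in ds.records])
        H = np.array([r.height for r in ds.records])
        X = np.column_stack([np.ones_like(D), np.log(D)])
        beta = np.linalg.lstsq(X, H, rcond=None)[0]
        np.testing.assert_allclose(fit.params, beta, rtol=1e-8, atol=1e-8)

    def test_optimum_beats_parameter_grid(self):
        """NLS objective at the optimum is no worse than anywhere on a 20^k
        grid around the initialization (brute-force oracle, n=50)."""
        rng = np.random.default_rng(42)
        D = np.exp(rng.uniform(np.log(3), np.log(90), 50))
        for name in ("michaelis_menten", "weibull", "power"):
            spec = get_model(name)
            truth = np.asarray(TRUE_PARAMS[name], dtype=float)
            H = spec(truth, D) + rng.normal(0, 2.0, 50)
            ds = make_dataset(D, H)
            fit = ak.fit_model(ds, spec)
            x0 = spec.init(D, H)
            axes = [np.linspace(0.5 * x, 1.5 * x, 20) if x != 0 else
                    np.linspace(-1, 1, 20) for x in x0]
            best_grid = min(
                float(np.sum((spec(np.array(p), D) - H) ** 2))
                for p in itertools.product(*axes)
            )
            assert fit.sse <= best_grid + 1e-9, name


class TestSelectionStatistics:
    def test_aic_from_k_and_loglik(self):
        # AIC = 2k - 2 lnL at k=4, lnL=-3246.6
        assert 2 * 4 - 2 * (-3246.6) == pytest.approx(6501.2)

    def test_aic_penalty_difference(self, vz_stand):
        """Two fits with identical SSE and n but arity 2 vs 3 differ by
        exactly 2 in AIC."""
        ds, _ = vz_stand
        fit2 = ak.fit_model(ds, "michaelis_menten")
        fit3 = ak.fit_model(ds, "weibull")
        fit3.sse = fit2.sse
        fit3.loglik = fit2.loglik
        assert ak.aic(fit3) - ak.aic(fit2) == pytest.approx(2.0)

    def test_adj_pseudo_r2_hand_value(self):
        assert ak.adj_pseudo_r2(0.9, n=100, k=3) == pytest.approx(0.89794, abs=5e-6)

    def test_perfect_fit_adjusted_r2_is_one(self):
        for k in (2, 3):
            assert ak.adj_pseudo_r2(1.0, n=50, k=k) == 1.0

    def test_aic_convention_flag(self, vz_stand):
        ds, _ = vz_stand
        fit = ak.fit_model(ds, "michaelis_menten")
        assert ak.aic(fit, count_sigma_in_k=True) - \
            ak.aic(fit, count_sigma_in_k=False) == pytest.approx(2.0)


class TestRanking:
    def test_single_fit_ranks_first(self, vz_stand):
        ds, _ = vz_stand
        fit = ak.fit_model(ds, "michaelis_menten")
        assert ak.rank_models([fit])[0] is fit

    def test_aic_tie_break(self, vz_stand):
        ds, _ = vz_stand
        a = ak.fit_model(ds, "michaelis_menten")
        b = ak.fit_model(ds, "exp2")
        b.adj_pseudo_r2 = a.adj_pseudo_r2
        b.rse = a.rse
        a.aic, b.aic = 100.0, 102.0
        assert ak.rank_models([b, a])[0] is a

    def test_non_converged_ranks_last(self, vz_stand):
        ds, _ = vz_stand
        good = ak.fit_model(ds, "michaelis_menten")
        bad = ak.fit_model(ds, "weibull")
        bad.converged = False
        ranked = ak.rank_models([bad, good])
        assert ranked[-1] is bad

    def test_empty_input_errors(self):
        with pytest.raises(DataError):
            ak.rank_models([])

    def test_ranking_table_layout(self, vz_stand):
        ds, _ = vz_stand
        fits = ak.fit_all_models(ds)
        table = ak.ranking_table(fits)
        assert set(table["model"]) == set(ak.hd_allometry.MODEL_ORDER)
        # one row per parameter
        assert len(table) == sum(m.arity for m in model_registry())
        assert table["rank"].min() == 1 and table["rank"].max() == 10
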