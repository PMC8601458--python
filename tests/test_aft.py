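"""Interval-censored Gaussian onset regression: likelihood, fit, lasso, prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, optimize, stats

from pubgrowth import aft
from pubgrowth.intervals import OnsetInterval

from conftest import interval_schedule


def simulate_onset_data(seed, n=300, beta_ow=-1.0, beta_phv=-0.15, sigma=0.55,
                        visits_spacing=1.0, interaction=0.0):
    """Markers + annually-censored onset intervals from a known linear link."""
    r = np.random.default_rng(seed)
    aphv = r.normal(11.7, 0.83, n)
    phv = r.normal(7.8, 0.91, n)
    size = r.normal(0.0, 5.0, n)
    ow = (r.random(n) < 0.15).astype(float)
    onset = (1.5 + 0.9 * aphv + beta_phv * phv + beta_ow * ow
             + interaction * (aphv - 11.7) * ow + r.normal(0, sigma, n))
    ivs = []
    for i in range(n):
        visits = np.arange(8.0, 19.01, visits_spacing)
        left, right, ct = interval_schedule(onset[i], visits)
        ivs.append(OnsetInterval(i, left, right, ct))
    table = pd.DataFrame(
        {"child_id": range(n), "aphv": aphv, "phv": phv, "size": size,
         "overweight": ow, "aphv_c": aphv - 11.7}
    )
    return ivs, table, onset


class TestLikelihood:
    def test_closed_form_single_interval(self):
        ll = aft.interval_gaussian_loglik(
            np.array([10.5]), 1.0, np.array([10.0]), np.array([11.0]),
            np.array(["interval"]), np.ones((1, 1)),
        )
        assert ll == pytest.approx(
            np.log(stats.norm.cdf(0.5) - stats.norm.cdf(-0.5)), abs=1e-12
        )

    def test_matches_quadrature_on_random_cases(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            mu = rng.normal(10, 2)
            sig = rng.uniform(0.3, 2.0)
            L = rng.normal(9, 2)
            R = L + rng.uniform(1e-3, 3.0)
            ll = aft.interval_gaussian_loglik(
                np.array([mu]), sig, np.array([L]), np.array([R]),
                np.array(["interval"]), np.ones((1, 1)),
            )
            q, _ = integrate.quad(lambda x: stats.norm.pdf(x, mu, sig), L, R,
                                  epsabs=1e-14, epsrel=1e-12)
            assert ll == pytest.approx(np.log(q), abs=1e-8)

    def test_narrow_interval_approaches_density_limit(self):
        """log P(interval) -> Gaussian log-density + log(width) as width -> 0."""
        mu, sig, L = 10.0, 0.8, 10.7
        for width in (1e-3, 1e-5):
            ll = aft.interval_gaussian_loglik(
                np.array([mu]), sig, np.array([L]), np.array([L + width]),
                np.array(["interval"]), np.ones((1, 1)),
            )
            expect = stats.norm.logpdf(L + width / 2, mu, sig) + np.log(width)
            assert ll == pytest.approx(expect, abs=1e-5)

    def test_tail_intervals_stay_finite(self):
        ll = aft.interval_gaussian_loglik(
            np.array([0.0]), 1.0, np.array([12.0]), np.array([12.5]),
            np.array(["interval"]), np.ones((1, 1)),
        )
        assert np.isfinite(ll) and ll < -60

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            aft.interval_gaussian_loglik(
                np.array([10.0]), 1.0, np.array([11.0]), np.array([10.0]),
                np.array(["interval"]), np.ones((1, 1)),
            )

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        n = 40
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        L = rng.normal(10, 1, n)
        R = L + rng.uniform(0.2, 1.5, n)
        ct = np.array(["interval"] * (n - 10) + ["right"] * 5 + ["left"] * 5)
        params = np.array([9.5, 0.3, np.log(0.9)])
        f0, g = aft._loglik_and_grad(params, L, R, ct, X)
        for j in range(3):
            e = np.zeros(3)
            e[j] = 1e-6
            fp = aft._loglik_and_grad(params + e, L, R, ct, X)[0]
            fm = aft._loglik_and_grad(params - e, L, R, ct, X)[0]
            assert g[j] == pytest.approx((fp - fm) / 2e-6, rel=1e-4, abs=1e-6)


class TestFit:
    def test_exact_observations_reduce_to_ols(self):
        rng = np.random.default_rng(1)
        n = 120
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        y = X @ np.array([10.0, 0.8, -0.3]) + rng.normal(0, 0.7, n)
        ivs = [OnsetInterval(i, y[i], y[i], "exact") for i in range(n)]
        tab = pd.DataFrame({"child_id": range(n), "x1": X[:, 1], "x2": X[:, 2]})
        fit = aft.fit_aft(ivs, tab, aft.ModelSpec(("x1", "x2")))
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.abs(fit.coef - ols).max() < 1e-6
        assert fit.sigma == pytest.approx((y - X @ ols).std(), abs=1e-6)

    def test_intercept_only_recovers_mean_under_symmetric_censoring(self):
        rng = np.random.default_rng(2)
        onset = rng.normal(11.0, 0.9, 400)
        ivs = [OnsetInterval(i, np.floor(o) , np.floor(o) + 1.0, "interval")
               for i, o in enumerate(onset)]
        fit = aft.fit_aft(ivs, None, aft.ModelSpec((), name="intercept_only"))
        assert fit.coef[0] == pytest.approx(onset.mean(), abs=0.1)
        assert fit.sigma == pytest.approx(0.9, abs=0.1)

    def test_all_right_censored_is_unidentifiable(self):
        ivs = [OnsetInterval(i, 12.0, np.inf, "right") for i in range(20)]
        with pytest.raises(ValueError):
            aft.fit_aft(ivs, None, aft.ModelSpec(()))

    def test_equivalence_with_grid_search_oracle(self):
        """MLE matches direct numerical optimization on a 20-child fixture."""
        ivs, table, _ = simulate_onset_data(9, n=20)
        fit = aft.fit_aft(ivs, table, aft.SIMPLE)
        ids, L, R, ct, X = aft.make_dataset(ivs, table, aft.SIMPLE.terms)

        def neg_ll(p):
            return -aft.interval_gaussian_loglik(p[:-1], np.exp(p[-1]), L, R, ct, X)

        start = np.concatenate([fit.coef + 0.05, [np.log(fit.sigma) + 0.05]])
        res = optimize.minimize(neg_ll, start, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 20000, "maxfev": 20000})
        assert np.abs(fit.coef - res.x[:-1]).max() < 1e-3
        assert abs(fit.sigma - np.exp(res.x[-1])) < 1e-3

    def test_sigma_decreases_with_informative_covariates(self):
        ivs, table, _ = simulate_onset_data(4, n=300)
        fit0 = aft.fit_aft(ivs, table, aft.ModelSpec((), name="null"))
        fit1 = aft.fit_aft(ivs, table, aft.SIMPLE)
        assert fit1.sigma < fit0.sigma

    def test_open_closed_endpoint_invariance(self):
        """A continuous model cannot distinguish (L, R] from [L, R)."""
        ivs, table, _ = simulate_onset_data(5, n=80)
        fit = aft.fit_aft(ivs, table, aft.SIMPLE)
        shifted = [
            OnsetInterval(iv.child_id,
                          iv.left + 1e-9 if iv.censor_type == "interval" else iv.left,
                          iv.right - 1e-9 if iv.censor_type == "interval" else iv.right,
                          iv.censor_type)
            for iv in ivs
        ]
        fit2 = aft.fit_aft(shifted, table, aft.SIMPLE)
        assert np.abs(fit.coef - fit2.coef).max() < 1e-5


@pytest.fixture(scope="module")
def lasso_data():
    return simulate_onset_data(6, n=250, beta_phv=0.0)


class TestLasso:
    def test_zero_lambda_matches_unpenalized_mle(self, lasso_data):
        ivs, table, _ = lasso_data
        terms = aft.candidate_terms()
        _, L, R, ct, X = aft.make_dataset(ivs, table, terms)
        Xs, _, _ = aft._standardize(X)
        p0 = aft._start_values(L, R, ct, Xs)
        p0[1:-1] = 0.0
        path = aft._lasso_path(L, R, ct, Xs, [0.0], x0=p0, polish=True)
        res = optimize.minimize(aft._loglik_and_grad, path[0], args=(L, R, ct, Xs),
                                jac=True, method="BFGS", options={"gtol": 1e-12})
        assert np.abs(path[0] - res.x).max() < 1e-4

    def test_large_lambda_shrinks_everything(self, lasso_data):
        ivs, table, _ = lasso_data
        spec, diag = aft.lasso_select(ivs, table, k=3, seed=0)
        lam_max = diag["lambdas"][0]
        _, L, R, ct, X = aft.make_dataset(ivs, table, diag["terms"])
        Xs, _, _ = aft._standardize(X)
        p0 = aft._start_values(L, R, ct, Xs)
        p0[1:-1] = 0.0
        fit = aft._ista(p0, lam_max, L, R, ct, Xs)
        assert np.all(fit[1:-1] == 0.0)
        # path coefficients at the largest lambda are all zero too
        assert np.all(diag["path_coefficients"][0] == 0.0)

    def test_hierarchy_repair(self):
        with pytest.raises(ValueError):
            aft.ModelSpec(("aphv:overweight",))
        spec = aft.ModelSpec(("aphv", "overweight", "aphv:overweight"))
        assert "aphv" in spec.terms

    def test_midpoint_variant_runs_and_drops_right_censored(self, lasso_data):
        ivs, table, _ = lasso_data
        spec, diag = aft.lasso_select(ivs, table, k=3, seed=0, method="midpoint")
        n_right = sum(iv.censor_type == "right" for iv in ivs)
        assert diag["n"] == len(ivs) - n_right
        assert isinstance(spec, aft.ModelSpec)


class TestPrediction:
    def test_normal_quantile_half_width(self):
        fit = aft.AftFit(terms=(), coef=np.array([11.0]), sigma=1.0, loglik=0.0,
                         cov=np.eye(2), n_by_censor={}, converged=True)
        pred = aft.predict_onset(fit, pd.DataFrame({"child_id": [0]}))
        assert pred["hi95"][0] - pred["pred"][0] == pytest.approx(1.959964, abs=1e-6)
        assert pred["hi50"][0] - pred["pred"][0] == pytest.approx(0.674490, abs=1e-6)

    def test_interval_nesting(self):
        ivs, table, _ = simulate_onset_data(7, n=120)
        fit = aft.fit_aft(ivs, table, aft.SIMPLE)
        pred = aft.predict_onset(fit, table)
        assert (pred["lo95"] < pred["lo75"]).all()
        assert (pred["lo75"] < pred["lo50"]).all()
        assert (pred["hi50"] < pred["hi75"]).all()
        assert (pred["hi75"] < pred["hi95"]).all()

    def test_missing_covariate_is_named(self):
        fit = aft.AftFit(terms=("aphv",), coef=np.array([0.0, 1.0]), sigma=1.0,
                         loglik=0.0, cov=np.eye(3), n_by_censor={}, converged=True)
        with pytest.raises(ValueError, match="aphv"):
            aft.predict_onset(fit, pd.DataFrame({"child_id": [0]}))


class TestSummarizeOnset:
    def test_exact_observations_give_sample_moments(self):
        vals = np.linspace(9.5, 12.5, 40)
        ivs = [OnsetInterval(i, v, v, "exact") for i, v in enumerate(vals)]
        out = aft.summarize_onset(ivs, {i: "g" for i in range(40)})
        assert out["mean_onset"][0] == pytest.approx(vals.mean(), abs=1e-6)
        assert out["sd_onset"][0] == pytest.approx(vals.std(), abs=1e-6)

    def test_location_equivariance(self):
        rng = np.random.default_rng(8)
        onset = rng.normal(11.0, 1.0, 120)
        ivs = [OnsetInterval(i, np.floor(o), np.floor(o) + 1, "interval")
               for i, o in enumerate(onset)]
        shifted = [OnsetInterval(iv.child_id, iv.left + 1.0, iv.right + 1.0,
                                 iv.censor_type) for iv in ivs]
        groups = {i: "g" for i in range(120)}
        s0 = aft.summarize_onset(ivs, groups)
        s1 = aft.summarize_onset(shifted, groups)
        assert s1["mean_onset"][0] - s0["mean_onset"][0] == pytest.approx(1.0, abs=1e-4)
        assert s1["sd_onset"][0] == pytest.approx(s0["sd_onset"][0], abs=1e-4)

    def test_annual_censoring_recovers_cohort_moments(self):
        """Mean/SD recovered from interval data at the reported scale."""
        rng = np.random.default_rng(9)
        onset = rng.normal(11.7, 0.90, 500)
        ivs = []
        for i, o in enumerate(onset):
            left, right, ct = interval_schedule(o, np.arange(8.0, 19.01, 1.0))
            ivs.append(OnsetInterval(i, left, right, ct))
        out = aft.summarize_onset(ivs, {i: "STRIP" for i in range(500)})
        assert out["mean_onset"][0] == pytest.approx(11.7, abs=0.1)
        assert out["sd_onset"][0] == pytest.approx(0.90, abs=0.1)

    def test_small_groups_are_skipped(self):
        ivs = [OnsetInterval(i, 10.0, 11.0, "interval") for i in range(5)]
        out = aft.summarize_onset(ivs, {i: "tiny" for i in range(5)})
        assert out.empty


class TestLognormalVariant:
    def test_recovers_log_scale_parameters(self):
        rng = np.random.default_rng(3)
        n = 300
        x = rng.normal(0, 1, n)
        onset = np.exp(2.4 + 0.08 * x + rng.normal(0, 0.08, n))
        ivs = [OnsetInterval(i, np.floor(o), np.floor(o) + 1.0, "interval")
               for i, o in enumerate(onset)]
        tab = pd.DataFrame({"child_id": range(n), "x": x})
        fit = aft.fit_aft(ivs, tab, aft.ModelSpec(("x",)), dist="lognormal")
        assert fit.dist == "lognormal"
        assert fit.coef[0] == pytest.approx(2.4, abs=0.03)
        assert fit.coef[1] == pytest.approx(0.08, abs=0.03)
        pred = aft.predict_onset(fit, tab)
        # back-transformed predictions live on the age scale and stay nested
        assert (pred["pred"] > 0).all()
        assert (pred["lo95"] < pred["lo50"]).all()
        assert (pred["hi50"] < pred["hi95"]).all()

    def test_unknown_distribution_rejected(self):
        ivs = [OnsetInterval(i, 10.0, 11.0, "interval") for i in range(12)]
        with pytest.raises(ValueError):
            aft.fit_aft(ivs, None, aft.ModelSpec(()), dist="weibull")
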