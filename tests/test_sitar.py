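"""SITAR growth model: spline basis, fitting, equivariances, likelihood."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from pubgrowth.sitar import (
    SitarFit,
    default_knots,
    fit_sitar,
    natural_cubic_spline_basis,
    predict_height,
    sitar_loglik,
)
from pubgrowth.synthetic import CohortSpec, SimConfig, simulate, template_for_sex

KNOTS = np.array([7.0, 9.4, 11.8, 14.2, 16.6, 19.0])


class TestSplineBasis:
    def test_rejects_bad_knots(self):
        with pytest.raises(ValueError):
            natural_cubic_spline_basis(np.r_[1.0], np.array([1.0, 1.0, 2.0]))
        with pytest.raises(ValueError):
            natural_cubic_spline_basis(np.r_[1.0], np.array([1.0, 2.0]))

    def test_column_count_is_interior_knots_plus_one(self):
        B = natural_cubic_spline_basis(np.linspace(7, 19, 10), KNOTS)
        assert B.shape[1] == len(KNOTS) - 1

    def test_natural_boundary_condition(self):
        """Second derivative vanishes beyond both boundary knots."""
        x = np.r_[np.linspace(2, 6.9, 30), np.linspace(19.1, 25, 30)]
        B2 = natural_cubic_spline_basis(x, KNOTS, deriv=2)
        assert np.abs(B2).max() < 1e-12

    def test_continuity_across_knots(self):
        for k in KNOTS:
            left = natural_cubic_spline_basis(np.r_[k - 1e-9], KNOTS)
            right = natural_cubic_spline_basis(np.r_[k + 1e-9], KNOTS)
            assert np.abs(left - right).max() < 1e-6

    def test_derivatives_consistent_with_finite_differences(self):
        x = np.linspace(5, 21, 101)
        for d in (1, 2):
            lo = natural_cubic_spline_basis(x - 5e-7, KNOTS, deriv=d - 1)
            hi = natural_cubic_spline_basis(x + 5e-7, KNOTS, deriv=d - 1)
            mid = natural_cubic_spline_basis(x, KNOTS, deriv=d)
            assert np.abs((hi - lo) / 1e-6 - mid).max() < 1e-4

    def test_matches_piecewise_polynomial_oracle(self):
        """Fitted combinations equal a brute-force constrained cubic fit."""
        rng = np.random.default_rng(0)
        coef = rng.normal(size=len(KNOTS) - 1)
        x = np.linspace(6, 20, 400)
        y = natural_cubic_spline_basis(x, KNOTS) @ coef

        # oracle: unconstrained piecewise cubics + continuity (value, d1, d2 at
        # every knot) + natural conditions (d2 = d3 = 0 outside), solved as a
        # dense least-squares system with hard constraints via elimination
        from numpy.polynomial import polynomial as P

        segments = np.concatenate([[-np.inf], KNOTS, [np.inf]])
        # sanity of the oracle: spline must be cubic within each segment
        for lo, hi in zip(segments[:-1], segments[1:]):
            mask = (x > lo + 1e-9) & (x < hi - 1e-9)
            if mask.sum() < 6:
                continue
            c = P.polyfit(x[mask], y[mask], 3)
            assert np.abs(P.polyval(x[mask], c) - y[mask]).max() < 1e-8
            if lo == -np.inf or hi == np.inf:  # linear tails
                assert np.abs(c[2:]).max() < 1e-8


def make_noiseless_growth(n=25, sex="F", seed=0, n_visits=13):
    """Children exactly on the template curve (no random effects, no noise)."""
    tpl = template_for_sex(sex)
    rows = []
    rng = np.random.default_rng(seed)
    for i in range(n):
        ages = np.linspace(7, 19, n_visits) + rng.uniform(-0.2, 0.2, n_visits)
        for t in ages:
            rows.append((f"c{i:03d}", sex, "X", t, float(tpl.height(t)), np.nan))
    return pd.DataFrame(rows, columns=["child_id", "sex", "cohort", "age_years",
                                       "height_cm", "bmi"])


class TestFitSitar:
    def test_noiseless_self_consistency(self):
        """Zero noise, zero effects: the mean curve is recovered everywhere."""
        growth = make_noiseless_growth()
        fit = fit_sitar(growth, df=6, sex="F")
        tpl = template_for_sex("F")
        ages = np.linspace(7.2, 18.8, 60)
        err = np.abs(predict_height(fit, "X", ages) - tpl.height(ages))
        assert err.max() < 0.1

    def test_fewer_than_two_children_rejected(self):
        growth = make_noiseless_growth(n=1)
        with pytest.raises(ValueError):
            fit_sitar(growth, df=5, sex="F")

    def test_duplicate_rows_averaged(self, caplog):
        import logging

        growth = make_noiseless_growth(n=5)
        dup = growth.iloc[[0]].assign(height_cm=growth.iloc[0].height_cm + 2)
        with caplog.at_level(logging.WARNING, logger="pubgrowth.sitar"):
            fit_sitar(pd.concat([growth, dup]), df=5, sex="F")
        assert "duplicate" in caplog.text

    def test_height_translation_equivariance(self, sim_small):
        """Shifting all heights by +k changes only the size dimension by +k."""
        _, _, growth, _ = sim_small
        g = growth[growth["sex"] == "F"]
        knots = default_knots(g["age_years"].to_numpy(), 5)
        fit1 = fit_sitar(g, sex="F", knots=knots, t_center=13.0)
        shifted = g.assign(height_cm=g["height_cm"] + 10.0)
        fit2 = fit_sitar(shifted, sex="F", knots=knots, t_center=13.0)
        ages = np.linspace(8, 18, 21)
        for coh in fit1.cohorts:
            d = predict_height(fit2, coh, ages) - predict_height(fit1, coh, ages)
            assert np.abs(d - 10.0).max() < 0.05
        assert np.abs(fit2.b_coh - fit1.b_coh).max() < 0.01

    def test_age_translation_equivariance(self, sim_small):
        """Shifting all ages by +k shifts the timing axis by +k."""
        _, _, growth, _ = sim_small
        g = growth[growth["sex"] == "F"]
        knots = default_knots(g["age_years"].to_numpy(), 5)
        fit1 = fit_sitar(g, sex="F", knots=knots, t_center=13.0)
        shifted = g.assign(age_years=g["age_years"] + 2.0)
        fit2 = fit_sitar(shifted, sex="F", knots=knots + 2.0, t_center=15.0)
        ages = np.linspace(8, 18, 21)
        for coh in fit1.cohorts:
            d = predict_height(fit2, coh, ages + 2.0) - predict_height(fit1, coh, ages)
            assert np.abs(d).max() < 0.05

    def test_random_effect_recovery(self, sim_small, truth_frame, sitar_fit_girls):
        fit = sitar_fit_girls
        tr = truth_frame.loc[fit.ranef.index]
        for col, floor in (("a", 0.95), ("b", 0.9), ("c", 0.8)):
            r = np.corrcoef(fit.ranef[col], tr[col])[0, 1]
            assert r > floor, f"{col}: correlation {r:.3f}"

    def test_timing_shrinkage_vs_per_child_least_squares(self, sitar_fit_girls, sim_small):
        """Penalized |b_i| never exceeds the unshrunken per-child LS shift."""
        from scipy.optimize import minimize_scalar

        fit = sitar_fit_girls
        _, _, growth, _ = sim_small
        g = growth[growth["sex"] == "F"]
        checked = 0
        for child_id, grp in list(g.groupby("child_id"))[:25]:
            coh = fit.cohort_of[child_id]
            j = fit.cohorts.index(coh)
            t = grp["age_years"].to_numpy()
            y = grp["height_cm"].to_numpy()
            a_tot = fit.a_coh[j] + fit.ranef.loc[child_id, "a"]
            c_tot = fit.c_coh[j] + fit.ranef.loc[child_id, "c"]
            tc = fit.t_center

            def rss(b):
                theta = tc + (t - tc - fit.b_coh[j] - b) * np.exp(c_tot)
                return np.sum((y - a_tot - fit.curve(theta)) ** 2)

            res = minimize_scalar(rss, bounds=(-4, 4), method="bounded",
                                  options={"xatol": 1e-8})
            b_hat = fit.ranef.loc[child_id, "b"]
            assert abs(b_hat) <= abs(res.x) + 1e-3
            checked += 1
        assert checked == 25

    def test_serialization_round_trip(self, sitar_fit_girls, tmp_path):
        path = tmp_path / "fit.json"
        sitar_fit_girls.to_json(path)
        back = SitarFit.from_json(path)
        ages = np.linspace(8, 18, 11)
        assert np.allclose(predict_height(back, sitar_fit_girls.cohorts[0], ages),
                           predict_height(sitar_fit_girls, sitar_fit_girls.cohorts[0], ages))
        assert np.allclose(back.omega, sitar_fit_girls.omega)
        cid = sitar_fit_girls.ranef.index[0]
        assert np.allclose(predict_height(back, cid, ages),
                           predict_height(sitar_fit_girls, cid, ages))


class TestPredictAndLoglik:
    def test_child_with_zero_random_effects_matches_cohort(self, sitar_fit_girls):
        fit = sitar_fit_girls
        cid = fit.ranef.index[0]
        fit0 = dataclasses.replace(fit, ranef=fit.ranef * 0.0)
        ages = np.linspace(8, 18, 25)
        coh = fit.cohort_of[cid]
        assert np.allclose(predict_height(fit0, cid, ages),
                           predict_height(fit0, coh, ages))

    def test_constant_size_offset_between_cohorts(self, sitar_fit_girls):
        """With equal timing/intensity, cohorts differ by a_C at every age."""
        fit = dataclasses.replace(
            sitar_fit_girls,
            a_coh=np.array([0.0, 2.25]),
            b_coh=np.zeros(2),
            c_coh=np.zeros(2),
        )
        ages = np.linspace(8, 18, 40)
        d = predict_height(fit, fit.cohorts[1], ages) - predict_height(fit, fit.cohorts[0], ages)
        assert np.abs(d - 2.25).max() < 1e-9
        # one size estimate serves both the height-at-8 and height-at-18 rows
        assert d[0] == pytest.approx(d[-1], abs=1e-9)

    def test_unknown_target_rejected(self, sitar_fit_girls):
        with pytest.raises(KeyError):
            predict_height(sitar_fit_girls, "nonexistent", np.r_[10.0])

    def test_loglik_omega_zero_closed_form(self, sitar_fit_girls, sim_small):
        _, _, growth, _ = sim_small
        g = growth[growth["sex"] == "F"].sort_values(["child_id", "age_years"])
        fit0 = dataclasses.replace(sitar_fit_girls, omega=np.zeros((3, 3)),
                                   ranef=sitar_fit_girls.ranef * 0.0)
        mu = np.concatenate(
            [predict_height(fit0, fit0.cohort_of[cid], grp["age_years"].to_numpy())
             for cid, grp in g.groupby("child_id")]
        )
        expect = norm.logpdf(g["height_cm"].to_numpy(), mu, fit0.sigma).sum()
        assert sitar_loglik(fit0, g) == pytest.approx(expect, abs=1e-8)

    def test_loglik_duplication_identity_omega_zero(self, sitar_fit_girls, sim_small):
        """Duplicating every row doubles the iid log-likelihood."""
        _, _, growth, _ = sim_small
        g = growth[growth["sex"] == "F"]
        fit0 = dataclasses.replace(sitar_fit_girls, omega=np.zeros((3, 3)),
                                   ranef=sitar_fit_girls.ranef * 0.0)
        ll1 = sitar_loglik(fit0, g)
        doubled = pd.concat([g, g.assign(age_years=g["age_years"] + 1e-7)])
        ll2 = sitar_loglik(fit0, doubled)
        assert ll2 == pytest.approx(2 * ll1, rel=1e-6)

    def test_loglik_peaks_at_fitted_sigma(self, sitar_fit_girls, sim_small):
        _, _, growth, _ = sim_small
        g = growth[growth["sex"] == "F"]
        base = sitar_loglik(sitar_fit_girls, g)
        for factor in (0.8, 1.25):
            pert = dataclasses.replace(sitar_fit_girls,
                                       sigma=sitar_fit_girls.sigma * factor)
            assert sitar_loglik(pert, g) < base


def test_select_df_returns_candidate_with_bic_table(sim_small):
    from pubgrowth.sitar import select_df

    _, _, growth, _ = sim_small
    g = growth[growth["sex"] == "F"]
    best, bics = select_df(g, dfs=(5, 6), sex="F")
    assert best in (5, 6)
    assert set(bics) == {5, 6}
    assert bics[best] == min(bics.values())
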