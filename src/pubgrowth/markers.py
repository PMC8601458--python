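"""Growth markers from a fitted SITAR model.

The height-velocity curve is the analytic derivative of the fitted height
curve — for a child or cohort with total effects (a, b, c),

    v(t) = exp(c) * h'(t0 + (t - t0 - b) * exp(c)),

never a finite difference of noisy data. The markers are

aPHV   age at peak height velocity, the argmax of v (years);
PHV    the velocity at that age (cm/year);
takeoff the pre-spurt velocity minimum on [first observed age, aPHV);
size   the child's SITAR size random effect a_i (cm).

Because SITAR curves are superimposed copies of one mean curve, individual
markers obey closed-form shift identities: with u* the mean-curve peak
argument and t0 the fit's centering age, aPHV = t0 + b + (u* - t0) exp(-c)
and PHV = exp(c) h'(u*). Both the direct
grid search and the identities are available and agree to numerical
tolerance; the identities are the fast default for whole-cohort tables.

Cohort contrasts mirror a growth-marker summary table: per-cohort mean
aPHV/PHV and mean heights at 8 and 18 years, pairwise differences with
delta-method 95% CIs and Wald tests (timing through (b_C, c_C), intensity
through c_C, size directly from a_C), plus one overall joint Wald test per
marker.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2, norm

from .sitar import SitarFit

logger = logging.getLogger(__name__)

MARKER_COLUMNS = [
    "child_id", "aphv", "phv", "size", "takeoff_age",
    "n_height_measurements", "flag",
]


def velocity_curve(fit: SitarFit, target, ages: np.ndarray) -> np.ndarray:
    """Analytic height velocity (cm/year) of a cohort or individual curve."""
    ages = np.asarray(ages, float)
    lo = min(fit.knots[0], fit.age_range[0])
    hi = max(fit.knots[-1], fit.age_range[1])
    margin = 0.1 * (hi - lo)
    if np.any(ages < lo - margin) or np.any(ages > hi + margin):
        raise ValueError(f"ages outside the fitted range [{lo:.1f}, {hi:.1f}] (+margin)")
    _, b, c = fit.effects_for(target)
    tc = fit.t_center
    ec = np.exp(c)
    return ec * fit.curve_deriv(tc + (ages - tc - b) * ec)


def _refine_extremum(f, lo, hi, x0, grid_step, minimize=False):
    """Golden-section polish of a grid extremum to ~1e-4 on the axis."""
    sign = 1.0 if minimize else -1.0
    a = max(lo, x0 - 2 * grid_step)
    b = min(hi, x0 + 2 * grid_step)
    res = optimize.minimize_scalar(
        lambda x: sign * f(x), bounds=(a, b), method="bounded",
        options={"xatol": 1e-5},
    )
    return float(res.x), float(sign * res.fun)


def mean_curve_peak(fit: SitarFit, grid_step: float = 0.01) -> tuple[float, float]:
    """(u*, h'(u*)): peak of the mean-curve derivative on the knot range."""
    lo, hi = float(fit.knots[0]), float(fit.knots[-1])
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    v = fit.curve_deriv(grid)
    k = int(np.argmax(v))
    if k == 0 or k == len(grid) - 1:
        raise ValueError("mean-curve velocity peaks on the range boundary")
    return _refine_extremum(lambda u: float(fit.curve_deriv(np.array([u]))[0]),
                            lo, hi, grid[k], grid_step)


def peak_markers(
    fit: SitarFit, target, method: str = "grid", grid_step: float = 0.01
) -> tuple[float, float]:
    """(aPHV, PHV) of a cohort mean curve or an individual curve.

    ``method='grid'`` searches the velocity curve directly (grid at
    ``grid_step`` years, golden-section refinement); ``method='closed_form'``
    uses the shift identities through the mean-curve peak. A velocity
    maximum on the search boundary raises (flagged as unreliable upstream).
    """
    _, b, c = fit.effects_for(target)
    tc = fit.t_center
    if method == "closed_form":
        u_star, hp = mean_curve_peak(fit)
        return tc + b + (u_star - tc) * np.exp(-c), float(np.exp(c) * hp)
    if method != "grid":
        raise ValueError("method must be 'grid' or 'closed_form'")
    ec = np.exp(c)
    # map the knot range from the transformed-age axis to this curve's ages
    lo = float(tc + b + (fit.knots[0] - tc) / ec)
    hi = float(tc + b + (fit.knots[-1] - tc) / ec)
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    v = ec * fit.curve_deriv(tc + (grid - tc - b) * ec)
    k = int(np.argmax(v))
    if k == 0 or k == len(grid) - 1:
        raise ValueError(f"velocity maximum on the range boundary for {target!r}")
    return _refine_extremum(
        lambda t: float(ec * fit.curve_deriv(np.array([tc + (t - tc - b) * ec]))[0]),
        lo, hi, grid[k], grid_step,
    )


def takeoff_age(
    fit: SitarFit, child_id, aphv: float | None = None, grid_step: float = 0.01
) -> float:
    """Growth-spurt takeoff: velocity minimum on [first observed age, aPHV).

    Raises when the minimum sits on the left boundary (the spurt had already
    started before observation; no pre-spurt nadir is identified).
    """
    if aphv is None:
        aphv, _ = peak_markers(fit, child_id, method="closed_form")
    t0 = float(fit.child_info.loc[child_id, "t_min"])
    if aphv - t0 < 2 * grid_step:
        raise ValueError(f"child {child_id!r}: no room below aPHV for a takeoff search")
    _, b, c = fit.effects_for(child_id)
    tc = fit.t_center
    ec = np.exp(c)
    grid = np.arange(t0, aphv - grid_step / 2, grid_step)
    v = ec * fit.curve_deriv(tc + (grid - tc - b) * ec)
    k = int(np.argmin(v))
    if k == 0:
        raise ValueError(f"child {child_id!r}: velocity minimum at the first observed age")
    x, _ = _refine_extremum(
        lambda t: float(ec * fit.curve_deriv(np.array([tc + (t - tc - b) * ec]))[0]),
        t0, aphv - grid_step, grid[k], grid_step, minimize=True,
    )
    return x


def markers_table(fit: SitarFit, method: str = "closed_form") -> pd.DataFrame:
    """Per-child marker table (aPHV, PHV, size, takeoff age, flags).

    Children whose velocity extrema fall on search boundaries are retained
    with a non-empty ``flag`` and should be excluded from downstream models;
    the count is logged.
    """
    rows = []
    n_flagged = 0
    for child_id in fit.ranef.index:
        flag = ""
        aphv = phv = tko = np.nan
        try:
            aphv, phv = peak_markers(fit, child_id, method=method)
        except ValueError:
            flag = "peak_on_boundary"
        if not flag:
            try:
                tko = takeoff_age(fit, child_id, aphv=aphv)
            except ValueError:
                flag = "takeoff_on_boundary"
        if flag:
            n_flagged += 1
        rows.append(
            {
                "child_id": child_id,
                "aphv": aphv,
                "phv": phv,
                "size": float(fit.ranef.loc[child_id, "a"]),
                "takeoff_age": tko,
                "n_height_measurements": int(fit.child_info.loc[child_id, "n_visits"]),
                "flag": flag,
            }
        )
    if n_flagged:
        logger.info("%d children flagged with boundary velocity extrema", n_flagged)
    return pd.DataFrame(rows, columns=MARKER_COLUMNS)


# ---------------------------------------------------------------------------
# cohort contrasts (delta method + Wald tests)
# ---------------------------------------------------------------------------


def _fixed_index(fit: SitarFit, kind: str, cohort: str) -> int | None:
    name = f"{kind}[{cohort}]"
    return fit.fixed_names.index(name) if name in fit.fixed_names else None


def _marker_gradient(fit: SitarFit, kind: str, cohort: str, u_star: float, hp: float):
    """Gradient of a cohort's marker w.r.t. the full fixed-effect vector."""
    g = np.zeros(len(fit.fixed_names))
    if cohort == fit.cohorts[0]:
        return g  # reference offsets are pinned at zero
    j = fit.cohorts.index(cohort)
    if kind == "timing":  # aPHV_C = t0 + b_C + (u* - t0) exp(-c_C)
        g[_fixed_index(fit, "b", cohort)] = 1.0
        g[_fixed_index(fit, "c", cohort)] = -(u_star - fit.t_center) * np.exp(
            -fit.c_coh[j]
        )
    elif kind == "intensity":  # PHV_C = exp(c_C) h'(u*)
        g[_fixed_index(fit, "c", cohort)] = np.exp(fit.c_coh[j]) * hp
    elif kind == "size":  # height shift a_C, constant over age
        g[_fixed_index(fit, "a", cohort)] = 1.0
    else:
        raise ValueError(kind)
    return g


def _marker_value(fit: SitarFit, kind: str, cohort: str, u_star: float, hp: float):
    j = fit.cohorts.index(cohort)
    if kind == "timing":
        return fit.t_center + fit.b_coh[j] + (u_star - fit.t_center) * np.exp(
            -fit.c_coh[j]
        )
    if kind == "intensity":
        return np.exp(fit.c_coh[j]) * hp
    return fit.a_coh[j]


def cohort_contrasts(fit: SitarFit, heights_at: tuple[float, ...] = (8.0, 18.0)):
    """Cohort marker summary with delta-method differences and Wald tests.

    Returns (means frame, differences frame). Means: per cohort, the
    cohort-curve aPHV and PHV, the SDs of the individual markers, and mean
    heights at the requested ages. Differences: one row per cohort pair and
    marker with the delta-method SE, 95% CI and Wald p; the overall p per
    marker is a joint Wald chi-square over all cohort-vs-reference offsets.
    Size differences are age-constant, so one size row serves every height
    age.
    """
    if len(fit.cohorts) >= 2 and np.linalg.matrix_rank(fit.cov_fixed) < len(fit.fixed_names):
        raise ValueError("singular fixed-effect covariance; contrasts unavailable")
    u_star, hp = mean_curve_peak(fit)

    # per-cohort means (cohort curves) and individual-marker SDs
    ind = markers_table(fit)
    ind = ind[ind["flag"] == ""]
    coh_of = fit.cohort_of
    mean_rows = []
    for coh in fit.cohorts:
        aphv_c = _marker_value(fit, "timing", coh, u_star, hp)
        phv_c = _marker_value(fit, "intensity", coh, u_star, hp)
        members = ind[ind["child_id"].map(coh_of) == coh]
        row = {
            "cohort": coh,
            "n": int((coh_of == coh).sum()),
            "aphv_mean": aphv_c,
            "aphv_sd": float(members["aphv"].std()),
            "phv_mean": phv_c,
            "phv_sd": float(members["phv"].std()),
        }
        j = fit.cohorts.index(coh)
        tc = fit.t_center
        for age in heights_at:
            theta = tc + (age - tc - fit.b_coh[j]) * np.exp(fit.c_coh[j])
            row[f"height_at_{age:g}y"] = float(
                fit.a_coh[j] + fit.curve(np.array([theta]))[0]
            )
        mean_rows.append(row)
    means = pd.DataFrame(mean_rows)

    diff_rows = []
    overall = {}
    z975 = norm.ppf(0.975)
    for kind in ("timing", "intensity", "size"):
        # overall joint Wald: all cohort-vs-reference marker differences zero
        if len(fit.cohorts) >= 2:
            D, G = [], []
            ref = fit.cohorts[0]
            for coh in fit.cohorts[1:]:
                D.append(_marker_value(fit, kind, coh, u_star, hp)
                         - _marker_value(fit, kind, ref, u_star, hp))
                G.append(_marker_gradient(fit, kind, coh, u_star, hp)
                         - _marker_gradient(fit, kind, ref, u_star, hp))
            D = np.array(D)
            G = np.array(G)
            S = G @ fit.cov_fixed @ G.T
            try:
                stat = float(D @ np.linalg.solve(S, D))
                overall[kind] = float(chi2.sf(stat, len(D)))
            except np.linalg.LinAlgError:
                overall[kind] = np.nan
        for ca, cb in itertools.combinations(fit.cohorts, 2):
            d = (_marker_value(fit, kind, cb, u_star, hp)
                 - _marker_value(fit, kind, ca, u_star, hp))
            g = (_marker_gradient(fit, kind, cb, u_star, hp)
                 - _marker_gradient(fit, kind, ca, u_star, hp))
            se = float(np.sqrt(g @ fit.cov_fixed @ g))
            p = 2 * norm.sf(abs(d) / se) if se > 0 else np.nan
            diff_rows.append(
                {
                    "marker": kind,
                    "cohort_a": ca,
                    "cohort_b": cb,
                    "difference": float(d),
                    "se": se,
                    "ci_lo": float(d - z975 * se),
                    "ci_hi": float(d + z975 * se),
                    "p": p,
                    "overall_p": overall.get(kind, np.nan),
                }
            )
    diffs = pd.DataFrame(diff_rows)
    return means, diffs


def bootstrap_contrast_ses(
    fit: SitarFit, n_draws: int = 500, seed: int = 0
) -> pd.DataFrame:
    """Monte-Carlo SEs of the marker differences from the fixed-effect covariance.

    Draws fixed-effect vectors from N(theta_hat, cov_fixed) and recomputes
    each pairwise marker difference; serves as an independent check on the
    first-order delta-method SEs.
    """
    rng = np.random.default_rng(seed)
    u_star, hp = mean_curve_peak(fit)
    draws = rng.multivariate_normal(
        np.zeros(len(fit.fixed_names)), fit.cov_fixed, size=n_draws
    )
    name_idx = {n: i for i, n in enumerate(fit.fixed_names)}

    def value(kind, coh, delta):
        j = fit.cohorts.index(coh)
        da = delta[name_idx[f"a[{coh}]"]] if f"a[{coh}]" in name_idx else 0.0
        db = delta[name_idx[f"b[{coh}]"]] if f"b[{coh}]" in name_idx else 0.0
        dc = delta[name_idx[f"c[{coh}]"]] if f"c[{coh}]" in name_idx else 0.0
        if kind == "timing":
            return (
                fit.t_center
                + fit.b_coh[j]
                + db
                + (u_star - fit.t_center) * np.exp(-(fit.c_coh[j] + dc))
            )
        if kind == "intensity":
            return np.exp(fit.c_coh[j] + dc) * hp
        return fit.a_coh[j] + da

    rows = []
    for kind in ("timing", "intensity", "size"):
        for ca, cb in itertools.combinations(fit.cohorts, 2):
            vals = np.array(
                [value(kind, cb, dl) - value(kind, ca, dl) for dl in draws]
            )
            rows.append(
                {
                    "marker": kind,
                    "cohort_a": ca,
                    "cohort_b": cb,
                    "se_bootstrap": float(vals.std(ddof=1)),
                }
            )
    return pd.DataFrame(rows)
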