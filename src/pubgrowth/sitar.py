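"""SITAR growth-curve model (Super-Imposition by Translation And Rotation).

Heights of child i in cohort C at ages t_ij follow a shape-invariant model

    y_ij = (beta0 + a_C + a_i) + h( t0 + (t_ij - t0 - b_C - b_i) * exp(c_C + c_i) ) + eps_ij

where h is a natural cubic spline shared by all children, (a_i, b_i, c_i)
~ N(0, Omega) are per-child random effects for size (cm), timing (years)
and intensity (log scale: exp(c) multiplies growth velocity, so c is
roughly a percentage change for small c), and a_C, b_C, c_C are
cohort-level fixed offsets with a named reference cohort pinned at zero.
With this sign convention a positive c advances and intensifies the growth
spurt: the individual velocity is exp(c) * h'(theta) and the individual age
at peak velocity is t0 + b + (u* - t0) exp(-c), u* being the mean-curve peak
argument and t0 the centering age about which intensity rotates the age
scale (the mean observed age by default; centering keeps timing and
intensity close to orthogonal).

Estimation alternates penalized joint optimization (Gauss-Newton on the
random effects and cohort offsets, exact linear solves for the curve
coefficients) with Laplace-approximate EM updates of the variance
components (Omega, sigma^2), iterating the outer loop to a relative
log-likelihood tolerance. The marginal log-likelihood is the Laplace
approximation; the fixed-effect covariance is the linearized (FOCE-style)
GLS information matrix.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# natural cubic spline basis
# ---------------------------------------------------------------------------


def natural_cubic_spline_basis(
    x: np.ndarray, knots: np.ndarray, deriv: int = 0
) -> np.ndarray:
    """Natural cubic spline basis (no intercept column).

    ``knots`` holds all knots, boundary first/last, strictly increasing,
    length m >= 3 (>= 1 interior). The basis has m - 1 columns, is linear
    beyond the boundary knots and has a continuous second derivative.
    ``deriv`` in {0, 1, 2} returns the basis or its derivative.
    """
    knots = np.asarray(knots, float)
    if knots.ndim != 1 or len(knots) < 3:
        raise ValueError("need at least 3 knots (2 boundary + 1 interior)")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    x = np.asarray(x, float)
    m = len(knots)
    last = knots[-1]
    second_last = knots[-2]

    def trunc3(z, d):
        zp = np.maximum(z, 0.0)
        if d == 0:
            return zp**3
        if d == 1:
            return 3.0 * zp**2
        return 6.0 * zp

    def dk(k, d):
        return (trunc3(x - knots[k], d) - trunc3(x - last, d)) / (last - knots[k])

    cols = np.empty(x.shape + (m - 1,))
    if deriv == 0:
        cols[..., 0] = x
    elif deriv == 1:
        cols[..., 0] = 1.0
    else:
        cols[..., 0] = 0.0
    d_last = (trunc3(x - second_last, deriv) - trunc3(x - last, deriv)) / (
        last - second_last
    )
    for k in range(m - 2):
        cols[..., k + 1] = dk(k, deriv) - d_last
    return cols


def default_knots(ages: np.ndarray, df: int) -> np.ndarray:
    """Boundary knots at the data range, df - 1 interior knots at age quantiles."""
    if df < 2:
        raise ValueError("df must be >= 2")
    qs = np.linspace(0, 1, df + 1)
    k = np.quantile(ages, qs)
    k = np.unique(k)
    if len(k) < 3:
        raise ValueError("too few distinct ages to place knots")
    return k


# ---------------------------------------------------------------------------
# fitted-model container
# ---------------------------------------------------------------------------


@dataclass
class SitarFit:
    sex: str
    knots: np.ndarray
    t_center: float
    beta0: float
    gamma: np.ndarray  # spline coefficients of the mean curve
    cohorts: list[str]  # reference first
    a_coh: np.ndarray  # per-cohort offsets, reference entries are 0
    b_coh: np.ndarray
    c_coh: np.ndarray
    ranef: pd.DataFrame  # index child_id, columns a, b, c
    child_info: pd.DataFrame  # index child_id: t_min, t_max, n_visits
    cohort_of: pd.Series  # child_id -> cohort label
    omega: np.ndarray
    sigma: float
    loglik: float
    cov_fixed: np.ndarray
    fixed_names: list[str]
    converged: bool
    n_outer: int
    n_children: int
    n_obs: int
    age_range: tuple = (7.0, 19.0)
    diagnostics: dict = field(default_factory=dict)

    # mean curve h (with the global intercept folded in) and derivatives
    def curve(self, u: np.ndarray) -> np.ndarray:
        return self.beta0 + natural_cubic_spline_basis(u, self.knots) @ self.gamma

    def curve_deriv(self, u: np.ndarray, order: int = 1) -> np.ndarray:
        return natural_cubic_spline_basis(u, self.knots, deriv=order) @ self.gamma

    def effects_for(self, target) -> tuple[float, float, float]:
        """Total (a, b, c) for a cohort name (random effects 0) or a child_id."""
        if target in self.cohorts:
            j = self.cohorts.index(target)
            return float(self.a_coh[j]), float(self.b_coh[j]), float(self.c_coh[j])
        if target in self.ranef.index:
            j = self.cohorts.index(self.cohort_of[target])
            re = self.ranef.loc[target]
            return (
                float(self.a_coh[j] + re["a"]),
                float(self.b_coh[j] + re["b"]),
                float(self.c_coh[j] + re["c"]),
            )
        raise KeyError(f"unknown cohort or child: {target!r}")

    def to_json(self, path) -> None:
        payload = {
            "sex": self.sex,
            "knots": self.knots.tolist(),
            "t_center": self.t_center,
            "beta0": self.beta0,
            "gamma": self.gamma.tolist(),
            "cohorts": self.cohorts,
            "a_coh": self.a_coh.tolist(),
            "b_coh": self.b_coh.tolist(),
            "c_coh": self.c_coh.tolist(),
            "ranef": {
                str(i): row.tolist()
                for i, row in zip(self.ranef.index, self.ranef.to_numpy())
            },
            "child_info": {
                str(i): row.tolist()
                for i, row in zip(self.child_info.index, self.child_info.to_numpy())
            },
            "cohort_of": {str(k): v for k, v in self.cohort_of.items()},
            "omega": self.omega.tolist(),
            "sigma": self.sigma,
            "loglik": self.loglik,
            "cov_fixed": self.cov_fixed.tolist(),
            "fixed_names": self.fixed_names,
            "converged": self.converged,
            "n_outer": self.n_outer,
            "n_children": self.n_children,
            "n_obs": self.n_obs,
            "age_range": list(self.age_range),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SitarFit":
        with open(path) as fh:
            d = json.load(fh)
        ranef = pd.DataFrame.from_dict(d["ranef"], orient="index", columns=["a", "b", "c"])
        child_info = pd.DataFrame.from_dict(
            d["child_info"], orient="index", columns=["t_min", "t_max", "n_visits"]
        )
        return cls(
            sex=d["sex"],
            knots=np.array(d["knots"]),
            t_center=d["t_center"],
            beta0=d["beta0"],
            gamma=np.array(d["gamma"]),
            cohorts=d["cohorts"],
            a_coh=np.array(d["a_coh"]),
            b_coh=np.array(d["b_coh"]),
            c_coh=np.array(d["c_coh"]),
            ranef=ranef,
            child_info=child_info,
            cohort_of=pd.Series(d["cohort_of"]),
            omega=np.array(d["omega"]),
            sigma=d["sigma"],
            loglik=d["loglik"],
            cov_fixed=np.array(d["cov_fixed"]),
            fixed_names=d["fixed_names"],
            converged=d["converged"],
            n_outer=d["n_outer"],
            n_children=d["n_children"],
            n_obs=d["n_obs"],
            age_range=tuple(d.get("age_range", (7.0, 19.0))),
        )


# ---------------------------------------------------------------------------
# internal fitting machinery
# ---------------------------------------------------------------------------


class _Data:
    """Sorted per-child arrays with reduceat segment boundaries."""

    def __init__(self, visits: pd.DataFrame, cohort_field: str):
        df = visits.copy()
        dup = df.duplicated(subset=["child_id", "age_years"], keep=False)
        if dup.any():
            logger.warning(
                "%d duplicate (child, age) height rows averaged",
                int(dup.sum() - df[dup].groupby(["child_id", "age_years"]).ngroups),
            )
            df = (
                df.groupby(["child_id", "age_years"], as_index=False)
                .agg({"height_cm": "mean", cohort_field: "first"})
            )
        counts = df.groupby("child_id").size()
        usable = counts[counts >= 2].index
        dropped = len(counts) - len(usable)
        if dropped:
            logger.info("%d children with < 2 height visits dropped from SITAR", dropped)
        df = df[df["child_id"].isin(usable)]
        df = df.sort_values(["child_id", "age_years"], kind="mergesort")
        self.child_ids = df["child_id"].drop_duplicates().to_list()
        if len(self.child_ids) < 2:
            raise ValueError("SITAR needs at least 2 children with >= 2 visits")
        id_to_idx = {c: k for k, c in enumerate(self.child_ids)}
        self.ci = df["child_id"].map(id_to_idx).to_numpy()
        self.t = df["age_years"].to_numpy(float)
        self.y = df["height_cm"].to_numpy(float)
        self.starts = np.searchsorted(self.ci, np.arange(len(self.child_ids)))
        self.n_child = len(self.child_ids)
        self.n_obs = len(self.t)
        coh_per_child = df.groupby("child_id", sort=False)[cohort_field].first()
        self.cohorts = sorted(coh_per_child.unique().tolist())
        coh_to_idx = {c: k for k, c in enumerate(self.cohorts)}
        self.child_coh = np.array([coh_to_idx[coh_per_child[c]] for c in self.child_ids])
        self.obs_coh = self.child_coh[self.ci]
        self.cohort_of = coh_per_child


class _State:
    def __init__(self, data: _Data, knots: np.ndarray, t_center: float = 0.0):
        self.knots = knots
        self.t_center = t_center
        p = len(knots) - 1
        self.beta0 = 0.0
        self.gamma = np.zeros(p)
        nc = len(data.cohorts)
        self.a_coh = np.zeros(nc)
        self.b_coh = np.zeros(nc)
        self.c_coh = np.zeros(nc)
        self.u = np.zeros((data.n_child, 3))  # a_i, b_i, c_i
        self.omega = np.diag([20.0, 0.8, 0.01])
        self.sigma2 = 1.0


def _model_parts(st: _State, d: _Data):
    """theta, residual, h', exp(c) for the current state, all per observation."""
    b_tot = st.b_coh[d.obs_coh] + st.u[d.ci, 1]
    c_tot = st.c_coh[d.obs_coh] + st.u[d.ci, 2]
    E = np.exp(c_tot)
    tc = st.t_center
    theta = tc + (d.t - tc - b_tot) * E
    B = natural_cubic_spline_basis(theta, st.knots)
    mu = st.beta0 + st.a_coh[d.obs_coh] + st.u[d.ci, 0] + B @ st.gamma
    r = d.y - mu
    hp = natural_cubic_spline_basis(theta, st.knots, deriv=1) @ st.gamma
    return theta, B, r, hp, E


def _child_reduce(d: _Data, arr: np.ndarray) -> np.ndarray:
    """Sum an (N, ...) array over each child's observations."""
    return np.add.reduceat(arr, d.starts, axis=0)


def _penalty(st: _State) -> float:
    oinv = np.linalg.inv(st.omega)
    return float(np.einsum("ij,jk,ik->", st.u, oinv, st.u))


def _objective(st: _State, d: _Data) -> float:
    _, _, r, _, _ = _model_parts(st, d)
    return float(r @ r) / st.sigma2 + _penalty(st)


def _update_random_effects(st: _State, d: _Data, n_iter: int = 3) -> None:
    oinv = np.linalg.inv(st.omega)
    for _ in range(n_iter):
        theta, _, r, hp, E = _model_parts(st, d)
        J = np.stack([np.ones_like(r), -hp * E, hp * (theta - st.t_center)], axis=1)  # d mu / d u
        JtJ = _child_reduce(d, J[:, :, None] * J[:, None, :])
        Jtr = _child_reduce(d, J * r[:, None])
        A = JtJ / st.sigma2 + oinv[None, :, :]
        g = Jtr / st.sigma2 - st.u @ oinv
        try:
            delta = np.linalg.solve(A, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            delta = np.stack([np.linalg.lstsq(Ai, gi, rcond=None)[0] for Ai, gi in zip(A, g)])
        base = float(r @ r) / st.sigma2 + _penalty(st)
        step = 1.0
        u0 = st.u.copy()
        for _ in range(8):
            st.u = u0 + step * delta
            if _objective(st, d) <= base + 1e-10:
                break
            step *= 0.5
        else:
            st.u = u0


def _update_cohort_shape(st: _State, d: _Data) -> None:
    """Gauss-Newton on the non-reference cohorts' (b_C, c_C)."""
    for j in range(1, len(d.cohorts)):
        mask = d.obs_coh == j
        if not mask.any():
            continue
        theta, _, r, hp, E = _model_parts(st, d)
        Jb = -hp[mask] * E[mask]
        Jc = hp[mask] * (theta[mask] - st.t_center)
        J = np.stack([Jb, Jc], axis=1)
        A = J.T @ J + 1e-8 * np.eye(2)
        g = J.T @ r[mask]
        delta = np.linalg.solve(A, g)
        base = _objective(st, d)
        step = 1.0
        b0, c0 = st.b_coh[j], st.c_coh[j]
        for _ in range(8):
            st.b_coh[j] = b0 + step * delta[0]
            st.c_coh[j] = c0 + step * delta[1]
            if _objective(st, d) <= base + 1e-10:
                break
            step *= 0.5
        else:
            st.b_coh[j], st.c_coh[j] = b0, c0


def _recenter_cohorts(st: _State, d: _Data) -> None:
    """Move cohort-mean random effects into the cohort fixed offsets.

    Leaves every child's total effect unchanged while shrinking the
    penalized random effects, which decouples the cohort offsets from the
    random-effect means and speeds the outer iteration markedly.
    """
    ref_mask = d.child_coh == 0
    if not ref_mask.any():
        return
    m0 = st.u[ref_mask].mean(axis=0)
    for j in range(1, len(d.cohorts)):
        mask = d.child_coh == j
        if not mask.any():
            continue
        shift = st.u[mask].mean(axis=0) - m0
        st.a_coh[j] += shift[0]
        st.b_coh[j] += shift[1]
        st.c_coh[j] += shift[2]
        st.u[mask] -= shift


def _recenter_global(st: _State, d: _Data) -> None:
    """Absorb the mean timing/intensity random effect into the curve itself.

    A common shift of all b_i is exactly a translation of the spline (same
    coefficients, knots moved), and a common shift of all c_i is exactly a
    rescaling of the age axis about t_center (knots contracted, truncated-
    power coefficients scaled). Absorbing them keeps every child's curve
    identical while driving the random-effect means to zero, removing the
    flat direction that otherwise lets the mean curve drift away from the
    population average.
    """
    c_tot = st.c_coh[d.child_coh] + st.u[:, 2]
    m_b = st.u[:, 1].mean()
    if abs(m_b) > 1e-12:
        delta = -m_b
        st.u[:, 1] += delta * np.exp(-c_tot)
        st.knots = st.knots - delta
        st.beta0 += st.gamma[0] * delta
    m_c = st.u[:, 2].mean()
    if abs(m_c) > 1e-12:
        tc = st.t_center
        st.u[:, 2] -= m_c
        st.knots = tc + (st.knots - tc) * np.exp(-m_c)
        g1 = st.gamma[0]
        st.gamma = st.gamma * np.exp(2 * m_c)
        st.gamma[0] = g1 * np.exp(m_c)
        st.beta0 += g1 * tc * (1 - np.exp(m_c))


def _update_linear(st: _State, d: _Data) -> None:
    """Exact update of beta0, gamma and the non-reference a_C offsets."""
    theta, B, _, _, _ = _model_parts(st, d)
    nc = len(d.cohorts)
    cols = [np.ones(d.n_obs), B]
    for j in range(1, nc):
        cols.append((d.obs_coh == j).astype(float)[:, None])
    X = np.column_stack([c if c.ndim == 2 else c[:, None] for c in cols])
    target = d.y - st.u[d.ci, 0]
    coef, *_ = np.linalg.lstsq(X, target, rcond=None)
    p = B.shape[1]
    st.beta0 = float(coef[0])
    st.gamma = coef[1 : 1 + p]
    st.a_coh[1:] = coef[1 + p :]
    # recenter size random effects into the intercept
    shift = st.u[:, 0].mean()
    st.beta0 += shift
    st.u[:, 0] -= shift


def _laplace_loglik(st: _State, d: _Data) -> float:
    theta, _, r, hp, E = _model_parts(st, d)
    J = np.stack([np.ones_like(r), -hp * E, hp * (theta - st.t_center)], axis=1)
    JtJ = _child_reduce(d, J[:, :, None] * J[:, None, :])
    rss_child = _child_reduce(d, r * r)
    n_child_obs = np.diff(np.append(d.starts, d.n_obs))
    oinv = np.linalg.inv(st.omega)
    sign_o, logdet_o = np.linalg.slogdet(st.omega)
    G = JtJ / st.sigma2 + oinv[None, :, :]
    sign_g, logdet_g = np.linalg.slogdet(G)
    pen = np.einsum("ij,jk,ik->i", st.u, oinv, st.u)
    ll = (
        -0.5 * n_child_obs * np.log(2 * np.pi * st.sigma2)
        - 0.5 * rss_child / st.sigma2
        - 0.5 * pen
        - 0.5 * logdet_o
        - 0.5 * logdet_g
    )
    return float(ll.sum())


def _update_variances(st: _State, d: _Data, min_var=(1e-6, 1e-8, 1e-10)) -> None:
    theta, _, r, hp, E = _model_parts(st, d)
    J = np.stack([np.ones_like(r), -hp * E, hp * (theta - st.t_center)], axis=1)
    JtJ = _child_reduce(d, J[:, :, None] * J[:, None, :])
    oinv = np.linalg.inv(st.omega)
    G = JtJ / st.sigma2 + oinv[None, :, :]
    V = np.linalg.inv(G)
    omega = (st.u[:, :, None] * st.u[:, None, :] + V).mean(axis=0)
    # keep Omega safely positive definite
    w, Q = np.linalg.eigh(omega)
    w = np.maximum(w, 1e-10)
    st.omega = (Q * w) @ Q.T
    rss = float(r @ r)
    trace_term = float(np.einsum("nij,nji->", JtJ, V))
    st.sigma2 = max((rss + trace_term) / d.n_obs, 1e-8)


def _initial_state(d: _Data, knots: np.ndarray, t_center: float = 0.0) -> _State:
    st = _State(d, knots, t_center)
    # curve + size from an OLS ignoring timing/intensity
    B = natural_cubic_spline_basis(d.t, knots)
    X = np.column_stack([np.ones(d.n_obs), B])
    coef, *_ = np.linalg.lstsq(X, d.y, rcond=None)
    st.beta0 = float(coef[0])
    st.gamma = coef[1:]
    resid = d.y - X @ coef
    st.u[:, 0] = _child_reduce(d, resid) / np.diff(np.append(d.starts, d.n_obs))
    # timing start: age of the largest observed height increment, centered
    b0 = np.zeros(d.n_child)
    for i in range(d.n_child):
        s, e = d.starts[i], (d.starts[i + 1] if i + 1 < d.n_child else d.n_obs)
        t, y = d.t[s:e], d.y[s:e]
        if len(t) >= 3:
            v = np.diff(y) / np.maximum(np.diff(t), 1e-6)
            k = int(np.argmax(v))
            b0[i] = 0.5 * (t[k] + t[k + 1])
    has = b0 != 0
    if has.sum() >= 2:
        b0[has] -= np.median(b0[has])
        st.u[:, 1] = np.clip(np.where(has, b0, 0.0), -3.0, 3.0)
    st.sigma2 = max(float(resid.var()), 1e-4)
    st.omega = np.diag(
        [max(st.u[:, 0].var(), 1.0), max(st.u[:, 1].var(), 0.25), 0.01]
    )
    return st


def _fixed_effect_covariance(st: _State, d: _Data):
    """Linearized GLS covariance of (beta0, gamma, b0, c0, a_C, b_C, c_C).

    b0 and c0 are the global curve-location directions (the timing and
    intensity analogues of beta0). They are pinned to zero during
    estimation — the recentering absorbs them into the knots — but must
    appear in the information matrix so that cohort-offset standard errors
    include the reference cohort's own sampling noise, exactly as beta0
    does for the size offsets.
    """
    theta, B, r, hp, E = _model_parts(st, d)
    nc = len(d.cohorts)
    p = B.shape[1]
    names = ["beta0"] + [f"gamma{k}" for k in range(p)] + ["b0", "c0"]
    blocks = [np.ones((d.n_obs, 1)), B,
              (-hp * E)[:, None], (hp * (theta - st.t_center))[:, None]]
    for j in range(1, nc):
        m = (d.obs_coh == j).astype(float)
        blocks.append(m[:, None])
        names.append(f"a[{d.cohorts[j]}]")
    for j in range(1, nc):
        m = (d.obs_coh == j).astype(float)
        blocks.append((-hp * E * m)[:, None])
        names.append(f"b[{d.cohorts[j]}]")
    for j in range(1, nc):
        m = (d.obs_coh == j).astype(float)
        blocks.append((hp * (theta - st.t_center) * m)[:, None])
        names.append(f"c[{d.cohorts[j]}]")
    X = np.column_stack(blocks)
    Ju = np.stack([np.ones(d.n_obs), -hp * E, hp * (theta - st.t_center)], axis=1)
    F = np.zeros((X.shape[1], X.shape[1]))
    for i in range(d.n_child):
        s, e = d.starts[i], (d.starts[i + 1] if i + 1 < d.n_child else d.n_obs)
        Ji = Ju[s:e]
        Vy = Ji @ st.omega @ Ji.T + st.sigma2 * np.eye(e - s)
        Xi = X[s:e]
        F += Xi.T @ np.linalg.solve(Vy, Xi)
    try:
        cov = np.linalg.inv(F)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(F)
    return cov, names


def fit_sitar(
    visits: pd.DataFrame,
    df: int = 5,
    cohort_field: str = "cohort",
    sex: str | None = None,
    knots: np.ndarray | None = None,
    max_outer: int = 200,
    tol: float = 1e-5,
    inner_cycles: int = 2,
    t_center: float | None = None,
) -> SitarFit:
    """Fit the SITAR model to one sex's growth visits.

    ``visits`` needs columns child_id, age_years, height_cm and
    ``cohort_field``. ``df`` is the spline dimension (interior knots + 1) on
    the transformed age scale; knots default to age quantiles and may be
    passed explicitly. Non-convergence within ``max_outer`` outer iterations
    is flagged on the returned fit, never silent.
    """
    if sex is None:
        sexes = visits["sex"].unique() if "sex" in visits.columns else ["?"]
        if len(sexes) > 1:
            raise ValueError("fit one sex at a time (pass a pre-filtered table)")
        sex = str(sexes[0])
    bad = ~visits["age_years"].between(0, 25) | ~visits["height_cm"].between(50, 230)
    if bad.any():
        logger.warning("%d implausible growth rows dropped", int(bad.sum()))
        visits = visits[~bad]
    d = _Data(visits, cohort_field)
    if knots is None:
        knots = default_knots(d.t, df)
    if t_center is None:
        t_center = float(d.t.mean())
    st = _initial_state(d, np.asarray(knots, float), t_center)

    ll_prev = -np.inf
    converged = False
    it = 0
    burn_in = 30  # knot translation/scaling allowed only while settling
    for it in range(1, max_outer + 1):
        for _ in range(inner_cycles):
            _update_random_effects(st, d)
            _recenter_cohorts(st, d)
            if it <= burn_in:
                _recenter_global(st, d)
            _update_cohort_shape(st, d)
            _update_linear(st, d)
        _update_variances(st, d)
        ll = _laplace_loglik(st, d)
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * (1 + abs(ll)):
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
    if not converged:
        logger.warning(
            "SITAR did not reach tol=%.1e within %d outer iterations", tol, max_outer
        )
    _update_random_effects(st, d, n_iter=4)
    cov, names = _fixed_effect_covariance(st, d)
    ranef = pd.DataFrame(st.u, index=pd.Index(d.child_ids, name="child_id"),
                         columns=["a", "b", "c"])
    ends = np.append(d.starts[1:], d.n_obs)
    child_info = pd.DataFrame(
        {
            "t_min": d.t[d.starts],
            "t_max": d.t[ends - 1],
            "n_visits": ends - d.starts,
        },
        index=ranef.index,
    )
    return SitarFit(
        sex=sex,
        knots=st.knots,
        t_center=st.t_center,
        beta0=st.beta0,
        gamma=st.gamma,
        cohorts=d.cohorts,
        a_coh=st.a_coh,
        b_coh=st.b_coh,
        c_coh=st.c_coh,
        ranef=ranef,
        child_info=child_info,
        cohort_of=d.cohort_of,
        omega=st.omega,
        sigma=float(np.sqrt(st.sigma2)),
        loglik=_laplace_loglik(st, d),
        cov_fixed=cov,
        fixed_names=names,
        converged=converged,
        n_outer=it,
        n_children=d.n_child,
        n_obs=d.n_obs,
        age_range=(float(d.t.min()), float(d.t.max())),
        diagnostics={"tol": tol, "max_outer": max_outer},
    )


def select_df(visits: pd.DataFrame, dfs=(4, 5, 6), **kwargs) -> tuple[int, dict]:
    """Pick the spline df among ``dfs`` by BIC of the Laplace log-likelihood."""
    bics = {}
    for df in dfs:
        fit = fit_sitar(visits, df=df, **kwargs)
        n_fixed = len(fit.fixed_names)
        k = n_fixed + 6 + 1  # fixed effects + Omega (6 free) + sigma
        bics[df] = -2 * fit.loglik + k * np.log(fit.n_obs)
    best = min(bics, key=bics.get)
    return best, bics


def predict_height(fit: SitarFit, target, ages: np.ndarray) -> np.ndarray:
    """Cohort mean curve (random effects zero) or an individual curve, in cm."""
    ages = np.asarray(ages, float)
    lo = min(fit.knots[0], fit.age_range[0])
    hi = max(fit.knots[-1], fit.age_range[1])
    margin = 0.1 * (hi - lo)
    if np.any(ages < lo - margin) or np.any(ages > hi + margin):
        raise ValueError(f"ages outside the fitted range [{lo:.1f}, {hi:.1f}] (+margin)")
    a, b, c = fit.effects_for(target)
    tc = fit.t_center
    theta = tc + (ages - tc - b) * np.exp(c)
    return a + fit.curve(theta)


def sitar_loglik(fit: SitarFit, visits: pd.DataFrame, cohort_field: str = "cohort") -> float:
    """Laplace marginal log-likelihood of ``fit`` evaluated on ``visits``.

    When Omega is (numerically) zero the random effects drop out and this is
    the plain sum of independent Gaussian log-densities.
    """
    d = _Data(visits, cohort_field)
    if set(d.child_ids) - set(fit.ranef.index):
        raise ValueError("visits contain children absent from the fit")
    st = _State(d, fit.knots, fit.t_center)
    st.beta0, st.gamma = fit.beta0, fit.gamma
    coh_map = {c: k for k, c in enumerate(fit.cohorts)}
    order = [coh_map[c] for c in d.cohorts]
    st.a_coh = fit.a_coh[order]
    st.b_coh = fit.b_coh[order]
    st.c_coh = fit.c_coh[order]
    st.u = fit.ranef.loc[d.child_ids].to_numpy()
    st.sigma2 = fit.sigma**2
    if np.abs(fit.omega).max() < 1e-12:
        _, _, r, _, _ = _model_parts(st, d)
        return float(
            -0.5 * d.n_obs * np.log(2 * np.pi * st.sigma2) - 0.5 * (r @ r) / st.sigma2
        )
    st.omega = fit.omega
    return _laplace_loglik(st, d)
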