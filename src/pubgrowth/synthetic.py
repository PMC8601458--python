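"""Multi-cohort longitudinal growth and puberty simulator.

Generates the data structure the two-stage analysis assumes: several
cohorts of children followed for height (every 6-12 months, ages ~7-19)
and, in cohorts with pubertal follow-up, Tanner breast staging (girls) or
testis-length measurement (boys) from age 8 onwards; plus a ground-truth
table so every downstream stage can be validated.

Each sex has a template height curve built from a declining childhood
velocity plus a Gaussian-bump adolescent spurt,

    v(u) = v1 * exp(-q (u - 7)) + P * exp(-(u - p)^2 / (2 w^2)),

integrated in closed form and calibrated so the age at peak velocity, the
peak velocity, and the heights at 8 and 18 years match typical Finnish
cohort values (girls: aPHV 11.7 y, PHV 7.8 cm/y, 127.7/165.6 cm; boys:
aPHV 13.7 y, PHV 9.9 cm/y, 129.8/179.6 cm). The default template is that
curve's exact projection onto a natural-cubic-spline family (the form the
growth model assumes, appropriate for recovery studies) with an affine
correction restoring the calibration targets exactly; the closed-form
original is available as kind="smooth". Children deviate from
the template by SITAR-style effects: size a (cm), timing b (years) and
intensity c (log velocity scale), drawn from N(0, Omega) plus cohort
offsets, with the age transformation centred at 13 years.

The true onset age is linearly linked to the child's growth markers,

    onset = mu0 + beta_aphv * aPHV + beta_phv * PHV + beta_ow * OW
            + beta_int * (aPHV - aPHV_template) * OW + N(0, sigma_onset^2),

so that beta_ow is the overweight effect at the template's mean aPHV.
Overweight truth comes from thresholding the child's simulated BMI at its
true takeoff age against the package's synthetic ISO-BMI reference; the
per-child BMI level is placed so a configurable fraction of children
exceeds the threshold. Dropout is an independent geometric stopping visit
(non-informative censoring). All outputs are deterministic functions of
the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
import yaml
from scipy import optimize
from scipy.stats import norm

from .overweight import synthetic_overweight_cutoff

T_CENTER = 13.0  # centering age of the simulated age transformation

GROWTH_COLUMNS = ["child_id", "sex", "cohort", "age_years", "height_cm", "bmi"]
PUBERTAL_COLUMNS = ["child_id", "sex", "age_years", "tanner_breast", "testis_len_mm"]
TRUTH_COLUMNS = [
    "child_id", "sex", "cohort", "a", "b", "c",
    "aphv", "phv", "takeoff_age", "overweight", "onset_age",
]


# ---------------------------------------------------------------------------
# template growth curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthTemplate:
    """Closed-form mean height curve: declining base velocity + Gaussian spurt."""

    h7: float      # height at age 7 (cm)
    v1: float      # childhood velocity at age 7 (cm/year)
    q: float       # exponential decay rate of childhood velocity (1/year)
    peak_loc: float  # centre of the spurt velocity bump (years)
    peak_amp: float  # bump amplitude (cm/year)
    width: float   # bump SD (years)

    def velocity(self, u):
        u = np.asarray(u, float)
        return self.v1 * np.exp(-self.q * (u - 7.0)) + self.peak_amp * np.exp(
            -((u - self.peak_loc) ** 2) / (2 * self.width**2)
        )

    def height(self, u):
        u = np.asarray(u, float)
        base = (self.v1 / self.q) * (1.0 - np.exp(-self.q * (u - 7.0)))
        spurt = (
            self.peak_amp
            * self.width
            * np.sqrt(2 * np.pi)
            * (norm.cdf((u - self.peak_loc) / self.width)
               - norm.cdf((7.0 - self.peak_loc) / self.width))
        )
        return self.h7 + base + spurt

    def _extremum(self, lo, hi, minimize):
        grid = np.arange(lo, hi, 0.001)
        v = self.velocity(grid)
        k = int(np.argmin(v) if minimize else np.argmax(v))
        sign = 1.0 if minimize else -1.0
        res = optimize.minimize_scalar(
            lambda u: sign * float(self.velocity(u)),
            bounds=(max(lo, grid[k] - 0.01), min(hi, grid[k] + 0.01)),
            method="bounded", options={"xatol": 1e-7},
        )
        return float(res.x), float(sign * res.fun)

    @property
    def aphv(self) -> float:
        return _template_extrema(self)[0]

    @property
    def phv(self) -> float:
        return _template_extrema(self)[1]

    @property
    def takeoff(self) -> float:
        return _template_extrema(self)[2]


@lru_cache(maxsize=None)
def _template_extrema(tpl) -> tuple[float, float, float]:
    """(aPHV, PHV, takeoff) of a (hashable, frozen) template, cached."""
    aphv, phv = tpl._extremum(7.0, 19.0, False)
    takeoff = tpl._extremum(7.0, aphv, True)[0]
    return aphv, phv, takeoff


def _calibrate_template(aphv, phv, h8, h18, q, width) -> GrowthTemplate:
    def eqs(x):
        v1, amp, loc = x
        tpl = GrowthTemplate(0.0, v1, q, loc, amp, width)
        a, p = tpl._extremum(7.0, 19.0, False)
        gain = tpl.height(18.0) - tpl.height(8.0)
        return [a - aphv, p - phv, gain - (h18 - h8)]

    v1_0 = 5.5
    amp_0 = phv - v1_0 * np.exp(-q * (aphv - 7.0))
    sol = optimize.fsolve(eqs, [v1_0, amp_0, aphv + 0.1], xtol=1e-12)
    tpl = GrowthTemplate(0.0, *((sol[0], q, sol[2], sol[1], width)))
    return replace(tpl, h7=h8 - float(tpl.height(8.0)))


@dataclass(frozen=True)
class SplineTemplate:
    """Natural-cubic-spline mean curve, the form the growth model assumes.

    Built by projecting a closed-form template onto a spline basis and then
    applying the exact affine correction h(u) = alpha + beta u + s h0(u - d)
    (still a natural cubic spline) so that aPHV, PHV and the heights at 8
    and 18 years hit their calibration targets exactly.
    """

    knots: tuple
    coef: tuple        # intercept + spline coefficients of the raw projection h0
    alpha: float
    beta: float
    scale: float
    delta: float

    def _h0(self, u, deriv=0):
        from .sitar import natural_cubic_spline_basis

        u = np.asarray(u, float)
        B = natural_cubic_spline_basis(u, np.asarray(self.knots), deriv=deriv)
        out = B @ np.asarray(self.coef)[1:]
        if deriv == 0:
            out = out + self.coef[0]
        return out

    def height(self, u):
        u = np.asarray(u, float)
        return self.alpha + self.beta * u + self.scale * self._h0(u - self.delta)

    def velocity(self, u):
        u = np.asarray(u, float)
        return self.beta + self.scale * self._h0(u - self.delta, deriv=1)

    _extremum = GrowthTemplate._extremum

    @property
    def aphv(self) -> float:
        return _template_extrema(self)[0]

    @property
    def phv(self) -> float:
        return _template_extrema(self)[1]

    @property
    def takeoff(self) -> float:
        return _template_extrema(self)[2]


def _spline_template(smooth: GrowthTemplate, aphv, phv, h8, h18, df=6) -> SplineTemplate:
    from .sitar import natural_cubic_spline_basis

    knots = np.linspace(7.0, 19.0, df + 1)
    grid = np.linspace(7.0, 19.0, 800)
    B = np.column_stack([np.ones_like(grid), natural_cubic_spline_basis(grid, knots)])
    coef, *_ = np.linalg.lstsq(B, smooth.height(grid), rcond=None)
    raw = SplineTemplate(tuple(knots), tuple(coef), 0.0, 0.0, 1.0, 0.0)
    aphv0, phv0 = raw._extremum(7.0, 19.0, False)
    delta = aphv - aphv0
    # beta + s * phv0 = phv ; 10 beta + s * gain0 = h18 - h8  (linear in beta, s)
    gain0 = float(raw.height(18.0 - delta) - raw.height(8.0 - delta))
    A = np.array([[1.0, phv0], [10.0, gain0]])
    beta, s = np.linalg.solve(A, np.array([phv, h18 - h8]))
    alpha = h8 - beta * 8.0 - s * float(raw.height(8.0 - delta))
    return SplineTemplate(tuple(knots), tuple(coef), float(alpha), float(beta),
                          float(s), float(delta))


_TARGETS = {
    "F": dict(aphv=11.7, phv=7.8, h8=127.7, h18=165.6, q=0.15, width=0.95),
    "M": dict(aphv=13.7, phv=9.9, h8=129.8, h18=179.6, q=0.12, width=1.0),
}


@lru_cache(maxsize=None)
def template_for_sex(sex: str, kind: str = "spline"):
    """Calibrated template curve (girls and boys differ in every target).

    ``kind='spline'`` (default) returns the natural-spline form the analysis
    model assumes; ``kind='smooth'`` returns the closed-form construction.
    """
    if sex not in _TARGETS:
        raise ValueError(f"sex must be 'F' or 'M', got {sex!r}")
    t = _TARGETS[sex]
    smooth = _calibrate_template(t["aphv"], t["phv"], t["h8"], t["h18"],
                                 q=t["q"], width=t["width"])
    if kind == "smooth":
        return smooth
    if kind == "spline":
        return _spline_template(smooth, t["aphv"], t["phv"], t["h8"], t["h18"])
    raise ValueError(f"unknown template kind {kind!r}")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """One cohort's offsets and visit-schedule structure."""

    name: str
    a_offset: float = 0.0   # size shift (cm)
    b_offset: float = 0.0   # timing shift (years)
    c_offset: float = 0.0   # intensity shift (log scale)
    growth_spacing_months: tuple[float, float] = (6.0, 12.0)
    pubertal_spacing_months: float | None = None  # None -> no pubertal follow-up
    pubertal_start_age: float = 8.0
    n: int | None = None     # overrides SimConfig.n_children_per_cohort
    sexes: tuple[str, ...] = ("F", "M")


@dataclass(frozen=True)
class SimConfig:
    n_children_per_cohort: int = 160
    cohorts: tuple[CohortSpec, ...] = (
        CohortSpec("DIPP"),  # reference; growth follow-up only
        CohortSpec(
            "STRIP",
            a_offset=1.5, b_offset=-0.09, c_offset=0.025,
            pubertal_spacing_months=12.0, n=200,
        ),
        CohortSpec(
            "BoyCohort",
            a_offset=2.25, b_offset=0.1, c_offset=0.013,
            growth_spacing_months=(6.0, 6.0),
            pubertal_spacing_months=6.0, n=50, sexes=("M",),
        ),
    )
    omega: tuple = ((25.0, 0.0, 0.0), (0.0, 0.64, 0.0), (0.0, 0.0, 0.0121))
    sigma_height: float = 0.5   # measurement noise SD, cm
    sigma_bmi: float = 0.3      # BMI measurement noise SD
    # onset link per sex: intercept, beta_aphv, beta_phv, beta_ow,
    # beta_interaction (on centred aPHV x OW), sigma_onset
    onset_link: dict = field(
        default_factory=lambda: {
            "F": {"intercept": 1.5, "aphv": 0.9, "phv": -0.15, "overweight": -1.0,
                  "interaction": -0.3, "sigma": 0.8},
            "M": {"intercept": 0.65, "aphv": 0.9, "phv": -0.15, "overweight": 0.0,
                  "interaction": 0.0, "sigma": 0.8},
        }
    )
    ow_prevalence: dict = field(default_factory=lambda: {"F": 0.15, "M": 0.178})
    bmi_level_sd: float = 1.8   # between-child SD of the BMI level
    bmi_slope_mean: float = 0.45
    bmi_slope_sd: float = 0.12
    testis_noise_sd: float = 0.5  # mm, clipped at +/- 2 SD
    tanner_stage_duration: float = 1.0  # years per stage past B2
    dropout_hazard: float = 0.02  # per growth visit
    age_range: tuple[float, float] = (7.0, 19.0)
    seed: int = 0

    def __post_init__(self) -> None:
        om = np.asarray(self.omega, float)
        if om.shape != (3, 3) or not np.allclose(om, om.T):
            raise ValueError("Omega must be a symmetric 3x3 matrix")
        if np.any(np.linalg.eigvalsh(om) < 0):
            raise ValueError("Omega must be positive semi-definite")
        for coh in self.cohorts:
            lo, hi = coh.growth_spacing_months
            if not (6.0 <= lo <= hi <= 12.0):
                raise ValueError(
                    f"cohort {coh.name}: growth spacing must lie in [6, 12] months"
                )
        if self.sigma_height < 0 or self.sigma_bmi < 0:
            raise ValueError("noise SDs must be non-negative")
        for link in self.onset_link.values():
            if link["sigma"] <= 0:
                raise ValueError("onset sigma must be positive")

    @property
    def omega_arr(self) -> np.ndarray:
        return np.asarray(self.omega, float)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cohorts" in raw:
            raw["cohorts"] = tuple(
                CohortSpec(**{**c, **{
                    k: tuple(v) for k, v in c.items() if isinstance(v, list)
                }})
                for c in raw["cohorts"]
            )
        if "omega" in raw:
            raw["omega"] = tuple(tuple(r) for r in raw["omega"])
        for key in ("age_range",):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruthRecord:
    child_id: str
    sex: str
    cohort: str
    a: float
    b: float
    c: float
    aphv: float
    phv: float
    takeoff_age: float
    overweight: bool
    onset_age: float

    def __post_init__(self) -> None:
        if not self.phv > 0:
            raise ValueError("true PHV must be positive")
        if not self.takeoff_age < self.aphv:
            raise ValueError("true takeoff age must precede true aPHV")


def _rng(config: SimConfig, *stream: int) -> np.random.Generator:
    # spawn_key gives properly independent per-purpose/per-child streams;
    # naive list seeding leaves weak cross-stream correlation that inflates
    # cohort-mean sampling variance measurably
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=stream)
    return np.random.default_rng(ss)


def _bmi_level_mean(config: SimConfig, sex: str) -> float:
    """BMI level placing `ow_prevalence` of children above the OW threshold.

    The threshold is evaluated at the template takeoff age; the per-child
    BMI at that age is level + slope_mean * (t - 7) + 0.02 (t - 7)^2.
    """
    tpl = template_for_sex(sex)
    tko = tpl.takeoff
    cut = float(synthetic_overweight_cutoff(tko, sex))
    rise = config.bmi_slope_mean * (tko - 7.0) + 0.02 * (tko - 7.0) ** 2
    z = norm.ppf(1.0 - config.ow_prevalence[sex])
    # total SD of BMI at takeoff across children (level + slope variation)
    sd = float(np.hypot(config.bmi_level_sd, config.bmi_slope_sd * (tko - 7.0)))
    return cut - rise - z * sd


def _child_ids(config: SimConfig) -> list[tuple[str, str, str, int]]:
    """(child_id, sex, cohort, index) in deterministic order."""
    out = []
    k = 0
    for coh in config.cohorts:
        n = coh.n if coh.n is not None else config.n_children_per_cohort
        for j in range(n):
            sex = coh.sexes[j % len(coh.sexes)]
            out.append((f"{coh.name}-{j:04d}", sex, coh.name, k))
            k += 1
    return out


def _bmi_params(config: SimConfig, sex: str, child_index: int) -> tuple[float, float]:
    rng = _rng(config, 3, child_index)
    level = _bmi_level_mean(config, sex) + rng.normal(0.0, config.bmi_level_sd)
    slope = rng.normal(config.bmi_slope_mean, config.bmi_slope_sd)
    return level, slope


def _bmi_true(level: float, slope: float, age) -> np.ndarray:
    age = np.asarray(age, float)
    return level + slope * (age - 7.0) + 0.02 * (age - 7.0) ** 2


def simulate_children(config: SimConfig) -> list[TruthRecord]:
    """Draw per-child effects and derive true markers and onset ages."""
    om = config.omega_arr
    if np.any(np.linalg.eigvalsh(om) < -1e-12):
        raise ValueError("Omega must be positive semi-definite")
    chol = np.linalg.cholesky(om + 1e-12 * np.eye(3))
    cohorts = {c.name: c for c in config.cohorts}
    records = []
    for child_id, sex, coh_name, k in _child_ids(config):
        coh = cohorts[coh_name]
        tpl = template_for_sex(sex)
        rng = _rng(config, 1, k)
        a_i, b_i, c_i = chol @ rng.standard_normal(3)
        a = a_i + coh.a_offset
        b = b_i + coh.b_offset
        c = c_i + coh.c_offset
        u_star = tpl.aphv
        aphv = T_CENTER + b + (u_star - T_CENTER) * np.exp(-c)
        phv = np.exp(c) * tpl.phv
        tko = T_CENTER + b + (tpl.takeoff - T_CENTER) * np.exp(-c)

        level, slope = _bmi_params(config, sex, k)
        bmi_tko = float(_bmi_true(level, slope, tko))
        ow = bmi_tko > float(synthetic_overweight_cutoff(tko, sex))

        link = config.onset_link[sex]
        onset = (
            link["intercept"]
            + link["aphv"] * aphv
            + link["phv"] * phv
            + link["overweight"] * ow
            + link["interaction"] * (aphv - tpl.aphv) * ow
            + rng.normal(0.0, link["sigma"])
        )
        records.append(
            TruthRecord(
                child_id, sex, coh_name,
                float(a_i), float(b_i), float(c_i),
                float(aphv), float(phv), float(tko), bool(ow), float(onset),
            )
        )
    return records


def visit_schedule(
    config: SimConfig, child_id: str
) -> tuple[np.ndarray, np.ndarray]:
    """(growth ages, pubertal ages) for one child, after dropout truncation."""
    matches = [(cid, sex, coh, k) for cid, sex, coh, k in _child_ids(config)
               if cid == child_id]
    if not matches:
        raise KeyError(f"unknown child {child_id!r}")
    _, _, coh_name, k = matches[0]
    coh = {c.name: c for c in config.cohorts}[coh_name]
    rng = _rng(config, 2, k)
    lo_m, hi_m = coh.growth_spacing_months
    start, end = config.age_range

    growth = [start]
    while growth[-1] < end:
        gap = rng.uniform(lo_m, hi_m) / 12.0 if hi_m > lo_m else lo_m / 12.0
        growth.append(growth[-1] + gap)
    growth = np.array([t for t in growth if t <= end + 1e-9])

    if coh.pubertal_spacing_months is None:
        pubertal = np.array([])
    else:
        gap = coh.pubertal_spacing_months / 12.0
        pubertal = np.arange(coh.pubertal_start_age, end + 1e-9, gap)
        pubertal = pubertal + rng.uniform(-0.04, 0.04, size=len(pubertal))
        pubertal = pubertal[pubertal >= coh.pubertal_start_age - 1e-9]

    if config.dropout_hazard > 0:
        stop_visit = rng.geometric(min(config.dropout_hazard, 1.0))
        growth = growth[:stop_visit]
        stop_age = growth[-1] if len(growth) else start
        if config.dropout_hazard >= 1.0:
            pubertal = pubertal[:0]
        else:
            pubertal = pubertal[pubertal <= stop_age + 1e-9]
    return growth, pubertal


def emit_observations(
    truth: list[TruthRecord], config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Noisy visit tables (growth, pubertal) for the given truth records."""
    cohorts = {c.name: c for c in config.cohorts}
    idx = {cid: (sex, coh, k) for cid, sex, coh, k in _child_ids(config)}
    growth_rows, pub_rows = [], []
    for rec in truth:
        sex, coh_name, k = idx[rec.child_id]
        coh = cohorts[coh_name]
        tpl = template_for_sex(sex)
        g_ages, p_ages = visit_schedule(config, rec.child_id)
        rng = _rng(config, 4, k)

        a = rec.a + coh.a_offset
        b = rec.b + coh.b_offset
        c = rec.c + coh.c_offset
        theta = T_CENTER + (g_ages - T_CENTER - b) * np.exp(c)
        heights = a + tpl.height(theta) + rng.normal(0, config.sigma_height, len(g_ages))
        level, slope = _bmi_params(config, sex, k)
        bmis = _bmi_true(level, slope, g_ages) + rng.normal(
            0, config.sigma_bmi, len(g_ages)
        )
        for t, h, bm in zip(g_ages, heights, bmis):
            growth_rows.append((rec.child_id, sex, coh_name, float(t), float(h), float(bm)))

        for t in p_ages:
            if sex == "F":
                if t < rec.onset_age:
                    stage = 1
                else:
                    stage = min(
                        5, 2 + int((t - rec.onset_age) / config.tanner_stage_duration)
                    )
                pub_rows.append((rec.child_id, sex, float(t), stage, np.nan))
            else:
                # logistic testis growth crossing 25 mm exactly at true onset
                s = 0.55
                t0 = rec.onset_age + s * np.log((45.0 - 15.0) / (25.0 - 15.0) - 1.0)
                length = 15.0 + 30.0 / (1.0 + np.exp(-(t - t0) / s))
                if config.testis_noise_sd > 0:
                    eps = rng.normal(0.0, config.testis_noise_sd)
                    eps = float(np.clip(eps, -2 * config.testis_noise_sd,
                                        2 * config.testis_noise_sd))
                    length += eps
                pub_rows.append((rec.child_id, sex, float(t), np.nan, float(length)))
    growth = pd.DataFrame(growth_rows, columns=GROWTH_COLUMNS)
    pubertal = pd.DataFrame(pub_rows, columns=PUBERTAL_COLUMNS)
    return growth, pubertal


def truth_table(truth: list[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.child_id, r.sex, r.cohort, r.a, r.b, r.c, r.aphv, r.phv,
             r.takeoff_age, int(r.overweight), r.onset_age)
            for r in truth
        ],
        columns=TRUTH_COLUMNS,
    )


def truth_from_table(df: pd.DataFrame) -> list[TruthRecord]:
    return [
        TruthRecord(
            r.child_id, r.sex, r.cohort, float(r.a), float(r.b), float(r.c),
            float(r.aphv), float(r.phv), float(r.takeoff_age),
            bool(r.overweight), float(r.onset_age),
        )
        for r in df.itertuples(index=False)
    ]


def simulate(config: SimConfig):
    """Full simulation: (truth records, growth table, pubertal table)."""
    truth = simulate_children(config)
    growth, pubertal = emit_observations(truth, config)
    return truth, growth, pubertal
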