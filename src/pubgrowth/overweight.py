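"""Overweight classification at growth-spurt takeoff.

A child's overweight status enters the onset model as a binary covariate
determined at the start of the growth spurt (the velocity minimum before
aPHV): the child's BMI at that age is read off an individual BMI-age
trajectory and converted to its adult-equivalent scale (ISO-BMI) with a
sex- and age-specific reference; ISO-BMI strictly above 25 is overweight
(overweight + obese pooled), everything else "other".

The BMI-age trajectory is a polynomial mixed-effects model with a random
intercept and random effects for every polynomial coefficient, fitted by
maximum likelihood (statsmodels MixedLM on internally centered/scaled age).
When the data are exactly polynomial (pooled per-child residuals
numerically zero) the variance components are not identifiable and the fit
falls back to per-child least squares with a warning.

The reference is pluggable: a CSV of (sex, age_years, bmi_child,
bmi_adult_equiv) rows, interpolated monotonically in BMI at each age and
linearly across ages. No national reference values are bundled; a clearly
synthetic reference is provided for simulations and tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ISO_BMI_CUTOFF = 25.0


# ---------------------------------------------------------------------------
# ISO-BMI reference
# ---------------------------------------------------------------------------


@dataclass
class IsoBmiReference:
    """Maps (sex, age, BMI) to an adult-equivalent BMI by interpolation."""

    table: pd.DataFrame  # sex, age_years, bmi_child, bmi_adult_equiv

    def __post_init__(self) -> None:
        req = {"sex", "age_years", "bmi_child", "bmi_adult_equiv"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"reference table missing columns: {sorted(missing)}")
        for (sex, age), grp in self.table.groupby(["sex", "age_years"]):
            v = grp.sort_values("bmi_child")["bmi_adult_equiv"].to_numpy()
            if len(v) < 2 or np.any(np.diff(v) <= 0):
                raise ValueError(
                    f"reference not strictly increasing in BMI at sex={sex}, age={age}"
                )

    def iso_bmi(self, sex: str, age: float, bmi: float) -> float:
        sub = self.table[self.table["sex"] == sex]
        if sub.empty:
            raise ValueError(f"reference has no rows for sex={sex!r}")
        ages = np.sort(sub["age_years"].unique())
        if not (ages[0] <= age <= ages[-1]):
            raise ValueError(
                f"reference gap: age {age:.2f} outside [{ages[0]:g}, {ages[-1]:g}] "
                f"for sex={sex}"
            )
        hi = int(np.searchsorted(ages, age))
        lo = max(hi - 1, 0) if ages[min(hi, len(ages) - 1)] != age else hi

        def at_age(a):
            g = sub[sub["age_years"] == a].sort_values("bmi_child")
            return float(
                np.interp(bmi, g["bmi_child"].to_numpy(), g["bmi_adult_equiv"].to_numpy())
            )

        if lo == hi or ages[hi] == age:
            return at_age(ages[min(hi, len(ages) - 1)])
        w = (age - ages[lo]) / (ages[hi] - ages[lo])
        return (1 - w) * at_age(ages[lo]) + w * at_age(ages[hi])

    @classmethod
    def from_csv(cls, path) -> "IsoBmiReference":
        return cls(pd.read_csv(path))


def synthetic_iso_bmi_reference(
    ages: np.ndarray | None = None, bmis: np.ndarray | None = None
) -> IsoBmiReference:
    """A synthetic stand-in ISO-BMI reference for simulations and tests.

    The adult-equivalent BMI is bmi * 25 / cutoff(age, sex), where
    cutoff(age, sex) rises linearly from a childhood value to 25 at age 18
    (boys start slightly lower, as pediatric BMI references do). This is a
    deliberately simple synthetic construction, not any national standard.
    """
    if ages is None:
        ages = np.arange(6.0, 20.0 + 1e-9, 0.5)
    if bmis is None:
        bmis = np.arange(10.0, 45.0 + 1e-9, 5.0)
    rows = []
    for sex, c7 in (("F", 17.8), ("M", 17.4)):
        for a in ages:
            cut = c7 + (25.0 - c7) * np.clip((a - 7.0) / 11.0, 0.0, 1.0)
            for b in bmis:
                rows.append((sex, float(a), float(b), float(b * 25.0 / cut)))
    return IsoBmiReference(
        pd.DataFrame(rows, columns=["sex", "age_years", "bmi_child", "bmi_adult_equiv"])
    )


def synthetic_overweight_cutoff(age: float | np.ndarray, sex: str) -> np.ndarray:
    """Child-BMI value mapping to ISO-BMI exactly 25 under the synthetic reference."""
    c7 = 17.8 if sex == "F" else 17.4
    return c7 + (25.0 - c7) * np.clip((np.asarray(age, float) - 7.0) / 11.0, 0.0, 1.0)


def classify_overweight(
    bmi: float, age: float, sex: str, ref: IsoBmiReference
) -> bool:
    """ISO-BMI strictly above 25 -> overweight; exactly 25 is 'other'."""
    return ref.iso_bmi(sex, age, bmi) > ISO_BMI_CUTOFF


# ---------------------------------------------------------------------------
# BMI-age trajectories
# ---------------------------------------------------------------------------


@dataclass
class BmiTrajectoryFit:
    degree: int
    age_center: float
    age_scale: float
    fixed: np.ndarray  # degree+1 coefficients on the scaled-age polynomial
    random: pd.DataFrame  # per-child deviations, same parameterization
    resid_sd: float
    cov_re: np.ndarray
    child_range: pd.DataFrame  # per-child observed age min/max
    method: str = "mixedlm"
    warnings_: list = field(default_factory=list)


def _poly_design(age_scaled: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(age_scaled, degree + 1, increasing=True)


def fit_bmi_trajectory(visits: pd.DataFrame, degree: int = 3) -> BmiTrajectoryFit:
    """Polynomial random-coefficients model for BMI against age, by ML.

    ``visits`` needs child_id, age_years, bmi. Ages are centered and scaled
    internally for conditioning. Every polynomial coefficient (including the
    intercept) carries a random effect.
    """
    req = {"child_id", "age_years", "bmi"}
    if req - set(visits.columns):
        raise ValueError(f"BMI table missing columns: {sorted(req - set(visits.columns))}")
    visits = visits.dropna(subset=["bmi"])
    ages = visits["age_years"].to_numpy(float)
    if len(visits) < degree + 2:
        raise ValueError("too few BMI observations for the requested degree")
    if len(np.unique(ages)) <= degree:
        raise ValueError("polynomial degree must be below the number of distinct ages")
    center, scale = float(ages.mean()), float(ages.std() or 1.0)
    z = (ages - center) / scale
    X = _poly_design(z, degree)
    y = visits["bmi"].to_numpy(float)
    groups = visits["child_id"].to_numpy()

    child_range = visits.groupby("child_id")["age_years"].agg(["min", "max"])
    child_range.columns = ["t_min", "t_max"]

    # per-child OLS: both the degenerate-case detector and the fallback
    percols = {}
    rss = 0.0
    for cid, grp in visits.groupby("child_id"):
        zi = (grp["age_years"].to_numpy(float) - center) / scale
        Xi = _poly_design(zi, degree)
        yi = grp["bmi"].to_numpy(float)
        coef, *_ = np.linalg.lstsq(Xi, yi, rcond=None)
        percols[cid] = coef
        rss += float(np.sum((yi - Xi @ coef) ** 2))

    if rss < 1e-16 * max(len(y), 1):
        logger.warning(
            "BMI data exactly polynomial per child (pooled residual ~ 0); "
            "variance components unidentifiable - using per-child least squares"
        )
        fixed = np.mean(np.stack(list(percols.values())), axis=0)
        random = pd.DataFrame(
            {cid: c - fixed for cid, c in percols.items()}
        ).T
        random.index.name = "child_id"
        return BmiTrajectoryFit(
            degree, center, scale, fixed, random, 0.0,
            np.cov(np.stack(list(percols.values())).T) if len(percols) > 1
            else np.zeros((degree + 1, degree + 1)),
            child_range, method="per_child_ols",
            warnings_=["degenerate noise-free data"],
        )

    from statsmodels.regression.mixed_linear_model import MixedLM

    warns: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = MixedLM(y, X, groups=groups, exog_re=X)
        result = model.fit(reml=False, method="lbfgs", maxiter=400)
        warns = [str(w.message) for w in caught]
    if np.min(np.diag(result.cov_re)) < 1e-8:
        msg = "estimated random-effect variance at the zero boundary"
        logger.warning(msg)
        warns.append(msg)
    random = pd.DataFrame(
        {cid: np.asarray(re) for cid, re in result.random_effects.items()}
    ).T
    random.index.name = "child_id"
    return BmiTrajectoryFit(
        degree, center, scale,
        np.asarray(result.fe_params),
        random,
        float(np.sqrt(result.scale)),
        np.asarray(result.cov_re),
        child_range,
        method="mixedlm",
        warnings_=warns,
    )


def bmi_at_age(fit: BmiTrajectoryFit, child_id, age: float, margin: float = 1.0):
    """Evaluate a child's BMI trajectory at ``age``.

    Returns (bmi, extrapolated_flag); the flag is set when ``age`` lies more
    than ``margin`` years outside the child's observed range.
    """
    if child_id not in fit.random.index:
        raise KeyError(f"unknown child {child_id!r}")
    z = (age - fit.age_center) / fit.age_scale
    coefs = fit.fixed + fit.random.loc[child_id].to_numpy()
    value = float(np.polynomial.polynomial.polyval(z, coefs))
    t_min, t_max = fit.child_range.loc[child_id]
    flagged = not (t_min - margin <= age <= t_max + margin)
    if flagged:
        logger.warning(
            "child %s: BMI evaluated at %.2f, outside [%.2f, %.2f] + %.1f yr margin",
            child_id, age, t_min, t_max, margin,
        )
    return value, flagged


def overweight_table(
    bmi_fit: BmiTrajectoryFit,
    marker_table: pd.DataFrame,
    sex: str,
    ref: IsoBmiReference,
) -> pd.DataFrame:
    """Overweight flag per child, from BMI at takeoff age against the reference."""
    rows = []
    for r in marker_table.itertuples(index=False):
        if r.flag or not np.isfinite(r.takeoff_age):
            continue
        if r.child_id not in bmi_fit.random.index:
            logger.info("child %s: no BMI trajectory; overweight undefined", r.child_id)
            continue
        bmi, extrap = bmi_at_age(bmi_fit, r.child_id, r.takeoff_age)
        iso = ref.iso_bmi(sex, r.takeoff_age, bmi)
        rows.append(
            {
                "child_id": r.child_id,
                "bmi_at_takeoff": bmi,
                "iso_bmi": iso,
                "overweight": int(iso > ISO_BMI_CUTOFF),
                "bmi_extrapolated": int(extrap),
            }
        )
    return pd.DataFrame(
        rows, columns=["child_id", "bmi_at_takeoff", "iso_bmi", "overweight",
                       "bmi_extrapolated"]
    )
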