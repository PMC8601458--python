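"""Censoring-interval construction for the age at pubertal onset.

Pubertal onset is never observed exactly: staging visits bracket it. For
girls, onset is the transition from Tanner breast stage B1 to B2 (or, when
B2 was skipped in the record, to the first stage above B1). For boys, onset
is the first visit at which the larger testis measures >= 25 mm *and* the
measurement is confirmed at the next visit; the interval runs from the last
visit below threshold to the first visit of the confirmed pair.

Each child is mapped to exactly one of three censoring types:

``interval``
    onset in (left, right] — bracketed by two visits;
``right``
    all visits pre-pubertal — onset after the last visit (right = +inf);
``left``
    pubertal already at the first visit — onset before it (left = 0).

Intervals are left-open/right-closed by convention; under the continuous
Gaussian onset model the likelihood is insensitive to the open/closed
choice, so the convention matters only for reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TESTIS_ONSET_MM = 25.0

INTERVAL_COLUMNS = ["child_id", "left", "right", "censor_type"]


@dataclass(frozen=True)
class OnsetInterval:
    """Censoring interval for one child's pubertal onset age (years)."""

    child_id: object
    left: float
    right: float
    censor_type: str  # interval | right | left | exact

    def __post_init__(self) -> None:
        if self.censor_type == "exact":
            # degenerate limit: an exactly observed onset (both bounds equal)
            if self.left != self.right:
                raise ValueError("exact observation must have left == right")
            return
        if not self.left < self.right:
            raise ValueError(
                f"child {self.child_id}: left bound {self.left} must be "
                f"strictly below right bound {self.right}"
            )
        if self.censor_type == "right" and np.isfinite(self.right):
            raise ValueError("right-censored interval must have right = +inf")
        if self.censor_type == "left" and self.left != 0.0:
            raise ValueError("left-censored interval must have left = 0")

    @property
    def interval_length(self) -> float:
        return self.right - self.left


def _sorted_child_groups(visits: pd.DataFrame, value_col: str):
    """Yield (child_id, ages, values) with missing values dropped, sorted by age."""
    required = {"child_id", "age_years", value_col}
    missing = required - set(visits.columns)
    if missing:
        raise ValueError(f"pubertal visit table is missing columns: {sorted(missing)}")
    sub = visits[["child_id", "age_years", value_col]].dropna(subset=[value_col])
    for child_id, grp in sub.groupby("child_id", sort=True):
        grp = grp.sort_values("age_years")
        yield child_id, grp["age_years"].to_numpy(float), grp[value_col].to_numpy(float)


def intervals_from_tanner_breast(visits: pd.DataFrame) -> list[OnsetInterval]:
    """Build girls' onset intervals from Tanner breast stages.

    Rule: onset lies between the last observed B1 and the first observed
    stage >= B2 (the next available breast-stage measurement when B2 itself
    is missing). All-B1 sequences are right-censored at the last visit;
    a first visit already >= B2 is left-censored at that age.

    A stage sequence that decreases (e.g. B2 then B1) is clinically
    implausible; it is logged and the last-B1/first->=2 rule applied verbatim.
    """
    out: list[OnsetInterval] = []
    for child_id, ages, stages in _sorted_child_groups(visits, "tanner_breast"):
        if np.any((stages < 1) | (stages > 5)):
            raise ValueError(f"child {child_id}: Tanner breast stage outside 1..5")
        if np.any(np.diff(stages) < 0):
            logger.warning(
                "child %s: non-monotone Tanner stage sequence; applying "
                "last-B1/first->=B2 rule verbatim",
                child_id,
            )
        b1_ages = ages[stages == 1]
        beyond = ages[stages >= 2]
        if beyond.size == 0:
            out.append(OnsetInterval(child_id, float(ages[-1]), np.inf, "right"))
        elif b1_ages.size == 0 or b1_ages[-1] > beyond[0]:
            # pubertal at (or before) first usable visit
            out.append(OnsetInterval(child_id, 0.0, float(beyond[0]), "left"))
        else:
            out.append(
                OnsetInterval(child_id, float(b1_ages[-1]), float(beyond[0]), "interval")
            )
    return out


def intervals_from_testis_length(
    visits: pd.DataFrame, threshold_mm: float = TESTIS_ONSET_MM
) -> list[OnsetInterval]:
    """Build boys' onset intervals from testis-length measurements.

    Onset requires the larger testis >= ``threshold_mm`` at two successive
    visits; the onset visit is the first of the confirmed pair. The interval
    runs from the last sub-threshold visit before that pair to the onset
    visit. Transient single crossings followed by a sub-threshold visit are
    ignored; a final-visit crossing that was never confirmed leaves the boy
    right-censored (logged), since the two-visit rule was not met.

    ``threshold_mm`` defaults to the 25 mm criterion; the legacy 20 mm
    threshold is available only as an override for sensitivity analyses.
    """
    out: list[OnsetInterval] = []
    for child_id, ages, lengths in _sorted_child_groups(visits, "testis_len_mm"):
        above = lengths >= threshold_mm
        onset_idx = None
        for v in range(len(ages) - 1):
            if above[v] and above[v + 1]:
                onset_idx = v
                break
        if onset_idx is None:
            if above.any():
                logger.info(
                    "child %s: unconfirmed >=%.0f mm measurement without a "
                    "successive confirmation; right-censored at last visit",
                    child_id,
                    threshold_mm,
                )
            out.append(OnsetInterval(child_id, float(ages[-1]), np.inf, "right"))
            continue
        below_before = np.nonzero(~above[:onset_idx])[0]
        if below_before.size == 0:
            out.append(OnsetInterval(child_id, 0.0, float(ages[onset_idx]), "left"))
        else:
            out.append(
                OnsetInterval(
                    child_id,
                    float(ages[below_before[-1]]),
                    float(ages[onset_idx]),
                    "interval",
                )
            )
    return out


def build_intervals(pubertal: pd.DataFrame, sex: str) -> list[OnsetInterval]:
    """Dispatch to the sex-appropriate rule (F: Tanner breast, M: testis length)."""
    if sex == "F":
        return intervals_from_tanner_breast(pubertal)
    if sex == "M":
        return intervals_from_testis_length(pubertal)
    raise ValueError(f"sex must be 'F' or 'M', got {sex!r}")


def intervals_to_frame(intervals: list[OnsetInterval]) -> pd.DataFrame:
    df = pd.DataFrame(
        [(iv.child_id, iv.left, iv.right, iv.censor_type) for iv in intervals],
        columns=INTERVAL_COLUMNS,
    )
    return df


def intervals_from_frame(df: pd.DataFrame) -> list[OnsetInterval]:
    return [
        OnsetInterval(r.child_id, float(r.left), float(r.right), r.censor_type)
        for r in df.itertuples(index=False)
    ]


def apply_inclusion_criteria(
    growth: pd.DataFrame,
    intervals: list[OnsetInterval],
    min_height_measurements: int = 4,
    age_window: tuple[float, float] = (7.0, 19.0),
) -> tuple[pd.DataFrame, list[OnsetInterval], dict]:
    """Restrict growth data to the analysis age window and select eligible children.

    Growth rows outside ``age_window`` are dropped. A child is eligible for
    the stage-2 onset analysis when it retains at least
    ``min_height_measurements`` height measurements inside the window *and*
    has a defined onset interval.

    Returns (windowed growth table, eligible intervals, exclusion report).
    The report counts exclusions by reason and eligible children by
    censoring type.
    """
    lo, hi = age_window
    in_window = growth[(growth["age_years"] >= lo) & (growth["age_years"] <= hi)]
    n_rows_dropped = len(growth) - len(in_window)

    counts = in_window.groupby("child_id").size()
    enough = set(counts[counts >= min_height_measurements].index)

    eligible: list[OnsetInterval] = []
    n_too_few = 0
    for iv in intervals:
        if iv.child_id in enough:
            eligible.append(iv)
        else:
            n_too_few += 1
    interval_ids = {iv.child_id for iv in intervals}
    n_no_interval = len(enough - interval_ids)

    by_type = {t: 0 for t in ("interval", "right", "left")}
    for iv in eligible:
        by_type[iv.censor_type] += 1
    n_elig = len(eligible)
    report = {
        "n_growth_rows_outside_window": int(n_rows_dropped),
        "n_with_pubertal_interval": len(intervals),
        "n_excluded_fewer_than_min_heights": int(n_too_few),
        "n_growth_only_no_interval": int(n_no_interval),
        "n_eligible": n_elig,
        "eligible_by_censor_type": by_type,
        "pct_by_censor_type": {
            t: (100.0 * c / n_elig if n_elig else float("nan"))
            for t, c in by_type.items()
        },
        "min_height_measurements": int(min_height_measurements),
        "age_window": [lo, hi],
    }
    return in_window, eligible, report
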