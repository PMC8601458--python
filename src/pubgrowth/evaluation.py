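"""Predictive evaluation of the onset model.

Out-of-sample predictions come from k-fold cross-validation with folds
drawn child-wise (each child is predicted by a model fitted without it;
k = 10 by default). Predictive success is the *agreement* statistic: for
every interval-censored child whose observed interval is shorter than 1.5
years, a one-year window centred on the predicted onset is compared with
the observed interval, and any overlap — including a single shared
endpoint — counts as agreement. Children with right- or left-censored
onsets, or with observed intervals of 1.5 years or more, are excluded from
the denominator (counted separately).

When lasso selection is part of the model it runs inside each training
fold, so no selection information leaks into the held-out children; the
leaky variant (select once on all data, then cross-validate) is available
behind a flag for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import aft
from .intervals import OnsetInterval

logger = logging.getLogger(__name__)


@dataclass
class AgreementResult:
    n_input: int
    n_uncensorable: int          # right/left-censored, never evaluable
    n_excluded_by_length: int    # interval length >= the cutoff
    n_evaluated: int
    n_agreements: int
    agreement_pct: float
    records: pd.DataFrame        # child_id, left, right, pred, pred_lo, pred_hi, agree


def make_folds(child_ids: list, k: int, seed: int) -> dict:
    """Seeded child-wise fold assignment {child_id: fold}."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(child_ids) < k:
        raise ValueError(f"need at least k={k} children")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(child_ids))
    return {child_ids[j]: int(i % k) for i, j in enumerate(order)}


def kfold_predict(
    intervals: list[OnsetInterval],
    table: pd.DataFrame,
    spec: aft.ModelSpec | str,
    k: int = 10,
    seed: int = 0,
    folds: dict | None = None,
    leaky_selection: bool = False,
) -> pd.DataFrame:
    """Out-of-fold point predictions for every child.

    ``spec`` may be a ModelSpec or the string 'lasso'; lasso selection is
    re-run inside each training fold unless ``leaky_selection`` is set, in
    which case terms are selected once on the full data first.
    """
    ids = [iv.child_id for iv in intervals]
    if folds is None:
        folds = make_folds(ids, k, seed)
    k_eff = max(folds.values()) + 1

    fixed_spec = None
    if isinstance(spec, str):
        if spec != "lasso":
            raise ValueError("spec must be a ModelSpec or 'lasso'")
        if leaky_selection:
            fixed_spec, _ = aft.lasso_select(intervals, table, seed=seed)
    else:
        fixed_spec = spec

    idx = table.set_index("child_id")
    rows = []
    for fold in range(k_eff):
        train = [iv for iv in intervals if folds[iv.child_id] != fold]
        test = [iv for iv in intervals if folds[iv.child_id] == fold]
        if not test:
            continue
        try:
            use_spec = fixed_spec
            if use_spec is None:
                use_spec, _ = aft.lasso_select(train, table, seed=seed)
            fit = aft.fit_aft(train, table, use_spec)
        except Exception as err:
            raise RuntimeError(f"fold {fold}: onset model refit failed: {err}") from err
        sub = idx.loc[[iv.child_id for iv in test]].reset_index()
        pred = aft.predict_onset(fit, sub, levels=())
        for cid, p in zip(sub["child_id"], pred["pred"]):
            rows.append({"child_id": cid, "fold": fold, "pred": float(p)})
    return pd.DataFrame(rows)


def agreement(
    observed: list[OnsetInterval],
    predicted: pd.DataFrame | dict,
    max_interval_length: float = 1.5,
    half_width: float = 0.5,
) -> AgreementResult:
    """Interval-overlap agreement between observed and predicted onsets.

    The predicted interval is [pred - half_width, pred + half_width] (one
    year wide by default, matching typical visit spacing); agreement means
    max(L, pred - hw) <= min(R, pred + hw). Only interval-censored children
    with R - L < ``max_interval_length`` enter the denominator.
    """
    if isinstance(predicted, pd.DataFrame):
        predicted = dict(zip(predicted["child_id"], predicted["pred"]))
    n_unc = 0
    n_len = 0
    rows = []
    for iv in observed:
        if iv.censor_type != "interval":
            n_unc += 1
            continue
        if iv.interval_length >= max_interval_length:
            n_len += 1
            continue
        if iv.child_id not in predicted:
            raise ValueError(f"no prediction for interval-censored child {iv.child_id}")
        p = float(predicted[iv.child_id])
        lo, hi = p - half_width, p + half_width
        agree = max(iv.left, lo) <= min(iv.right, hi)
        rows.append(
            {
                "child_id": iv.child_id,
                "left": iv.left,
                "right": iv.right,
                "pred": p,
                "pred_lo": lo,
                "pred_hi": hi,
                "agree": bool(agree),
            }
        )
    records = pd.DataFrame(
        rows, columns=["child_id", "left", "right", "pred", "pred_lo", "pred_hi", "agree"]
    )
    n_eval = len(records)
    n_agree = int(records["agree"].sum()) if n_eval else 0
    return AgreementResult(
        n_input=len(observed),
        n_uncensorable=n_unc,
        n_excluded_by_length=n_len,
        n_evaluated=n_eval,
        n_agreements=n_agree,
        agreement_pct=(100.0 * n_agree / n_eval) if n_eval else float("nan"),
        records=records,
    )


def compare_models(
    intervals: list[OnsetInterval],
    table: pd.DataFrame,
    specs: dict[str, aft.ModelSpec | str],
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """CV agreement for several model specs on identical folds (paired).

    Returns one row per spec with the agreement percentage and the
    full-data coefficient estimates (se) for reporting.
    """
    if len(specs) < 2:
        raise ValueError("compare_models needs at least 2 specs")
    ids = [iv.child_id for iv in intervals]
    folds = make_folds(ids, k, seed)
    rows = []
    for name, spec in specs.items():
        preds = kfold_predict(intervals, table, spec, k=k, seed=seed, folds=folds)
        res = agreement(intervals, preds)
        use_spec = spec
        if isinstance(spec, str):
            use_spec, _ = aft.lasso_select(intervals, table, seed=seed)
        fit = aft.fit_aft(intervals, table, use_spec)
        coefs = "; ".join(
            f"{t}={b:.3f} ({s:.3f})"
            for t, b, s in zip(fit.coef_names, fit.coef, fit.se)
        )
        rows.append(
            {
                "model": name,
                "terms": "+".join(fit.terms) if fit.terms else "(intercept)",
                "agreement_pct": res.agreement_pct,
                "n_evaluated": res.n_evaluated,
                "sigma": fit.sigma,
                "coefficients": coefs,
            }
        )
    return pd.DataFrame(rows)
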