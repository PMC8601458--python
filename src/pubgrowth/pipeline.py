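"""End-to-end two-stage pipeline: readers, configuration, driver, report.

One invocation processes one sex (all analyses are sex-stratified):
read or simulate the visit tables, fit the SITAR growth model, derive the
growth markers, build the onset censoring intervals, classify overweight at
takeoff, apply the inclusion criteria, fit the onset models (simple plus
extended or lasso-selected), cross-validate the agreement statistic, and
compute cohort contrasts. Every stage writes its artifact into the run
directory together with a manifest (seed, config, package version) and a
human-readable markdown report; the report is rendered from stored
artifacts only.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, aft, evaluation, intervals as iv_mod, markers as mk
from . import overweight as ow_mod
from .sitar import SitarFit, fit_sitar
from .synthetic import SimConfig, simulate, truth_table

logger = logging.getLogger(__name__)

GROWTH_REQUIRED = ["child_id", "sex", "cohort", "age_years", "height_cm"]
PUBERTAL_REQUIRED = ["child_id", "age_years"]


def read_visits(path, kind: str) -> tuple[pd.DataFrame, dict]:
    """Read and validate a growth or pubertal CSV.

    Growth tables need child_id, sex, cohort, age_years, height_cm and
    either bmi or weight_kg (BMI is recomputed from height and weight when
    only the latter is present). Pubertal tables need child_id, age_years
    and tanner_breast and/or testis_len_mm. Rows with negative or missing
    ages are dropped and reported; duplicate (child, age) height rows are
    averaged with a warning.
    """
    df = pd.read_csv(path)
    report: dict = {"path": str(path), "kind": kind, "n_rows_in": len(df)}
    required = GROWTH_REQUIRED if kind == "growth" else PUBERTAL_REQUIRED
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if kind == "pubertal" and not (
        "tanner_breast" in df.columns or "testis_len_mm" in df.columns
    ):
        raise ValueError(f"{path}: need tanner_breast and/or testis_len_mm")

    df["age_years"] = pd.to_numeric(df["age_years"], errors="coerce")
    bad_age = df["age_years"].isna() | (df["age_years"] < 0)
    if bad_age.any():
        logger.warning("%s: %d rows with missing/negative age dropped", path, bad_age.sum())
    df = df[~bad_age]
    report["n_rows_bad_age"] = int(bad_age.sum())

    if kind == "growth":
        if "bmi" not in df.columns:
            if "weight_kg" not in df.columns:
                raise ValueError(f"{path}: need a bmi or weight_kg column")
            df = df.assign(bmi=df["weight_kg"] / (df["height_cm"] / 100.0) ** 2)
        dup = df.duplicated(subset=["child_id", "age_years"], keep=False)
        n_dup_groups = 0
        if dup.any():
            n_dup_groups = int(
                dup.sum() - df[dup].groupby(["child_id", "age_years"]).ngroups
            )
            logger.warning("%s: %d duplicate (child, age) rows averaged", path, n_dup_groups)
            keys = ["child_id", "sex", "cohort", "age_years"]
            df = df.groupby(keys, as_index=False)[["height_cm", "bmi"]].mean()
        report["n_duplicates_averaged"] = n_dup_groups
    df = df.sort_values(["child_id", "age_years"], kind="mergesort").reset_index(drop=True)
    report["n_rows_out"] = len(df)
    report["n_children"] = int(df["child_id"].nunique())
    return df, report


@dataclass
class RunConfig:
    sex: str
    out_dir: str
    growth_path: str | None = None      # None -> simulate
    pubertal_path: str | None = None
    sim: SimConfig | None = None
    cohort_field: str = "cohort"
    sitar_df: int = 5
    bmi_degree: int = 3
    iso_bmi_reference_path: str | None = None  # None -> synthetic reference
    model: str = "extended"  # simple | extended | lasso
    k_folds: int = 10
    seed: int = 0
    min_height_measurements: int = 4
    age_window: tuple[float, float] = (7.0, 19.0)
    make_plot: bool = True
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")
        if self.model not in ("simple", "extended", "lasso"):
            raise ValueError("model must be simple, extended or lasso")
        for p in (self.growth_path, self.pubertal_path, self.iso_bmi_reference_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if self.growth_path is None and self.sim is None:
            self.sim = SimConfig(seed=self.seed)


def _config_digest(config: RunConfig) -> str:
    def default(o):
        return str(o)

    payload = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _extended_spec(sex: str) -> aft.ModelSpec:
    return aft.EXTENDED_GIRLS if sex == "F" else aft.EXTENDED_BOYS


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute the full two-stage analysis for one sex; returns the artifacts.

    Any stage failure aborts with the stage name attached.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    stage = "setup"
    pkg_logger = logging.getLogger("pubgrowth")
    log_handler = logging.FileHandler(out / "run.log")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    pkg_logger.addHandler(log_handler)
    try:
        stage = "input"
        if config.growth_path is None:
            sim = config.sim or SimConfig(seed=config.seed)
            truth, growth_all, pubertal_all = simulate(sim)
            truth_table(truth).to_csv(out / "truth.csv", index=False)
            growth_all.to_csv(out / "growth.csv", index=False)
            pubertal_all.to_csv(out / "pubertal.csv", index=False)
            growth = growth_all[growth_all["sex"] == config.sex]
            pubertal = pubertal_all[pubertal_all["sex"] == config.sex]
        else:
            growth, g_report = read_visits(config.growth_path, "growth")
            growth = growth[growth["sex"] == config.sex]
            artifacts["growth_validation"] = g_report
            pubertal = pd.DataFrame(columns=["child_id", "age_years"])
            if config.pubertal_path is not None:
                pubertal, p_report = read_visits(config.pubertal_path, "pubertal")
                pubertal = pubertal[pubertal["child_id"].isin(growth["child_id"])]
                artifacts["pubertal_validation"] = p_report
        if growth.empty:
            raise ValueError(f"no growth rows for sex={config.sex}")

        stage = "inclusion_window"
        lo, hi = config.age_window
        growth = growth[(growth["age_years"] >= lo) & (growth["age_years"] <= hi)]

        stage = "sitar_fit"
        fit = fit_sitar(growth, df=config.sitar_df, cohort_field=config.cohort_field,
                        sex=config.sex)
        fit.to_json(out / "sitar_fit.json")
        artifacts["sitar_fit"] = fit

        stage = "growth_markers"
        marker_df = mk.markers_table(fit)
        marker_df.to_csv(out / "markers.csv", index=False)
        artifacts["markers"] = marker_df

        stage = "cohort_contrasts"
        if len(fit.cohorts) >= 2:
            means, diffs = mk.cohort_contrasts(fit)
            means.to_csv(out / "contrast_means.csv", index=False)
            diffs.to_csv(out / "contrast_diffs.csv", index=False)
            artifacts["contrast_means"] = means
            artifacts["contrast_diffs"] = diffs

        stage = "onset_intervals"
        sex_col = "tanner_breast" if config.sex == "F" else "testis_len_mm"
        have_pub = sex_col in pubertal.columns and pubertal[sex_col].notna().any()
        onset_ivs = iv_mod.build_intervals(pubertal, config.sex) if have_pub else []
        iv_mod.intervals_to_frame(onset_ivs).to_csv(out / "intervals.csv", index=False)

        stage = "overweight"
        have_bmi = "bmi" in growth.columns and growth["bmi"].notna().any()
        ow_df = pd.DataFrame(columns=["child_id", "overweight"])
        if have_bmi:
            bmi_fit = ow_mod.fit_bmi_trajectory(growth, degree=config.bmi_degree)
            ref = (
                ow_mod.IsoBmiReference.from_csv(config.iso_bmi_reference_path)
                if config.iso_bmi_reference_path
                else ow_mod.synthetic_iso_bmi_reference()
            )
            ow_df = ow_mod.overweight_table(bmi_fit, marker_df, config.sex, ref)
            ow_df.to_csv(out / "overweight.csv", index=False)
        artifacts["overweight"] = ow_df

        stage = "inclusion_criteria"
        growth_w, eligible, incl_report = iv_mod.apply_inclusion_criteria(
            growth, onset_ivs, config.min_height_measurements, config.age_window
        )
        (out / "inclusion_report.json").write_text(json.dumps(incl_report, indent=1))
        artifacts["inclusion_report"] = incl_report

        stage = "onset_model"
        results = {}
        agreement_block = {}
        if eligible:
            covars = marker_df[marker_df["flag"] == ""][
                ["child_id", "aphv", "phv", "size"]
            ].merge(ow_df[["child_id", "overweight"]], on="child_id", how="inner")
            usable = set(covars["child_id"])
            eligible = [e for e in eligible if e.child_id in usable]

            specs: dict[str, aft.ModelSpec | str] = {"simple": aft.SIMPLE}
            if config.model == "extended":
                specs["extended"] = _extended_spec(config.sex)
            elif config.model == "lasso":
                specs["lasso"] = "lasso"
            for name, spec in specs.items():
                use_spec = spec
                if isinstance(spec, str):
                    use_spec, lasso_diag = aft.lasso_select(
                        eligible, covars, seed=config.seed
                    )
                    results["lasso_selected_terms"] = list(use_spec.terms)
                m_fit = aft.fit_aft(eligible, covars, use_spec)
                results[name] = m_fit
                preds = evaluation.kfold_predict(
                    eligible, covars, spec, k=config.k_folds, seed=config.seed
                )
                agr = evaluation.agreement(eligible, preds)
                agreement_block[name] = agr
                preds_full = aft.predict_onset(
                    m_fit, covars[covars["child_id"].isin(preds["child_id"])]
                )
                cv = preds.set_index("child_id")["pred"]
                preds_full = preds_full.assign(
                    pred_cv=preds_full["child_id"].map(cv)
                )
                preds_full.to_csv(out / f"predictions_{name}.csv", index=False)
                agr.records.to_csv(out / f"agreement_{name}.csv", index=False)
            summary = {
                name: {
                    "agreement_pct": agr.agreement_pct,
                    "n_evaluated": agr.n_evaluated,
                    "n_agreements": agr.n_agreements,
                    "n_excluded_by_length": agr.n_excluded_by_length,
                    "n_uncensorable": agr.n_uncensorable,
                }
                for name, agr in agreement_block.items()
            }
            (out / "agreement.json").write_text(json.dumps(summary, indent=1))
            artifacts["agreement"] = agreement_block
            artifacts["onset_fits"] = results
            coef_rows = []
            for name, m_fit in results.items():
                if not isinstance(m_fit, aft.AftFit):
                    continue
                sf = m_fit.summary_frame().assign(model=name, sigma=m_fit.sigma)
                coef_rows.append(sf)
            pd.concat(coef_rows).to_csv(out / "onset_coefficients.csv", index=False)

            stage = "plot"
            if config.make_plot:
                last = list(agreement_block)[-1]
                _plot_predictions(
                    agreement_block[last].records, results[last].sigma,
                    out / "prediction_intervals.png", config.sex,
                )

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "sex": config.sex,
            "model": config.model,
            "config_digest": _config_digest(config),
            "n_children_growth": int(growth["child_id"].nunique()),
            "n_eligible_stage2": len(eligible) if eligible else 0,
            "artifacts": sorted(p.name for p in out.iterdir()),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        artifacts["manifest"] = manifest

        stage = "report"
        write_report(out)
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err
    finally:
        pkg_logger.removeHandler(log_handler)
        log_handler.close()
    return artifacts


def _plot_predictions(records: pd.DataFrame, sigma: float, path, sex: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import norm as _norm

    fig, ax = plt.subplots(figsize=(6, 5))
    if len(records):
        lo, hi = records["pred"].min() - 1.5, records["pred"].max() + 1.5
        xs = np.linspace(lo, hi, 50)
        for lev, shade in ((0.95, 0.15), (0.75, 0.25), (0.5, 0.35)):
            z = _norm.ppf(0.5 + lev / 2)
            ax.fill_between(xs, xs - z * sigma, xs + z * sigma,
                            color="grey", alpha=shade, lw=0)
        ax.vlines(records["pred"], records["left"], records["right"],
                  color="tab:blue", lw=1)
        ax.plot(xs, xs, color="black", lw=0.8)
    ax.set_xlabel("predicted onset age (years)")
    ax.set_ylabel("observed onset interval (years)")
    ax.set_title(f"Observed vs predicted pubertal onset ({'girls' if sex == 'F' else 'boys'})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_report(run_dir) -> Path:
    """Render report.md from the artifacts already stored in ``run_dir``."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError("manifest.json missing; run the pipeline first")
    manifest = json.loads(manifest_path.read_text())
    lines = [
        "# Pubertal onset determination - run report",
        "",
        f"- package version: {manifest['package_version']}",
        f"- sex: {manifest['sex']}   seed: {manifest['seed']}   model: {manifest['model']}",
        f"- children with growth data: {manifest['n_children_growth']}",
        f"- eligible for the onset model: {manifest['n_eligible_stage2']}",
        "",
    ]

    def add_csv(title, name, fmt="%.3f"):
        p = run_dir / name
        lines.append(f"## {title}")
        lines.append("")
        if p.exists():
            df = pd.read_csv(p)
            lines.append(df.to_markdown(index=False, floatfmt=".3f"))
        else:
            lines.append("not computed")
        lines.append("")

    add_csv("Cohort growth-marker means", "contrast_means.csv")
    add_csv("Cohort differences (delta method, Wald)", "contrast_diffs.csv")
    lines.append("## Overweight at growth-spurt takeoff")
    lines.append("")
    ow_path = run_dir / "overweight.csv"
    if ow_path.exists():
        ow = pd.read_csv(ow_path)
        if len(ow):
            lines.append(
                f"- {int(ow['overweight'].sum())} of {len(ow)} classified children "
                f"({100.0 * ow['overweight'].mean():.1f}%) overweight (ISO-BMI > 25)"
            )
        else:
            lines.append("not computed")
    else:
        lines.append("not computed")
    lines.append("")
    add_csv("Onset model coefficients", "onset_coefficients.csv")
    agr = run_dir / "agreement.json"
    lines.append("## Cross-validated agreement")
    lines.append("")
    if agr.exists():
        for name, block in json.loads(agr.read_text()).items():
            lines.append(
                f"- {name}: {block['agreement_pct']:.1f}% "
                f"({block['n_agreements']}/{block['n_evaluated']} evaluated; "
                f"{block['n_excluded_by_length']} excluded by interval length, "
                f"{block['n_uncensorable']} not interval-censored)"
            )
    else:
        lines.append("not computed")
    lines.append("")
    if (run_dir / "prediction_intervals.png").exists():
        lines.append("![prediction intervals](prediction_intervals.png)")
        lines.append("")
    path = run_dir / "report.md"
    path.write_text("\n".join(lines))
    return path
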