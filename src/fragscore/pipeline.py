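"""End-to-end orchestration: simulate/load -> filter -> score -> validate -> report.

Produces the study-style artifact bundle: per-patient score panels, per-model
validation reports, the pairwise DeLong matrix, discrimination/calibration and
risk-stratification summary tables, Kaplan-Meier curves, and a run manifest.
All outputs are deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort_io import Cohort, EligibilityConfig, Sex, filter_eligible, read_cohort
from .risk_scores import (
    MODEL_NAMES,
    ScorePanel,
    derive_holt_intercept,
    load_model_config,
    score_patient,
)
from .survival import km_estimate, logrank_test
from .synthetic_cohort import CohortSimConfig, generate_cohort
from .validation_metrics import (
    StratumResult,
    ValidationReport,
    build_report,
    delong_test,
    stratum_table,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "render_table3", "render_table4"]


@dataclass
class RunConfig:
    """One analysis run: exactly one input source (CSV path or simulation)."""

    input_csv: Optional[str] = None
    sim: Optional[CohortSimConfig] = None
    models: Sequence[str] = MODEL_NAMES
    model_config_path: Optional[str] = None
    threshold: float | str = "youden"
    hl_groups: int = 10
    hl_df_style: str = "validation"
    interval_mode: str = "upper"
    # None disables the Holt probability transform; "derive" back-solves the
    # published stratum bound pair; a float is used as-is
    holt_intercept: float | str | None = "derive"
    eligibility: EligibilityConfig = field(default_factory=EligibilityConfig)
    out_dir: str = "fragscore_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.sim is None):
            raise ValueError("exactly one of input_csv or sim must be given")


@dataclass
class PipelineResult:
    cohort: Cohort
    exclusion_log: dict[str, int]
    panels: pd.DataFrame
    reports: dict[str, ValidationReport]
    delong: Optional[pd.DataFrame]
    strata: dict[str, list[StratumResult]]
    km_overall: pd.DataFrame
    logrank_by_sex: Optional[tuple[float, float]]
    scoring_failures: dict[str, int]
    manifest: dict


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full validation flow and write the artifact bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.sim is not None:
        cohort = generate_cohort(config.sim)
    else:
        cohort = read_cohort(config.input_csv)
    eligible, log = filter_eligible(cohort, config.eligibility)

    model_cfg = load_model_config(config.model_config_path)
    if config.holt_intercept is not None and "holt" in model_cfg:
        intercept = (
            derive_holt_intercept()
            if config.holt_intercept == "derive"
            else float(config.holt_intercept)
        )
        model_cfg["holt"].transform["intercept"] = intercept

    models = [m for m in config.models if m in model_cfg]
    panels: dict[str, list[ScorePanel]] = {m: [] for m in models}
    failures: dict[str, int] = {m: 0 for m in models}
    scored_ids: dict[str, set] = {m: set() for m in models}
    for rec in eligible:
        for m in models:
            try:
                panels[m].append(score_patient(rec, model_cfg[m]))
                scored_ids[m].add(rec.patient_id)
            except Exception:
                failures[m] += 1

    outcomes = {r.patient_id: bool(r.dead_1y) for r in eligible if r.dead_1y is not None}

    reports: dict[str, ValidationReport] = {}
    oriented_scores: dict[str, np.ndarray] = {}
    strata: dict[str, list[StratumResult]] = {}
    # common patient set across models so DeLong comparisons stay paired
    common = set(outcomes)
    for m in models:
        common &= scored_ids[m]
    common_order = [r.patient_id for r in eligible if r.patient_id in common]
    y_common = np.array([outcomes[pid] for pid in common_order], dtype=int)

    for m in models:
        spec = model_cfg[m]
        model_panels = [p for p in panels[m] if p.patient_id in outcomes]
        y = np.array([outcomes[p.patient_id] for p in model_panels], dtype=int)
        raw = np.array([float(p.raw_score) for p in model_panels])
        probs = [p.predicted_prob for p in model_panels]
        reports[m] = build_report(
            m, spec, raw, probs, y,
            threshold=config.threshold,
            hl_groups=config.hl_groups,
            hl_df_style=config.hl_df_style,
        )
        strata[m] = stratum_table(model_panels, outcomes, spec, config.interval_mode)
        by_id = {p.patient_id: float(p.raw_score) for p in panels[m]}
        oriented_scores[m] = spec.orientation * np.array(
            [by_id[pid] for pid in common_order]
        )

    delong_df = None
    if len(models) > 1 and len(common_order) > 0 and 0 < y_common.sum() < len(y_common):
        mat = pd.DataFrame(index=models, columns=models, dtype=float)
        for i, ma in enumerate(models):
            for mb in models[i:]:
                if ma == mb:
                    mat.loc[ma, mb] = 1.0
                    continue
                _, _, _, p = delong_test(oriented_scores[ma], oriented_scores[mb], y_common)
                mat.loc[ma, mb] = p
                mat.loc[mb, ma] = p
        for m in models:
            reports[m].delong_p_vs = {
                other: float(mat.loc[m, other]) for other in models if other != m
            }
        delong_df = mat

    # survival: overall KM and male-vs-female log-rank
    with_fu = [r for r in eligible if not r.lost_to_followup]
    times = [r.followup_months for r in with_fu]
    events = [_observed_death(r) for r in with_fu]
    km = km_estimate(times, events).to_frame()
    logrank = None
    male = [(r.followup_months, _observed_death(r)) for r in with_fu if r.sex == Sex.MALE]
    female = [(r.followup_months, _observed_death(r)) for r in with_fu if r.sex == Sex.FEMALE]
    if male and female:
        logrank = logrank_test(
            [t for t, _ in male], [e for _, e in male],
            [t for t, _ in female], [e for _, e in female],
        )

    panel_rows = [
        {
            "patient_id": p.patient_id,
            "model": p.model,
            "raw_score": str(p.raw_score),
            "predicted_prob": "" if p.predicted_prob is None else f"{p.predicted_prob:.10g}",
            "stratum": p.stratum,
        }
        for m in models
        for p in panels[m]
    ]
    panel_df = pd.DataFrame(panel_rows)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "models": list(models),
        "n_input": len(cohort),
        "n_eligible": len(eligible),
        "exclusions": log,
        "scoring_failures": failures,
        "threshold_rule": str(config.threshold),
        "hl_groups": config.hl_groups,
        "hl_df_style": config.hl_df_style,
        "interval_mode": config.interval_mode,
        "holt_intercept": (
            None if config.holt_intercept is None
            else model_cfg["holt"].transform.get("intercept")
        ),
    }

    result = PipelineResult(
        cohort=eligible,
        exclusion_log=log,
        panels=panel_df,
        reports=reports,
        delong=delong_df,
        strata=strata,
        km_overall=km,
        logrank_by_sex=logrank,
        scoring_failures=failures,
        manifest=manifest,
    )
    _write_bundle(result, out)
    return result


def _observed_death(r) -> bool:
    """KM event flag from the record schema.

    The record stores only the one-year vital status, so deaths beyond 12
    months are indistinguishable from censoring and are treated as censored
    at the end of follow-up.
    """
    return bool(r.dead_1y)


def _report_to_dict(rep: ValidationReport) -> dict:
    d = dataclasses.asdict(rep)
    return d


def _write_bundle(result: PipelineResult, out: Path) -> None:
    result.panels.to_csv(out / "panels.csv", index=False)
    reports_json = {m: _report_to_dict(r) for m, r in result.reports.items()}
    (out / "reports.json").write_text(
        json.dumps(reports_json, indent=2, sort_keys=True, allow_nan=True)
    )
    if result.delong is not None:
        result.delong.to_csv(out / "delong_matrix.tsv", sep="\t")
    render_table3(result.reports).to_csv(out / "table3.tsv", sep="\t", index=False)
    render_table4(result.strata).to_csv(out / "table4.tsv", sep="\t", index=False)
    result.km_overall.to_csv(out / "km_curve.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True)
    )


def _fmt_ci(point: float, ci: tuple[float, float], nd: int = 2) -> str:
    return f"{point:.{nd}f} ({ci[0]:.{nd}f}-{ci[1]:.{nd}f})"


def render_table3(reports: Mapping[str, ValidationReport]) -> pd.DataFrame:
    """Discrimination/calibration summary: AUC (CI), H-L p, slope (CI)."""
    rows = []
    for m, r in reports.items():
        calib = r.calibration
        rows.append(
            {
                "model": m,
                "auc_95ci": _fmt_ci(r.auc, r.auc_ci),
                "auc_oriented_95ci": _fmt_ci(r.auc_oriented, r.auc_oriented_ci),
                "hl_p": "NA" if r.hl_p is None else f"{r.hl_p:.2f}",
                "calibration_slope_95ci": (
                    "NA"
                    if calib is None or calib.slope is None or calib.slope_ci is None
                    else _fmt_ci(calib.slope, calib.slope_ci)
                ),
                "sensitivity": f"{r.confusion.sensitivity:.2f}",
                "specificity": f"{r.confusion.specificity:.2f}",
            }
        )
    return pd.DataFrame(rows)


def render_table4(strata: Mapping[str, list[StratumResult]]) -> pd.DataFrame:
    """Risk-stratification summary: predicted %, n, observed %, accuracy %."""
    rows = []
    for m, tab in strata.items():
        total = sum(s.n for s in tab)
        for s in tab:
            rows.append(
                {
                    "model": m,
                    "stratum": s.label,
                    "predicted_mortality_pct": (
                        "NA" if s.predicted_pct is None else f"{s.predicted_pct:.1f}"
                    ),
                    "n": "None" if s.n == 0 else str(s.n),
                    "n_pct": "None" if s.n == 0 or total == 0 else f"{100 * s.n / total:.1f}",
                    "observed_mortality_pct": (
                        "None" if s.observed_pct is None else f"{s.observed_pct:.1f}"
                    ),
                    "accuracy_pct": (
                        "None" if s.accuracy_pct is None else f"{s.accuracy_pct:.1f}"
                    ),
                }
            )
    return pd.DataFrame(rows)
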