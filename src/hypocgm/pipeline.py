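"""End-to-end orchestration: simulate -> QC -> metrics -> episodes ->
questionnaire scoring -> group comparisons -> report.

The same analysis entry points accept user-supplied CSVs in the
documented schemas, so the simulator is just one possible input source.
The rendered report mirrors the study's summary structure: per C-peptide
group and per threshold (4.0 / 3.0 / 2.2 mmol/l), the proportion of
subjects with at least one episode, the episode rate and the episode
duration per person per week, plus the variability metrics and the
between-group contrasts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import clarke as clarke_mod
from . import episodes as ep_mod
from . import metrics as metrics_mod
from . import qc as qc_mod
from . import stats as stats_mod
from .config import (
    GeneratorConfig,
    config_to_flat,
    default_cgm_config,
    default_questionnaire_config,
)
from .errors import DegenerateInputError, InputError, NonConvergenceError
from .simulate import generate_cohort
from .types import GroupComparison

logger = logging.getLogger(__name__)

ADJUSTMENT_COVARIATES = ("age_years", "male", "hba1c_mmol_mol", "prandial")


@dataclass
class PipelineRun:
    """Provenance record for one pipeline execution."""

    config: dict[str, str]
    seed: int
    mode: str
    stage_seconds: dict[str, float] = field(default_factory=dict)
    manifest: dict[str, str] = field(default_factory=dict)  # file -> sha256
    warnings: list[str] = field(default_factory=list)
    report: dict = field(default_factory=dict)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _comparison_row(c: GroupComparison) -> dict:
    return {
        "outcome": c.outcome,
        "contrast": c.contrast,
        "effect_type": c.effect_type,
        "estimate": c.estimate,
        "ci_low": c.ci_low,
        "ci_high": c.ci_high,
        "p_value": c.p_value,
        "adjusted_for": ";".join(c.adjusted_for),
        "method": c.method,
        "flags": ";".join(c.flags),
    }


# ---------------------------------------------------------------------------
# CGM-study analysis
# ---------------------------------------------------------------------------

def analyze_cgm(subjects, traces, smbg, group_order: Optional[list[str]] = None):
    """QC, metrics, episode summaries and group contrasts for a CGM cohort.

    ``group_order`` names the index (low C-peptide) group first; defaults
    to order of first appearance among subjects.
    """
    if group_order is None:
        group_order = list(dict.fromkeys(s.group for s in subjects))
    warnings: list[str] = []

    qc_reports, metric_rows, summary_rows, episode_rows = {}, [], [], []
    per_subject = {}
    for subj in subjects:
        if subj.subject_id not in traces:
            raise InputError(f"no CGM trace for subject {subj.subject_id}")
        rep = qc_mod.apply_qc(traces[subj.subject_id],
                              smbg.get(subj.subject_id, []))
        qc_reports[subj.subject_id] = rep
        if rep.excluded:
            warnings.append(f"{subj.subject_id}: excluded (<24 h retained)")
            continue
        mset = metrics_mod.compute_metrics(subj.subject_id, rep.segments)
        summary = ep_mod.analyze_subject(rep.segments, rep.retained_hours)
        per_subject[subj.subject_id] = (subj, mset, summary)
        metric_rows.append(
            {
                "subject_id": subj.subject_id,
                "group": subj.group,
                "mean_glucose": mset.mean_glucose,
                "sd_glucose": mset.sd_glucose,
                "mage": mset.mage,
                "lbgi": mset.lbgi,
                "hours_of_data": mset.hours_of_data,
            }
        )
        for thr in ep_mod.THRESHOLDS:
            ts = summary.by_threshold[thr]
            summary_rows.append(
                {
                    "subject_id": subj.subject_id,
                    "group": subj.group,
                    "threshold": thr,
                    "n_episodes": ts.n_episodes,
                    "rate_per_week": ts.rate_per_week,
                    "duration_min_per_week": ts.duration_min_per_week,
                    "day_rate_per_week": ts.day_rate_per_week,
                    "night_rate_per_week": ts.night_rate_per_week,
                    "exposure_weeks": summary.exposure_weeks,
                }
            )
            for ep in ep_mod.detect_episodes(rep.segments, thr):
                episode_rows.append(
                    {
                        "subject_id": subj.subject_id,
                        "group": subj.group,
                        "threshold": thr,
                        "start": ep.start,
                        "end": ep.end,
                        "duration_min": ep.duration_min,
                        "nadir": ep.nadir,
                        "period": ep.period,
                    }
                )

    metrics_df = pd.DataFrame(metric_rows)
    summary_df = pd.DataFrame(summary_rows)
    episodes_df = pd.DataFrame(episode_rows)
    qc_df = (
        pd.concat([r.to_frame() for r in qc_reports.values()], ignore_index=True)
        if qc_reports
        else pd.DataFrame()
    )

    # -- group summaries -----------------------------------------------------
    group_summary = []
    for g in group_order:
        gm = metrics_df[metrics_df["group"] == g] if not metrics_df.empty else metrics_df
        for thr in ep_mod.THRESHOLDS:
            gs = summary_df[
                (summary_df["group"] == g) & (summary_df["threshold"] == thr)
            ]
            n = len(gs)
            total_events = int(gs["n_episodes"].sum()) if n else 0
            total_weeks = float(gs["exposure_weeks"].sum()) if n else 0.0
            rate, rlo, rhi = (
                stats_mod.poisson_rate_ci(total_events, total_weeks)
                if total_weeks > 0
                else (float("nan"),) * 3
            )
            group_summary.append(
                {
                    "group": g,
                    "threshold": thr,
                    "n_subjects": n,
                    "prop_with_episode": float((gs["n_episodes"] > 0).mean())
                    if n
                    else float("nan"),
                    "mean_rate_per_week": float(gs["rate_per_week"].mean())
                    if n
                    else float("nan"),
                    "mean_duration_min_per_week": float(
                        gs["duration_min_per_week"].mean()
                    )
                    if n
                    else float("nan"),
                    "pooled_rate_per_week": rate,
                    "pooled_rate_ci_low": rlo,
                    "pooled_rate_ci_high": rhi,
                    "mean_sd_glucose": float(gm["sd_glucose"].mean())
                    if len(gm)
                    else float("nan"),
                    "mean_glucose": float(gm["mean_glucose"].mean())
                    if len(gm)
                    else float("nan"),
                    "mean_lbgi": float(gm["lbgi"].mean()) if len(gm) else float("nan"),
                }
            )
    group_summary_df = pd.DataFrame(group_summary)

    # -- contrasts -----------------------------------------------------------
    comparisons: list[GroupComparison] = []
    if len(group_order) == 2 and not metrics_df.empty:
        g_low, g_high = group_order
        low_ids = [s.subject_id for s in subjects if s.group == g_low]
        high_ids = [s.subject_id for s in subjects if s.group == g_high]

        def _paired(series_name, frame, value_col, outcome):
            lo_v, hi_v = [], []
            for a, b in zip(low_ids, high_ids):
                ra = frame[(frame["subject_id"] == a)]
                rb = frame[(frame["subject_id"] == b)]
                if len(ra) == 1 and len(rb) == 1:
                    va, vb = ra[value_col].iloc[0], rb[value_col].iloc[0]
                    if pd.notna(va) and pd.notna(vb):
                        lo_v.append(va)
                        hi_v.append(vb)
            if len(lo_v) >= 2:
                try:
                    comparisons.append(
                        stats_mod.paired_t(
                            np.asarray(lo_v) - np.asarray(hi_v), outcome=outcome
                        )
                    )
                except DegenerateInputError as exc:
                    warnings.append(f"{outcome}: {exc}")

        _paired("sd", metrics_df, "sd_glucose", "SD of glucose (mmol/l)")
        _paired("mean", metrics_df, "mean_glucose", "mean glucose (mmol/l)")
        _paired("mage", metrics_df, "mage", "MAGE (mmol/l)")
        _paired("lbgi", metrics_df, "lbgi", "LBGI")

        for thr in ep_mod.THRESHOLDS:
            sub = summary_df[summary_df["threshold"] == thr]
            lo = sub[sub["group"] == g_low]
            hi = sub[sub["group"] == g_high]
            _paired(
                "rate",
                sub,
                "rate_per_week",
                f"episode rate <= {thr} mmol/l (per person per week)",
            )
            _paired(
                "dur",
                sub,
                "duration_min_per_week",
                f"hypoglycaemia duration <= {thr} mmol/l (min per person per week)",
            )
            try:
                comparisons.append(
                    stats_mod.chi_square_2x2(
                        int((lo["n_episodes"] > 0).sum()),
                        int((lo["n_episodes"] == 0).sum()),
                        int((hi["n_episodes"] > 0).sum()),
                        int((hi["n_episodes"] == 0).sum()),
                        outcome=f"proportion with >= 1 episode <= {thr} mmol/l",
                    )
                )
            except DegenerateInputError as exc:
                warnings.append(f"proportion at {thr}: {exc}")
            comparisons.append(
                stats_mod.rate_compare(
                    int(lo["n_episodes"].sum()),
                    float(lo["exposure_weeks"].sum()),
                    int(hi["n_episodes"].sum()),
                    float(hi["exposure_weeks"].sum()),
                    outcome=f"episode rate ratio <= {thr} mmol/l",
                )
            )

    comparisons_df = pd.DataFrame([_comparison_row(c) for c in comparisons])
    return {
        "qc": qc_df,
        "metrics": metrics_df,
        "episodes": episodes_df,
        "hypo_summary": summary_df,
        "group_summary": group_summary_df,
        "comparisons": comparisons_df,
        "warnings": warnings,
        "qc_reports": qc_reports,
    }


# ---------------------------------------------------------------------------
# Questionnaire-study analysis
# ---------------------------------------------------------------------------

def analyze_questionnaire(subjects, responses,
                          group_order: Optional[list[str]] = None):
    """Clarke scoring, recoded monthly rates and group contrasts."""
    if group_order is None:
        group_order = list(dict.fromkeys(s.group for s in subjects))
    warnings: list[str] = []
    by_id = {s.subject_id: s for s in subjects}

    rows = []
    for resp in responses:
        if resp.subject_id not in by_id:
            raise InputError(f"questionnaire for unknown subject {resp.subject_id}")
        subj = by_id[resp.subject_id]
        res = clarke_mod.score_clarke(resp)
        rows.append(
            {
                "subject_id": res.subject_id,
                "group": subj.group,
                "score": res.score,
                "reduced_awareness": res.reduced_awareness,
                "q5_rate_per_month": res.q5_rate_per_month,
                "q6_rate_per_month": res.q6_rate_per_month,
                "q3_any_assistance": res.q3_any_assistance,
                "q4_any_unconscious": res.q4_any_unconscious,
                "age_years": subj.age_years,
                "male": 1 if subj.sex == "M" else 0,
                "hba1c_mmol_mol": subj.hba1c_mmol_mol,
                "prandial": 1 if subj.prandial_insulin else 0,
                "group_low": 1 if subj.group == group_order[0] else 0,
            }
        )
    scored_df = pd.DataFrame(rows)

    group_summary = []
    for g in group_order:
        gd = scored_df[scored_df["group"] == g]
        n = len(gd)
        row = {"group": g, "n_subjects": n}
        for q in ("q5", "q6"):
            events = int(gd[f"{q}_rate_per_month"].sum())
            rate, lo, hi = (
                stats_mod.poisson_rate_ci(events, n)
                if n
                else (float("nan"),) * 3
            )
            row[f"{q}_rate_per_month"] = rate
            row[f"{q}_rate_ci_low"] = lo
            row[f"{q}_rate_ci_high"] = hi
        row["prop_reduced_awareness"] = (
            float(gd["reduced_awareness"].mean()) if n else float("nan")
        )
        row["prop_q3_any"] = float(gd["q3_any_assistance"].mean()) if n else float("nan")
        row["prop_q4_any"] = float(gd["q4_any_unconscious"].mean()) if n else float("nan")
        group_summary.append(row)
    group_summary_df = pd.DataFrame(group_summary)

    comparisons: list[GroupComparison] = []
    if len(group_order) == 2 and len(scored_df):
        g_low, g_high = group_order
        lo = scored_df[scored_df["group"] == g_low]
        hi = scored_df[scored_df["group"] == g_high]
        for q, label in (("q5", "symptomatic"), ("q6", "asymptomatic")):
            c = stats_mod.rate_compare(
                int(lo[f"{q}_rate_per_month"].sum()),
                len(lo),
                int(hi[f"{q}_rate_per_month"].sum()),
                len(hi),
                outcome=f"self-reported {label} hypoglycaemia "
                f"(episodes per person per month)",
            )
            comparisons.append(c)
            if c.flags and "unbounded" in c.flags[0]:
                warnings.append(f"{q}: rate ratio undefined (zero events)")
        for col, outcome in (
            ("reduced_awareness", "reduced awareness (Clarke score >= 4)"),
            ("q3_any_assistance", "any episode needing assistance"),
            ("q4_any_unconscious", "any unconsciousness/seizure episode"),
        ):
            try:
                comparisons.append(
                    stats_mod.chi_square_2x2(
                        int(lo[col].sum()),
                        int((~lo[col].astype(bool)).sum()),
                        int(hi[col].sum()),
                        int((~hi[col].astype(bool)).sum()),
                        outcome=outcome,
                    )
                )
            except DegenerateInputError as exc:
                warnings.append(f"{outcome}: {exc}")

        scored_df["exposure_months"] = 1.0
        scored_df["q56_events"] = (
            scored_df["q5_rate_per_month"] + scored_df["q6_rate_per_month"]
        )
        adj_specs = [
            ("q56_events", "count", "self-reported hypoglycaemia rate"),
            ("q4_any_unconscious", "binary", "any unconsciousness/seizure episode"),
            ("reduced_awareness", "binary", "reduced awareness (Clarke score >= 4)"),
        ]
        for col, kind, outcome in adj_specs:
            for covs in ((), ADJUSTMENT_COVARIATES):
                try:
                    df = scored_df.copy()
                    df[col] = df[col].astype(float)
                    c = stats_mod.adjusted_models(
                        df,
                        col,
                        kind,
                        group_col="group_low",
                        covariates=covs,
                        exposure_col="exposure_months" if kind == "count" else None,
                    )
                    c = dataclasses.replace(c, outcome=outcome)
                    comparisons.append(c)
                except (NonConvergenceError, DegenerateInputError) as exc:
                    warnings.append(f"{outcome} ({kind}, adj={bool(covs)}): {exc}")

    comparisons_df = pd.DataFrame([_comparison_row(c) for c in comparisons])
    return {
        "clarke_scored": scored_df,
        "group_summary": group_summary_df,
        "comparisons": comparisons_df,
        "warnings": warnings,
    }


# ---------------------------------------------------------------------------
# Report rendering and the full pipeline
# ---------------------------------------------------------------------------

def _round_floats(obj, nd=4):
    if isinstance(obj, float):
        return round(obj, nd) if np.isfinite(obj) else None
    if isinstance(obj, dict):
        return {k: _round_floats(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, nd) for v in obj]
    return obj


def render_text_report(report: dict) -> str:
    """Plain-text rendering of the group summaries and contrasts."""
    lines = []
    if "cgm" in report:
        gs = report["cgm"]["group_summary"]
        lines.append("CGM study: hypoglycaemia by C-peptide group")
        lines.append("=" * 60)
        for panel, col, fmt in (
            ("Proportion with >= 1 episode", "prop_with_episode", "{:.0%}"),
            ("Rate (episodes/person/week)", "mean_rate_per_week", "{:.2f}"),
            ("Duration (min/person/week)", "mean_duration_min_per_week", "{:.0f}"),
        ):
            lines.append(f"\n{panel}:")
            for row in gs:
                if row[col] is None:
                    continue
                lines.append(
                    f"  {row['group']:>6}  <= {row['threshold']:.1f} mmol/l : "
                    + fmt.format(row[col])
                )
        lines.append("\nVariability (group means): ")
        seen = set()
        for row in gs:
            if row["group"] in seen:
                continue
            seen.add(row["group"])
            lines.append(
                f"  {row['group']:>6}  mean {row['mean_glucose']} mmol/l, "
                f"SD {row['mean_sd_glucose']} mmol/l, LBGI {row['mean_lbgi']}"
            )
    if "questionnaire" in report:
        gs = report["questionnaire"]["group_summary"]
        lines.append("\nQuestionnaire study: self-reported hypoglycaemia")
        lines.append("=" * 60)
        for row in gs:
            lines.append(
                f"  {row['group']:>6} (n={row['n_subjects']}): "
                f"Q5 {row['q5_rate_per_month']}/month, "
                f"Q6 {row['q6_rate_per_month']}/month, "
                f"reduced awareness {row['prop_reduced_awareness']}"
            )
    for section in report.values():
        comps = section.get("comparisons", [])
        if comps:
            lines.append("\nContrasts:")
            for c in comps:
                p = c["p_value"]
                lines.append(
                    f"  {c['outcome']}: {c['effect_type']} "
                    f"{c['estimate']} ({c['ci_low']}, {c['ci_high']})"
                    + (f", p={p}" if p is not None else "")
                    + (" [adjusted]" if c["adjusted_for"] else "")
                )
    return "\n".join(lines) + "\n"


def run_pipeline(
    config: Optional[GeneratorConfig] = None,
    mode: str = "cgm-study",
    out_dir: str = "hypocgm_out",
    seed: Optional[int] = None,
) -> PipelineRun:
    """Simulate the configured cohort(s), run the full analysis, and write
    the CSV outputs plus a JSON + text report to ``out_dir``.

    The report files are a pure function of (config, seed): timings live
    only on the returned :class:`PipelineRun`.
    """
    if mode not in ("cgm-study", "questionnaire-study", "both"):
        raise InputError(f"unknown mode {mode!r}")
    os.makedirs(out_dir, exist_ok=True)

    run_modes = ["cgm-study", "questionnaire-study"] if mode == "both" else [mode]
    report: dict = {}
    run = PipelineRun(config={}, seed=-1, mode=mode)

    for m in run_modes:
        if config is not None:
            cfg = dataclasses.replace(
                config, study="cgm" if m == "cgm-study" else "questionnaire"
            )
        elif m == "cgm-study":
            cfg = default_cgm_config(seed if seed is not None else 0)
        else:
            cfg = default_questionnaire_config(seed if seed is not None else 0)
        if seed is not None:
            cfg = dataclasses.replace(cfg, seed=seed)
        cfg.validate()
        run.config.update(
            {f"{m}.{k}": v for k, v in config_to_flat(cfg).items()}
        )
        run.seed = cfg.seed

        sub_dir = os.path.join(out_dir, m.replace("-study", ""))
        t0 = time.perf_counter()
        cohort = generate_cohort(cfg)
        manifest = cohort.write(sub_dir)
        run.stage_seconds[f"{m}.simulate"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        group_order = [g.label for g in cfg.groups]
        if m == "cgm-study":
            res = analyze_cgm(cohort.subjects, cohort.traces, cohort.smbg,
                              group_order)
            for name, key in (
                ("qc_report.csv", "qc"),
                ("metrics.csv", "metrics"),
                ("episodes.csv", "episodes"),
                ("hypo_summary.csv", "hypo_summary"),
                ("comparisons.csv", "comparisons"),
            ):
                path = os.path.join(sub_dir, name)
                res[key].to_csv(path, index=False)
                manifest[name] = path
            report["cgm"] = {
                "group_summary": _round_floats(
                    res["group_summary"].to_dict(orient="records")
                ),
                "comparisons": _round_floats(
                    res["comparisons"].to_dict(orient="records")
                ),
            }
        else:
            res = analyze_questionnaire(cohort.subjects, cohort.clarke,
                                        group_order)
            for name, key in (
                ("clarke_scored.csv", "clarke_scored"),
                ("comparisons.csv", "comparisons"),
            ):
                path = os.path.join(sub_dir, name)
                res[key].to_csv(path, index=False)
                manifest[name] = path
            report["questionnaire"] = {
                "group_summary": _round_floats(
                    res["group_summary"].to_dict(orient="records")
                ),
                "comparisons": _round_floats(
                    res["comparisons"].to_dict(orient="records")
                ),
            }
        run.warnings.extend(res["warnings"])
        run.stage_seconds[f"{m}.analyze"] = time.perf_counter() - t0
        for name, path in manifest.items():
            run.manifest[f"{m}/{name}"] = _sha256(path)

    report_path = os.path.join(out_dir, "report.json")
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, allow_nan=False)
        fh.write("\n")
    text_path = os.path.join(out_dir, "report.txt")
    with open(text_path, "w") as fh:
        fh.write(render_text_report(report))
    run.manifest["report.json"] = _sha256(report_path)
    run.manifest["report.txt"] = _sha256(text_path)
    run.report = report
    return run
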