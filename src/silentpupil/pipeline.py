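"""Top-level study analysis over participant-mean trace tables.

Takes the eight (group × stimulus) trace tables, extracts the four response
parameters per participant, and reproduces the study's statistical layout:
Welch group comparisons per parameter with a Bonferroni family of four per
stimulus, paired melanopsin-vs-cone comparisons, PIPR at 6 s post offset
and at the timepoint of maximal group difference, ROC diagnostic accuracy
for every candidate marker, and (when clinical covariates are supplied)
Spearman correlations within the glaucoma group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import stats as st
from .io import AnalysisConfig, TraceTable
from .metrics import (
    GroupCurve,
    compute_pipr,
    extract_metrics,
    max_group_difference_time,
)
from .preprocess import CleanTrial

__all__ = [
    "AnalysisBundle",
    "run_full_analysis",
    "trace_to_clean_trial",
    "cohort_to_trace_tables",
    "default_trace_grid",
]

PARAMETERS = ("a", "b", "c", "d")
PARAM_FIELD = {
    "a": "time_to_max_constriction_ms",
    "b": "diameter_at_max_constriction_pct",
    "c": "redilation_rate_pct_per_s",
    "d": "diameter_6s_post_offset_pct",
}
GROUPS = ("glaucoma", "control")


@dataclass
class AnalysisBundle:
    participant_metrics: pd.DataFrame
    group_comparisons: pd.DataFrame
    paired_comparisons: pd.DataFrame
    roc: pd.DataFrame
    pipr: pd.DataFrame
    pipr_participants: pd.DataFrame
    max_difference_time_post_offset_s: float | None
    correlations: pd.DataFrame | None
    warnings: list[str] = field(default_factory=list)


def trace_to_clean_trial(table: TraceTable, participant: str,
                         pulse_duration_s: float = 3.0) -> CleanTrial:
    """View one participant column as a cleaned trial (NaN samples dropped)."""
    y = table.trace(participant)
    ok = np.isfinite(y)
    return CleanTrial(time_s=table.time_s[ok], diameter_pct=y[ok],
                      mask_fraction=float(1.0 - ok.mean()),
                      pulse_duration_s=pulse_duration_s)


def default_trace_grid(fs_hz: float = 120.0, start_s: float = -1.0,
                       end_s: float = 18.0) -> np.ndarray:
    """Common onset-aligned time grid for participant-mean traces."""
    n = int(round((end_s - start_s) * fs_hz)) + 1
    return start_s + np.arange(n) / fs_hz


def cohort_to_trace_tables(dataset, config: AnalysisConfig | None = None,
                           grid: np.ndarray | None = None,
                           ) -> dict[tuple[str, str], TraceTable]:
    """Preprocess a simulated cohort into participant-mean trace tables.

    Each raw trial is cleaned (mask → interpolate → smooth → normalize),
    aligned to pulse onset, linearly resampled onto the common grid, and
    averaged within participant; excluded trials are simply dropped.
    Participants with no usable trials for a stimulus become
    non-contributor (all-NA) columns.
    """
    from .preprocess import TrialExcluded, preprocess_trial
    from .synthetic import STIMULI

    if config is None:
        config = AnalysisConfig()
    if grid is None:
        grid = default_trace_grid(config.sampling_rate_hz)

    mean_trace: dict[tuple[str, str], np.ndarray] = {}
    for (pid, stim), recs in dataset.recordings.items():
        traces = []
        for raw in recs:
            try:
                trial = preprocess_trial(
                    raw, fs=config.sampling_rate_hz,
                    exclude_mask_fraction=config.exclude_mask_fraction,
                    sd_limit=config.derivative_sd_limit,
                    confidence_threshold=config.confidence_threshold)
            except TrialExcluded:
                continue
            traces.append(np.interp(grid, trial.time_s, trial.diameter_pct))
        if traces:
            mean_trace[(pid, stim)] = np.mean(np.stack(traces), axis=0)

    tables: dict[tuple[str, str], TraceTable] = {}
    for group in GROUPS:
        pids = dataset.participants(group)
        for stim in STIMULI:
            cols = {}
            non_contrib = []
            for pid in pids:
                tr = mean_trace.get((pid, stim))
                if tr is None:
                    non_contrib.append(pid)
                else:
                    cols[pid] = tr
            if not cols:
                continue
            tables[(group, stim)] = TraceTable(
                time_s=grid, traces=pd.DataFrame(cols),
                non_contributors=tuple(non_contrib),
                group=group, stimulus=stim)
    return tables


def _metrics_frame(tables: Mapping[tuple[str, str], TraceTable],
                   config: AnalysisConfig, warnings: list[str]) -> pd.DataFrame:
    rows = []
    for (group, stim), table in tables.items():
        for pid in table.participants:
            trial = trace_to_clean_trial(table, pid, config.pulse_duration_s)
            try:
                m = extract_metrics(trial, config.pulse_duration_s,
                                    config.pipr_t_post_offset_s)
            except ValueError as exc:
                warnings.append(f"{group}/{stim}/{pid}: {exc}")
                continue
            rows.append({
                "participant": pid, "group": group, "stimulus": stim,
                "a": m.time_to_max_constriction_ms,
                "b": m.diameter_at_max_constriction_pct,
                "c": m.redilation_rate_pct_per_s,
                "d": m.diameter_6s_post_offset_pct})
    return pd.DataFrame(rows)


def _group_comparisons(metrics: pd.DataFrame, stimuli: list[str],
                       config: AnalysisConfig) -> pd.DataFrame:
    rows = []
    for stim in stimuli:
        sub = metrics[metrics["stimulus"] == stim]
        pvals = {}
        for param in PARAMETERS:
            g = sub.loc[sub["group"] == "glaucoma", param].dropna().to_numpy()
            c = sub.loc[sub["group"] == "control", param].dropna().to_numpy()
            if g.size < 2 or c.size < 2:
                continue
            res = st.welch_t(g, c)
            pvals[param] = res.p_value
            rows.append({
                "stimulus": stim, "parameter": param,
                "glaucoma_mean": res.mean_a,
                "glaucoma_ci_low": res.ci_a[0], "glaucoma_ci_high": res.ci_a[1],
                "control_mean": res.mean_b,
                "control_ci_low": res.ci_b[0], "control_ci_high": res.ci_b[1],
                "t": res.statistic, "df": res.df, "p": res.p_value})
        decisions = st.bonferroni([pvals[p] for p in pvals],
                                  family_size=config.bonferroni_family)
        for row, sig in zip(rows[-len(pvals):], decisions):
            row["significant_bonferroni"] = sig
    return pd.DataFrame(rows)


def _paired_comparisons(metrics: pd.DataFrame) -> pd.DataFrame:
    mel = metrics[metrics["stimulus"] == "Melanopsin"].set_index("participant")
    lms = metrics[metrics["stimulus"] == "LMS"].set_index("participant")
    common = mel.index.intersection(lms.index)
    rows = []
    for param in PARAMETERS:
        a = mel.loc[common, param].astype(float)
        b = lms.loc[common, param].astype(float)
        ok = a.notna() & b.notna()
        if ok.sum() < 2:
            continue
        res = st.paired_t(a[ok].to_numpy(), b[ok].to_numpy())
        rows.append({"parameter": param, "n_pairs": int(ok.sum()),
                     "mean_paired_difference": res.mean_difference,
                     "t": res.statistic, "p": res.p_value})
    return pd.DataFrame(rows)


def _pipr_analysis(tables: Mapping[tuple[str, str], TraceTable],
                   config: AnalysisConfig, warnings: list[str],
                   ) -> tuple[pd.DataFrame, float | None, pd.DataFrame]:
    have = all((g, s) in tables for g in GROUPS for s in ("Red", "Blue"))
    if not have:
        warnings.append("red/blue trace tables missing: PIPR analysis skipped")
        return pd.DataFrame(), None, pd.DataFrame()

    # per-group PIPR curves (red − blue) on the shared grid
    curves = {}
    per_part: dict[str, dict[str, np.ndarray]] = {g: {} for g in GROUPS}
    grid = tables[("glaucoma", "Red")].time_s
    for group in GROUPS:
        red_t, blue_t = tables[(group, "Red")], tables[(group, "Blue")]
        if not (np.array_equal(red_t.time_s, grid)
                and np.array_equal(blue_t.time_s, grid)):
            raise ValueError("red/blue trace tables must share a time grid")
        both = [p for p in red_t.participants if p in blue_t.participants]
        traces = []
        for pid in both:
            diff = red_t.trace(pid) - blue_t.trace(pid)
            per_part[group][pid] = diff
            traces.append(diff)
        curves[group] = GroupCurve(grid, np.array(traces), group)

    window = config.pipr_search_window_s
    t_max = max_group_difference_time(curves["control"], curves["glaucoma"],
                                      window, config.pulse_duration_s)

    rows = []
    for label, t_post in (("6s", config.pipr_t_post_offset_s),
                          ("max_difference", t_max)):
        t_eval = config.pulse_duration_s + t_post
        vals = {g: np.array([np.interp(t_eval, grid, tr)
                             for tr in per_part[g].values()])
                for g in GROUPS}
        res = st.welch_t(vals["glaucoma"], vals["control"])
        roc = st.roc_auc(np.concatenate([vals["glaucoma"], vals["control"]]),
                         np.concatenate([np.ones(vals["glaucoma"].size, int),
                                         np.zeros(vals["control"].size, int)]))
        rows.append({
            "timepoint": label, "t_post_offset_s": t_post,
            "glaucoma_mean": res.mean_a,
            "glaucoma_ci_low": res.ci_a[0], "glaucoma_ci_high": res.ci_a[1],
            "control_mean": res.mean_b,
            "control_ci_low": res.ci_b[0], "control_ci_high": res.ci_b[1],
            "p": res.p_value, "auc": roc.auc,
            "auc_ci_low": roc.ci_lower, "auc_ci_high": roc.ci_upper})

    pipr_parts = []
    for group in GROUPS:
        for pid, tr in per_part[group].items():
            pipr_parts.append({
                "participant": pid, "group": group,
                "pipr_6s": float(np.interp(
                    config.pulse_duration_s + config.pipr_t_post_offset_s,
                    grid, tr))})
    return pd.DataFrame(rows), t_max, pd.DataFrame(pipr_parts)


def _roc_frame(metrics: pd.DataFrame, stimuli: list[str]) -> pd.DataFrame:
    rows = []
    for stim in stimuli:
        sub = metrics[metrics["stimulus"] == stim]
        for param in PARAMETERS:
            ok = sub[param].notna()
            scores = sub.loc[ok, param].to_numpy(dtype=float)
            labels = (sub.loc[ok, "group"] == "glaucoma").to_numpy(int)
            if len(np.unique(labels)) < 2:
                continue
            r = st.roc_auc(scores, labels)
            rows.append({"stimulus": stim, "parameter": param, "auc": r.auc,
                         "ci_low": r.ci_lower, "ci_high": r.ci_upper})
    return pd.DataFrame(rows)


def _correlations(metrics: pd.DataFrame, clinical: pd.DataFrame,
                  stimuli: list[str], warnings: list[str]) -> pd.DataFrame:
    clin = clinical.set_index("participant")
    covars = [c for c in ("md_db", "psd_db", "cprnfl_um") if c in clin.columns]
    rows = []
    for stim in stimuli:
        sub = metrics[(metrics["stimulus"] == stim)
                      & (metrics["group"] == "glaucoma")].set_index("participant")
        common = sub.index.intersection(clin.index)
        for param in PARAMETERS:
            for cov in covars:
                x = sub.loc[common, param].astype(float)
                y = clin.loc[common, cov].astype(float)
                ok = x.notna() & y.notna()
                if ok.sum() < 4:
                    warnings.append(f"{stim}/{param} vs {cov}: n < 4, skipped")
                    continue
                res = st.spearman(x[ok].to_numpy(), y[ok].to_numpy())
                rows.append({"stimulus": stim, "parameter": param,
                             "covariate": cov, "rho": res.rho,
                             "p": res.p_value, "n": res.n})
    return pd.DataFrame(rows)


def run_full_analysis(trace_tables: Mapping[tuple[str, str], TraceTable],
                      clinical_table: pd.DataFrame | None = None,
                      config: AnalysisConfig | None = None) -> AnalysisBundle:
    """Run the complete statistical analysis over trace tables.

    ``trace_tables`` maps ``(group, stimulus)`` — groups ``glaucoma`` /
    ``control``, stimuli ``Melanopsin`` / ``LMS`` / ``Red`` / ``Blue`` — to
    participant-mean trace tables.  Missing stimuli yield a partial bundle
    with warnings rather than an error.
    """
    if config is None:
        config = AnalysisConfig()
    warnings: list[str] = []

    metrics = _metrics_frame(trace_tables, config, warnings)
    ss_stimuli = [s for s in ("Melanopsin", "LMS")
                  if not metrics.empty
                  and s in set(metrics.get("stimulus", pd.Series(dtype=str)))]

    group_cmp = (_group_comparisons(metrics, ss_stimuli, config)
                 if ss_stimuli else pd.DataFrame())
    paired = (_paired_comparisons(metrics)
              if set(ss_stimuli) == {"Melanopsin", "LMS"} else pd.DataFrame())
    if len(ss_stimuli) < 2:
        warnings.append("need both Melanopsin and LMS tables for paired tests")

    pipr_summary, t_max, pipr_parts = _pipr_analysis(trace_tables, config,
                                                     warnings)

    roc = _roc_frame(metrics, ss_stimuli) if ss_stimuli else pd.DataFrame()

    correlations = None
    if clinical_table is not None and not metrics.empty:
        correlations = _correlations(metrics, clinical_table, ss_stimuli,
                                     warnings)

    return AnalysisBundle(
        participant_metrics=metrics,
        group_comparisons=group_cmp,
        paired_comparisons=paired,
        roc=roc,
        pipr=pipr_summary,
        pipr_participants=pipr_parts,
        max_difference_time_post_offset_s=t_max,
        correlations=correlations,
        warnings=warnings)
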