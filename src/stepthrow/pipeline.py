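"""End-to-end orchestration: generate -> kinematics -> events -> modulation -> stats.

The pipeline reflects every trial to a canonical right-sided step, derives
CoM kinematics and gait events, fits per-subject constant-central jerk
envelopes, measures modulation latencies of jump trials, and runs the
group statistics (foot-placement accuracy, CoM-velocity coupling, duration
and latency ANOVAs).  ``run_all`` writes all artifacts plus a manifest
that makes every number in the report re-derivable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig, GeneratorParams, config_snapshot
from .core import JUMP_TARGETS, Trial, reflect_to_right
from .events import EventSet, detect_events
from .kinematics import ComKinematics, com_velocity, compute_kinematics
from .modulation import (align_trials, cohort_modulation_summary,
                         modulation_latency, reference_ellipses)
from .mvstats import (bonferroni, hotelling_one_sample, mardia_tests,
                      pair_within_subject, rm_anova_one_way)
from .synth import iter_cohort

__all__ = ["TrialAnalysis", "analyze_trial", "analyze_cohort", "run_all",
           "CohortResult", "LATENCY_BIN_MS"]

#: histogram bin width for the modulation-latency distribution [ms]
LATENCY_BIN_MS = 20.0


@dataclass
class TrialAnalysis:
    """Per-trial analysis products (right-normalized)."""

    trial_id: str
    subject_id: str
    side: str
    condition: str
    initial_target: str
    final_target: str
    events: EventSet
    v_lift: np.ndarray | None          # (2,) CoM velocity at foot lift [m/s]
    final_minus_ideal: np.ndarray | None
    jerk_time: np.ndarray | None = None
    jerk: np.ndarray | None = None     # (n, 2) retained for modulation analysis


def analyze_trial(trial: Trial, cfg: AnalysisConfig, keep_jerk: bool = True
                  ) -> TrialAnalysis:
    """Kinematics + events for one trial (any side; reflected internally)."""
    rt = reflect_to_right(trial)
    kin = compute_kinematics(rt, cfg)
    ev = detect_events(rt, kin, cfg)

    v_lift = None
    delta = None
    if ev.initiation is not None and ev.foot_lift is not None:
        _, _, v_lift = com_velocity(kin.acc[:, :2], kin.time, ev.initiation, ev.foot_lift)
    if ev.final_foot_position is not None:
        delta = ev.final_foot_position - np.asarray(rt.ideal_foot_position)

    return TrialAnalysis(
        trial_id=trial.trial_id, subject_id=trial.subject.subject_id,
        side=trial.side, condition=trial.condition,
        initial_target=trial.initial_target, final_target=trial.final_target,
        events=ev, v_lift=v_lift, final_minus_ideal=delta,
        jerk_time=kin.time if keep_jerk else None,
        jerk=kin.jerk if keep_jerk else None,
    )


def _events_row(ta: TrialAnalysis) -> dict:
    ev = ta.events
    return {
        "trial_id": ta.trial_id, "subject": ta.subject_id, "side": ta.side,
        "condition": ta.condition, "initial_target": ta.initial_target,
        "final_target": ta.final_target,
        "initiation": ev.initiation, "trigger": ev.trigger, "led_on": ev.led_on,
        "foot_lift": ev.foot_lift, "landing": ev.landing,
        "prestep_duration": ev.prestep_duration, "jump_latency": ev.jump_latency,
        "final_ml": None if ev.final_foot_position is None else float(ev.final_foot_position[0]),
        "final_ap": None if ev.final_foot_position is None else float(ev.final_foot_position[1]),
        "v_lift_ml": None if ta.v_lift is None else float(ta.v_lift[0]),
        "v_lift_ap": None if ta.v_lift is None else float(ta.v_lift[1]),
        "err_ml": None if ta.final_minus_ideal is None else float(ta.final_minus_ideal[0]),
        "err_ap": None if ta.final_minus_ideal is None else float(ta.final_minus_ideal[1]),
        "excluded": ev.excluded, "reason": ev.reason,
    }


@dataclass
class CohortResult:
    events: pd.DataFrame
    modulation: pd.DataFrame
    modulation_summary: dict
    stats: dict = field(default_factory=dict)
    log: list = field(default_factory=list)


def _subject_modulation(analyses: list[TrialAnalysis], cfg: AnalysisConfig) -> list[dict]:
    """Fit the subject's constant-central jerk envelope and measure every
    retained jump trial's divergence latency."""
    refs = [a for a in analyses
            if a.condition == "constant" and a.final_target == "central"
            and not a.events.excluded and a.jerk is not None]
    jumps = [a for a in analyses if a.condition == "jump"
             and not a.events.excluded and a.jerk is not None]
    rows = []
    if len(refs) < 3 or not jumps:
        return rows
    series = [(a.jerk_time, a.jerk) for a in refs + jumps]
    anchors = [a.events.initiation for a in refs + jumps]
    aligned = align_trials(series, anchors, window=(-0.1, np.inf),
                           min_span=cfg.min_modulation_delay)
    ref_set = aligned.data[:len(refs)]
    ell = reference_ellipses(
        type(aligned)(rel_time=aligned.rel_time, data=ref_set, fs=aligned.fs),
        level=cfg.ellipse_level, kind=cfg.ellipse_kind)
    for k, a in enumerate(jumps):
        traj = aligned.data[len(refs) + k]
        led_rel = a.events.led_on - a.events.initiation
        lift_rel = a.events.foot_lift - a.events.initiation
        res = modulation_latency(ell, traj, led_rel, lift_rel, cfg)
        rows.append({
            "trial_id": a.trial_id, "subject": a.subject_id,
            "direction": a.final_target,
            "excluded_outside_at_jump": res.excluded_outside_at_jump,
            "detected": res.detected,
            "detected_before_foot_lift": res.detected_before_foot_lift,
            "latency_ms": res.latency_ms,
        })
    return rows


def analyze_cohort(trial_iter, cfg: AnalysisConfig) -> CohortResult:
    """Analyze an iterable of trials (grouped or not by subject)."""
    by_subject: dict[str, list[TrialAnalysis]] = {}
    for trial in trial_iter:
        ta = analyze_trial(trial, cfg, keep_jerk=True)
        by_subject.setdefault(ta.subject_id, []).append(ta)

    event_rows, mod_rows, log = [], [], []
    for subject_id in sorted(by_subject):
        analyses = by_subject[subject_id]
        event_rows.extend(_events_row(a) for a in analyses)
        mod_rows.extend(_subject_modulation(analyses, cfg))
        n_exc = sum(a.events.excluded for a in analyses)
        if n_exc:
            reasons = pd.Series([a.events.reason for a in analyses
                                 if a.events.excluded]).value_counts().to_dict()
            log.append(f"{subject_id}: {n_exc} trial(s) excluded ({reasons})")

    events = pd.DataFrame(event_rows)
    modulation = pd.DataFrame(
        mod_rows, columns=["trial_id", "subject", "direction",
                           "excluded_outside_at_jump", "detected",
                           "detected_before_foot_lift", "latency_ms"])
    summary = (cohort_modulation_summary(modulation) if len(modulation)
               else {"pooled": {"n_jump_trials": 0}, "per_subject_median_ms": pd.Series(dtype=float),
                     "per_direction_median_ms": pd.Series(dtype=float)})
    result = CohortResult(events=events, modulation=modulation,
                          modulation_summary=summary, log=log)
    result.stats = cohort_statistics(events, modulation, cfg)
    return result


# ---------------------------------------------------------------------------
# group statistics

def _condition_label(row) -> str:
    return f"{row['condition']}-{row['final_target']}"


def _subject_condition_means(events: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    df = events[~events["excluded"].astype(bool)].copy()
    df = df.dropna(subset=cols)
    df["cond"] = df.apply(_condition_label, axis=1)
    return df.groupby(["subject", "cond"])[cols].mean()


def _paired_family(means: pd.DataFrame, conditions: list[str], reference: str,
                   cols: list[str], alpha: float) -> pd.DataFrame:
    """One-sample Hotelling tests of per-subject (condition - reference)
    means against zero, Bonferroni-corrected within the family."""
    wide = means.reset_index().pivot(index="subject", columns="cond", values=cols)
    rows = []
    usable = [c for c in conditions if c in {c2 for _, c2 in wide.columns}]
    if reference not in usable:
        return pd.DataFrame(rows)
    values = {}
    for cond in usable:
        block = wide.loc[:, [(col, cond) for col in cols]].to_numpy(float)
        values[cond] = block
    complete = ~np.any([np.isnan(v).any(axis=1) for v in values.values()], axis=0)
    if complete.sum() <= len(cols):
        return pd.DataFrame(rows)
    values = {c: v[complete] for c, v in values.items()}
    diffs = pair_within_subject(values, reference)
    tests = [c for c in usable if c != reference]
    for cond in tests:
        gs = hotelling_one_sample(diffs[cond])
        md = mardia_tests(diffs[cond]) if diffs[cond].shape[0] > 3 else None
        rows.append({
            "comparison": f"{cond} vs {reference}", "n": gs.n,
            "mean_ml": gs.mean[0], "mean_ap": gs.mean[1],
            "t2": gs.t2, "f": gs.f_value, "df1": gs.df[0], "df2": gs.df[1],
            "p": gs.p_value,
            "mardia_skew_p": None if md is None else md.skew_p,
            "mardia_kurt_p": None if md is None else md.kurt_p,
        })
    if rows:
        adj, rej = bonferroni([r["p"] for r in rows], alpha=alpha)
        for r, a_, j in zip(rows, adj, rej):
            r["p_bonferroni"], r["significant"] = a_, bool(j)
    return pd.DataFrame(rows)


def _pairwise_family(means: pd.DataFrame, conditions: list[str], cols: list[str],
                     alpha: float) -> pd.DataFrame:
    """All pairwise Hotelling contrasts within a set of conditions."""
    wide = means.reset_index().pivot(index="subject", columns="cond", values=cols)
    have = {c2 for _, c2 in wide.columns}
    usable = [c for c in conditions if c in have]
    rows = []
    for i, a in enumerate(usable):
        for b in usable[i + 1:]:
            va = wide.loc[:, [(col, a) for col in cols]].to_numpy(float)
            vb = wide.loc[:, [(col, b) for col in cols]].to_numpy(float)
            ok = ~(np.isnan(va).any(axis=1) | np.isnan(vb).any(axis=1))
            if ok.sum() <= len(cols):
                continue
            gs = hotelling_one_sample(va[ok] - vb[ok])
            rows.append({"comparison": f"{a} vs {b}", "n": gs.n,
                         "t2": gs.t2, "f": gs.f_value,
                         "df1": gs.df[0], "df2": gs.df[1], "p": gs.p_value})
    if rows:
        adj, rej = bonferroni([r["p"] for r in rows], alpha=alpha)
        for r, a_, j in zip(rows, adj, rej):
            r["p_bonferroni"], r["significant"] = a_, bool(j)
    return pd.DataFrame(rows)


def _anova_table(events: pd.DataFrame, modulation: pd.DataFrame) -> pd.DataFrame:
    rows = []
    ok = events[~events["excluded"].astype(bool)]

    const = ok[ok["condition"] == "constant"].dropna(subset=["prestep_duration"])
    dur = const.pivot_table(index="subject", columns="final_target",
                            values="prestep_duration", aggfunc="mean")
    if dur.notna().all(axis=None) and dur.shape[0] >= 2 and dur.shape[1] >= 2:
        r = rm_anova_one_way(dur.to_numpy())
        rows.append({"measure": "prestep_duration_by_target", "k": dur.shape[1],
                     "n": dur.shape[0], "f": r.f_value, "df1": r.df[0], "df2": r.df[1],
                     "p": r.p_value, "gg_epsilon": r.epsilon, "p_gg": r.p_corrected})

    det = modulation[modulation["detected"].astype(bool)] if len(modulation) else modulation
    if len(det):
        lat = det.pivot_table(index="subject", columns="direction",
                              values="latency_ms", aggfunc="median")
        if lat.notna().all(axis=None) and lat.shape[0] >= 2 and lat.shape[1] >= 2:
            r = rm_anova_one_way(lat.to_numpy())
            rows.append({"measure": "modulation_latency_by_direction", "k": lat.shape[1],
                         "n": lat.shape[0], "f": r.f_value, "df1": r.df[0], "df2": r.df[1],
                         "p": r.p_value, "gg_epsilon": r.epsilon, "p_gg": r.p_corrected})
    return pd.DataFrame(rows)


def _prolongation_test(events: pd.DataFrame) -> dict | None:
    """Paired contrast of jump vs constant-central pre-step durations."""
    from scipy import stats as sps

    ok = events[~events["excluded"].astype(bool)].dropna(subset=["prestep_duration"])
    cc = ok[(ok["condition"] == "constant") & (ok["final_target"] == "central")]
    jp = ok[ok["condition"] == "jump"]
    a = cc.groupby("subject")["prestep_duration"].mean()
    b = jp.groupby("subject")["prestep_duration"].mean()
    common = a.index.intersection(b.index)
    if len(common) < 3:
        return None
    d = (b[common] - a[common]).to_numpy()
    t, p = sps.ttest_rel(b[common], a[common])
    return {"n": int(len(common)), "mean_prolongation_ms": float(1e3 * d.mean()),
            "sd_ms": float(1e3 * d.std(ddof=1)), "t": float(t), "p": float(p)}


def cohort_statistics(events: pd.DataFrame, modulation: pd.DataFrame,
                      cfg: AnalysisConfig) -> dict:
    """The comparison set of the study: foot-placement accuracy per target,
    paired CoM-velocity contrasts, duration/latency ANOVAs, and the
    modulation-latency histogram (20 ms bins)."""
    stats_out: dict = {}
    const_conds = [f"constant-{t}" for t in ("central",) + JUMP_TARGETS]
    jump_conds = [f"jump-{t}" for t in JUMP_TARGETS]

    stats_out["foot_accuracy"] = accuracy_statistics(events, cfg.alpha)
    stats_out["velocity_vs_central"] = _paired_family(
        _subject_condition_means(events, ["v_lift_ml", "v_lift_ap"]),
        const_conds + jump_conds, "constant-central", ["v_lift_ml", "v_lift_ap"],
        cfg.alpha)
    stats_out["velocity_pairwise_constant"] = _pairwise_family(
        _subject_condition_means(events, ["v_lift_ml", "v_lift_ap"]),
        [f"constant-{t}" for t in JUMP_TARGETS], ["v_lift_ml", "v_lift_ap"], cfg.alpha)
    stats_out["velocity_pairwise_jump"] = _pairwise_family(
        _subject_condition_means(events, ["v_lift_ml", "v_lift_ap"]),
        jump_conds, ["v_lift_ml", "v_lift_ap"], cfg.alpha)
    stats_out["anova"] = _anova_table(events, modulation)
    prol = _prolongation_test(events)
    if prol is not None:
        stats_out["prolongation"] = pd.DataFrame([prol])

    det = modulation[modulation["detected"].astype(bool)] if len(modulation) else modulation
    lat = det["latency_ms"].dropna() if len(det) else pd.Series(dtype=float)
    if len(lat):
        hi = float(np.ceil(lat.max() / LATENCY_BIN_MS) * LATENCY_BIN_MS)
        edges = np.arange(0.0, hi + LATENCY_BIN_MS, LATENCY_BIN_MS)
        counts, edges = np.histogram(lat, bins=edges)
        stats_out["latency_histogram"] = pd.DataFrame(
            {"bin_left_ms": edges[:-1], "bin_right_ms": edges[1:], "count": counts})
    else:
        stats_out["latency_histogram"] = pd.DataFrame(
            columns=["bin_left_ms", "bin_right_ms", "count"])
    return stats_out


# ---------------------------------------------------------------------------
# accuracy family (needs per-trial ideal positions, so computed separately)

def accuracy_statistics(analyses_events: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Hotelling tests of (landed - ideal) foot position against zero, per
    condition, from an events table carrying err_ml/err_ap columns."""
    df = analyses_events[~analyses_events["excluded"].astype(bool)].dropna(
        subset=["err_ml", "err_ap"])
    rows = []
    if not len(df):
        return pd.DataFrame(rows)
    df = df.copy()
    df["cond"] = df.apply(_condition_label, axis=1)
    for cond, grp in df.groupby("cond"):
        per = grp.groupby("subject")[["err_ml", "err_ap"]].mean().to_numpy(float)
        if per.shape[0] <= 2:
            continue
        gs = hotelling_one_sample(per)
        rows.append({"condition": cond, "n": gs.n,
                     "mean_err_ml": gs.mean[0], "mean_err_ap": gs.mean[1],
                     "t2": gs.t2, "f": gs.f_value, "df1": gs.df[0], "df2": gs.df[1],
                     "p": gs.p_value})
    out = pd.DataFrame(rows)
    if len(out):
        adj, rej = bonferroni(out["p"].to_numpy(), alpha=alpha)
        out["p_bonferroni"], out["significant"] = adj, rej
    return out


# ---------------------------------------------------------------------------
# run-all

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(params: GeneratorParams, cfg: AnalysisConfig, out_dir,
            seed: int | None = None) -> dict:
    """Generate a cohort and run the complete analysis, writing
    events.csv, modulation.csv, ground_truth.csv, stats tables, a summary
    and a manifest into ``out_dir``.  Returns the manifest dict."""
    out = Path(out_dir)
    (out / "stats").mkdir(parents=True, exist_ok=True)
    seed = params.seed if seed is None else seed

    gts = []
    def trials():
        for trial, gt in iter_cohort(params, seed=seed, cfg=cfg):
            gts.append(gt)
            yield trial

    result = analyze_cohort(trials(), cfg)
    from .synth import ground_truth_frame
    gt_df = ground_truth_frame(gts)

    files = {}
    def write(name: str, df: pd.DataFrame):
        path = out / name
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, index=False, float_format="%.9g")
        files[name] = _sha256(path)

    write("events.csv", result.events)
    write("modulation.csv", result.modulation)
    write("ground_truth.csv", gt_df)
    for name, df in result.stats.items():
        if isinstance(df, pd.DataFrame):
            write(f"stats/{name}.csv", df)

    summary = _summary_text(result, params)
    (out / "summary.txt").write_text(summary)
    files["summary.txt"] = _sha256(out / "summary.txt")

    manifest = {
        "package_version": __version__,
        "seed": int(seed),
        "config": config_snapshot(cfg, params),
        "files": files,
        "exclusions": result.log,
        "n_trials": int(len(result.events)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def exclusion_summary(events: pd.DataFrame) -> dict:
    """Exclusion bookkeeping: flagged jump trials as counts and as
    percentages of the jump trials and of all trials."""
    n_total = len(events)
    jump = events[events["condition"] == "jump"]
    n_jump = len(jump)
    n_flagged = int(jump["excluded"].astype(bool).sum())
    return {
        "n_trials": int(n_total),
        "n_jump_trials": int(n_jump),
        "n_flagged_jump_trials": n_flagged,
        "pct_of_jump_trials": 100.0 * n_flagged / n_jump if n_jump else 0.0,
        "pct_of_all_trials": 100.0 * n_flagged / n_total if n_total else 0.0,
    }


def _summary_text(result: CohortResult, params: GeneratorParams) -> str:
    ev = result.events
    pooled = result.modulation_summary["pooled"]
    exc = exclusion_summary(ev)
    lines = [
        "stepthrow cohort summary",
        "========================",
        f"subjects: {ev['subject'].nunique()}   trials: {len(ev)}",
        f"jump trials: {(ev['condition'] == 'jump').sum()} "
        f"({100 * (ev['condition'] == 'jump').mean():.1f}%)",
        f"flagged jump trials: {exc['n_flagged_jump_trials']} "
        f"({exc['pct_of_jump_trials']:.1f}% of jump trials, "
        f"{exc['pct_of_all_trials']:.1f}% of all trials)",
        "",
        "modulation (jump trials):",
    ]
    for key, val in pooled.items():
        lines.append(f"  {key}: {val if val is None else round(val, 2) if isinstance(val, float) else val}")
    ok = ev[~ev["excluded"].astype(bool)]
    cc = ok[(ok["condition"] == "constant") & (ok["final_target"] == "central")]
    if len(cc):
        lines += ["", f"constant-central pre-step duration: "
                      f"{1e3 * cc['prestep_duration'].mean():.0f} "
                      f"({1e3 * cc['prestep_duration'].std(ddof=1):.0f}) ms"]
    jl = ok[ok["condition"] == "jump"]["jump_latency"].dropna()
    if len(jl):
        lines.append(f"target-jump latency after initiation: "
                     f"{1e3 * jl.mean():.0f} ({1e3 * jl.std(ddof=1):.0f}) ms")
    if result.log:
        lines += ["", "exclusion log:"] + [f"  {l}" for l in result.log]
    return "\n".join(lines) + "\n"
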