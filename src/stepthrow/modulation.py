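"""Modulation-latency detection from 2-D CoM jerk.

Constant-central reference trials, aligned at pre-step initiation, define a
per-time-point 2-D (ML, AP) jerk envelope: at each aligned sample the
sample mean and covariance across reference trials give an ellipse whose
boundary is a Mahalanobis contour.  A jump trial is said to be *modulated*
at the first time, at least 100 ms after the new target lit up, at which
its jerk leaves the ellipse; trials already outside the ellipse at the
moment of the jump are excluded from latency statistics.

Two ellipse semantics are available:

* ``dispersion`` (default) — a trial-population ellipse whose boundary is
  the chi-square(2) quantile of the configured level; for Gaussian
  reference data a same-law trial lies inside with probability equal to
  the level, pointwise.
* ``prediction`` — the small-sample Hotelling prediction ellipse with an
  F-quantile boundary and (1 + 1/n) inflation.

A *mean-confidence* ellipse (which shrinks with the number of reference
trials) is deliberately not offered here: single trials are tested for
membership, and against a mean-confidence region essentially every trial
would diverge immediately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import AnalysisConfig

__all__ = [
    "AlignedTrials", "EllipseSeries", "ModulationResult",
    "align_trials", "reference_ellipses", "mahalanobis_sq",
    "modulation_latency", "cohort_modulation_summary", "ellipse_boundary_radius_sq",
]


@dataclass
class AlignedTrials:
    """Jerk traces on a common grid with t = 0 at the anchor event."""

    rel_time: np.ndarray  # (T,) seconds relative to the anchor
    data: np.ndarray      # (n_trials, T, 2) ML/AP jerk
    fs: float

    def sample(self, t: float) -> int:
        i = int(round((t - self.rel_time[0]) * self.fs))
        if not 0 <= i < len(self.rel_time):
            raise ValueError(f"time {t:.3f} s outside aligned support "
                             f"[{self.rel_time[0]:.3f}, {self.rel_time[-1]:.3f}] s")
        return i


def align_trials(series: list[tuple[np.ndarray, np.ndarray]], anchors: list[float],
                 window: tuple[float, float] | None = None,
                 min_span: float = 0.0) -> AlignedTrials:
    """Align trials' (time, values) pairs so that t = 0 at each trial's anchor.

    All trials must share one sampling rate.  The common grid is the
    intersection of the trials' supports (optionally further cropped to
    ``window``); shifting a trial's recording clock moves its anchor by the
    same amount and therefore changes nothing after alignment.
    """
    if len(series) == 0:
        raise ValueError("no trials to align")
    if len(series) != len(anchors):
        raise ValueError("series and anchors length mismatch")
    fs = 1.0 / float(np.mean(np.diff(series[0][0])))
    starts, stops = [], []
    shifted = []
    for (time, values), anchor in zip(series, anchors):
        fs_i = 1.0 / float(np.mean(np.diff(time)))
        if abs(fs_i - fs) > 1e-6 * fs:
            raise ValueError(f"sampling-rate mismatch across trials ({fs_i:.6g} vs {fs:.6g} Hz)")
        rel = time - anchor
        starts.append(rel[0])
        stops.append(rel[-1])
        shifted.append((rel, np.asarray(values, dtype=float)))
    lo, hi = max(starts), min(stops)
    if window is not None:
        lo, hi = max(lo, window[0]), min(hi, window[1])
    if hi - lo <= max(min_span, 2.0 / fs):
        raise ValueError(f"aligned overlap [{lo:.3f}, {hi:.3f}] s is empty or "
                         f"shorter than the required {min_span:.3f} s")
    n_t = int(np.floor((hi - lo) * fs)) + 1
    rel_time = lo + np.arange(n_t) / fs
    out = np.empty((len(shifted), n_t, shifted[0][1].shape[1]))
    for k, (rel, values) in enumerate(shifted):
        i0 = int(round((lo - rel[0]) * fs))
        out[k] = values[i0:i0 + n_t]
    return AlignedTrials(rel_time=rel_time, data=out, fs=fs)


def ellipse_boundary_radius_sq(kind: str, level: float, n_ref: int, p: int = 2) -> float:
    """Squared Mahalanobis radius of the ellipse boundary."""
    if kind == "dispersion":
        return float(stats.chi2.ppf(level, p))
    if kind == "prediction":
        f = stats.f.ppf(level, p, n_ref - p)
        return float((1 + 1 / n_ref) * p * (n_ref - 1) / (n_ref - p) * f)
    raise ValueError(f"unknown ellipse kind {kind!r}")


@dataclass
class EllipseSeries:
    """Per-time-point 2-D reference ellipses (mean, covariance, boundary)."""

    rel_time: np.ndarray    # (T,)
    center: np.ndarray      # (T, 2)
    cov: np.ndarray         # (T, 2, 2) symmetric positive-definite
    cov_inv: np.ndarray     # (T, 2, 2)
    level: float
    kind: str
    n_ref: int
    radius_sq: float        # boundary Mahalanobis distance squared
    regularized: np.ndarray  # (T,) bool, True where jitter was added
    fs: float

    def sample(self, t: float) -> int:
        i = int(round((t - self.rel_time[0]) * self.fs))
        if not 0 <= i < len(self.rel_time):
            raise ValueError(f"time {t:.3f} s outside ellipse support")
        return i


def reference_ellipses(aligned: AlignedTrials, level: float = 0.95,
                       kind: str = "dispersion") -> EllipseSeries:
    """Fit the per-time-point reference ellipses from aligned jerk traces.

    Near-singular covariances (e.g. identical reference trials) are
    regularized by an eigenvalue floor and flagged per sample.
    """
    n, n_t, p = aligned.data.shape
    if n < 3:
        raise ValueError(f"need at least 3 reference trials, got {n}")
    center = aligned.data.mean(axis=0)
    dev = aligned.data - center[None]
    cov = np.einsum("ktp,ktq->tpq", dev, dev) / (n - 1)

    scale = np.trace(cov, axis1=1, axis2=2) / p
    floor = 1e-10 * np.maximum(scale, 1e-30)
    w, v = np.linalg.eigh(cov)
    regularized = w[:, 0] < floor
    w = np.maximum(w, floor[:, None])
    cov = np.einsum("tpq,tq,trq->tpr", v, w, v)
    cov_inv = np.einsum("tpq,tq,trq->tpr", v, 1.0 / w, v)

    return EllipseSeries(rel_time=aligned.rel_time.copy(), center=center,
                         cov=cov, cov_inv=cov_inv, level=level, kind=kind,
                         n_ref=n, radius_sq=ellipse_boundary_radius_sq(kind, level, n),
                         regularized=regularized, fs=aligned.fs)


def mahalanobis_sq(ellipses: EllipseSeries, traj: np.ndarray) -> np.ndarray:
    """Per-sample squared Mahalanobis distance of a (T, 2) trajectory from
    the reference centers, in the reference metric."""
    if traj.shape != ellipses.center.shape:
        raise ValueError(f"trajectory shape {traj.shape} does not match the "
                         f"ellipse grid {ellipses.center.shape}")
    d = traj - ellipses.center
    return np.einsum("tp,tpq,tq->t", d, ellipses.cov_inv, d)


def _segments(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive [start, end] index pairs of the True runs in ``mask``."""
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        return []
    splits = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.r_[idx[0], idx[splits + 1]]
    ends = np.r_[idx[splits], idx[-1]]
    return list(zip(starts.tolist(), ends.tolist()))


def _close_gaps(mask: np.ndarray, gap: int) -> np.ndarray:
    """Bridge runs of False shorter than ``gap`` samples that are flanked by
    True on both sides (morphological closing of the outside mask)."""
    if gap <= 0 or not mask.any():
        return mask
    m = mask.copy()
    idx = np.nonzero(~m)[0]
    if len(idx) == 0:
        return m
    splits = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.r_[idx[0], idx[splits + 1]]
    ends = np.r_[idx[splits], idx[-1]]
    for s, e in zip(starts, ends):
        if e - s + 1 <= gap and s > 0 and e < len(m) - 1:
            m[s:e + 1] = True
    return m


@dataclass
class ModulationResult:
    """Outcome of the divergence search for one jump trial."""

    detected: bool
    latency: float | None              # seconds from led-on; None if undetected
    detected_before_foot_lift: bool | None
    excluded_outside_at_jump: bool

    @property
    def latency_ms(self) -> float | None:
        return None if self.latency is None else 1e3 * self.latency


def modulation_latency(ellipses: EllipseSeries, traj: np.ndarray,
                       led_on_rel: float, foot_lift_rel: float,
                       cfg: AnalysisConfig) -> ModulationResult:
    """Latency of a jump trial's first divergence from the reference envelope.

    ``traj`` is the trial's aligned (T, 2) jerk on the ellipse grid;
    ``led_on_rel`` / ``foot_lift_rel`` are event times on the aligned clock
    (t = 0 at the alignment anchor).  A trial outside the ellipse at led-on
    is excluded.  Otherwise the search starts ``min_modulation_delay``
    after led-on; an excursion counts as a divergence when it persists
    ``divergence_persistence`` seconds (returns inside shorter than
    ``divergence_gap_tolerance`` are bridged) and reaches
    ``divergence_confirm_ratio`` times the squared boundary radius within
    the persistence window.  The reported latency is the *start* of the
    qualifying excursion, so the persistence and confirmation requirements
    delay nothing.
    """
    d2 = mahalanobis_sq(ellipses, traj)
    outside = d2 > ellipses.radius_sq
    if outside[ellipses.sample(led_on_rel)]:
        return ModulationResult(detected=False, latency=None,
                                detected_before_foot_lift=None,
                                excluded_outside_at_jump=True)
    # ceil to the grid: a reported latency must never undercut the minimum
    start = int(np.ceil((led_on_rel + cfg.min_modulation_delay
                         - ellipses.rel_time[0]) * ellipses.fs - 1e-9))
    start = int(np.clip(start, 0, len(ellipses.rel_time) - 1))
    per = max(1, int(round(cfg.divergence_persistence * ellipses.fs)))
    gap = int(round(cfg.divergence_gap_tolerance * ellipses.fs))
    confirm = cfg.divergence_confirm_ratio * ellipses.radius_sq
    closed = _close_gaps(outside, gap)

    t_div = None
    for s, e in _segments(closed):  # [s, e] inclusive, outside the envelope
        cand = max(s, start)
        if e - cand + 1 < per:
            continue
        if cfg.divergence_confirm_ratio > 0 and d2[cand:cand + per].max() <= confirm:
            continue
        t_div = float(ellipses.rel_time[cand])
        break
    if t_div is None:
        return ModulationResult(detected=False, latency=None,
                                detected_before_foot_lift=None,
                                excluded_outside_at_jump=False)
    return ModulationResult(detected=True, latency=t_div - led_on_rel,
                            detected_before_foot_lift=bool(t_div < foot_lift_rel),
                            excluded_outside_at_jump=False)


def cohort_modulation_summary(results) -> dict:
    """Pooled, per-subject and per-jump-direction modulation statistics.

    ``results`` is a DataFrame with columns ``subject``, ``direction``,
    ``excluded_outside_at_jump``, ``detected``, ``detected_before_foot_lift``
    and ``latency_ms``.  Excluded trials never contribute to latency
    quantiles; an empty latency set is reported as absent (None).
    """
    import pandas as pd

    df = results
    n = len(df)
    eligible = df[~df["excluded_outside_at_jump"].astype(bool)]
    detected = eligible[eligible["detected"].astype(bool)]
    lat = detected["latency_ms"].dropna()

    def _q(series, q):
        return None if len(series) == 0 else float(np.quantile(series, q))

    pooled = {
        "n_jump_trials": int(n),
        "pct_excluded_at_jump": 100.0 * (n - len(eligible)) / n if n else 0.0,
        "pct_detected": 100.0 * len(detected) / len(eligible) if len(eligible) else 0.0,
        "pct_detected_before_foot_lift": (
            100.0 * detected["detected_before_foot_lift"].astype(bool).mean()
            if len(detected) else 0.0),
        "median_latency_ms": _q(lat, 0.5),
        "iqr_latency_ms": (None if len(lat) == 0
                           else float(np.quantile(lat, 0.75) - np.quantile(lat, 0.25))),
    }
    per_subject = (detected.groupby("subject")["latency_ms"].median()
                   if len(detected) else pd.Series(dtype=float))
    per_direction = (detected.groupby("direction")["latency_ms"].median()
                     if len(detected) else pd.Series(dtype=float))
    return {"pooled": pooled,
            "per_subject_median_ms": per_subject,
            "per_direction_median_ms": per_direction}
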