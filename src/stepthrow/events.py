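"""Gait-event detection and trial-exclusion rules.

Events of a step attempt, all stored as times in seconds:

* **initiation** — first point after target illumination at which the ML
  CoP velocity toward the stepping foot exceeds 5 cm/s at every sample of a
  50 ms window ("exceeds" is read strictly; boundary equality does not
  count).
* **foot lift** — first point after initiation at which the stepping
  plate's vertical force drops below 1% of body weight (quiet-stance summed
  vertical force).
* **landing** — first point after foot lift at which the ML, AP and
  vertical speeds of the stepping-foot hallux marker are simultaneously
  below 2 cm/s (per-axis comparison, not the 3-D speed norm).
* **final foot position** — mean (ML, AP) of the three stepping-foot
  markers at the landing sample.

Jump trials are excluded when the trigger fired at or before initiation or
when led-on fell closer to foot lift than a configurable margin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import AnalysisConfig
from .core import Trial
from .kinematics import ComKinematics, butter_zero_lag, derivative

__all__ = [
    "EventSet", "detect_prestep_initiation", "detect_foot_lift",
    "detect_landing", "final_foot_position", "exclude_jump_trial",
    "detect_events",
]


@dataclass
class EventSet:
    """Detected event times and derived quantities for one trial."""

    initiation: float | None = None
    trigger: float | None = None
    led_on: float | None = None
    foot_lift: float | None = None
    landing: float | None = None
    final_foot_position: np.ndarray | None = None
    excluded: bool = False
    reason: str | None = None

    @property
    def prestep_duration(self) -> float | None:
        if self.initiation is None or self.foot_lift is None:
            return None
        return self.foot_lift - self.initiation

    @property
    def jump_latency(self) -> float | None:
        """Led-on time relative to pre-step initiation."""
        if self.initiation is None or self.led_on is None:
            return None
        return self.led_on - self.initiation

    def ordered(self) -> bool:
        """True when initiation < foot lift < landing all hold."""
        t = (self.initiation, self.foot_lift, self.landing)
        return all(v is not None for v in t) and t[0] < t[1] < t[2]


def _first_sustained(mask: np.ndarray, window: int, start: int) -> int | None:
    """First index >= start at which ``mask`` holds for ``window`` consecutive
    samples (the window must fit inside the series)."""
    if window < 1:
        raise ValueError("window must be >= 1 sample")
    ok = mask.astype(np.int64)
    runs = np.convolve(ok, np.ones(window, dtype=np.int64), mode="valid")
    hits = np.nonzero(runs[start:] == window)[0]
    return None if len(hits) == 0 else int(start + hits[0])


def detect_prestep_initiation(time: np.ndarray, cop_ml_vel: np.ndarray,
                              illumination: float, cfg: AnalysisConfig) -> float | None:
    """Earliest t >= illumination with CoP ML velocity above threshold at
    every sample of [t, t + sustain_window]; None when no step initiates."""
    fs = 1.0 / float(np.mean(np.diff(time)))
    win = max(1, int(round(cfg.sustain_window * fs)))
    start = int(np.searchsorted(time, illumination))
    idx = _first_sustained(cop_ml_vel > cfg.cop_vel_threshold, win, start)
    return None if idx is None else float(time[idx])


def detect_foot_lift(time: np.ndarray, fz_stepping: np.ndarray, body_weight: float,
                     after: float, cfg: AnalysisConfig) -> float | None:
    """First crossing of the stepping-side vertical force below
    ``lift_fraction`` x body weight after ``after``; None when absent."""
    start = int(np.searchsorted(time, after))
    below = fz_stepping[start:] < cfg.lift_fraction * body_weight
    hits = np.nonzero(below)[0]
    return None if len(hits) == 0 else float(time[start + hits[0]])


def detect_landing(time: np.ndarray, hallux: np.ndarray, after: float,
                   cfg: AnalysisConfig) -> float | None:
    """First t > after with |d/dt hallux| below threshold on all three axes.

    ``hallux`` is the (n, 3) filtered hallux trajectory on the marker grid.
    """
    fs = 1.0 / float(np.mean(np.diff(time)))
    speed = np.abs(derivative(hallux, fs))
    start = int(np.searchsorted(time, after, side="right"))
    settled = np.all(speed < cfg.landing_speed_threshold, axis=1)
    hits = np.nonzero(settled[start:])[0]
    return None if len(hits) == 0 else float(time[start + hits[0]])


def final_foot_position(markers_time: np.ndarray, stepping_foot: np.ndarray,
                        landing: float) -> np.ndarray:
    """Mean (ML, AP) of the three stepping-foot markers at the landing sample."""
    i = int(np.clip(np.searchsorted(markers_time, landing), 0, len(markers_time) - 1))
    return stepping_foot[i, :, :2].mean(axis=0)


def exclude_jump_trial(ev: EventSet, cfg: AnalysisConfig) -> tuple[bool, str | None]:
    """Jump-trial exclusion: trigger at/before initiation, or led-on too
    close to foot lift for any modulation to be observable."""
    if ev.trigger is not None and ev.initiation is not None and ev.trigger <= ev.initiation:
        return True, "pre-initiation trigger"
    if (ev.led_on is not None and ev.foot_lift is not None
            and ev.foot_lift - ev.led_on < cfg.jump_exclusion_margin):
        return True, "jump too close to foot lift"
    return False, None


def detect_events(trial: Trial, kin: ComKinematics, cfg: AnalysisConfig) -> EventSet:
    """Run all detectors on a right-normalized trial and apply exclusions."""
    ev = EventSet()
    if trial.jump_command_time is not None:
        ev.trigger = float(trial.jump_command_time)
        ev.led_on = ev.trigger + cfg.led_delay

    ev.initiation = detect_prestep_initiation(kin.time, kin.cop_ml_vel,
                                              trial.illumination_time, cfg)
    if ev.initiation is None:
        ev.excluded, ev.reason = True, "no step initiated"
        return ev

    ev.foot_lift = detect_foot_lift(kin.time, kin.fz_stepping, kin.body_weight,
                                    ev.initiation, cfg)
    if ev.foot_lift is None:
        ev.excluded, ev.reason = True, "no foot lift"
        return ev

    m = trial.markers
    hallux = butter_zero_lag(m.feet["stepping"][:, 0, :], cfg.cutoff_marker,
                             m.fs, cfg.filter_order)
    foot = butter_zero_lag(m.feet["stepping"].reshape(len(m.time), 9),
                           cfg.cutoff_marker, m.fs, cfg.filter_order
                           ).reshape(len(m.time), 3, 3)
    ev.landing = detect_landing(m.time, hallux, ev.foot_lift, cfg)
    if ev.landing is None:
        ev.excluded, ev.reason = True, "no landing"
        return ev
    ev.final_foot_position = final_foot_position(m.time, foot, ev.landing)

    if trial.condition == "jump":
        ev.excluded, ev.reason = exclude_jump_trial(ev, cfg)
    return ev
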