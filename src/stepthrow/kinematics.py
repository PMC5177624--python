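"""Signal conditioning and CoM kinematics.

The body's centre-of-mass (CoM) acceleration is obtained from Newton's
second law as the summed ground-reaction force of the two plates divided by
the subject's mass, with the quiet-stance mean (recording start to target
illumination) subtracted as a baseline so that net CoM acceleration is zero
while the subject stands still.  CoM velocity follows by cumulative
trapezoidal integration anchored at zero at pre-step initiation, and CoM
jerk is the first time derivative of the filtered acceleration (central
differences in the interior, one-sided at the ends).  All force-derived
series live on the force-plate time grid; marker series stay on their
native grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import butter, filtfilt

from .config import AnalysisConfig
from .core import Trial

__all__ = [
    "butter_zero_lag", "com_acceleration", "com_velocity", "com_jerk",
    "combined_cop", "cop_ml_velocity", "derivative", "ComKinematics",
    "compute_kinematics",
]


def butter_zero_lag(x: np.ndarray, cutoff: float, fs: float, order: int = 2,
                    axis: int = 0) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter (one forward and one backward
    pass, so the effective magnitude response is |H|^2 and the gain at the
    cut-off frequency is 0.5)."""
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist ({fs / 2} Hz)")
    n = x.shape[axis]
    b, a = butter(order, cutoff, fs=fs)
    settle = max(3 * (max(len(a), len(b)) - 1), int(round(fs / cutoff)))
    if n <= 3 * settle:
        raise ValueError(f"series of {n} samples is too short to filter reliably "
                         f"(need > {3 * settle})")
    return filtfilt(b, a, x, axis=axis)


def derivative(x: np.ndarray, fs: float, axis: int = 0) -> np.ndarray:
    """First time derivative: central differences interior, one-sided ends."""
    if x.shape[axis] < 3:
        raise ValueError("need at least 3 samples to differentiate")
    return np.gradient(x, 1.0 / fs, axis=axis)


def com_acceleration(total_force: np.ndarray, mass: float, time: np.ndarray,
                     baseline: tuple[float, float], min_baseline: float = 0.250) -> np.ndarray:
    """CoM acceleration from the summed plate force, quiet-stance baselined.

    Parameters
    ----------
    total_force : (n, k) array
        Summed (already filtered) force of both plates, any number of axes.
    baseline : (t0, t1)
        Quiet-stance window (recording start to target illumination) whose
        per-axis mean is taken as the zero of acceleration.
    """
    t0, t1 = baseline
    if t1 - t0 < min_baseline:
        raise ValueError(f"baseline window of {t1 - t0:.3f} s is shorter than "
                         f"the required minimum {min_baseline:.3f} s")
    sel = (time >= t0) & (time <= t1)
    a = np.asarray(total_force, dtype=float) / mass
    return a - a[sel].mean(axis=0)


def com_velocity(a: np.ndarray, time: np.ndarray, t_from: float, t_to: float
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trapezoidal integral of CoM acceleration with v(t_from) = 0.

    Returns ``(t_seg, v_seg, v_at_to)`` where ``v_seg`` covers
    [t_from, t_to] on the acceleration grid and ``v_at_to`` is the velocity
    at the final sample (the quantity evaluated at foot lift).
    """
    if not (time[0] <= t_from < t_to <= time[-1]):
        raise ValueError(f"integration window [{t_from}, {t_to}] outside recording "
                         f"[{time[0]}, {time[-1]}] or reversed")
    i0 = int(np.searchsorted(time, t_from))
    i1 = int(np.searchsorted(time, t_to, side="right"))
    t_seg = time[i0:i1]
    v_seg = cumulative_trapezoid(a[i0:i1], t_seg, axis=0, initial=0.0)
    return t_seg, v_seg, v_seg[-1]


def com_jerk(a: np.ndarray, fs: float) -> np.ndarray:
    """CoM jerk: first time derivative of the (filtered) acceleration."""
    return derivative(a, fs, axis=0)


def combined_cop(plates: dict, min_load: float = 1.0) -> np.ndarray:
    """Force-weighted average CoP of the two plates (n, 2).

    Plates whose vertical load is below ``min_load`` newtons contribute
    nothing (the stepping plate during swing); if neither plate carries
    load the sample is invalid.
    """
    num = 0.0
    den = 0.0
    for p in plates.values():
        if p.cop is None:
            raise ValueError(f"plate[{p.plate_side}] has no CoP record")
        w = np.clip(p.force[:, 2], 0.0, None)
        w = np.where(w < min_load, 0.0, w)
        num = num + w[:, None] * p.cop
        den = den + w
    if np.any(den <= 0):
        raise ValueError("vertical load below contact threshold on both plates "
                         "during the requested window")
    return num / den[:, None]


def cop_ml_velocity(cop_ml: np.ndarray, fs: float, stepping_sign: float = 1.0) -> np.ndarray:
    """Signed ML CoP velocity, positive toward the stepping foot.

    ``stepping_sign`` is +1 when the stepping side lies on the +ML axis
    (always the case after reflection to a canonical right-sided step).
    """
    return stepping_sign * derivative(cop_ml, fs)


@dataclass
class ComKinematics:
    """Force-rate CoM kinematics of one (right-normalized) trial."""

    time: np.ndarray          # force-plate grid [s]
    acc: np.ndarray           # (n, 3) CoM acceleration, baselined [m/s^2]
    jerk: np.ndarray          # (n, 2) ML/AP CoM jerk [m/s^3]
    cop: np.ndarray           # (n, 2) combined CoP [m]
    cop_ml_vel: np.ndarray    # (n,) ML CoP velocity toward the stepping foot [m/s]
    fz_stepping: np.ndarray   # (n,) filtered stepping-plate vertical force [N]
    body_weight: float        # quiet-stance summed vertical force [N]
    baseline: tuple           # window used for baselining [s]
    fs: float

    def sample(self, t: float) -> int:
        """Nearest grid index for a time (times are authoritative; indices
        are derived only at point of use)."""
        return int(np.clip(round((t - self.time[0]) * self.fs), 0, len(self.time) - 1))


def compute_kinematics(trial: Trial, cfg: AnalysisConfig) -> ComKinematics:
    """Filter a trial's force channels and derive the CoM kinematics.

    The trial must already be in the canonical right-sided frame (see
    :func:`stepthrow.core.reflect_to_right`); the stepping foot then lies on
    the +ML axis and "toward the stepping foot" is simply +ML.
    """
    step = trial.plates["stepping"]
    trail = trial.plates["trailing"]
    time = step.time
    fs = step.fs

    f_step = butter_zero_lag(step.force, cfg.cutoff_force, fs, cfg.filter_order)
    f_trail = butter_zero_lag(trail.force, cfg.cutoff_force, fs, cfg.filter_order)

    baseline = (float(time[0]), float(trial.illumination_time))
    acc = com_acceleration(f_step + f_trail, trial.subject.mass, time,
                           baseline, cfg.min_baseline)
    jerk = com_jerk(acc[:, :2], fs)

    # combined CoP from the unfiltered records, then filtered at the force cut-off
    cop_raw = combined_cop(trial.plates)
    cop = butter_zero_lag(cop_raw, cfg.cutoff_force, fs, cfg.filter_order)
    cop_for_vel = cop
    if cfg.cop_vel_smooth is not None:
        cop_for_vel = butter_zero_lag(cop_raw, cfg.cop_vel_smooth, fs, cfg.filter_order)
    ml_vel = cop_ml_velocity(cop_for_vel[:, 0], fs, stepping_sign=1.0)

    sel = (time >= baseline[0]) & (time <= baseline[1])
    bw = float((f_step[sel, 2] + f_trail[sel, 2]).mean())

    return ComKinematics(time=time, acc=acc, jerk=jerk, cop=cop, cop_ml_vel=ml_vel,
                         fz_stepping=f_step[:, 2], body_weight=bw,
                         baseline=baseline, fs=fs)
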