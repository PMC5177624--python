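"""Synthetic stepping-trial generator with known ground truth.

Emulates the study protocol: subjects stand with a 15 cm gap between the
medial foot borders, a floor target lights up, and after a self-paced
reaction the anticipatory postural activity begins — the centre of
pressure shifts toward the stepping foot while the net ground-reaction
force accelerates the CoM away from it and forwards, so that at foot lift
the body carries a velocity coupled to the target ("throw").  In jump
trials the vertical-force difference between the plates crossing 80 N
triggers a target jump (displayed 16.5 ms later); after a skewed reaction
latency a non-specific AP braking pulse and a target-specific corrective
pulse modulate the pre-step activity, and foot lift is delayed.

Waveform family
---------------
All force pulses are smooth sine-family templates with closed-form
integrals, which makes every ground-truth quantity (CoM velocity at foot
lift, event times) analytically checkable:

* vertical load shift: quarter-sine loading of the stepping plate over the
  first ``loading_fraction`` of the pre-step, then a quadratic unload that
  crosses 1% body weight exactly at the scheduled foot-lift time.  The CoP
  follows as the load-weighted average of the fixed per-plate CoPs, which
  reproduces the initial ML CoP shift toward the stepping foot.
* horizontal throw: one raised-cosine (sin^2) net-force pulse per axis on
  a subject-level tempo template, integrating to
  ``throw_gain @ target_vector`` — so within-subject jerk variability is
  amplitude-like rather than phase-like, as required for per-time-point
  envelope comparisons to be meaningful.
* jump modulation: a raised-cosine AP braking pulse plus per-axis
  corrective raised-cosines spanning modulation onset to foot lift,
  integrating to the velocity change required by the new target.  The
  raised-cosine onset means jerk builds from zero instead of stepping, as
  a neuromuscular force transient does.
* execution noise: a slowly varying band-limited horizontal force
  fluctuation, ramped on at initiation so quiet stance stays quiet.

The 80 N trigger latency is an *outcome*: the loading amplitude is tuned
per trial so the threshold crossing lands at a draw from a truncated
normal whose truncated mean equals ``trigger_latency_target``.

Sensor noise is zero-mean Gaussian, band-limited by a second-order
low-pass before being added at each channel's native rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.signal import butter, filtfilt

from .config import AnalysisConfig, GeneratorParams
from .core import (JUMP_TARGETS, TARGETS, ForcePlateSeries, MarkerSeries,
                   SubjectInfo, TargetLayout, Trial)

__all__ = [
    "TrialPlan", "GroundTruth", "SimulationError",
    "make_schedule", "simulate_trial", "simulate_cohort", "iter_cohort",
    "ground_truth_frame",
]

#: marker offsets (ML, AP) about the foot centre; they sum to zero so the
#: three-marker mean is the foot centre
_MARKER_OFFSETS = np.array([[0.000, 0.090],
                            [-0.025, -0.030],
                            [0.025, -0.060]])


class SimulationError(RuntimeError):
    """A parameter combination produced an unrealizable trial."""


@dataclass(frozen=True)
class TrialPlan:
    subject: int
    index: int
    block: int
    side: str
    condition: str           # "constant" or "jump"
    initial_target: str
    final_target: str


@dataclass
class GroundTruth:
    """True event times and outcomes of one generated trial.

    Signed quantities are stored in the canonical right-sided frame
    regardless of the trial's actual stepping side, so they compare
    directly with an analysis pipeline that reflects trials to the right.
    """

    trial_id: str
    subject_id: str
    side: str
    condition: str
    initial_target: str
    final_target: str
    illumination: float
    initiation: float
    trigger: float | None
    led_on: float | None
    modulation_onset: float | None
    foot_lift: float
    landing: float
    final_ml: float
    final_ap: float
    v_lift_ml: float
    v_lift_ap: float


# ---------------------------------------------------------------------------
# schedule

def make_schedule(params: GeneratorParams, rng: np.random.Generator) -> list[list[TrialPlan]]:
    """Per-subject pseudo-random trial schedules realizing the printed
    condition probabilities exactly.

    Per subject and per 16 trials: 8 constant-central, 1 constant trial to
    each of the four peripheral targets, and 1 jump trial to each of the
    four peripheral targets — i.e. for 160 trials, 120 constant (80
    central, 10 per peripheral) and 40 jump (10 per direction), so
    P(jump) = 0.25 and P(jump | central illuminated) = 40/120 = 1/3.
    Stepping sides are balanced within every cell (alternating for odd
    cell counts) and the order is shuffled under the supplied RNG.
    """
    params.validate()
    unit = params.trials_per_subject // 16
    cells: list[tuple[str, str, str, int]] = []  # condition, initial, final, count
    cells.append(("constant", "central", "central", 8 * unit))
    for t in JUMP_TARGETS:
        cells.append(("constant", t, t, unit))
        cells.append(("jump", "central", t, unit))

    schedules = []
    for subj in range(params.n_subjects):
        plans = []
        parity = 0
        for condition, initial, final, count in cells:
            sides = ["right", "left"] * (count // 2)
            if count % 2:
                sides.append(["right", "left"][parity])
                parity ^= 1
            for side in sides:
                plans.append((side, condition, initial, final))
        rng.shuffle(plans)
        schedules.append([
            TrialPlan(subject=subj, index=i, block=i // params.block_size,
                      side=s, condition=c, initial_target=a, final_target=b)
            for i, (s, c, a, b) in enumerate(plans)
        ])
    return schedules


# ---------------------------------------------------------------------------
# per-subject traits

@dataclass
class _SubjectTraits:
    subject_id: str
    mass: float
    dur_offset: float
    t_pulse: float              # subject-level throw-pulse duration [s]
    gain: np.ndarray            # (2,) throw gain, subject-specific
    bias: dict                  # target -> (2,) fixed ideal-position bias
    info: SubjectInfo


def _draw_subject(idx: int, params: GeneratorParams, rng: np.random.Generator) -> _SubjectTraits:
    subject_id = f"S{idx + 1:02d}"
    mass = float(np.clip(rng.normal(params.mass_mean, params.mass_sd), 50.0, 95.0))
    dur_offset = float(rng.normal(0.0, params.prestep_sd_subject))
    gain = np.array([params.throw_gain_ml, params.throw_gain_ap])
    gain = gain * (1.0 + rng.normal(0.0, params.gain_sd_subject, 2))
    bias = {t: rng.normal(0.0, params.ideal_bias_sd, 2) for t in TARGETS}
    dominant = "right" if idx % 2 == 0 else "left"
    t_pulse = params.pulse_fraction * (params.prestep_mean + dur_offset)
    return _SubjectTraits(subject_id=subject_id, mass=mass, dur_offset=dur_offset,
                          t_pulse=t_pulse, gain=gain, bias=bias,
                          info=SubjectInfo(subject_id=subject_id, mass=mass,
                                           dominant_side=dominant))


def _trigger_latency_mu(params: GeneratorParams) -> tuple[float, float, float]:
    """Location of the truncated-normal trigger-latency draw such that the
    *truncated* mean equals the configured target; returns (mu, lo, hi)."""
    lo = params.trigger_latency_min
    hi = 0.85 * params.loading_fraction * params.prestep_mean
    sd = params.trigger_latency_sd
    if not lo < params.trigger_latency_target < hi:
        raise SimulationError(
            f"trigger_latency_target={params.trigger_latency_target} s is not "
            f"attainable inside the loading phase ({lo:.3f}..{hi:.3f} s)")

    def gap(mu):
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return stats.truncnorm.mean(a, b, loc=mu, scale=sd) - params.trigger_latency_target

    mu = brentq(gap, lo - 6 * sd, hi + 6 * sd, xtol=1e-6)
    return float(mu), lo, hi


# ---------------------------------------------------------------------------
# waveforms

def _colored_noise(rng: np.random.Generator, n: int, sd: float, cutoff: float,
                   fs: float) -> np.ndarray:
    """Band-limited Gaussian noise with the requested post-filter SD."""
    if sd <= 0:
        return np.zeros(n)
    w = rng.standard_normal(n)
    b, a = butter(2, min(cutoff, 0.45 * fs), fs=fs)
    x = filtfilt(b, a, w)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _band_noise(rng: np.random.Generator, n: int, sd: float,
                band: tuple[float, float], fs: float) -> np.ndarray:
    """Band-pass Gaussian noise (slow motor fluctuations)."""
    if sd <= 0:
        return np.zeros(n)
    w = rng.standard_normal(n)
    b, a = butter(2, band, btype="bandpass", fs=fs)
    x = filtfilt(b, a, w)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _fz_step_clean(t: np.ndarray, t_init: float, t1: float, peak: float,
                   bw: float, t_lift: float, lift_fraction: float) -> np.ndarray:
    """Stepping-plate vertical force: quiet half-load, quarter-sine loading
    to ``bw/2 + peak`` over [0, t1] after initiation, then a quadratic
    unload crossing ``lift_fraction * bw`` exactly at ``t_lift`` (relative
    to initiation) and clamping at zero thereafter."""
    rel = t - t_init
    fz = np.full(len(t), bw / 2)
    m1 = (rel >= 0) & (rel <= t1)
    fz[m1] = bw / 2 + peak * np.sin(np.pi * rel[m1] / (2 * t1))
    f1 = bw / 2 + peak
    ustar = 1.0 - math.sqrt(lift_fraction * bw / f1)
    t_unload = (t_lift - t1) / ustar
    if t_unload <= 0:
        raise SimulationError("foot-lift time precedes the end of the loading phase")
    m2 = rel > t1
    u = (rel[m2] - t1) / t_unload
    fz[m2] = f1 * np.clip(1.0 - u, 0.0, None) ** 2
    return fz


def _smooth_pulse(t: np.ndarray, onset: float, duration: float, amplitude) -> np.ndarray:
    """Raised-cosine (sin^2) force pulse; ``amplitude`` may be a scalar or
    (2,) vector.  The pulse and its first derivative vanish at both ends, so
    the resulting jerk builds from zero rather than stepping — the time
    integral is ``amplitude * duration / 2``."""
    rel = (t - onset) / duration
    env = np.where((rel >= 0) & (rel <= 1),
                   np.sin(np.pi * np.clip(rel, 0, 1)) ** 2, 0.0)
    amplitude = np.atleast_1d(amplitude)
    return env[:, None] * amplitude[None, :]


def _min_jerk(s: np.ndarray) -> np.ndarray:
    return 10 * s ** 3 - 15 * s ** 4 + 6 * s ** 5


# ---------------------------------------------------------------------------
# single trial

def simulate_trial(plan: TrialPlan, params: GeneratorParams, subject: _SubjectTraits,
                   rng: np.random.Generator, cfg: AnalysisConfig | None = None,
                   trigger_mu: tuple[float, float, float] | None = None
                   ) -> tuple[Trial, GroundTruth]:
    """Simulate one trial of the schedule; returns the trial and its ground
    truth.  The trial is built in the canonical right-sided frame and
    mirrored afterwards when the plan calls for a left-sided step."""
    cfg = cfg or AnalysisConfig()
    layout = TargetLayout(stance_gap=params.stance_gap,
                          foot_half_width=params.foot_half_width)
    if trigger_mu is None:
        trigger_mu = _trigger_latency_mu(params)
    mu, lat_lo, lat_hi = trigger_mu

    fs = params.fs_force
    illum = float(rng.uniform(params.illum_min, params.illum_max))
    t_init = illum + max(0.15, rng.normal(params.reaction_mean, params.reaction_sd))
    t_base = max(0.35, params.prestep_mean + subject.dur_offset
                 + rng.normal(0.0, params.prestep_sd_trial))
    t1 = params.loading_fraction * t_base
    bw = subject.mass * cfg.gravity

    a_, b_ = (lat_lo - mu) / params.trigger_latency_sd, (lat_hi - mu) / params.trigger_latency_sd
    lat_des = float(stats.truncnorm.rvs(a_, b_, loc=mu, scale=params.trigger_latency_sd,
                                        random_state=rng))
    lat_des = min(lat_des, 0.85 * t1)
    peak = (cfg.trigger_force / 2) / math.sin(np.pi * lat_des / (2 * t1))

    t_end = illum + params.record_tail
    n = int(round(t_end * fs)) + 1
    t = np.arange(n) / fs

    nz_step = _colored_noise(rng, n, params.noise_force_sd, params.noise_force_bw, fs)
    nz_trail = _colored_noise(rng, n, params.noise_force_sd, params.noise_force_bw, fs)
    nh = {side: np.column_stack([
        _colored_noise(rng, n, params.noise_force_sd, params.noise_force_bw, fs),
        _colored_noise(rng, n, params.noise_force_sd, params.noise_force_bw, fs)])
        for side in ("stepping", "trailing")}
    ncop = {side: np.column_stack([
        _colored_noise(rng, n, params.noise_cop_sd, params.noise_force_bw, fs),
        _colored_noise(rng, n, params.noise_cop_sd, params.noise_force_bw, fs)])
        for side in ("stepping", "trailing")}

    lat_react = float(rng.lognormal(math.log(params.modulation_latency_median),
                                    params.modulation_latency_sigma))
    prolong = float(rng.normal(params.jump_prolong_mean, params.jump_prolong_sd))
    t_swing = max(0.25, rng.normal(params.swing_duration_mean, params.swing_duration_sd))

    # the pre-step (and hence the whole step) must fit inside the recording
    dur_cap = (t_end - t_init) - t_swing + params.swing_lead - 0.06

    trigger = led_on = t_mod = None
    if plan.condition == "jump":
        t_lift_dur = t_base
        for _ in range(2):  # trigger search is self-consistent after one rebuild
            fz_clean = _fz_step_clean(t, t_init, t1, peak, bw, t_lift_dur, cfg.lift_fraction)
            diff = 2 * fz_clean - bw + nz_step - nz_trail
            hits = np.nonzero((np.abs(diff) >= cfg.trigger_force) & (t > t_init))[0]
            if len(hits) == 0:
                raise SimulationError(
                    f"trigger cannot fire before foot lift (trial {plan.index} of "
                    f"subject {subject.subject_id})")
            trigger = float(t[hits[0]])
            led_on = trigger + cfg.led_delay
            t_mod = min(led_on + lat_react,
                        t_init + dur_cap - params.min_onset_to_lift)
            t_lift_dur = min(max(t_base + prolong,
                                 (t_mod - t_init) + params.min_onset_to_lift,
                                 t1 + 0.05),
                             dur_cap)
    else:
        t_lift_dur = min(t_base, dur_cap)

    fz_clean = _fz_step_clean(t, t_init, t1, peak, bw, t_lift_dur, cfg.lift_fraction)

    # --- horizontal net force: throw pulse (+ modulation in jump trials)
    gain = subject.gain * (1.0 + rng.normal(0.0, params.gain_sd_trial, 2))
    vec_initial = layout.vector(plan.initial_target, "right")
    v_throw = gain * vec_initial
    # the throw pulse follows the subject's tempo template so reference
    # traces stay phase-aligned; it must complete before foot lift
    t_pulse = min(subject.t_pulse, t_lift_dur)
    f_net = subject.mass * _smooth_pulse(t, t_init, t_pulse,
                                         v_throw * 2.0 / t_pulse)
    # slow execution noise during the pre-step activity (ramped on at
    # initiation so quiet stance stays quiet)
    motor = np.column_stack([
        _band_noise(rng, n, params.motor_noise_sd, params.motor_noise_band, fs),
        _band_noise(rng, n, params.motor_noise_sd, params.motor_noise_band, fs)])
    ramp = np.clip((t - t_init) / 0.15, 0.0, 1.0)
    ramp = ramp * ramp * (3 - 2 * ramp)
    f_net = f_net + motor * ramp[:, None]
    v_lift = v_throw.copy()
    if plan.condition == "jump":
        vec_final = layout.vector(plan.final_target, "right")
        dv = gain * (vec_final - vec_initial)
        f_net += _smooth_pulse(t, t_mod, params.brake_duration,
                               np.array([0.0, -params.brake_force]))
        dv_brake = np.array([0.0, -params.brake_force * params.brake_duration
                             / (2 * subject.mass)])
        t_corr = (t_init + t_lift_dur) - t_mod
        amp_corr = (dv - dv_brake) * subject.mass * 2.0 / t_corr
        f_net += _smooth_pulse(t, t_mod, t_corr, amp_corr)
        v_lift = v_throw + dv

    # --- assemble plates; horizontal shear split by vertical load share
    w_step = np.clip(fz_clean / bw, 0.0, 1.0)
    plates = {}
    for side, fz, w in (("stepping", fz_clean, w_step),
                        ("trailing", bw - fz_clean, 1.0 - w_step)):
        force = np.column_stack([f_net * w[:, None] + nh[side],
                                 fz + (nz_step if side == "stepping" else nz_trail)])
        sign = 1.0 if side == "stepping" else -1.0
        cop = np.tile([sign * layout.foot_offset, 0.0], (n, 1)) + ncop[side]
        plates[side] = ForcePlateSeries(time=t, force=force, cop=cop, plate_side=side)

    # --- ground-truth events on the clean signals
    lift_hits = np.nonzero((t > t_init) & (fz_clean < cfg.lift_fraction * bw))[0]
    gt_lift = float(t[lift_hits[0]])

    # --- markers: rigid minimum-jerk swing beginning slightly before the
    #     force-defined lift (heel-off precedes the 1% BW crossing)
    fsm = params.fs_marker
    nm = int(round(t_end * fsm)) + 1
    tm = np.arange(nm) / fsm
    start = layout.origin("right")
    ideal = layout.position(plan.final_target, "right") + subject.bias[plan.final_target]
    landing_pos = ideal + rng.normal(0.0, params.placement_sd, 2)
    t_sw0 = (t_init + t_lift_dur) - params.swing_lead
    s = np.clip((tm - t_sw0) / t_swing, 0.0, 1.0)
    horiz = start[None, :] + (landing_pos - start)[None, :] * _min_jerk(s)[:, None]
    # vertical bell with zero end velocity *and* acceleration, so the foot
    # settles as smoothly as the horizontal minimum-jerk profile
    vert = params.marker_height + params.step_height * 64 * (s * (1 - s)) ** 3

    step_clean = np.empty((nm, 3, 3))
    step_clean[:, :, 0] = horiz[:, None, 0] + _MARKER_OFFSETS[None, :, 0]
    step_clean[:, :, 1] = horiz[:, None, 1] + _MARKER_OFFSETS[None, :, 1]
    step_clean[:, :, 2] = vert[:, None]

    trail_pos = np.empty((nm, 3, 3))
    trail_pos[:, :, 0] = -layout.foot_offset - _MARKER_OFFSETS[None, :, 0]
    trail_pos[:, :, 1] = _MARKER_OFFSETS[None, :, 1]
    trail_pos[:, :, 2] = params.marker_height

    # ground-truth landing: threshold rule applied to the clean hallux track
    hallux_speed = np.abs(np.gradient(step_clean[:, 0, :], 1.0 / fsm, axis=0))
    settled = np.all(hallux_speed < cfg.landing_speed_threshold, axis=1)
    land_hits = np.nonzero(settled & (tm > gt_lift))[0]
    if len(land_hits) == 0:
        raise SimulationError("swing does not settle within the recording")
    gt_landing = float(tm[land_hits[0]])

    feet = {"stepping": step_clean, "trailing": trail_pos}
    for foot in feet:
        noise = np.stack([np.column_stack([
            _colored_noise(rng, nm, params.noise_marker_sd, params.noise_marker_bw, fsm)
            for _ in range(3)]) for _ in range(3)], axis=1)
        feet[foot] = feet[foot] + noise

    trial = Trial(
        trial_id=f"{subject.subject_id}_t{plan.index:03d}",
        subject=subject.info,
        side="right",
        condition=plan.condition,
        initial_target=plan.initial_target,
        final_target=plan.final_target,
        illumination_time=illum,
        jump_command_time=trigger,
        plates=plates,
        markers=MarkerSeries(time=tm, feet=feet),
        ideal_foot_position=ideal.copy(),
    )
    if plan.side == "left":
        trial = _mirror_to_left(trial)

    gt = GroundTruth(
        trial_id=trial.trial_id, subject_id=subject.subject_id, side=plan.side,
        condition=plan.condition, initial_target=plan.initial_target,
        final_target=plan.final_target, illumination=illum, initiation=t_init,
        trigger=trigger, led_on=led_on, modulation_onset=t_mod,
        foot_lift=gt_lift, landing=gt_landing,
        final_ml=float(landing_pos[0]), final_ap=float(landing_pos[1]),
        v_lift_ml=float(v_lift[0]), v_lift_ap=float(v_lift[1]),
    )
    return trial.validate(), gt


def _mirror_to_left(trial: Trial) -> Trial:
    """Mirror a canonical right-sided trial into a genuine left-sided one
    (the exact inverse of the reflection applied during analysis)."""
    from .core import reflect_to_right

    flipped = Trial(**{**trial.__dict__, "side": "left"})
    mirrored = reflect_to_right(flipped)   # negates every ML component
    mirrored.side = "left"
    return mirrored


# ---------------------------------------------------------------------------
# cohort

def iter_cohort(params: GeneratorParams, seed: int | None = None,
                cfg: AnalysisConfig | None = None):
    """Yield (trial, ground_truth) pairs for the whole cohort, subject by
    subject, fully reproducible under the seed (``params.seed`` when the
    argument is None)."""
    params.validate()
    cfg = cfg or AnalysisConfig()
    seed = params.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(params.n_subjects + 1)
    schedules = make_schedule(params, np.random.default_rng(children[0]))
    trig_mu = _trigger_latency_mu(params)
    for idx in range(params.n_subjects):
        rng = np.random.default_rng(children[idx + 1])
        subject = _draw_subject(idx, params, rng)
        for plan in schedules[idx]:
            yield simulate_trial(plan, params, subject, rng, cfg=cfg,
                                 trigger_mu=trig_mu)


def simulate_cohort(params: GeneratorParams, seed: int | None = None,
                    cfg: AnalysisConfig | None = None
                    ) -> tuple[list[Trial], pd.DataFrame]:
    """Simulate the full cohort in memory; returns the trials and the
    ground-truth table."""
    trials, gts = [], []
    for trial, gt in iter_cohort(params, seed=seed, cfg=cfg):
        trials.append(trial)
        gts.append(gt)
    return trials, ground_truth_frame(gts)


def ground_truth_frame(gts: list[GroundTruth]) -> pd.DataFrame:
    return pd.DataFrame([gt.__dict__ for gt in gts])
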