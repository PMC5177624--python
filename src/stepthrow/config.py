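"""Analysis and generator configuration.

All values are SI (metres, seconds, newtons, kilograms) unless a name says
otherwise.  The defaults encode the protocol constants of the stepping
experiment this package models: a 15 cm stance gap, zero-lag Butterworth
filtering at 15 Hz (markers) / 30 Hz (force), a 5 cm/s ML CoP-velocity
initiation rule sustained for 50 ms, foot lift at 1% body weight, landing at
2 cm/s hallux speed, an 80 N vertical-force-difference jump trigger with a
16.5 ms display delay, and a 100 ms minimum modulation latency.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["AnalysisConfig", "GeneratorParams", "ConfigError", "validate_config", "load_config"]


class ConfigError(ValueError):
    """Raised when a configuration value is missing, unknown or out of range."""


@dataclass
class AnalysisConfig:
    """Thresholds and filter settings for the analysis pipeline."""

    #: zero-lag Butterworth cut-off for marker trajectories [Hz]
    cutoff_marker: float = 15.0
    #: zero-lag Butterworth cut-off for force and CoP channels [Hz]
    cutoff_force: float = 30.0
    #: Butterworth order per pass (applied forward and backward)
    filter_order: int = 2
    #: ML CoP velocity toward the stepping foot defining pre-step initiation [m/s]
    cop_vel_threshold: float = 0.05
    #: duration the CoP-velocity threshold must be exceeded [s]
    sustain_window: float = 0.050
    #: stepping-side vertical force fraction of body weight defining foot lift
    lift_fraction: float = 0.01
    #: per-axis hallux speed below which the foot has landed [m/s]
    landing_speed_threshold: float = 0.02
    #: vertical force difference between sides that triggers a target jump [N]
    trigger_force: float = 80.0
    #: electrical delay between trigger signal and new target lighting up [s]
    led_delay: float = 0.0165
    #: earliest physiologically plausible modulation latency after a jump [s]
    min_modulation_delay: float = 0.100
    #: jump trials with foot lift closer than this to led-on are excluded [s]
    jump_exclusion_margin: float = 0.150
    #: minimum quiet-stance window required for force baselining [s]
    min_baseline: float = 0.250
    #: coverage level of the per-time-point reference ellipses
    ellipse_level: float = 0.95
    #: "dispersion" (chi-square boundary) or "prediction" (F boundary)
    ellipse_kind: str = "dispersion"
    #: time a trajectory must stay outside the ellipse for a divergence to
    #: count [s]; the latency is still the *start* of the excursion.  Brief
    #: marginal excursions of an undiverged trial are otherwise mistaken
    #: for modulations when a long window is searched sample by sample.
    divergence_persistence: float = 0.080
    #: returns inside the ellipse shorter than this are bridged before the
    #: persistence rule is applied [s].  A genuine modulation's Mahalanobis
    #: distance dips briefly whenever the corrective jerk crosses zero;
    #: unrelated noise excursions are separated by far longer returns.
    divergence_gap_tolerance: float = 0.020
    #: an excursion must reach this multiple of the squared boundary radius
    #: within the persistence window to count as a divergence (0 disables).
    #: Genuine modulations overshoot the envelope by orders of magnitude;
    #: chance excursions of an undiverged trial hover just outside it.
    divergence_confirm_ratio: float = 4.0
    #: optional extra low-pass on CoP before differentiation [Hz] (None = off)
    cop_vel_smooth: float | None = None
    #: significance level before Bonferroni correction
    alpha: float = 0.05
    #: gravitational acceleration [m/s^2]
    gravity: float = 9.81

    def validate(self, fs_force: float = 1000.0, fs_marker: float = 200.0) -> "AnalysisConfig":
        pos = [
            "cutoff_marker", "cutoff_force", "cop_vel_threshold", "sustain_window",
            "lift_fraction", "landing_speed_threshold", "trigger_force", "led_delay",
            "min_modulation_delay", "jump_exclusion_margin", "min_baseline", "gravity",
        ]
        for name in pos:
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)!r}")
        if not 0 < self.ellipse_level < 1:
            raise ConfigError(f"ellipse_level must be in (0, 1), got {self.ellipse_level!r}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha!r}")
        if self.filter_order < 1:
            raise ConfigError("filter_order must be >= 1")
        if self.divergence_persistence < 0:
            raise ConfigError("divergence_persistence must be >= 0 seconds")
        if self.divergence_gap_tolerance < 0:
            raise ConfigError("divergence_gap_tolerance must be >= 0 seconds")
        if self.divergence_confirm_ratio < 0:
            raise ConfigError("divergence_confirm_ratio must be >= 0")
        if self.ellipse_kind not in ("dispersion", "prediction"):
            raise ConfigError(f"ellipse_kind must be 'dispersion' or 'prediction', got {self.ellipse_kind!r}")
        if self.cutoff_force >= fs_force / 2:
            raise ConfigError(f"cutoff_force={self.cutoff_force} Hz is at or above Nyquist ({fs_force / 2} Hz)")
        if self.cutoff_marker >= fs_marker / 2:
            raise ConfigError(f"cutoff_marker={self.cutoff_marker} Hz is at or above Nyquist ({fs_marker / 2} Hz)")
        if self.cop_vel_smooth is not None and not 0 < self.cop_vel_smooth < fs_force / 2:
            raise ConfigError("cop_vel_smooth must be in (0, Nyquist) or null")
        return self


@dataclass
class GeneratorParams:
    """Parameters of the synthetic stepping-trial generator.

    The defaults reproduce the statistical structure of the study protocol:
    160 trials per subject in 10 blocks of 16 (120 constant / 40 jump), a
    pre-step duration of 561 (89) ms, a target-jump trigger latency of
    96 (43) ms after initiation (emergent from the 80 N rule; the loading
    amplitude is the tuned quantity), a log-normal per-trial modulation
    reaction latency with median 223 ms, and a mean foot-lift prolongation
    of 69 (55) ms in jump trials.
    """

    n_subjects: int = 10
    trials_per_subject: int = 160
    block_size: int = 16
    #: gap between medial foot borders at stance [m]
    stance_gap: float = 0.15
    #: lateral offset from a foot's medial border to its centre [m]
    foot_half_width: float = 0.04
    mass_mean: float = 70.0
    mass_sd: float = 10.0
    #: pre-step (initiation to foot lift) duration, constant condition [s]
    prestep_mean: float = 0.561
    prestep_sd_trial: float = 0.077
    prestep_sd_subject: float = 0.045
    #: additional pre-step duration in jump trials [s]
    jump_prolong_mean: float = 0.069
    jump_prolong_sd: float = 0.055
    #: target mean latency of the 80 N trigger after initiation [s]
    trigger_latency_target: float = 0.096
    trigger_latency_sd: float = 0.043
    trigger_latency_min: float = 0.040
    #: median of the log-normal reaction latency from led-on to modulation [s]
    modulation_latency_median: float = 0.223
    #: log-space sigma of the reaction latency (sets the IQR skew)
    modulation_latency_sigma: float = 0.50
    #: injected modulation onsets are kept at least this far before foot lift [s]
    min_onset_to_lift: float = 0.120
    #: loading-phase length as a fraction of the base pre-step duration
    loading_fraction: float = 0.45
    #: throw-pulse length as a fraction of the subject's mean pre-step
    #: duration.  The pulse follows a subject-level tempo template so that
    #: within-subject jerk variability is amplitude-like (time-stable);
    #: trial-to-trial duration variability is realized in the unload/lift
    #: timing instead.
    pulse_fraction: float = 0.75
    #: diagonal gain mapping target position to CoM velocity at foot lift [1/s]
    throw_gain_ml: float = -0.35
    throw_gain_ap: float = 0.75
    gain_sd_subject: float = 0.05
    gain_sd_trial: float = 0.08
    #: peak of the non-specific AP braking pulse after a target jump [N]
    brake_force: float = 25.0
    brake_duration: float = 0.080
    swing_duration_mean: float = 0.45
    swing_duration_sd: float = 0.04
    #: hallux motion (heel-off / foot roll) precedes the 1% BW force lift [s]
    swing_lead: float = 0.080
    #: foot-placement scatter about the subject's ideal position [m]
    placement_sd: float = 0.008
    #: per-subject fixed bias of the self-defined ideal position [m]
    ideal_bias_sd: float = 0.005
    #: reaction time from target illumination to pre-step initiation [s]
    reaction_mean: float = 0.400
    reaction_sd: float = 0.080
    illum_min: float = 1.0
    illum_max: float = 1.6
    #: recording continues this long after illumination [s]
    record_tail: float = 2.2
    fs_force: float = 1000.0
    fs_marker: float = 200.0
    noise_force_sd: float = 0.05
    #: motor execution noise: slowly varying horizontal net-force
    #: fluctuation present during the pre-step activity [N per axis]
    motor_noise_sd: float = 3.5
    #: pass band of the motor fluctuation [Hz]
    motor_noise_band: tuple = (1.0, 3.0)
    noise_cop_sd: float = 5e-5
    noise_marker_sd: float = 1.0e-4
    #: band limit of the force/CoP sensor noise [Hz]
    noise_force_bw: float = 80.0
    noise_marker_bw: float = 20.0
    marker_height: float = 0.02
    step_height: float = 0.05
    seed: int = 0

    def validate(self) -> "GeneratorParams":
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.trials_per_subject % self.block_size:
            raise ConfigError(
                f"trials_per_subject={self.trials_per_subject} is not divisible into "
                f"blocks of {self.block_size}")
        if self.trials_per_subject % 16:
            raise ConfigError(
                "trials_per_subject must be a multiple of 16 so the printed "
                "condition probabilities are realizable as exact counts")
        for name in ["stance_gap", "mass_mean", "prestep_mean", "trigger_latency_target",
                     "modulation_latency_median", "swing_duration_mean", "fs_force", "fs_marker"]:
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)!r}")
        if not 0 < self.loading_fraction < 1:
            raise ConfigError("loading_fraction must be in (0, 1)")
        if self.illum_min > self.illum_max:
            raise ConfigError("illum_min must not exceed illum_max")
        if self.illum_min <= 0.3:
            raise ConfigError("illum_min must leave a usable quiet-stance baseline (> 0.3 s)")
        return self


def _from_mapping(cls, section: dict, name: str):
    known = {f.name for f in fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in '{name}' section: {sorted(unknown)}")
    try:
        return cls(**section)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from exc


def validate_config(raw: dict | None) -> tuple[AnalysisConfig, GeneratorParams]:
    """Resolve a raw mapping (``analysis:`` / ``generator:`` sections) to
    validated config objects, filling unset keys with the protocol defaults.
    Unknown sections or keys are rejected by name.
    """
    raw = dict(raw or {})
    unknown = set(raw) - {"analysis", "generator"}
    if unknown:
        raise ConfigError(f"unknown top-level config section(s): {sorted(unknown)}")
    params = _from_mapping(GeneratorParams, raw.get("generator") or {}, "generator").validate()
    cfg = _from_mapping(AnalysisConfig, raw.get("analysis") or {}, "analysis")
    cfg.validate(fs_force=params.fs_force, fs_marker=params.fs_marker)
    return cfg, params


def load_config(path) -> tuple[AnalysisConfig, GeneratorParams]:
    """Read a YAML config file; an empty file yields the full defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is not None and not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    return validate_config(raw)


def config_snapshot(cfg: AnalysisConfig, params: GeneratorParams) -> dict:
    """Fully resolved configuration as a plain dict (for manifests)."""
    return {"analysis": asdict(cfg), "generator": asdict(params)}
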