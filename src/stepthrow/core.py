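"""Domain types and coordinate conventions.

Laboratory frame
----------------
Right-handed, origin at the midpoint between the medial foot borders at
stance: x = medio-lateral (ML, positive toward the stepping side once a
trial has been reflected to a canonical right-sided step), y =
antero-posterior (AP, positive forward), z = vertical (positive up).  All
series of a trial share this frame; events are stored as times in seconds
from recording start and converted to sample indices only at point of use.

Target layout
-------------
Five floor targets per side, specified in polar form about the stepping
foot's start position: medial/central/lateral share a 35 cm step length at
0/25/50 degrees (measured from the AP axis, rotating laterally) and
proximal/central/distal share the 25-degree direction at 20/35/50 cm.  The
four central-to-peripheral displacements all have magnitude 15 cm to the
nearest centimetre.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MARKER_NAMES", "TARGET_POLAR", "TARGETS", "JUMP_TARGETS",
    "SubjectInfo", "TargetLayout", "ForcePlateSeries", "MarkerSeries", "Trial",
    "TrialValidationError", "reflect_to_right", "target_distance",
]

#: marker order within each foot block
MARKER_NAMES = ("hallux", "mt1_base", "mt5_head")

#: (step length [m], direction [deg] from the AP axis, rotating laterally)
TARGET_POLAR = {
    "medial": (0.35, 0.0),
    "central": (0.35, 25.0),
    "lateral": (0.35, 50.0),
    "proximal": (0.20, 25.0),
    "distal": (0.50, 25.0),
}
TARGETS = tuple(TARGET_POLAR)
JUMP_TARGETS = ("medial", "lateral", "proximal", "distal")


class TrialValidationError(ValueError):
    """A trial bundle violates an invariant; the message names the field."""


@dataclass(frozen=True)
class SubjectInfo:
    subject_id: str
    mass: float  # kg
    dominant_side: str = "right"  # metadata only

    def __post_init__(self):
        if not (math.isfinite(self.mass) and self.mass > 0):
            raise TrialValidationError(f"subject.mass must be finite and positive, got {self.mass!r}")
        if self.dominant_side not in ("left", "right"):
            raise TrialValidationError(f"subject.dominant_side must be 'left' or 'right', got {self.dominant_side!r}")


@dataclass(frozen=True)
class TargetLayout:
    """Polar-specified targets per side with derived Cartesian coordinates."""

    stance_gap: float = 0.15
    foot_half_width: float = 0.04

    @property
    def foot_offset(self) -> float:
        """|ML| lab coordinate of a stepping foot's centre at stance [m]."""
        return self.stance_gap / 2 + self.foot_half_width

    def origin(self, side: str = "right") -> np.ndarray:
        """Stepping-foot start position (ML, AP) in the lab frame [m]."""
        sign = {"right": 1.0, "left": -1.0}[side]
        return np.array([sign * self.foot_offset, 0.0])

    def vector(self, target: str, side: str = "right") -> np.ndarray:
        """Step vector (ML, AP) from the stepping-foot origin to ``target`` [m]."""
        try:
            length, direction = TARGET_POLAR[target]
        except KeyError:
            raise KeyError(f"unknown target id {target!r}; expected one of {TARGETS}") from None
        theta = math.radians(direction)
        sign = {"right": 1.0, "left": -1.0}[side]
        return np.array([sign * length * math.sin(theta), length * math.cos(theta)])

    def position(self, target: str, side: str = "right") -> np.ndarray:
        """Target centre (ML, AP) in the lab frame [m]."""
        return self.origin(side) + self.vector(target, side)


def target_distance(layout: TargetLayout, a: str, b: str, side: str = "right") -> float:
    """Euclidean distance between two same-side target centres, in cm."""
    d = layout.vector(a, side) - layout.vector(b, side)
    return float(np.hypot(*d) * 100.0)


def _check_uniform(time: np.ndarray, what: str, rtol: float = 1e-4) -> float:
    if time.ndim != 1 or len(time) < 3:
        raise TrialValidationError(f"{what}.time must be a 1-D array with >= 3 samples")
    dt = np.diff(time)
    if not np.all(np.isfinite(dt)) or dt.min() <= 0:
        raise TrialValidationError(f"{what}.time must be strictly increasing")
    if (dt.max() - dt.min()) > rtol * dt.mean():
        raise TrialValidationError(
            f"{what}.time is not uniformly sampled "
            f"(dt ranges {dt.min():.6g}..{dt.max():.6g} s)")
    return float(1.0 / dt.mean())


@dataclass
class ForcePlateSeries:
    """One plate's record: time [s], 3-D force [N], optional CoP (ML, AP) [m]."""

    time: np.ndarray
    force: np.ndarray  # (n, 3): ML, AP, vertical
    cop: np.ndarray | None  # (n, 2): ML, AP
    plate_side: str  # "stepping" or "trailing"

    @property
    def fs(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.time)))

    def validate(self) -> None:
        name = f"plate[{self.plate_side}]"
        if self.plate_side not in ("stepping", "trailing"):
            raise TrialValidationError(f"plate_side must be 'stepping' or 'trailing', got {self.plate_side!r}")
        _check_uniform(self.time, name)
        if self.force.shape != (len(self.time), 3):
            raise TrialValidationError(
                f"{name}.force shape {self.force.shape} does not match time length {len(self.time)}")
        if not np.all(np.isfinite(self.force)):
            raise TrialValidationError(f"{name}.force contains non-finite values")
        if self.cop is not None:
            if self.cop.shape != (len(self.time), 2):
                raise TrialValidationError(
                    f"{name}.cop shape {self.cop.shape} does not match time length {len(self.time)}")
            if not np.all(np.isfinite(self.cop)):
                raise TrialValidationError(f"{name}.cop contains non-finite values")


@dataclass
class MarkerSeries:
    """Foot-marker trajectories: per foot, 3 markers (hallux, first-metatarsal
    base, fifth-metatarsal head) as (n, 3, 3) position arrays in metres."""

    time: np.ndarray
    feet: dict  # {"stepping": (n, 3, 3), "trailing": (n, 3, 3)}

    @property
    def fs(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.time)))

    def validate(self) -> None:
        _check_uniform(self.time, "markers")
        if "stepping" not in self.feet:
            raise TrialValidationError("markers.feet must include the stepping foot")
        for foot, pos in self.feet.items():
            if pos.shape != (len(self.time), 3, 3):
                raise TrialValidationError(
                    f"markers.feet[{foot!r}] shape {pos.shape} does not match "
                    f"(n={len(self.time)}, 3 markers, 3 dims)")
            if not np.all(np.isfinite(pos)):
                raise TrialValidationError(f"markers.feet[{foot!r}] contains non-finite values")


@dataclass
class Trial:
    """One step attempt: metadata plus synchronized force and marker series."""

    trial_id: str
    subject: SubjectInfo
    side: str  # stepping side: "left" or "right"
    condition: str  # "constant" or "jump"
    initial_target: str
    final_target: str
    illumination_time: float
    jump_command_time: float | None  # trigger time; led-on follows after the display delay
    plates: dict  # {"stepping": ForcePlateSeries, "trailing": ForcePlateSeries}
    markers: MarkerSeries
    ideal_foot_position: np.ndarray  # (ML, AP) lab frame [m]

    def validate(self) -> "Trial":
        if self.side not in ("left", "right"):
            raise TrialValidationError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.condition not in ("constant", "jump"):
            raise TrialValidationError(f"condition must be 'constant' or 'jump', got {self.condition!r}")
        for t in (self.initial_target, self.final_target):
            if t not in TARGET_POLAR:
                raise TrialValidationError(f"unknown target id {t!r}")
        if self.condition == "constant" and self.initial_target != self.final_target:
            raise TrialValidationError("constant trial must have initial_target == final_target")
        if (self.jump_command_time is not None) != (self.condition == "jump"):
            raise TrialValidationError(
                f"jump_command_time must be present iff condition == 'jump' "
                f"(condition={self.condition!r}, jump_command_time={self.jump_command_time!r})")
        if set(self.plates) != {"stepping", "trailing"}:
            raise TrialValidationError(f"plates must have keys 'stepping' and 'trailing', got {sorted(self.plates)}")
        for plate in self.plates.values():
            plate.validate()
        self.markers.validate()
        t0, t1 = self.plates["stepping"].time[0], self.plates["stepping"].time[-1]
        if not t0 <= self.illumination_time <= t1:
            raise TrialValidationError(
                f"illumination_time={self.illumination_time} outside recording [{t0}, {t1}]")
        if self.jump_command_time is not None and not t0 <= self.jump_command_time <= t1:
            raise TrialValidationError(
                f"jump_command_time={self.jump_command_time} outside recording [{t0}, {t1}]")
        if np.asarray(self.ideal_foot_position).shape != (2,):
            raise TrialValidationError("ideal_foot_position must be a 2-vector (ML, AP)")
        return self


def _mirror_plate(p: ForcePlateSeries) -> ForcePlateSeries:
    force = p.force.copy()
    force[:, 0] = -force[:, 0]
    cop = None
    if p.cop is not None:
        cop = p.cop.copy()
        cop[:, 0] = -cop[:, 0]
    return ForcePlateSeries(time=p.time.copy(), force=force, cop=cop, plate_side=p.plate_side)


def reflect_to_right(trial: Trial) -> Trial:
    """Return the trial as a canonical right-sided step.

    Left-sided trials are reflected about the laboratory AP axis: all ML
    components (forces, CoP, marker x, ideal foot position x) are negated
    and the side is relabelled ``right``.  Right-sided trials are returned
    unchanged, so the operation is idempotent on its output.
    """
    if trial.side == "right":
        return trial
    feet = {}
    for foot, pos in trial.markers.feet.items():
        pos = pos.copy()
        pos[:, :, 0] = -pos[:, :, 0]
        feet[foot] = pos
    ideal = np.asarray(trial.ideal_foot_position, dtype=float).copy()
    ideal[0] = -ideal[0]
    return Trial(
        trial_id=trial.trial_id,
        subject=trial.subject,
        side="right",
        condition=trial.condition,
        initial_target=trial.initial_target,
        final_target=trial.final_target,
        illumination_time=trial.illumination_time,
        jump_command_time=trial.jump_command_time,
        plates={k: _mirror_plate(v) for k, v in trial.plates.items()},
        markers=MarkerSeries(time=trial.markers.time.copy(), feet=feet),
        ideal_foot_position=ideal,
    )
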