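"""Trial bundle reader/writer.

A trial is stored as a directory of plain-text files::

    <trial_id>/meta.yaml          metadata (schema-versioned)
    <trial_id>/force_stepping.csv t,fx,fy,fz,copx,copy   (1000 Hz typical)
    <trial_id>/force_trailing.csv t,fx,fy,fz,copx,copy
    <trial_id>/markers.csv        t + 18 position columns (200 Hz typical)

Marker columns are ``<foot>_<marker>_<axis>`` with foot in
(stepping, trailing), marker in (hallux, mt1_base, mt5_head) and axis in
(x, y, z).  Floats are written with 12 significant digits, which makes
write/read round trips exact to well below 1e-9 relative error and two
writes of the same trial byte-identical.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (MARKER_NAMES, ForcePlateSeries, MarkerSeries, SubjectInfo,
                   Trial, TrialValidationError)

__all__ = ["read_trial", "write_trial", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1

_FORCE_COLS = ["t", "fx", "fy", "fz", "copx", "copy"]
_AXES = ("x", "y", "z")


def _marker_cols() -> list[str]:
    return ["t"] + [f"{foot}_{m}_{ax}" for foot in ("stepping", "trailing")
                    for m in MARKER_NAMES for ax in _AXES]


def _write_csv(path: Path, header: list[str], data: np.ndarray) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(",".join(header) + "\n")
        np.savetxt(fh, data, fmt="%.12g", delimiter=",")


def write_trial(trial: Trial, root) -> Path:
    """Write a validated trial bundle under ``root/<trial_id>``; returns the path."""
    trial.validate()
    out = Path(root) / trial.trial_id
    out.mkdir(parents=True, exist_ok=True)

    meta = {
        "schema_version": SCHEMA_VERSION,
        "trial_id": trial.trial_id,
        "subject": {"subject_id": trial.subject.subject_id,
                    "mass": float(trial.subject.mass),
                    "dominant_side": trial.subject.dominant_side},
        "side": trial.side,
        "condition": trial.condition,
        "initial_target": trial.initial_target,
        "final_target": trial.final_target,
        "illumination_time": float(trial.illumination_time),
        "jump_command_time": (None if trial.jump_command_time is None
                              else float(trial.jump_command_time)),
        "ideal_foot_position": [float(v) for v in trial.ideal_foot_position],
        "fs_force": float(trial.plates["stepping"].fs),
        "fs_marker": float(trial.markers.fs),
    }
    with open(out / "meta.yaml", "w", newline="\n") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True, default_flow_style=False)

    for side in ("stepping", "trailing"):
        p = trial.plates[side]
        cop = p.cop if p.cop is not None else np.full((len(p.time), 2), np.nan)
        _write_csv(out / f"force_{side}.csv", _FORCE_COLS,
                   np.column_stack([p.time, p.force, cop]))

    m = trial.markers
    blocks = [m.time]
    for foot in ("stepping", "trailing"):
        blocks.append(m.feet[foot].reshape(len(m.time), 9))
    _write_csv(out / "markers.csv", _marker_cols(), np.column_stack(blocks))
    return out


def _read_csv(path: Path, expected_cols: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise TrialValidationError(f"missing bundle file: {path.name}")
    df = pd.read_csv(path)
    if list(df.columns) != expected_cols:
        raise TrialValidationError(
            f"{path.name}: expected columns {expected_cols}, found {list(df.columns)}")
    if df.isna().all(axis=None):
        raise TrialValidationError(f"{path.name}: no data rows")
    return df


def read_trial(path) -> Trial:
    """Read a trial bundle written by :func:`write_trial` and validate it."""
    path = Path(path)
    meta_path = path / "meta.yaml"
    if not meta_path.exists():
        raise TrialValidationError(f"missing bundle file: meta.yaml (in {path})")
    with open(meta_path) as fh:
        try:
            meta = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise TrialValidationError(f"meta.yaml is not valid YAML: {exc}") from exc
    if not isinstance(meta, dict):
        raise TrialValidationError("meta.yaml: expected a mapping")
    version = meta.get("schema_version")
    if version != SCHEMA_VERSION:
        raise TrialValidationError(
            f"meta.yaml: unsupported schema_version {version!r} (expected {SCHEMA_VERSION})")
    required = ["trial_id", "subject", "side", "condition", "initial_target",
                "final_target", "illumination_time", "ideal_foot_position",
                "fs_force", "fs_marker"]
    for key in required:
        if key not in meta:
            raise TrialValidationError(f"meta.yaml: missing field {key!r}")
    sub = meta["subject"]
    for key in ("subject_id", "mass"):
        if key not in sub:
            raise TrialValidationError(f"meta.yaml: missing field subject.{key}")

    plates = {}
    for side in ("stepping", "trailing"):
        df = _read_csv(path / f"force_{side}.csv", _FORCE_COLS)
        cop = df[["copx", "copy"]].to_numpy(float)
        plates[side] = ForcePlateSeries(
            time=df["t"].to_numpy(float),
            force=df[["fx", "fy", "fz"]].to_numpy(float),
            cop=None if np.isnan(cop).all() else cop,
            plate_side=side,
        )

    mdf = _read_csv(path / "markers.csv", _marker_cols())
    n = len(mdf)
    feet = {foot: mdf.iloc[:, 1 + 9 * i:1 + 9 * (i + 1)].to_numpy(float).reshape(n, 3, 3)
            for i, foot in enumerate(("stepping", "trailing"))}
    markers = MarkerSeries(time=mdf["t"].to_numpy(float), feet=feet)

    trial = Trial(
        trial_id=str(meta["trial_id"]),
        subject=SubjectInfo(subject_id=str(sub["subject_id"]), mass=float(sub["mass"]),
                            dominant_side=sub.get("dominant_side", "right")),
        side=meta["side"],
        condition=meta["condition"],
        initial_target=meta["initial_target"],
        final_target=meta["final_target"],
        illumination_time=float(meta["illumination_time"]),
        jump_command_time=(None if meta.get("jump_command_time") is None
                           else float(meta["jump_command_time"])),
        plates=plates,
        markers=markers,
        ideal_foot_position=np.asarray(meta["ideal_foot_position"], dtype=float),
    ).validate()

    for side in ("stepping", "trailing"):
        fs = plates[side].fs
        if abs(fs - meta["fs_force"]) > 1e-3 * meta["fs_force"]:
            raise TrialValidationError(
                f"force_{side}.csv sampling rate {fs:.6g} Hz does not match "
                f"meta fs_force={meta['fs_force']:.6g} Hz")
    if abs(markers.fs - meta["fs_marker"]) > 1e-3 * meta["fs_marker"]:
        raise TrialValidationError(
            f"markers.csv sampling rate {markers.fs:.6g} Hz does not match "
            f"meta fs_marker={meta['fs_marker']:.6g} Hz")
    return trial


def iter_trial_dirs(root) -> list[Path]:
    """Sorted list of trial bundle directories under ``root``."""
    root = Path(root)
    return sorted(p.parent for p in root.glob("*/meta.yaml"))
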