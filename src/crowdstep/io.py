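"""Readers and writers for the trial file formats.

A trial is a directory of plain-text files sharing one clock:

* ``manifest.yaml`` — trial id, condition, order index, metronome tempo,
  corridor geometry and the pedestrian roster (``ped_id: group``).
* ``trajectories.csv`` — ``trial_id, ped_id, group, t_s, x_m, y_m`` with
  optional shoulder-marker columns ``lshoulder_x_m, lshoulder_y_m,
  rshoulder_x_m, rshoulder_y_m``.
* ``steps.csv`` (optional) — ``trial_id, ped_id, foot, strike_t_s``.
* ``imu.csv`` (optional) — ``trial_id, ped_id, foot, t_s, omega_ml_dps``.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .core import (
    CorridorGeometry,
    ImuTrace,
    PedestrianTrack,
    StepSeries,
    TrialDataset,
    ValidationError,
)

TRAJ_FILE = "trajectories.csv"
STEPS_FILE = "steps.csv"
IMU_FILE = "imu.csv"
MANIFEST_FILE = "manifest.yaml"

_SHOULDER_COLS = ["lshoulder_x_m", "lshoulder_y_m", "rshoulder_x_m", "rshoulder_y_m"]

# Slack on the corridor bounds check: tracking jitter at the walls.
_BOUNDS_TOL = 0.25


class ParseError(ValueError):
    """A file failed to parse; the message names file and offending row."""


def geometry_to_dict(g: CorridorGeometry) -> dict:
    d = dataclasses.asdict(g)
    d["central_window"] = list(g.central_window)
    return d


def geometry_from_dict(d: dict) -> CorridorGeometry:
    d = dict(d)
    if "central_window" in d:
        d["central_window"] = tuple(d["central_window"])
    return CorridorGeometry(**d)


def write_trial(ds: TrialDataset, out_dir: str | os.PathLike) -> list[Path]:
    """Write a trial directory; returns the list of files written.

    ``read_trial`` on the result reproduces ``ds`` to 1e-9.
    """
    if not ds.tracks:
        raise ValidationError("refusing to write a trial with no tracks")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    rows = []
    for pid in sorted(ds.tracks):
        tr = ds.tracks[pid]
        frame = {
            "trial_id": ds.trial_id,
            "ped_id": pid,
            "group": tr.group,
            "t_s": tr.t,
            "x_m": tr.xy[:, 0],
            "y_m": tr.xy[:, 1],
        }
        if tr.has_shoulders:
            frame["lshoulder_x_m"] = tr.shoulder_left[:, 0]
            frame["lshoulder_y_m"] = tr.shoulder_left[:, 1]
            frame["rshoulder_x_m"] = tr.shoulder_right[:, 0]
            frame["rshoulder_y_m"] = tr.shoulder_right[:, 1]
        rows.append(pd.DataFrame(frame))
    traj_path = out / TRAJ_FILE
    pd.concat(rows, ignore_index=True).to_csv(traj_path, index=False, float_format="%.12g")
    written.append(traj_path)

    if ds.steps:
        step_df = pd.concat(
            [
                pd.DataFrame(
                    {
                        "trial_id": ds.trial_id,
                        "ped_id": s.ped_id,
                        "foot": s.foot,
                        "strike_t_s": s.strikes,
                    }
                )
                for s in ds.steps
            ],
            ignore_index=True,
        )
        steps_path = out / STEPS_FILE
        step_df.to_csv(steps_path, index=False, float_format="%.12g")
        written.append(steps_path)

    if ds.imu:
        imu_df = pd.concat(
            [
                pd.DataFrame(
                    {
                        "trial_id": ds.trial_id,
                        "ped_id": tr.ped_id,
                        "foot": tr.foot,
                        "t_s": tr.t,
                        "omega_ml_dps": tr.omega_ml,
                    }
                )
                for tr in ds.imu
            ],
            ignore_index=True,
        )
        imu_path = out / IMU_FILE
        imu_df.to_csv(imu_path, index=False, float_format="%.12g")
        written.append(imu_path)

    manifest = {
        "trial_id": ds.trial_id,
        "condition": ds.condition,
        "order_index": int(ds.order_index),
        "tempo": float(ds.tempo),
        "geometry": geometry_to_dict(ds.geometry),
        "pedestrians": {pid: ds.tracks[pid].group for pid in sorted(ds.tracks)},
    }
    man_path = out / MANIFEST_FILE
    man_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    written.append(man_path)
    return written


def read_trial(
    trial_dir: str | os.PathLike, geometry: Optional[CorridorGeometry] = None
) -> TrialDataset:
    """Read and validate one trial directory.

    The manifest's geometry is used unless ``geometry`` overrides it.
    Raises :class:`ParseError` on malformed rows and
    :class:`~crowdstep.core.ValidationError` on invariant violations
    (non-monotonic time, duplicate samples, pedestrians missing from the
    manifest roster, out-of-corridor coordinates).
    """
    d = Path(trial_dir)
    man_path = d / MANIFEST_FILE
    if not man_path.exists():
        raise ParseError(f"{man_path}: manifest missing")
    manifest = yaml.safe_load(man_path.read_text())
    geom = geometry if geometry is not None else geometry_from_dict(manifest["geometry"])
    roster: dict[str, str] = {str(k): v for k, v in manifest["pedestrians"].items()}

    traj_path = d / TRAJ_FILE
    try:
        df = pd.read_csv(traj_path, dtype={"ped_id": str})
    except Exception as e:  # noqa: BLE001 - reraise with file context
        raise ParseError(f"{traj_path}: {e}") from e
    required = {"trial_id", "ped_id", "group", "t_s", "x_m", "y_m"}
    if not required.issubset(df.columns):
        raise ParseError(f"{traj_path}: missing columns {sorted(required - set(df.columns))}")
    for col in ("t_s", "x_m", "y_m"):
        bad = df.index[~np.isfinite(pd.to_numeric(df[col], errors="coerce"))]
        if len(bad):
            raise ParseError(f"{traj_path}: row {bad[0] + 2}: bad value in column {col}")

    tracks: dict[str, PedestrianTrack] = {}
    has_shoulders = all(c in df.columns for c in _SHOULDER_COLS)
    for pid, sub in df.groupby("ped_id", sort=True):
        pid = str(pid)
        if pid not in roster:
            raise ValidationError(f"{traj_path}: pedestrian {pid} absent from manifest roster")
        sub = sub.sort_values("t_s", kind="stable")
        t = sub["t_s"].to_numpy(float)
        if np.any(np.diff(t) == 0):
            raise ValidationError(f"{traj_path}: duplicate (ped_id, t) sample for {pid}")
        xy = sub[["x_m", "y_m"]].to_numpy(float)
        _check_bounds(pid, xy, geom)
        group = str(sub["group"].iloc[0])
        if group != roster[pid]:
            raise ValidationError(f"{traj_path}: group of {pid} disagrees with manifest")
        kwargs = {}
        if has_shoulders and sub[_SHOULDER_COLS].notna().all().all():
            kwargs["shoulder_left"] = sub[_SHOULDER_COLS[:2]].to_numpy(float)
            kwargs["shoulder_right"] = sub[_SHOULDER_COLS[2:]].to_numpy(float)
        tracks[pid] = PedestrianTrack(ped_id=pid, group=group, t=t, xy=xy, **kwargs)

    steps: list[StepSeries] = []
    steps_path = d / STEPS_FILE
    if steps_path.exists():
        sdf = pd.read_csv(steps_path, dtype={"ped_id": str})
        for (pid, foot), sub in sdf.groupby(["ped_id", "foot"], sort=True):
            steps.append(
                StepSeries(
                    ped_id=str(pid),
                    foot=str(foot),
                    strikes=np.sort(sub["strike_t_s"].to_numpy(float)),
                )
            )

    imu: list[ImuTrace] = []
    imu_path = d / IMU_FILE
    if imu_path.exists():
        idf = pd.read_csv(imu_path, dtype={"ped_id": str})
        for (pid, foot), sub in idf.groupby(["ped_id", "foot"], sort=True):
            sub = sub.sort_values("t_s", kind="stable")
            imu.append(
                ImuTrace(
                    ped_id=str(pid),
                    foot=str(foot),
                    t=sub["t_s"].to_numpy(float),
                    omega_ml=sub["omega_ml_dps"].to_numpy(float),
                )
            )

    return TrialDataset(
        trial_id=str(manifest["trial_id"]),
        condition=str(manifest["condition"]),
        geometry=geom,
        tracks=tracks,
        steps=steps,
        imu=imu,
        order_index=int(manifest.get("order_index", 0)),
        tempo=float(manifest.get("tempo", 120.0)),
    )


def _check_bounds(pid: str, xy: np.ndarray, geom: CorridorGeometry) -> None:
    y = xy[:, 1]
    x = xy[:, 0]
    if np.any(y < -_BOUNDS_TOL) or np.any(y > geom.meas_width + _BOUNDS_TOL):
        raise ValidationError(
            f"pedestrian {pid}: transverse coordinate outside corridor width "
            f"[0, {geom.meas_width}] m — check the x/y axis convention"
        )
    if np.any(x < geom.x_min - _BOUNDS_TOL) or np.any(x > geom.x_max + _BOUNDS_TOL):
        raise ValidationError(f"pedestrian {pid}: longitudinal coordinate outside corridor")
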