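"""Domain types and coordinate conventions for bidirectional-flow trials.

Conventions used throughout the package:

* ``x`` is the long axis of the corridor, in metres, increasing in the
  rightward group's direction of travel; the measurement area occupies
  ``x in [0, meas_length]``.
* ``y`` is the transverse axis, ``y in [0, meas_width]``.
* Times are seconds from the trial start signal; all data streams
  (trajectories at 30 Hz, inertial traces at 100 Hz) share one clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

RIGHTWARD = "rightward"
LEFTWARD = "leftward"
GROUPS = (RIGHTWARD, LEFTWARD)

FEET = ("left", "right")


class ValidationError(ValueError):
    """A dataset violates a structural invariant."""


@dataclass(frozen=True)
class CorridorGeometry:
    """Geometry of the experimental corridor.

    The corridor is a straight strip: a central measurement area flanked by
    buffer zones and waiting areas on both sides.  ``central_window`` is a
    square region centred in the measurement area used for lane counting.
    """

    meas_length: float = 10.0
    meas_width: float = 3.0
    central_window: tuple[float, float] = (3.0, 3.0)
    buffer_length: float = 1.2
    waiting_length: float = 8.4

    def __post_init__(self) -> None:
        for name in ("meas_length", "meas_width", "buffer_length", "waiting_length"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        wl, ww = self.central_window
        if wl <= 0 or ww <= 0 or wl > self.meas_length or ww > self.meas_width:
            raise ValidationError("central_window must be positive and fit inside the measurement area")

    @property
    def x_min(self) -> float:
        """Far end of the rightward group's waiting area."""
        return -(self.buffer_length + self.waiting_length)

    @property
    def x_max(self) -> float:
        return self.meas_length + self.buffer_length + self.waiting_length

    def inside_measurement(self, xy: np.ndarray) -> np.ndarray:
        """Boolean mask of positions inside the measurement area.

        ``xy`` has shape (..., 2).
        """
        x, y = xy[..., 0], xy[..., 1]
        return (x >= 0) & (x <= self.meas_length) & (y >= 0) & (y <= self.meas_width)

    def inside_central_window(self, xy: np.ndarray) -> np.ndarray:
        wl, ww = self.central_window
        cx, cy = self.meas_length / 2.0, self.meas_width / 2.0
        x, y = xy[..., 0], xy[..., 1]
        return (
            (x >= cx - wl / 2.0) & (x <= cx + wl / 2.0)
            & (y >= cy - ww / 2.0) & (y <= cy + ww / 2.0)
        )


@dataclass
class PedestrianTrack:
    """Timed 2-D positions of one pedestrian.

    ``t`` is strictly increasing (seconds); ``xy`` is an (n, 2) array of
    positions in metres.  Optional shoulder marker positions (left and right,
    each (n, 2), on the same time base) support shoulder-rotation analysis.
    """

    ped_id: str
    group: str
    t: np.ndarray
    xy: np.ndarray
    sample_rate: float = 30.0
    shoulder_left: Optional[np.ndarray] = None
    shoulder_right: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r} for {self.ped_id}")
        if self.t.ndim != 1 or self.xy.shape != (self.t.size, 2):
            raise ValidationError(f"track {self.ped_id}: t and xy shapes inconsistent")
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise ValidationError(f"track {self.ped_id}: times not strictly increasing")
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.xy)):
            raise ValidationError(f"track {self.ped_id}: non-finite samples")

    @property
    def has_shoulders(self) -> bool:
        return self.shoulder_left is not None and self.shoulder_right is not None

    def position_at(self, t: float) -> np.ndarray:
        """Position at the nearest sample time (no interpolation)."""
        return self.xy[self.nearest_index(t)]

    def nearest_index(self, t: float) -> int:
        i = int(np.searchsorted(self.t, t))
        if i == 0:
            return 0
        if i >= self.t.size:
            return self.t.size - 1
        return i if (self.t[i] - t) < (t - self.t[i - 1]) else i - 1


@dataclass
class StepSeries:
    """Ordered heel-strike times for one foot of one pedestrian."""

    ped_id: str
    foot: str
    strikes: np.ndarray

    def __post_init__(self) -> None:
        self.strikes = np.asarray(self.strikes, dtype=float)
        if self.foot not in FEET:
            raise ValidationError(f"unknown foot {self.foot!r}")
        if self.strikes.size and np.any(np.diff(self.strikes) <= 0):
            raise ValidationError(
                f"step series {self.ped_id}/{self.foot}: strikes not strictly increasing"
            )

    @property
    def durations(self) -> np.ndarray:
        """Step durations: time between consecutive heel strikes of this foot."""
        return np.diff(self.strikes)

    def duration_at(self, k: int) -> float:
        """Step duration attributed to strike k.

        The backward interval ``strikes[k] - strikes[k-1]``; the first strike
        is assigned its forward interval so every strike of a series with at
        least two strikes carries a duration.
        """
        if self.strikes.size < 2:
            raise ValueError("need at least two strikes for a duration")
        if k == 0:
            return float(self.strikes[1] - self.strikes[0])
        return float(self.strikes[k] - self.strikes[k - 1])


@dataclass
class ImuTrace:
    """Medio-lateral angular velocity of one foot-mounted inertial sensor.

    ``events_hint`` optionally lists (toe_off_s, heel_strike_s) intervals; when
    present, heel-strike detection is restricted to those windows.
    """

    ped_id: str
    foot: str
    t: np.ndarray
    omega_ml: np.ndarray
    sample_rate: float = 100.0
    events_hint: Optional[list[tuple[float, float]]] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.omega_ml = np.asarray(self.omega_ml, dtype=float)
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be > 0")
        if self.t.size != self.omega_ml.size or self.t.size < 2:
            raise ValidationError("trace needs >= 2 aligned samples")


@dataclass
class TrialDataset:
    """All data streams of one bidirectional-flow trial."""

    trial_id: str
    condition: str  # "NO_CUE" or "CUE"
    geometry: CorridorGeometry
    tracks: dict[str, PedestrianTrack]
    steps: list[StepSeries] = field(default_factory=list)
    imu: list[ImuTrace] = field(default_factory=list)
    order_index: int = 0
    tempo: float = 120.0

    def __post_init__(self) -> None:
        if self.condition not in ("NO_CUE", "CUE"):
            raise ValidationError(f"unknown condition {self.condition!r}")
        for s in self.steps:
            if s.ped_id not in self.tracks:
                raise ValidationError(f"step series for unknown pedestrian {s.ped_id}")
        for tr in self.imu:
            if tr.ped_id not in self.tracks:
                raise ValidationError(f"IMU trace for unknown pedestrian {tr.ped_id}")

    @property
    def groups_present(self) -> set[str]:
        return {tr.group for tr in self.tracks.values()}

    def group_ids(self, group: str) -> list[str]:
        return sorted(p for p, tr in self.tracks.items() if tr.group == group)

    @property
    def instrumented_ids(self) -> list[str]:
        return sorted({s.ped_id for s in self.steps})

    def steps_for(self, ped_id: str) -> dict[str, StepSeries]:
        return {s.foot: s for s in self.steps if s.ped_id == ped_id}

    def merged_strikes(self, ped_id: str) -> np.ndarray:
        """All heel strikes of a pedestrian, both feet merged and sorted."""
        per_foot = [s.strikes for s in self.steps if s.ped_id == ped_id]
        if not per_foot:
            return np.empty(0)
        return np.sort(np.concatenate(per_foot))

    @property
    def time_span(self) -> tuple[float, float]:
        t0 = min(tr.t[0] for tr in self.tracks.values())
        t1 = max(tr.t[-1] for tr in self.tracks.values())
        return float(t0), float(t1)


def entry_exit_times(
    track: PedestrianTrack, geometry: CorridorGeometry
) -> Optional[tuple[float, float]]:
    """First and last sample times with the pedestrian inside the measurement area.

    Returns ``None`` if the track never enters the area.
    """
    inside = geometry.inside_measurement(track.xy)
    if not inside.any():
        return None
    idx = np.flatnonzero(inside)
    return float(track.t[idx[0]]), float(track.t[idx[-1]])
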