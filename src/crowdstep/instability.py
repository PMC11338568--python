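"""Structural-instability and lateral-exploration metrics.

Time to potential collision (tau): the smallest extrapolation horizon on a
0.03 s grid at which two cross-group pedestrians, continuing at their current
velocities, come within the collision threshold (0.6 m); the corresponding
distance is ``lambda = tau * (|v_i| + |v_j|) / 2``.  Curvature measures the
per-second turning of the unit velocity vector; the transverse mean squared
displacement and shoulder rotation quantify lateral exploration and evasive
body turning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import CorridorGeometry, PedestrianTrack, TrialDataset, ValidationError, entry_exit_times
from .pairing import StageBoundaries, _positions_at

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RiskParams:
    """Extrapolation grid (tau_step..tau_max in steps of tau_step) and
    collision threshold delta_c (m).  ``mean_mode`` selects how trial means
    aggregate: over all finite pair-frame records, or over per-pedestrian
    minima."""

    tau_step: float = 0.03
    tau_max: float = 9.0
    delta_c: float = 0.6
    velocity_dt: float = 1.0
    mean_mode: str = "records"  # or "ped_min"

    def __post_init__(self) -> None:
        if self.tau_step <= 0 or self.tau_max <= self.tau_step:
            raise ValidationError("tau grid must be increasing and positive")
        if self.delta_c <= 0:
            raise ValidationError("delta_c must be > 0")
        if self.mean_mode not in ("records", "ped_min"):
            raise ValidationError("mean_mode must be 'records' or 'ped_min'")

    @property
    def n_grid(self) -> int:
        return int(round(self.tau_max / self.tau_step))

    @property
    def tau_grid(self) -> np.ndarray:
        return np.arange(1, self.n_grid + 1) * self.tau_step


@dataclass
class RiskSeries:
    trial_id: str
    records: pd.DataFrame  # columns t, i, j, tau_s, lambda_m
    mean_tau: float
    mean_lambda: float


@dataclass
class CurvatureSeries:
    ped_id: str
    samples: np.ndarray  # (n, 2) columns t, kappa


@dataclass
class TransverseMSD:
    condition: str
    t: np.ndarray
    d: np.ndarray


@dataclass
class ShoulderRotation:
    per_ped: dict[str, float]
    trial_mean: float


# ---------------------------------------------------------------------------
# collision risk


def _grid_tau(t1: np.ndarray, t2: np.ndarray, params: RiskParams) -> np.ndarray:
    """Smallest grid multiple of tau_step inside [t1, t2], NaN when none.

    [t1, t2] is the interval over which the extrapolated distance stays at or
    below delta_c; the returned value is an exact grid element.
    """
    lo = np.maximum(t1, params.tau_step)
    n = np.ceil(lo / params.tau_step - 1e-9)
    tau = n * params.tau_step
    ok = (tau <= t2 + 1e-12) & (n <= params.n_grid) & np.isfinite(t1)
    return np.where(ok, tau, np.nan)


def _tau_pairwise(d0: np.ndarray, dv: np.ndarray, params: RiskParams) -> np.ndarray:
    """Vectorized tau for relative positions d0 and velocities dv, (n, 2)."""
    a = np.einsum("ij,ij->i", dv, dv)
    b = 2.0 * np.einsum("ij,ij->i", d0, dv)
    c = np.einsum("ij,ij->i", d0, d0) - params.delta_c**2
    t1 = np.full(a.shape, np.nan)
    t2 = np.full(a.shape, np.nan)
    static = a < 1e-12
    # Static relative motion: within threshold now or never.
    t1[static & (c <= 0)] = 0.0
    t2[static & (c <= 0)] = np.inf
    moving = ~static
    disc = b[moving] ** 2 - 4.0 * a[moving] * c[moving]
    has_roots = disc >= 0
    sq = np.sqrt(np.where(has_roots, disc, 0.0))
    r1 = (-b[moving] - sq) / (2.0 * a[moving])
    r2 = (-b[moving] + sq) / (2.0 * a[moving])
    t1m = np.where(has_roots, r1, np.nan)
    t2m = np.where(has_roots, r2, np.nan)
    # Interval entirely in the past: the pair is receding.
    past = has_roots & (t2m < 0)
    t1m[past] = np.nan
    t2m[past] = np.nan
    t1[moving] = np.clip(t1m, 0.0, None)
    t2[moving] = t2m
    return _grid_tau(t1, t2, params)


def time_to_collision(
    ds: TrialDataset,
    t: float,
    i: str,
    j: str,
    params: RiskParams = RiskParams(),
) -> Optional[tuple[float, float]]:
    """(tau, lambda) for cross-group pedestrians i and j at time t, or None.

    Velocities are backward differences over ``velocity_dt``; None is
    returned (and logged) when either velocity is undefined, and when no grid
    horizon brings the pair within delta_c.
    """
    if ds.tracks[i].group == ds.tracks[j].group:
        raise ValidationError("time_to_collision applies to cross-group pairs")
    dt = params.velocity_dt
    t_lo = max(ds.tracks[i].t[0], ds.tracks[j].t[0])
    if t - dt < t_lo - 1e-9:
        log.debug("velocity undefined at t=%.2f for (%s, %s)", t, i, j)
        return None
    ri = ds.tracks[i].position_at(t)
    rj = ds.tracks[j].position_at(t)
    vi = (ri - ds.tracks[i].position_at(t - dt)) / dt
    vj = (rj - ds.tracks[j].position_at(t - dt)) / dt
    tau = _tau_pairwise((ri - rj)[None, :], (vi - vj)[None, :], params)[0]
    if not np.isfinite(tau):
        return None
    lam = tau * (np.linalg.norm(vi) + np.linalg.norm(vj)) / 2.0
    return float(tau), float(lam)


def trial_risk_means(ds: TrialDataset, params: RiskParams = RiskParams()) -> RiskSeries:
    """tau and lambda for every cross-group pair at every trajectory sample.

    Only frames where both pedestrians are inside the measurement area and
    have defined velocities contribute.  Pairs with no qualifying horizon
    contribute nothing.
    """
    ped_ids = sorted(ds.tracks)
    groups = np.array([ds.tracks[p].group for p in ped_ids])
    cross_i, cross_j = np.nonzero(
        (groups[:, None] == "rightward") & (groups[None, :] == "leftward")
    )
    if cross_i.size == 0:
        raise ValidationError("no cross-group pairs in trial")
    rate = max(tr.sample_rate for tr in ds.tracks.values())
    t_start, t_end = ds.time_span
    grid = np.arange(t_start + params.velocity_dt, t_end + 0.5 / rate, 1.0 / rate)
    ids, pos, present = _positions_at(ds, grid)
    assert ids == ped_ids
    _, pos_prev, present_prev = _positions_at(ds, grid - params.velocity_dt)
    vel = (pos - pos_prev) / params.velocity_dt
    inside = ds.geometry.inside_measurement(pos) & present & present_prev

    recs = []
    for s in range(grid.size):
        ok = inside[s, cross_i] & inside[s, cross_j]
        if not ok.any():
            continue
        ii, jj = cross_i[ok], cross_j[ok]
        d0 = pos[s, ii] - pos[s, jj]
        dv = vel[s, ii] - vel[s, jj]
        tau = _tau_pairwise(d0, dv, params)
        fin = np.isfinite(tau)
        if not fin.any():
            continue
        speed = (np.linalg.norm(vel[s, ii[fin]], axis=1) + np.linalg.norm(vel[s, jj[fin]], axis=1)) / 2.0
        for a, b, tv, lv in zip(ii[fin], jj[fin], tau[fin], tau[fin] * speed):
            recs.append((grid[s], ped_ids[a], ped_ids[b], tv, lv))
    records = pd.DataFrame(recs, columns=["t", "i", "j", "tau_s", "lambda_m"])
    if records.empty:
        return RiskSeries(ds.trial_id, records, float("nan"), float("nan"))
    if params.mean_mode == "records":
        mt, ml = float(records["tau_s"].mean()), float(records["lambda_m"].mean())
    else:
        per_ped = pd.concat(
            [records[["i", "tau_s", "lambda_m"]].rename(columns={"i": "p"}),
             records[["j", "tau_s", "lambda_m"]].rename(columns={"j": "p"})]
        )
        mins = per_ped.groupby("p")[["tau_s", "lambda_m"]].min()
        mt, ml = float(mins["tau_s"].mean()), float(mins["lambda_m"].mean())
    return RiskSeries(ds.trial_id, records, mt, ml)


# ---------------------------------------------------------------------------
# curvature


def curvature(track: PedestrianTrack, dt: float = 1.0) -> CurvatureSeries:
    """kappa(t) = |e(t + dt) - e(t)| / dt on a dt-spaced grid.

    ``e`` is the unit vector of the backward-difference velocity
    ``v(t) = r(t) - r(t - dt)``.  Evaluation points where either velocity
    vanishes are skipped and logged; a track shorter than 2*dt yields an
    empty series.
    """
    t0, t1 = track.t[0], track.t[-1]
    rows = []
    n_skipped = 0
    t = t0 + dt
    while t + dt <= t1 + 1e-9:
        r_prev = track.position_at(t - dt)
        r_now = track.position_at(t)
        r_next = track.position_at(t + dt)
        v1 = r_now - r_prev
        v2 = r_next - r_now
        n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if n1 < 1e-12 or n2 < 1e-12:
            n_skipped += 1
        else:
            kappa = np.linalg.norm(v2 / n2 - v1 / n1) / dt
            rows.append((t, kappa))
        t += dt
    if n_skipped:
        log.debug("track %s: skipped %d zero-velocity curvature samples", track.ped_id, n_skipped)
    return CurvatureSeries(
        ped_id=track.ped_id, samples=np.array(rows) if rows else np.empty((0, 2))
    )


def stage_mean_curvature(
    ds: TrialDataset, stages: StageBoundaries, dt: float = 1.0
) -> dict[int, float]:
    """Mean curvature over all pedestrians' samples within each stage.

    Stage 3 is omitted when undefined; stages whose span holds no curvature
    samples map to NaN.
    """
    series = [curvature(tr, dt) for tr in ds.tracks.values()]
    all_samples = np.vstack([s.samples for s in series if s.samples.size])
    out: dict[int, float] = {}
    for k, (lo, hi) in stages.stage_intervals.items():
        sel = (all_samples[:, 0] >= lo) & (all_samples[:, 0] < hi)
        out[k] = float(all_samples[sel, 1].mean()) if sel.any() else float("nan")
    return out


# ---------------------------------------------------------------------------
# transverse MSD


def transverse_msd(trials: Sequence[TrialDataset]) -> TransverseMSD:
    """Mean squared transverse displacement from measurement-area entry.

    Each pedestrian's clock is zeroed at its first in-area sample; the
    average runs over all pedestrians of all trials and is reported up to
    the shortest in-area duration among them.
    """
    curves = []
    rate = None
    for ds in trials:
        for tr in ds.tracks.values():
            ee = entry_exit_times(tr, ds.geometry)
            if ee is None:
                continue
            i0 = int(np.searchsorted(tr.t, ee[0]))
            i1 = int(np.searchsorted(tr.t, ee[1], side="right"))
            y = tr.xy[i0:i1, 1]
            curves.append((y - y[0]) ** 2)
            rate = tr.sample_rate
    if not curves:
        raise ValidationError("no pedestrian enters the measurement area")
    n = min(c.size for c in curves)
    d = np.mean([c[:n] for c in curves], axis=0)
    t = np.arange(n) / rate
    cond = trials[0].condition
    return TransverseMSD(condition=cond, t=t, d=d)


# ---------------------------------------------------------------------------
# shoulder rotation


def shoulder_rotation(ds: TrialDataset) -> ShoulderRotation:
    """Mean absolute shoulder-line angle from the transverse (y) axis.

    The angle of the left-to-right shoulder segment is folded into
    [0, pi/2]; frames are averaged per pedestrian, pedestrians per trial.
    """
    missing = [p for p, tr in ds.tracks.items() if not tr.has_shoulders]
    per_ped = {}
    for pid, tr in ds.tracks.items():
        if not tr.has_shoulders:
            continue
        seg = tr.shoulder_right - tr.shoulder_left
        angle = np.arctan2(np.abs(seg[:, 0]), np.abs(seg[:, 1]))
        per_ped[pid] = float(np.mean(angle))
    if not per_ped:
        raise ValidationError(f"no shoulder markers present (missing for: {sorted(missing)})")
    return ShoulderRotation(per_ped=per_ped, trial_mean=float(np.mean(list(per_ped.values()))))
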