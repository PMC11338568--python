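"""Following relation, pair identification, lane clustering and trial stages.

Pedestrian *i* follows *j* at time *t* when *i*'s position at *t* is within
``dr`` of *j*'s position at ``t - dt`` (defaults dt = 1 s, dr = 0.7 m).  The
undirected transitive closure of this relation at a given instant partitions
the crowd into lanes; the pedestrian each walker follows longest over a trial
defines its pair for the synchronization analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import CorridorGeometry, StepSeries, TrialDataset, ValidationError, entry_exit_times

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FollowParams:
    dt: float = 1.0
    dr: float = 0.7
    same_group_only: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.dr <= 0:
            raise ValidationError("dt and dr must be > 0")


@dataclass
class FollowGraph:
    """Directed follower -> predecessor edges at one instant."""

    time: float
    edges: list[tuple[str, str]]

    def predecessors_of(self, ped_id: str) -> list[str]:
        return [j for i, j in self.edges if i == ped_id]


@dataclass
class PairAssignment:
    """A follower, the pedestrian it followed longest, and matched strikes.

    ``matches`` is an (n, 4) array with columns ``t_p, t_f, dt_p, dt_f``:
    each predecessor heel strike inside the measurement area, the nearest
    strike of the mapped follower foot, and the two step durations.
    """

    follower_id: str
    predecessor_id: str
    followed_duration: float
    foot_map: dict[str, str]
    matches: np.ndarray


@dataclass
class LanePartition:
    time: float
    clusters: list[frozenset[str]]
    lane_count_central: int


@dataclass
class StageBoundaries:
    """The six instants bounding the five stages of lane formation.

    t0 first entry, t1 first crossing of the two groups' front runners,
    t2 first exit, t3 last entry, t4 last crossing of any cross-group pair,
    t5 last exit.  When the first exit precedes the last entry is violated
    (t2 > t3) the full-bidirectional-flow stage does not exist.
    """

    t0: float
    t1: float
    t2: float
    t3: float
    t4: float
    t5: float

    @property
    def stage3_defined(self) -> bool:
        return self.t2 <= self.t3

    @property
    def stage_intervals(self) -> dict[int, tuple[float, float]]:
        out = {1: (self.t0, self.t1), 2: (self.t1, self.t2), 4: (self.t3, self.t4), 5: (self.t4, self.t5)}
        if self.stage3_defined:
            out[3] = (self.t2, self.t3)
        return dict(sorted(out.items()))


# ---------------------------------------------------------------------------
# position lookup


def _positions_at(ds: TrialDataset, times: np.ndarray):
    """Nearest-sample positions for every pedestrian at each query time.

    Returns (ped_ids, pos, present): ``pos`` has shape (n_times, n_peds, 2);
    ``present`` marks query times within each track's sampled span (half a
    sample period of slack).
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    ped_ids = sorted(ds.tracks)
    pos = np.full((times.size, len(ped_ids), 2), np.nan)
    present = np.zeros((times.size, len(ped_ids)), dtype=bool)
    for j, pid in enumerate(ped_ids):
        tr = ds.tracks[pid]
        idx = np.searchsorted(tr.t, times)
        idx = np.clip(idx, 1, tr.t.size - 1)
        left_closer = (times - tr.t[idx - 1]) < (tr.t[idx] - times)
        idx = np.where(left_closer, idx - 1, idx)
        idx = np.where(times <= tr.t[0], 0, idx)
        pos[:, j, :] = tr.xy[idx]
        slack = 0.5 / tr.sample_rate
        present[:, j] = (times >= tr.t[0] - slack) & (times <= tr.t[-1] + slack)
    return ped_ids, pos, present


def _adjacency(
    pos_now: np.ndarray,
    pos_before: np.ndarray,
    present_now: np.ndarray,
    present_before: np.ndarray,
    same_group: np.ndarray,
    params: FollowParams,
) -> np.ndarray:
    """Boolean matrix A[i, j] = i follows j (positions of one instant)."""
    diff = pos_now[:, None, :] - pos_before[None, :, :]
    dist2 = np.einsum("ijk,ijk->ij", diff, diff)
    a = dist2 < params.dr**2
    a &= present_now[:, None] & present_before[None, :]
    np.fill_diagonal(a, False)
    if params.same_group_only:
        a &= same_group
    return a


def _same_group_matrix(ds: TrialDataset, ped_ids: list[str]) -> np.ndarray:
    g = np.array([ds.tracks[p].group for p in ped_ids])
    return g[:, None] == g[None, :]


# ---------------------------------------------------------------------------
# operations


def following(ds: TrialDataset, t: float, params: FollowParams = FollowParams()) -> FollowGraph:
    """The follower -> predecessor graph at time ``t``."""
    t_start, _ = ds.time_span
    if t - params.dt < t_start - 1e-9:
        warnings.warn(f"t - dt = {t - params.dt:.3f} s precedes trial start; empty graph", stacklevel=2)
        return FollowGraph(time=t, edges=[])
    ped_ids, pos, present = _positions_at(ds, np.array([t, t - params.dt]))
    a = _adjacency(pos[0], pos[1], present[0], present[1], _same_group_matrix(ds, ped_ids), params)
    ii, jj = np.nonzero(a)
    return FollowGraph(time=t, edges=[(ped_ids[i], ped_ids[j]) for i, j in zip(ii, jj)])


def followed_time_matrix(
    ds: TrialDataset, params: FollowParams = FollowParams()
) -> tuple[list[str], np.ndarray]:
    """Total time (s) pedestrian i spends following j over the trial."""
    t_start, t_end = ds.time_span
    rate = max(tr.sample_rate for tr in ds.tracks.values())
    h = 1.0 / rate
    grid = np.arange(t_start + params.dt, t_end + h / 2, h)
    if grid.size == 0:
        raise ValidationError("trial too short for the following window dt")
    ped_ids, pos_now, present_now = _positions_at(ds, grid)
    _, pos_before, present_before = _positions_at(ds, grid - params.dt)
    same = _same_group_matrix(ds, ped_ids)
    total = np.zeros((len(ped_ids), len(ped_ids)))
    for s in range(grid.size):
        total += _adjacency(pos_now[s], pos_before[s], present_now[s], present_before[s], same, params)
    return ped_ids, total * h


def match_step_series(
    pred_steps: dict[str, StepSeries],
    foll_steps: dict[str, StepSeries],
    window: tuple[float, float],
    policy: str = "anatomical",
) -> tuple[dict[str, str], np.ndarray]:
    """Match each predecessor heel strike to the nearest follower strike.

    ``policy`` selects the foot bijection.  The default, ``"anatomical"``,
    compares like feet (left-left, right-right): it is phase-neutral, so a
    stable half-cycle offset shows up as anti-phase rather than being folded
    into in-phase by re-crossing the feet, and independent gaits yield a
    uniform phase-shift distribution.  ``"nearest"`` instead picks the
    bijection (uncrossed versus crossed) with the smaller mean absolute
    nearest-strike offset over the predecessor's strikes inside ``window``
    (ties go uncrossed); note this caps offsets at a quarter cycle and makes
    anti-phase unobservable by construction.  Follower strikes may be matched
    to more than one predecessor strike; duplicates are logged.

    Returns the foot map and an (n, 4) array ``[t_p, t_f, dt_p, dt_f]``.
    """
    for d in (pred_steps, foll_steps):
        if set(d) != {"left", "right"}:
            raise ValidationError("both feet required for step matching")
    if policy not in ("anatomical", "nearest"):
        raise ValidationError(f"unknown foot-map policy {policy!r}")
    lo, hi = window
    bijections = ({"left": "left", "right": "right"}, {"left": "right", "right": "left"})
    if policy == "anatomical":
        bijections = bijections[:1]
    candidates = []
    for foot_map in bijections:
        rows = []
        offsets = []
        ok = True
        for pf, ff in foot_map.items():
            ps, fs = pred_steps[pf], foll_steps[ff]
            if ps.strikes.size < 2 or fs.strikes.size < 2:
                ok = False
                break
            # Only predecessor strikes while the follower is also stepping
            # (one stride of slack) have a meaningful nearest counterpart.
            stride = float(np.median(np.diff(fs.strikes)))
            lo_f = max(lo, fs.strikes[0] - stride)
            hi_f = min(hi, fs.strikes[-1] + stride)
            sel = np.flatnonzero((ps.strikes >= lo_f) & (ps.strikes <= hi_f))
            for k in sel:
                t_p = ps.strikes[k]
                m = int(np.argmin(np.abs(fs.strikes - t_p)))
                t_f = fs.strikes[m]
                rows.append((t_p, t_f, ps.duration_at(k), fs.duration_at(m), ff, m))
                offsets.append(abs(t_f - t_p))
        if ok and rows:
            candidates.append((float(np.mean(offsets)), foot_map, rows))
    if not candidates:
        return {}, np.empty((0, 4))
    candidates.sort(key=lambda c: c[0])
    _, foot_map, rows = candidates[0]
    used = [(ff, m) for *_xs, ff, m in rows]
    if len(set(used)) < len(used):
        log.debug("follower strikes reused for multiple predecessor strikes (%d duplicates)",
                  len(used) - len(set(used)))
    rows.sort(key=lambda r: r[0])
    return foot_map, np.array([r[:4] for r in rows], dtype=float)


def identify_pairs(
    ds: TrialDataset,
    params: FollowParams = FollowParams(),
    foot_map_policy: str = "anatomical",
) -> list[PairAssignment]:
    """Pair each instrumented pedestrian with the one it followed longest.

    Followers with step data but no positive followed time are excluded and
    logged.  Followed-duration ties break toward the lower predecessor id.
    Predecessor strikes are restricted to the predecessor's first-to-last
    presence in the measurement area.
    """
    ped_ids, total = followed_time_matrix(ds, params)
    index = {p: k for k, p in enumerate(ped_ids)}
    followers = ds.instrumented_ids or ped_ids
    pairs: list[PairAssignment] = []
    for f in followers:
        row = total[index[f]]
        best = float(row.max())
        if best <= 0:
            log.info("pedestrian %s never follows anyone; no pair", f)
            continue
        if np.count_nonzero(row == best) > 1:
            log.info("followed-duration tie for %s; lower ped_id wins", f)
        j = ped_ids[int(np.argmax(row))]  # ped_ids sorted: argmax = lowest id on ties
        pred_steps = ds.steps_for(j)
        foll_steps = ds.steps_for(f)
        if set(pred_steps) != {"left", "right"} or set(foll_steps) != {"left", "right"}:
            log.info("pair (%s, %s) lacks two-foot step data; skipped", f, j)
            continue
        window = entry_exit_times(ds.tracks[j], ds.geometry)
        if window is None:
            log.info("predecessor %s never enters the measurement area; pair skipped", j)
            continue
        foot_map, matches = match_step_series(pred_steps, foll_steps, window, foot_map_policy)
        if matches.size == 0:
            continue
        pairs.append(
            PairAssignment(
                follower_id=f,
                predecessor_id=j,
                followed_duration=best,
                foot_map=foot_map,
                matches=matches,
            )
        )
    return pairs


def lane_partition(
    ds: TrialDataset, t: float, params: FollowParams = FollowParams()
) -> LanePartition:
    """Lanes at time ``t``: connected components of the undirected following
    relation over pedestrians inside the measurement area."""
    ped_ids, pos, present = _positions_at(ds, np.array([t, t - params.dt]))
    inside = ds.geometry.inside_measurement(pos[0]) & present[0]
    a = _adjacency(pos[0], pos[1], present[0], present[1], _same_group_matrix(ds, ped_ids), params)
    keep = np.flatnonzero(inside)
    clusters, central = _components(ds.geometry, ped_ids, pos[0], a, keep)
    return LanePartition(time=t, clusters=clusters, lane_count_central=central)


def _components(geometry, ped_ids, pos, adj, keep) -> tuple[list[frozenset[str]], int]:
    """Union-find over the symmetrized adjacency restricted to ``keep``."""
    parent = {int(i): int(i) for i in keep}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    sym = adj | adj.T
    for i in keep:
        for j in keep:
            if j > i and sym[i, j]:
                ri, rj = find(int(i)), find(int(j))
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, set[int]] = {}
    for i in keep:
        groups.setdefault(find(int(i)), set()).add(int(i))
    clusters = [frozenset(ped_ids[i] for i in members) for members in groups.values()]
    in_central = geometry.inside_central_window(pos)
    central = sum(1 for members in groups.values() if any(in_central[i] for i in members))
    return clusters, central


def mean_lane_count(
    ds: TrialDataset, stages: StageBoundaries, params: FollowParams = FollowParams()
) -> float:
    """Central-window lane count averaged over the lane-bearing stages (2-4).

    Samples on the trajectory grid falling in stage 2, stage 3 (when defined)
    and stage 4 contribute; returns NaN when that span holds no samples.
    """
    rate = max(tr.sample_rate for tr in ds.tracks.values())
    h = 1.0 / rate
    t_start, t_end = ds.time_span
    grid = np.arange(t_start, t_end + h / 2, h)
    mask = np.zeros(grid.size, dtype=bool)
    for k, (lo, hi) in stages.stage_intervals.items():
        if k in (2, 3, 4):
            mask |= (grid >= lo) & (grid < hi)
    times = grid[mask & (grid - params.dt >= t_start - 1e-9)]
    if times.size == 0:
        return float("nan")
    ped_ids, pos_now, present_now = _positions_at(ds, times)
    _, pos_before, present_before = _positions_at(ds, times - params.dt)
    same = _same_group_matrix(ds, ped_ids)
    counts = np.empty(times.size)
    for s in range(times.size):
        a = _adjacency(pos_now[s], pos_before[s], present_now[s], present_before[s], same, params)
        inside = ds.geometry.inside_measurement(pos_now[s]) & present_now[s]
        _, counts[s] = _components(ds.geometry, ped_ids, pos_now[s], a, np.flatnonzero(inside))
    return float(counts.mean())


def stage_boundaries(ds: TrialDataset) -> StageBoundaries:
    """The six stage instants of a trial, evaluated on the trajectory grid.

    Crossings are detected as the first grid sample at which the x-gap
    between a rightward and a leftward pedestrian closes (>= 0).
    """
    if ds.groups_present != {"rightward", "leftward"}:
        raise ValidationError("stage boundaries require both groups")
    entries, exits = [], []
    for tr in ds.tracks.values():
        ee = entry_exit_times(tr, ds.geometry)
        if ee is None:
            raise ValidationError(f"pedestrian {tr.ped_id} never enters the measurement area")
        entries.append(ee[0])
        exits.append(ee[1])
    t0, t2 = min(entries), min(exits)
    t3, t5 = max(entries), max(exits)

    rate = max(tr.sample_rate for tr in ds.tracks.values())
    t_start, t_end = ds.time_span
    grid = np.arange(t_start, t_end + 0.5 / rate, 1.0 / rate)
    ped_ids, pos, present = _positions_at(ds, grid)
    right = [k for k, p in enumerate(ped_ids) if ds.tracks[p].group == "rightward"]
    left = [k for k, p in enumerate(ped_ids) if ds.tracks[p].group == "leftward"]
    xr = pos[:, right, 0]
    xl = pos[:, left, 0]
    crossed = xr[:, :, None] >= xl[:, None, :]  # (time, right, left)
    ever = crossed.any(axis=0)
    if not ever.any():
        raise ValidationError("the groups never cross")
    first_idx = crossed.argmax(axis=0)  # first True along time for each pair
    cross_times = grid[first_idx[ever]]
    t1 = float(cross_times.min())
    t4 = float(cross_times.max())
    return StageBoundaries(t0=float(t0), t1=t1, t2=float(t2), t3=float(t3), t4=t4, t5=float(t5))


def lane_partitions_over(
    ds: TrialDataset, times: np.ndarray, params: FollowParams = FollowParams()
) -> dict[float, LanePartition]:
    """Convenience: lane partitions at each of ``times``."""
    return {float(t): lane_partition(ds, float(t), params) for t in np.atleast_1d(times)}
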