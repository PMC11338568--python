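"""Step-synchronization classification and the pair-shuffling null.

A follower strike at ``t_f`` matched to a predecessor strike at ``t_p`` is
in-phase synchronized when ``|t_f - t_p| <= K`` and anti-phase synchronized
when the offset lies within ``K`` of plus or minus a quarter of the summed
single-foot step durations.  Either label additionally requires duration
conformity, ``|dt_f - dt_p| <= (dt_f + dt_p) / 8``.  The relaxation time K
defaults to 0.1 s.

The chance level of these windows is estimated by re-pairing followers with
predecessors drawn from other trials of the same condition ("virtual
trials"): synchrony surviving the shuffle is attributable to a shared clock,
not to interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import TrialDataset, ValidationError, entry_exit_times
from .pairing import FollowParams, LanePartition, PairAssignment, _positions_at, identify_pairs, match_step_series

IN_PHASE = "in_phase"
ANTI_PHASE = "anti_phase"
UNSYNCHRONIZED = "unsynchronized"

N_PHASE_BINS = 24


@dataclass(frozen=True)
class SyncParams:
    """K is the synchronization relaxation time (s); the duration-conformity
    threshold is fixed at (dt_f + dt_p)/8."""

    K: float = 0.1
    n_shuffles: int = 1000
    delta_k_max: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValidationError("K must be > 0")
        if self.n_shuffles < 1:
            raise ValidationError("n_shuffles must be >= 1")


@dataclass
class StepMatch:
    t_p: float
    t_f: float
    dt_p: float
    dt_f: float
    phase_shift: float
    label: str
    duration_ok: bool


@dataclass
class SyncSummary:
    trial_id: str
    prop_sync: float
    mean_duration_diff: float
    phase_hist: np.ndarray
    n_matches: int
    is_null: bool = False
    shuffle_seed: Optional[int] = None


@dataclass
class NeighbourDiscrepancy:
    """Heel-strike timing discrepancy with the kth same-lane neighbour."""

    k: int
    series: np.ndarray  # (m, 2) columns: t, delta_k
    random_series: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# classification


def classify_matches(matches: np.ndarray, params: SyncParams = SyncParams()):
    """Vectorized classification of an (n, 4) match array ``[t_p, t_f, dt_p, dt_f]``.

    Returns ``(labels, phase_shift, duration_ok)`` where labels are 0
    (unsynchronized), 1 (in-phase) or 2 (anti-phase).
    """
    m = np.asarray(matches, dtype=float).reshape(-1, 4)
    t_p, t_f, dt_p, dt_f = m[:, 0], m[:, 1], m[:, 2], m[:, 3]
    if np.any(dt_p <= 0) or np.any(dt_f <= 0):
        raise ValidationError("step durations must be positive")
    off = t_f - t_p
    quarter = (dt_f + dt_p) / 4.0
    duration_ok = np.abs(dt_f - dt_p) <= (dt_f + dt_p) / 8.0
    in_phase = (np.abs(off) <= params.K) & duration_ok
    anti = ((np.abs(off + quarter) <= params.K) | (np.abs(off - quarter) <= params.K)) & duration_ok
    labels = np.zeros(m.shape[0], dtype=int)
    labels[anti] = 2
    labels[in_phase] = 1  # in-phase takes precedence if K is large enough to overlap
    mean_dur = (dt_f + dt_p) / 2.0
    raw = 2.0 * np.pi * off / mean_dur
    phase = np.pi - np.mod(np.pi - raw, 2.0 * np.pi)  # wrap into (-pi, pi]
    return labels, phase, duration_ok


_LABEL_NAMES = {0: UNSYNCHRONIZED, 1: IN_PHASE, 2: ANTI_PHASE}


def classify_step(
    t_f: float, t_p: float, dt_f: float, dt_p: float, params: SyncParams = SyncParams()
) -> StepMatch:
    """Classify a single matched strike pair."""
    labels, phase, dur_ok = classify_matches(
        np.array([[t_p, t_f, dt_p, dt_f]]), params
    )
    return StepMatch(
        t_p=t_p,
        t_f=t_f,
        dt_p=dt_p,
        dt_f=dt_f,
        phase_shift=float(phase[0]),
        label=_LABEL_NAMES[int(labels[0])],
        duration_ok=bool(dur_ok[0]),
    )


def phase_histogram(phase: np.ndarray, n_bins: int = N_PHASE_BINS) -> np.ndarray:
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    hist, _ = np.histogram(phase, bins=edges)
    return hist


def trial_sync_summary(
    pairs: Sequence[PairAssignment],
    params: SyncParams = SyncParams(),
    trial_id: str = "",
    is_null: bool = False,
    shuffle_seed: Optional[int] = None,
) -> SyncSummary:
    """Proportion of synchronized footsteps and duration differences of a trial."""
    mats = [p.matches for p in pairs if p.matches.size]
    if not mats:
        return SyncSummary(trial_id, float("nan"), float("nan"), np.zeros(N_PHASE_BINS, int), 0,
                           is_null=is_null, shuffle_seed=shuffle_seed)
    m = np.vstack(mats)
    labels, phase, _ = classify_matches(m, params)
    prop = float(np.mean(labels != 0))
    dur_diff = float(np.mean(np.abs(m[:, 3] - m[:, 2])))
    return SyncSummary(
        trial_id=trial_id,
        prop_sync=prop,
        mean_duration_diff=dur_diff,
        phase_hist=phase_histogram(phase),
        n_matches=int(m.shape[0]),
        is_null=is_null,
        shuffle_seed=shuffle_seed,
    )


# ---------------------------------------------------------------------------
# shuffle null


def shuffle_null(
    trials: Sequence[TrialDataset],
    params: SyncParams = SyncParams(),
    follow_params: FollowParams = FollowParams(),
    pairs_per_trial: Optional[Sequence[Sequence[PairAssignment]]] = None,
    foot_map_policy: str = "anatomical",
) -> list[SyncSummary]:
    """Virtual-trial ensemble: followers re-paired across trials of a condition.

    For every pair of every trial, the follower is kept and a predecessor is
    drawn by (i) uniformly picking another trial of the condition, then (ii)
    uniformly picking one of its pairs that shares no member id with the
    original pair; the drawn pair's predecessor is matched against the
    follower on the shared trial-start clock.  Each of ``params.n_shuffles``
    draws yields one condition-wide :class:`SyncSummary`.

    ``pairs_per_trial`` lets callers reuse pair assignments already computed.
    """
    if len(trials) < 2:
        raise ValidationError("the shuffle null needs at least two trials")
    if pairs_per_trial is None:
        pairs_per_trial = [identify_pairs(ds, follow_params) for ds in trials]
    windows = []  # per trial: predecessor in-area windows keyed by ped_id
    for ds, prs in zip(trials, pairs_per_trial):
        w = {}
        for p in prs:
            w[p.predecessor_id] = entry_exit_times(ds.tracks[p.predecessor_id], ds.geometry)
        windows.append(w)

    children = np.random.SeedSequence(params.seed).spawn(params.n_shuffles)
    out: list[SyncSummary] = []
    for k, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        virtual: list[PairAssignment] = []
        for i, (ds, prs) in enumerate(zip(trials, pairs_per_trial)):
            for pair in prs:
                match = _draw_partner(rng, i, pair, trials, pairs_per_trial, windows, ds,
                                      foot_map_policy)
                if match is not None:
                    virtual.append(match)
        out.append(
            trial_sync_summary(
                virtual, params, trial_id=f"null-{k}", is_null=True, shuffle_seed=k
            )
        )
    return out


def _draw_partner(rng, focal_idx, pair, trials, pairs_per_trial, windows, ds, foot_map_policy):
    others = [o for o in range(len(trials)) if o != focal_idx and pairs_per_trial[o]]
    rng.shuffle(others)
    forbidden = {pair.follower_id, pair.predecessor_id}
    for o in others:
        eligible = [
            q for q in pairs_per_trial[o]
            if q.follower_id not in forbidden and q.predecessor_id not in forbidden
        ]
        if not eligible:
            continue
        q = eligible[rng.integers(len(eligible))]
        pred_steps = trials[o].steps_for(q.predecessor_id)
        foll_steps = ds.steps_for(pair.follower_id)
        window = windows[o][q.predecessor_id]
        if window is None:
            continue
        foot_map, matches = match_step_series(pred_steps, foll_steps, window, foot_map_policy)
        if matches.size == 0:
            continue
        return PairAssignment(
            follower_id=pair.follower_id,
            predecessor_id=f"{o}:{q.predecessor_id}",
            followed_duration=pair.followed_duration,
            foot_map=foot_map,
            matches=matches,
        )
    return None


# ---------------------------------------------------------------------------
# kth-neighbour strike discrepancy


def neighbour_discrepancy(
    ds: TrialDataset,
    partitions: dict[float, LanePartition],
    k: int,
    params: SyncParams = SyncParams(),
    donor_trials: Optional[Sequence[TrialDataset]] = None,
) -> NeighbourDiscrepancy:
    """Mean |strike-time difference| with the kth nearest same-lane neighbour.

    At each partition time, every instrumented pedestrian with at least ``k``
    same-lane neighbours (also instrumented) contributes the absolute
    difference between its strike nearest to that time and the neighbour's
    strike nearest to that strike.

    When ``donor_trials`` is given, a random-reference series is computed
    alongside: each neighbour's strike train is replaced by that of a
    uniformly drawn instrumented pedestrian from a uniformly drawn donor
    trial (seeded by ``params.seed``), giving the no-interaction baseline
    the measured discrepancy is judged against.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    strikes = {p: ds.merged_strikes(p) for p in ds.instrumented_ids}
    strikes = {p: s for p, s in strikes.items() if s.size}
    donors = None
    if donor_trials:
        donors = [
            (dt, pid, dt.merged_strikes(pid))
            for dt in donor_trials
            for pid in dt.instrumented_ids
            if dt.merged_strikes(pid).size
        ]
        rng = np.random.default_rng(params.seed)
    times = sorted(partitions)
    rows, rand_rows = [], []
    for t in times:
        part = partitions[t]
        ped_ids, pos, _ = _positions_at(ds, np.array([t]))
        index = {p: i for i, p in enumerate(ped_ids)}
        vals, rand_vals = [], []
        for cluster in part.clusters:
            members = [p for p in cluster if p in strikes]
            for i in members:
                neigh = [p for p in members if p != i]
                if len(neigh) < k:
                    continue
                d = [np.linalg.norm(pos[0, index[i]] - pos[0, index[j]]) for j in neigh]
                j_k = neigh[int(np.argsort(d)[k - 1])]
                s_i = strikes[i][np.argmin(np.abs(strikes[i] - t))]
                s_j = strikes[j_k][np.argmin(np.abs(strikes[j_k] - s_i))]
                vals.append(abs(s_i - s_j))
                if donors:
                    _, _, train = donors[rng.integers(len(donors))]
                    s_r = train[np.argmin(np.abs(train - s_i))]
                    rand_vals.append(abs(s_i - s_r))
        if vals:
            rows.append((t, float(np.mean(vals))))
        if rand_vals:
            rand_rows.append((t, float(np.mean(rand_vals))))
    series = np.array(rows) if rows else np.empty((0, 2))
    rand = np.array(rand_rows) if rand_rows else None
    return NeighbourDiscrepancy(k=k, series=series, random_series=rand)


def delta_k_series(
    ds: TrialDataset,
    partitions: dict[float, LanePartition],
    params: SyncParams = SyncParams(),
    donor_trials: Optional[Sequence[TrialDataset]] = None,
) -> list[NeighbourDiscrepancy]:
    """Neighbour discrepancies for every k up to ``params.delta_k_max``."""
    return [
        neighbour_discrepancy(ds, partitions, k, params, donor_trials)
        for k in range(1, params.delta_k_max + 1)
    ]
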