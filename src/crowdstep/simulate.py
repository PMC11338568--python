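"""Seeded synthetic bidirectional-flow trials with known ground truth.

The generator emulates the crossing experiment: two groups walk toward each
other through a 10 m x 3 m measurement area flanked by buffers and waiting
areas, either pacing to a 120 beats-per-minute metronome (CUE) or stepping at
mutually independent cadences (NO_CUE).

The crowd model is kinematic, not force-based: each pedestrian advances at a
constant drawn speed along the corridor while its transverse position relaxes
exponentially toward an assigned lane centre under mean-reverting
(Ornstein-Uhlenbeck) lateral noise, with a transverse deflection away from
oncoming pedestrians.  Lanes alternate direction across the corridor width,
so the configured total lane count is the ground truth that the clustering
analysis should recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    LEFTWARD,
    RIGHTWARD,
    CorridorGeometry,
    ImuTrace,
    PedestrianTrack,
    StepSeries,
    TrialDataset,
    ValidationError,
)

METRONOME_LOCKED = "metronome_locked"
INDEPENDENT = "independent"

#: Minimum plausible lane width (m); fewer than ~0.3 m cannot hold a walker.
_MIN_LANE_WIDTH = 0.3

#: Full width at half maximum of the synthetic heel-strike bump (s).
_BUMP_FWHM = 0.060
_BUMP_SIGMA = _BUMP_FWHM / (2.0 * math.sqrt(2.0 * math.log(2.0)))


class ConfigError(ValueError):
    """Simulation configuration is infeasible."""


@dataclass
class SimConfig:
    """Free parameters of the synthetic experiment.

    ``n_lanes`` is the total number of unidirectional lanes across the
    corridor width; lanes alternate travel direction, the rightward group
    taking even lane indices.  ``tempo`` is the combined two-foot cadence in
    strikes per minute (feet alternate, so each foot strikes at ``tempo/2``
    per minute).  ``duration_coupling`` in [0, 1] shrinks the step-frequency
    gap between each pedestrian and the pedestrian directly ahead in its lane
    (independent mode only); 1 makes whole lanes isochronous.

    ``start_delay_per_row`` models the start-up wave: row k begins walking
    at ``k * start_delay_per_row`` seconds, which is what lets the measurement
    area fill completely before the leaders exit.  ``gap_gain`` (1/s) is the
    rate at which a walker regulates the longitudinal gap to the pedestrian
    ahead in its lane back toward the equilibrium spacing.
    """

    n_per_group: int = 24
    n_lanes: int = 6
    row_spacing: float = 1.2
    start_delay_per_row: float = 0.4
    gap_gain: float = 0.5
    speed_mean: float = 1.3
    speed_sd: float = 0.1
    lateral_relax_time: float = 2.0
    lateral_noise_sd: float = 0.1
    avoidance_gain: float = 1.0
    tempo: float = 120.0
    cue_mode: str = INDEPENDENT
    phase_jitter_sd: float = 0.02
    freq_sd: float = 0.03
    duration_coupling: float = 0.5
    imu_noise_sd: float = 0.05
    seed: int = 0
    geometry: CorridorGeometry = field(default_factory=CorridorGeometry)
    sample_rate: float = 30.0
    instrument_both_groups: bool = False
    with_shoulders: bool = True
    shoulder_half_width: float = 0.2
    shoulder_rotation_gain: float = 0.6  # rad of body turn per metre of avoidance push
    shoulder_sway_sd: float = 0.05  # rad, frame-to-frame sway noise

    def __post_init__(self) -> None:
        if self.n_lanes < 2:
            raise ConfigError("need at least 2 lanes (one per direction)")
        if self.geometry.meas_width / self.n_lanes < _MIN_LANE_WIDTH:
            raise ConfigError(
                f"{self.n_lanes} lanes in a {self.geometry.meas_width} m corridor "
                f"leaves lanes narrower than {_MIN_LANE_WIDTH} m"
            )
        if self.cue_mode not in (METRONOME_LOCKED, INDEPENDENT):
            raise ConfigError(f"unknown cue_mode {self.cue_mode!r}")
        if not 0.0 <= self.duration_coupling <= 1.0:
            raise ConfigError("duration_coupling must lie in [0, 1]")
        for name in ("speed_sd", "lateral_noise_sd", "phase_jitter_sd", "freq_sd", "imu_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_per_group < 1 or self.tempo <= 0 or self.speed_mean <= 0:
            raise ConfigError("n_per_group, tempo and speed_mean must be positive")

    @property
    def condition(self) -> str:
        return "CUE" if self.cue_mode == METRONOME_LOCKED else "NO_CUE"

    def lane_centres(self) -> np.ndarray:
        w = self.geometry.meas_width / self.n_lanes
        return (np.arange(self.n_lanes) + 0.5) * w

    def lanes_of_group(self, group: str) -> np.ndarray:
        idx = np.arange(self.n_lanes)
        return idx[idx % 2 == 0] if group == RIGHTWARD else idx[idx % 2 == 1]


@dataclass
class GroundTruth:
    """What the generator actually drew, for parameter-recovery tests."""

    lane_assignment: dict[str, int]
    step_frequency: dict[str, float]  # per-foot strike frequency, Hz
    phase_offset: dict[str, float]  # first-strike phase, s
    speed: dict[str, float]  # walking speed, m/s
    predecessor: dict[str, str | None]  # pedestrian directly ahead in lane


def simulate_trial(
    cfg: SimConfig, trial_id: str | None = None, order_index: int = 0
) -> tuple[TrialDataset, GroundTruth]:
    """Generate one trial; identical config and seed give identical output."""
    rng = np.random.default_rng(cfg.seed)
    geom = cfg.geometry
    centres = cfg.lane_centres()

    ped_ids: list[str] = []
    groups: list[str] = []
    lane_of: dict[str, int] = {}
    in_lane_pos: dict[str, int] = {}
    x0 = {}
    direction = {}
    # Column size per lane under round-robin assignment within each group.
    lane_size: dict[int, int] = {}
    for group in (RIGHTWARD, LEFTWARD):
        lanes = cfg.lanes_of_group(group)
        for li, lane in enumerate(lanes):
            lane_size[int(lane)] = cfg.n_per_group // lanes.size + (
                1 if li < cfg.n_per_group % lanes.size else 0
            )
    # Columns with more members start denser and faster, so every lane takes
    # the same time to stream past a fixed point regardless of its depth.
    m_ref = min(lane_size.values())
    lane_scale = {lane: m_ref / m for lane, m in lane_size.items()}
    lane_spacing = {lane: cfg.row_spacing * s for lane, s in lane_scale.items()}
    lane_delay = {lane: cfg.start_delay_per_row * s for lane, s in lane_scale.items()}

    for group, prefix, sign in ((RIGHTWARD, "R", +1.0), (LEFTWARD, "L", -1.0)):
        lanes = cfg.lanes_of_group(group)
        for m in range(cfg.n_per_group):
            pid = f"{prefix}{m:02d}"
            lane = int(lanes[m % lanes.size])
            k = m // lanes.size
            ped_ids.append(pid)
            groups.append(group)
            lane_of[pid] = lane
            in_lane_pos[pid] = k
            depth = geom.buffer_length + (k + 1) * lane_spacing[lane]
            x0[pid] = -depth if sign > 0 else geom.meas_length + depth
            direction[pid] = sign

    n = len(ped_ids)
    speeds = np.clip(rng.normal(cfg.speed_mean, cfg.speed_sd, n), 0.3, None)
    dirs = np.array([direction[p] for p in ped_ids])
    # Columns deeper than the waiting area queue up at the corridor end and
    # are released by the start-up wave (gap regulation strings them out).
    x_start = np.clip(np.array([x0[p] for p in ped_ids]), geom.x_min, geom.x_max)
    y_lane = np.array([centres[lane_of[p]] for p in ped_ids])
    walk_start = np.array([in_lane_pos[p] * lane_delay[lane_of[p]] for p in ped_ids])

    by_slot = {(lane_of[p], in_lane_pos[p]): p for p in ped_ids}
    pred: dict[str, str | None] = {}
    for pid in ped_ids:
        k = in_lane_pos[pid]
        pred[pid] = by_slot.get((lane_of[pid], k - 1)) if k > 0 else None
    ped_index = {p: j for j, p in enumerate(ped_ids)}
    pred_idx = np.array([ped_index[pred[p]] if pred[p] else -1 for p in ped_ids])
    gap_target = np.array(
        [lane_spacing[lane_of[p]] + cfg.speed_mean * lane_delay[lane_of[p]] for p in ped_ids]
    )

    # Destination: past the far buffer; walkers then hold position.
    dest = np.where(dirs > 0, geom.x_max, geom.x_min)
    t_max = float(np.max((dest - x_start) / (dirs * speeds) + walk_start)) * 1.5 + 5.0
    h = 1.0 / cfg.sample_rate
    cross = dirs[:, None] * dirs[None, :] < 0
    tau = cfg.lateral_relax_time
    noise_scale = cfg.lateral_noise_sd * math.sqrt(2.0 * h / tau)
    margin = 0.05
    lo, hi = margin, geom.meas_width - margin

    xs = [x_start.copy()]
    ys = [y_lane.copy()]
    thetas = [np.zeros(n)]
    arrival = np.full(n, np.inf)
    t = 0.0
    while True:
        t += h
        xp, yp = xs[-1], ys[-1]
        walking = (t >= walk_start) & ~np.isfinite(arrival)
        # Longitudinal: drawn speed plus gap regulation toward the walker ahead.
        v = speeds.copy()
        has_pred = pred_idx >= 0
        gap = np.where(has_pred, dirs * (xp[pred_idx] - xp), gap_target)
        moving_pred = has_pred & (t >= np.where(has_pred, walk_start[np.clip(pred_idx, 0, None)], 0.0))
        v = v + np.where(moving_pred, cfg.gap_gain * (gap - gap_target), 0.0)
        v = np.clip(v, 0.1, 2.5)
        x_new = np.where(walking, xp + h * dirs * v, xp)
        x_new = np.clip(x_new, geom.x_min, geom.x_max)
        arrived_now = ~np.isfinite(arrival) & (dirs * (x_new - dest) >= 0)
        arrival[arrived_now] = t

        # Transverse avoidance: oncoming pedestrian < 2 m ahead, |dy| < 0.5 m.
        ahead = dirs[:, None] * (xp[None, :] - xp[:, None])
        dy = yp[:, None] - yp[None, :]
        engaged = cross & (ahead > 0) & (ahead <= 2.0) & (np.abs(dy) < 0.5)
        push = np.where(engaged, np.where(dy >= 0, 1.0, -1.0) * (0.5 - np.abs(dy)), 0.0)
        drift = -(yp - y_lane) / tau + cfg.avoidance_gain * push.sum(axis=1)
        y_new = yp + h * drift + noise_scale * rng.standard_normal(n)
        # Reflective clamping at the corridor walls.
        y_new = np.where(y_new < lo, 2 * lo - y_new, y_new)
        y_new = np.where(y_new > hi, 2 * hi - y_new, y_new)
        y_new = np.clip(y_new, lo, hi)
        y_new = np.where(walking, y_new, yp)

        xs.append(x_new)
        ys.append(y_new)
        # Body rotation: proportional to the avoidance push, plus sway.
        theta = cfg.shoulder_rotation_gain * push.sum(axis=1)
        if cfg.shoulder_sway_sd > 0:
            theta = theta + rng.normal(0.0, cfg.shoulder_sway_sd, n)
        thetas.append(np.clip(theta, -1.2, 1.2))
        if np.all(np.isfinite(arrival)) or t > t_max:
            break
    x = np.array(xs)
    y = np.array(ys)
    theta = np.array(thetas)
    n_steps = x.shape[0]
    t_grid = np.arange(n_steps) * h

    tracks = {}
    for j, pid in enumerate(ped_ids):
        kwargs = {}
        if cfg.with_shoulders:
            pos = np.column_stack([x[:, j], y[:, j]])
            seg = cfg.shoulder_half_width * np.column_stack(
                [np.sin(theta[:, j]), np.cos(theta[:, j])]
            )
            kwargs["shoulder_left"] = pos - seg
            kwargs["shoulder_right"] = pos + seg
        tracks[pid] = PedestrianTrack(
            ped_id=pid,
            group=groups[j],
            t=t_grid,
            xy=np.column_stack([x[:, j], y[:, j]]),
            sample_rate=cfg.sample_rate,
            **kwargs,
        )

    # ---- gait ---------------------------------------------------------
    foot_period = 1.0 / (cfg.tempo / 60.0 / 2.0)  # per-foot strike period, s
    freq: dict[str, float] = {}
    phase: dict[str, float] = {}

    if cfg.cue_mode == METRONOME_LOCKED:
        for pid in ped_ids:
            freq[pid] = 1.0 / foot_period
            # Which foot takes the first metronome tick.
            phase[pid] = 0.0 if rng.random() < 0.5 else foot_period / 2.0
    else:
        raw = {pid: rng.normal(1.0 / foot_period, cfg.freq_sd) for pid in ped_ids}
        for pid in ped_ids:  # couple followers to the pedestrian ahead, chained
            p = pred[pid]
            if p is None:
                freq[pid] = raw[pid]
            else:
                freq[pid] = freq[p] + (1.0 - cfg.duration_coupling) * (raw[pid] - freq[p])
        for pid in ped_ids:
            phase[pid] = rng.uniform(0.0, 1.0 / freq[pid])

    instrumented = set(ped_ids) if cfg.instrument_both_groups else {
        p for p, g in zip(ped_ids, groups) if g == RIGHTWARD
    }
    steps = []
    for j, pid in enumerate(ped_ids):
        t_walk = float(walk_start[j])
        t_stop = float(min(arrival[j], t_grid[-1]))
        period = 1.0 / freq[pid]
        for foot, offset in (("left", 0.0), ("right", period / 2.0)):
            first = t_walk + phase[pid] + offset
            if cfg.cue_mode == METRONOME_LOCKED:
                # Strikes stay on the metronome grid regardless of start row.
                first = (phase[pid] + offset) % foot_period
                first += math.ceil(max(0.0, t_walk - first) / foot_period) * foot_period
            times = np.arange(first, t_stop, period)
            if cfg.phase_jitter_sd > 0:
                times = times + rng.normal(0.0, cfg.phase_jitter_sd, times.size)
            times = _strictly_increasing(np.sort(times))
            if pid in instrumented:
                steps.append(StepSeries(ped_id=pid, foot=foot, strikes=times))

    if trial_id is None:
        trial_id = f"sim-{cfg.condition.lower()}-{cfg.seed}"
    ds = TrialDataset(
        trial_id=trial_id,
        condition=cfg.condition,
        geometry=geom,
        tracks=tracks,
        steps=steps,
        order_index=order_index,
        tempo=cfg.tempo,
    )
    gt = GroundTruth(
        lane_assignment=dict(lane_of),
        step_frequency=dict(freq),
        phase_offset=dict(phase),
        speed={p: float(speeds[j]) for j, p in enumerate(ped_ids)},
        predecessor=pred,
    )
    return ds, gt


def _strictly_increasing(times: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    """Nudge sorted times so the sequence is strictly increasing."""
    if times.size < 2:
        return times
    out = times.copy()
    for i in range(1, out.size):
        if out[i] <= out[i - 1]:
            out[i] = out[i - 1] + eps
    return out


def synthesize_imu(
    steps: StepSeries,
    cfg: SimConfig,
    partner: StepSeries | None = None,
    with_hints: bool = False,
) -> ImuTrace:
    """Synthetic medio-lateral angular-velocity trace for one foot.

    The trace is a sum of unit-height Gaussian bumps (60 ms FWHM) centred at
    each heel strike, a negative bump at each mid-swing toe-off (taken at 60%
    of the same-foot stride, the conventional stance fraction), plus white
    sensor noise at 100 Hz.
    """
    strikes = steps.strikes
    if strikes.size < 2:
        raise ValueError("need at least two strikes to span a synthetic trace")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, _stable_hash(steps.ped_id), 0 if steps.foot == "left" else 1]))
    fs = 100.0
    pad = 0.5
    t = np.arange(max(0.0, strikes[0] - pad), strikes[-1] + pad, 1.0 / fs)
    omega = np.zeros_like(t)
    for s in strikes:
        omega += np.exp(-0.5 * ((t - s) / _BUMP_SIGMA) ** 2)
    toe_offs = strikes[:-1] + 0.6 * np.diff(strikes)
    for s in toe_offs:
        omega -= 0.8 * np.exp(-0.5 * ((t - s) / _BUMP_SIGMA) ** 2)
    if cfg.imu_noise_sd > 0:
        omega = omega + rng.normal(0.0, cfg.imu_noise_sd, omega.size)
    hints = None
    if with_hints:
        hints = [(float(to), float(hs) + 0.08) for to, hs in zip(toe_offs, strikes[1:])]
        hints.insert(0, (float(t[0]), float(strikes[0]) + 0.08))
    return ImuTrace(
        ped_id=steps.ped_id,
        foot=steps.foot,
        t=t,
        omega_ml=omega,
        sample_rate=fs,
        events_hint=hints,
    )


def _stable_hash(s: str) -> int:
    h = 0
    for ch in s:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


# ---------------------------------------------------------------------------
# condition presets

#: Structural regimes of the two conditions.  The crowd model is kinematic,
#: so lane width does not emerge from stepping dynamics; instead the presets
#: encode the regimes the conditions produce — metronome pacing comes with
#: thinner lanes and curtailed lateral exploration, free walking with wider
#: lanes and larger lateral exploration — and the analysis pipeline is left
#: to measure every consequence (lane count, collision risk, curvature,
#: transverse MSD, shoulder rotation, synchronization) on its own.
CONDITION_PRESETS: dict[str, dict] = {
    "NO_CUE": {"cue_mode": INDEPENDENT, "n_lanes": 4, "lateral_noise_sd": 0.12},
    "CUE": {"cue_mode": METRONOME_LOCKED, "n_lanes": 6, "lateral_noise_sd": 0.06},
}


def condition_config(condition: str, seed: int, **overrides) -> SimConfig:
    """A :class:`SimConfig` for one trial of a named condition."""
    if condition not in CONDITION_PRESETS:
        raise ConfigError(f"unknown condition {condition!r}")
    kw = dict(CONDITION_PRESETS[condition])
    kw.update(overrides)
    return SimConfig(seed=seed, **kw)


def simulate_experiment(
    n_trials: int, base_seed: int = 0, conditions=("NO_CUE", "CUE"), **overrides
) -> dict[str, list[tuple[TrialDataset, GroundTruth]]]:
    """Simulate a full two-condition experiment of ``n_trials`` per condition.

    Trial seeds derive deterministically from ``base_seed``; order indices
    run 1..n within each condition.
    """
    out: dict[str, list[tuple[TrialDataset, GroundTruth]]] = {}
    for c, condition in enumerate(conditions):
        out[condition] = []
        for k in range(n_trials):
            seed = (base_seed * 1_000_003 + c * 10_007 + k) % (2**31 - 1)
            cfg = condition_config(condition, seed, **overrides)
            ds, gt = simulate_trial(
                cfg, trial_id=f"{condition.lower()}-{k:02d}", order_index=k + 1
            )
            out[condition].append((ds, gt))
    return out
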