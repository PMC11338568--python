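"""Per-trial analysis driver and condition-level report assembly."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core import TrialDataset, ValidationError, entry_exit_times
from .instability import (
    RiskParams,
    curvature,
    shoulder_rotation,
    stage_mean_curvature,
    transverse_msd,
    trial_risk_means,
)
from .pairing import FollowParams, StageBoundaries, identify_pairs, mean_lane_count, stage_boundaries
from .sync import SyncParams, SyncSummary, trial_sync_summary

log = logging.getLogger(__name__)


@dataclass
class TrialSummary:
    """Scalar per-trial metrics feeding the statistics layer."""

    trial_id: str
    condition: str
    order_index: int
    n_pairs: int
    prop_sync: float
    mean_duration_diff: float
    phase_hist: list[int]
    lane_count: float
    mean_tau: float
    mean_lambda: float
    stage_curvature: dict[int, float]
    shoulder_rotation_rad: Optional[float] = None
    stages: Optional[dict[str, float]] = None
    per_ped_tau: dict[str, float] = field(default_factory=dict)
    per_ped_curvature: dict[str, float] = field(default_factory=dict)
    strata: dict[str, dict[str, str]] = field(default_factory=dict)


def classify_strata(ds: TrialDataset) -> dict[str, dict[str, str]]:
    """Leader/follower and wall/centre stratum of each pedestrian.

    Leaders are the first half of each group to enter the measurement area;
    wall/centre comes from the starting transverse position (middle third of
    the corridor width = centre).
    """
    out: dict[str, dict[str, str]] = {}
    w = ds.geometry.meas_width
    for group in ds.groups_present:
        ids = ds.group_ids(group)
        entries = {}
        for pid in ids:
            ee = entry_exit_times(ds.tracks[pid], ds.geometry)
            entries[pid] = ee[0] if ee else float("inf")
        ranked = sorted(ids, key=lambda p: (entries[p], p))
        half = len(ranked) // 2
        leaders = set(ranked[:half])
        for pid in ids:
            y0 = ds.tracks[pid].xy[0, 1]
            out[pid] = {
                "position": "leader" if pid in leaders else "follower",
                "lateral": "centre" if w / 3.0 <= y0 <= 2.0 * w / 3.0 else "wall",
            }
    return out


def analyze_trial(
    ds: TrialDataset,
    follow_params: FollowParams = FollowParams(),
    sync_params: SyncParams = SyncParams(),
    risk_params: RiskParams = RiskParams(),
) -> TrialSummary:
    """Run the full single-trial pipeline: stages, lanes, pairs, sync, risk,
    curvature and (when markers are present) shoulder rotation."""
    stages = stage_boundaries(ds)
    lanes = mean_lane_count(ds, stages, follow_params)
    pairs = identify_pairs(ds, follow_params)
    sync = trial_sync_summary(pairs, sync_params, trial_id=ds.trial_id)
    risk = trial_risk_means(ds, risk_params)
    stage_curv = stage_mean_curvature(ds, stages)

    per_ped_tau: dict[str, float] = {}
    if not risk.records.empty:
        melted = {}
        for col in ("i", "j"):
            for pid, sub in risk.records.groupby(col)["tau_s"]:
                melted.setdefault(pid, []).append(sub.to_numpy())
        per_ped_tau = {p: float(np.concatenate(v).mean()) for p, v in melted.items()}
    per_ped_curv = {}
    for pid, tr in ds.tracks.items():
        cs = curvature(tr)
        if cs.samples.size:
            per_ped_curv[pid] = float(cs.samples[:, 1].mean())

    shoulders = None
    if any(tr.has_shoulders for tr in ds.tracks.values()):
        shoulders = shoulder_rotation(ds).trial_mean

    return TrialSummary(
        trial_id=ds.trial_id,
        condition=ds.condition,
        order_index=ds.order_index,
        n_pairs=len(pairs),
        prop_sync=sync.prop_sync,
        mean_duration_diff=sync.mean_duration_diff,
        phase_hist=[int(c) for c in sync.phase_hist],
        lane_count=lanes,
        mean_tau=risk.mean_tau,
        mean_lambda=risk.mean_lambda,
        stage_curvature=stage_curv,
        shoulder_rotation_rad=shoulders,
        stages={f"t{k}": getattr(stages, f"t{k}") for k in range(6)},
        per_ped_tau=per_ped_tau,
        per_ped_curvature=per_ped_curv,
        strata=classify_strata(ds),
    )


# ---------------------------------------------------------------------------
# report


def _collect(summaries: Sequence[TrialSummary], condition: str, attr: str) -> np.ndarray:
    vals = [getattr(s, attr) for s in summaries if s.condition == condition]
    return np.array([v for v in vals if v is not None and np.isfinite(v)], dtype=float)


def _strata_values(summaries, condition, key, which, metric_attr) -> np.ndarray:
    vals = []
    for s in summaries:
        if s.condition != condition:
            continue
        source = getattr(s, metric_attr)
        for pid, v in source.items():
            if pid in s.strata and s.strata[pid][key] == which and np.isfinite(v):
                vals.append(v)
    return np.array(vals, dtype=float)


def build_report(
    summaries: Sequence[TrialSummary],
    nulls: Optional[dict[str, Sequence[SyncSummary]]] = None,
    out_dir: str | Path = "report",
    delta_series: Optional[dict] = None,
    make_figures: bool = True,
) -> dict:
    """Assemble the condition-level report: JSON comparisons plus figures.

    Missing metrics are listed under ``absent`` rather than fabricated;
    comparisons with fewer than two values on a side are flagged
    ``insufficient-n``.
    """
    from .stats import order_trend, welch_compare

    if not summaries:
        raise ValidationError("no trial summaries to report")
    nulls = nulls or {}
    conditions = sorted({s.condition for s in summaries})
    report: dict = {"schema_version": 1, "conditions": {}, "comparisons": [], "trends": [], "absent": [], "figures": []}

    def compare(metric, a, b, labels):
        if len(a) < 2 or len(b) < 2:
            report["comparisons"].append(
                {"metric": metric, "labels": list(labels), "status": "insufficient-n",
                 "n": [int(len(a)), int(len(b))]}
            )
            return
        r = welch_compare(a, b, metric=metric, labels=labels)
        entry = dataclasses.asdict(r)
        entry["labels"] = list(labels)
        entry["n"] = list(r.n)
        entry["status"] = "ok"
        report["comparisons"].append(entry)

    for cond in conditions:
        cond_sums = [s for s in summaries if s.condition == cond]
        report["conditions"][cond] = {
            "n_trials": len(cond_sums),
            "prop_sync_mean": _nanmean(_collect(summaries, cond, "prop_sync")),
            "duration_diff_mean_s": _nanmean(_collect(summaries, cond, "mean_duration_diff")),
            "lane_count_mean": _nanmean(_collect(summaries, cond, "lane_count")),
            "tau_mean_s": _nanmean(_collect(summaries, cond, "mean_tau")),
            "lambda_mean_m": _nanmean(_collect(summaries, cond, "mean_lambda")),
        }
        # actual vs shuffled-pair null
        if cond in nulls and len(nulls[cond]) >= 2:
            null_prop = np.array([n.prop_sync for n in nulls[cond] if np.isfinite(n.prop_sync)])
            null_dur = np.array([n.mean_duration_diff for n in nulls[cond] if np.isfinite(n.mean_duration_diff)])
            compare(f"prop_sync:{cond}", _collect(summaries, cond, "prop_sync"), null_prop,
                    ("actual", "random"))
            compare(f"duration_diff:{cond}", _collect(summaries, cond, "mean_duration_diff"),
                    null_dur, ("actual", "random"))
        else:
            report["absent"].append(f"null ensemble for {cond}; sync-vs-null comparison omitted")

    if len(conditions) == 2:
        c0, c1 = conditions  # alphabetical: CUE, NO_CUE
        for metric in ("prop_sync", "mean_duration_diff", "lane_count", "mean_tau", "mean_lambda",
                       "shoulder_rotation_rad"):
            a, b = _collect(summaries, c0, metric), _collect(summaries, c1, metric)
            if metric == "shoulder_rotation_rad" and (len(a) == 0 and len(b) == 0):
                report["absent"].append("shoulder rotation (no marker data)")
                continue
            compare(f"{metric}:{c0}-vs-{c1}", a, b, (c0, c1))
        for stage in (1, 2, 3, 4, 5):
            a = np.array([s.stage_curvature.get(stage, float("nan")) for s in summaries if s.condition == c0])
            b = np.array([s.stage_curvature.get(stage, float("nan")) for s in summaries if s.condition == c1])
            compare(f"stage{stage}_curvature:{c0}-vs-{c1}", a[np.isfinite(a)], b[np.isfinite(b)], (c0, c1))
        for key, groups in (("position", ("leader", "follower")), ("lateral", ("wall", "centre"))):
            for cond in conditions:
                for metric_attr, name in (("per_ped_tau", "tau"), ("per_ped_curvature", "curvature")):
                    a = _strata_values(summaries, cond, key, groups[0], metric_attr)
                    b = _strata_values(summaries, cond, key, groups[1], metric_attr)
                    compare(f"{name}:{groups[0]}-vs-{groups[1]}:{cond}", a, b, groups)

    for cond in conditions:
        cond_sums = [s for s in summaries if s.condition == cond and np.isfinite(s.lane_count)]
        if len(cond_sums) >= 3:
            tr = order_trend([s.lane_count for s in cond_sums], [s.order_index for s in cond_sums],
                             name=f"lane_count_vs_order:{cond}")
            report["trends"].append(dataclasses.asdict(tr))

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if make_figures:
        report["figures"] = _figures(summaries, delta_series, out)
    (out / "report.json").write_text(json.dumps(report, indent=2, default=_js))
    return report


def _nanmean(x: np.ndarray) -> float:
    return float(np.mean(x)) if x.size else float("nan")


def _js(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _figures(summaries, delta_series, out: Path) -> list[str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    conditions = sorted({s.condition for s in summaries})

    fig, axes = plt.subplots(1, len(conditions), figsize=(5 * len(conditions), 3.2), squeeze=False)
    edges = np.linspace(-np.pi, np.pi, 25)
    centres = 0.5 * (edges[:-1] + edges[1:])
    for ax, cond in zip(axes[0], conditions):
        hist = np.sum([s.phase_hist for s in summaries if s.condition == cond], axis=0)
        total = hist.sum() or 1
        ax.bar(centres, hist / total, width=np.diff(edges), color="0.4")
        ax.set_title(cond)
        ax.set_xlabel("phase shift (rad)")
        ax.set_ylabel("proportion")
        ax.set_xticks([-np.pi, 0, np.pi], [r"$-\pi$", "0", r"$\pi$"])
    fig.tight_layout()
    p = out / "phase_histogram.svg"
    fig.savefig(p)
    plt.close(fig)
    written.append(p.name)

    if delta_series:
        fig, axes = plt.subplots(1, len(delta_series), figsize=(5 * len(delta_series), 3.2), squeeze=False)
        for ax, (cond, series_list) in zip(axes[0], sorted(delta_series.items())):
            for nd in series_list:
                if nd.series.size:
                    ax.plot(nd.series[:, 0], nd.series[:, 1], label=f"k={nd.k}")
                if nd.random_series is not None and nd.random_series.size:
                    ax.plot(nd.random_series[:, 0], nd.random_series[:, 1], "k--", lw=1,
                            label="random" if nd.k == 1 else None)
            ax.set_title(cond)
            ax.set_xlabel("time (s)")
            ax.set_ylabel(r"$\delta_k$ (s)")
            ax.legend(fontsize=7)
        fig.tight_layout()
        p = out / "delta_k.svg"
        fig.savefig(p)
        plt.close(fig)
        written.append(p.name)

    metrics = [("lane_count", "lanes"), ("mean_tau", r"$\tau$ (s)"), ("mean_lambda", r"$\lambda$ (m)"),
               ("prop_sync", "prop. sync")]
    fig, axes = plt.subplots(1, len(metrics), figsize=(3 * len(metrics), 3.2))
    for ax, (attr, label) in zip(axes, metrics):
        data = [_collect(summaries, c, attr) for c in conditions]
        data = [d for d in data if d.size]
        if data:
            ax.violinplot(data, showmeans=True)
            ax.boxplot([d for d in data], widths=0.15)
            ax.set_xticks(range(1, len(conditions) + 1), conditions, fontsize=8)
        ax.set_ylabel(label)
    fig.tight_layout()
    p = out / "trial_metrics.svg"
    fig.savefig(p)
    plt.close(fig)
    written.append(p.name)
    return written
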