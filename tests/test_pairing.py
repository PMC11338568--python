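"""Following relation, pairs, lane clustering, stage segmentation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import crowdstep as cs
from crowdstep.core import ValidationError
from crowdstep.pairing import FollowParams, match_step_series

from conftest import make_track, make_trial


def walking_track(ped_id, group, offset, speed=1.3, y=1.5, duration=10.0):
    t = np.arange(0, duration * 30 + 1) / 30.0
    sign = 1.0 if group == "rightward" else -1.0
    return make_track(ped_id, group, t, offset + sign * speed * t, y)


def alternating_steps(ped_id, t0=0.0, period=1.0, n=12):
    return [
        cs.StepSeries(ped_id, "left", t0 + np.arange(n) * period),
        cs.StepSeries(ped_id, "right", t0 + period / 2 + np.arange(n) * period),
    ]


class TestFollowing:
    def make_pair_trial(self, dy):
        t = np.arange(0, 91) / 30.0
        i = make_track("i", "rightward", t, 5.0, 1.5)
        j = make_track("j", "rightward", t, 5.3, 1.5 + dy)
        return make_trial([i, j])

    def test_edge_within_dr(self):
        g = cs.following(self.make_pair_trial(0.0), 2.0)
        assert ("i", "j") in g.edges  # distance 0.3 < 0.7

    def test_no_edge_beyond_dr(self):
        g = cs.following(self.make_pair_trial(0.8), 2.0)
        # |r_i(t) - r_j(t-1)| = sqrt(0.3^2 + 0.8^2) > 0.7
        assert ("i", "j") not in g.edges

    def test_never_self_edge(self):
        g = cs.following(self.make_pair_trial(0.0), 2.0)
        assert all(i != j for i, j in g.edges)

    def test_cross_group_excluded_by_default(self):
        t = np.arange(0, 91) / 30.0
        i = make_track("i", "rightward", t, 5.0, 1.5)
        j = make_track("j", "leftward", t, 5.3, 1.5)
        ds = make_trial([i, j])
        assert cs.following(ds, 2.0).edges == []
        loose = cs.following(ds, 2.0, FollowParams(same_group_only=False))
        assert ("i", "j") in loose.edges

    def test_before_start_warns_empty(self):
        ds = self.make_pair_trial(0.0)
        with pytest.warns(UserWarning):
            g = cs.following(ds, 0.5)
        assert g.edges == []

    @given(st.floats(-50, 50), st.floats(-1.0, 1.0))
    def test_translation_invariance(self, dx, dy):
        t = np.arange(0, 91) / 30.0
        base = {"i": (5.0, 1.5), "j": (5.3, 1.8), "k": (6.5, 1.5)}
        def build(shift):
            tracks = [make_track(p, "rightward", t, x + shift[0], y + shift[1])
                      for p, (x, y) in base.items()]
            return make_trial(tracks)
        g0 = cs.following(build((0, 0)), 2.0)
        g1 = cs.following(build((dx, dy)), 2.0)
        assert sorted(g0.edges) == sorted(g1.edges)


class TestIdentifyPairs:
    def test_longest_followed_wins(self):
        # i trails j the whole trial; k is within range only briefly.
        t = np.arange(0, 301) / 30.0
        i = make_track("i", "rightward", t, 1.3 * t, 1.5)
        j = make_track("j", "rightward", t, 1.3 + 1.3 * t, 1.5)
        k_y = np.where(t < 3.0, 1.5, 2.9)  # drifts away after 3 s
        k = make_track("k", "rightward", t, 1.3 + 1.3 * t, k_y)
        steps = alternating_steps("i") + alternating_steps("j") + alternating_steps("k")
        ds = make_trial([i, j, k], steps=steps)
        pairs = {p.follower_id: p for p in cs.identify_pairs(ds)}
        assert pairs["i"].predecessor_id == "j"
        assert pairs["i"].followed_duration > 5.0

    def test_tie_breaks_to_lower_ped_id(self):
        t = np.arange(0, 301) / 30.0
        i = make_track("i", "rightward", t, 1.3 * t, 1.5)
        a = make_track("a", "rightward", t, 1.3 + 1.3 * t, 1.4)
        b = make_track("b", "rightward", t, 1.3 + 1.3 * t, 1.6)
        steps = alternating_steps("i") + alternating_steps("a") + alternating_steps("b")
        ds = make_trial([i, a, b], steps=steps)
        pairs = {p.follower_id: p for p in cs.identify_pairs(ds)}
        assert pairs["i"].predecessor_id == "a"

    def test_isolated_follower_excluded(self):
        t = np.arange(0, 301) / 30.0
        i = make_track("i", "rightward", t, 1.3 * t, 0.3)
        j = make_track("j", "rightward", t, 1.3 * t + 5.0, 2.7)
        steps = alternating_steps("i") + alternating_steps("j")
        ds = make_trial([i, j], steps=steps)
        assert cs.identify_pairs(ds) == []


class TestFootMatching:
    def test_nearest_policy_picks_smaller_offset_bijection(self):
        pred = {"left": cs.StepSeries("p", "left", [1.0, 2.0, 3.0]),
                "right": cs.StepSeries("p", "right", [1.5, 2.5, 3.5])}
        foll = {"left": cs.StepSeries("f", "left", [1.05, 2.05, 3.05]),
                "right": cs.StepSeries("f", "right", [1.55, 2.55, 3.55])}
        fmap, matches = match_step_series(pred, foll, (0.0, 4.0), policy="nearest")
        assert fmap == {"left": "left", "right": "right"}
        np.testing.assert_allclose(matches[:, 1] - matches[:, 0], 0.05)

    def test_nearest_policy_crosses_feet_when_cheaper(self):
        pred = {"left": cs.StepSeries("p", "left", [1.0, 2.0, 3.0]),
                "right": cs.StepSeries("p", "right", [1.5, 2.5, 3.5])}
        foll = {"left": cs.StepSeries("f", "left", [1.55, 2.55, 3.55]),
                "right": cs.StepSeries("f", "right", [1.05, 2.05, 3.05])}
        fmap, _ = match_step_series(pred, foll, (0.0, 4.0), policy="nearest")
        assert fmap == {"left": "right", "right": "left"}

    def test_anatomical_policy_preserves_half_cycle_offsets(self):
        # A stable half-cycle offset is anti-phase; anatomical matching must
        # not fold it away by crossing the feet.
        pred = {"left": cs.StepSeries("p", "left", np.arange(1.0, 8.0)),
                "right": cs.StepSeries("p", "right", np.arange(1.5, 8.0))}
        foll = {"left": cs.StepSeries("f", "left", np.arange(1.5, 8.0)),
                "right": cs.StepSeries("f", "right", np.arange(1.0, 8.0))}
        fmap, matches = match_step_series(pred, foll, (0.0, 8.0))
        assert fmap == {"left": "left", "right": "right"}
        offs = np.abs(matches[:, 1] - matches[:, 0])
        assert np.all(np.isclose(offs, 0.5))

    def test_window_restricts_predecessor_strikes(self):
        pred = {"left": cs.StepSeries("p", "left", [1.0, 2.0, 3.0, 4.0]),
                "right": cs.StepSeries("p", "right", [1.5, 2.5, 3.5, 4.5])}
        foll = {"left": cs.StepSeries("f", "left", [1.0, 2.0, 3.0, 4.0]),
                "right": cs.StepSeries("f", "right", [1.5, 2.5, 3.5, 4.5])}
        _, matches = match_step_series(pred, foll, (1.9, 3.6))
        assert matches.shape[0] == 4  # strikes 2.0, 3.0, 2.5, 3.5


class TestLanePartition:
    def chain(self, ids, y, t):
        return [make_track(p, "rightward", t, 1.3 * t + 1.3 * k, y)
                for k, p in enumerate(ids)]

    def test_two_chains_two_clusters(self):
        t = np.arange(0, 301) / 30.0
        ds = make_trial(self.chain(["a", "b", "c"], 0.8, t) + self.chain(["d", "e", "f"], 2.2, t))
        part = cs.lane_partition(ds, 3.0)
        assert sorted(sorted(c) for c in part.clusters) == [["a", "b", "c"], ["d", "e", "f"]]

    def test_no_edges_all_singletons(self):
        t = np.arange(0, 91) / 30.0
        tracks = [make_track(p, "rightward", t, 2.0 + 3.0 * k, 1.5) for k, p in enumerate("abc")]
        part = cs.lane_partition(make_trial(tracks), 2.0)
        assert len(part.clusters) == 3

    def test_single_chain_single_cluster(self):
        t = np.arange(0, 601) / 30.0
        ids = [f"p{k:02d}" for k in range(8)]
        ds = make_trial(self.chain(ids, 1.5, t))
        part = cs.lane_partition(ds, 3.0)
        in_area = [p for p in ids if 0 <= ds.tracks[p].position_at(3.0)[0] <= 10]
        assert any(set(c) == set(in_area) for c in part.clusters)
        assert len(part.clusters) == 1

    @given(st.integers(2, 10), st.integers(0, 10_000))
    def test_clusters_match_union_find_oracle(self, n, seed):
        # Random static configurations: components of the symmetrized
        # following relation must equal a brute-force transitive closure.
        rng = np.random.default_rng(seed)
        t = np.arange(0, 61) / 30.0
        xs = rng.uniform(0.5, 9.5, n)
        ys = rng.uniform(0.1, 2.9, n)
        ids = [f"p{k}" for k in range(n)]
        ds = make_trial([make_track(p, "rightward", t, xs[k], ys[k]) for k, p in enumerate(ids)])
        part = cs.lane_partition(ds, 1.5)

        # oracle: naive O(n^3) closure over the directed following relation
        adj = np.zeros((n, n), dtype=bool)
        for a in range(n):
            for b in range(n):
                if a != b and np.hypot(xs[a] - xs[b], ys[a] - ys[b]) < 0.7:
                    adj[a, b] = True
        adj |= adj.T
        reach = adj | np.eye(n, dtype=bool)
        for _ in range(n):
            reach = reach | (reach @ reach)
        oracle = {frozenset(np.flatnonzero(reach[a])) for a in range(n)}
        got = {frozenset(ids.index(p) for p in c) for c in part.clusters}
        assert got == oracle

    def test_lane_count_central_counts_window_members(self):
        t = np.arange(0, 91) / 30.0
        inside = make_track("a", "rightward", t, 5.0, 1.5)   # central window
        outside = make_track("b", "rightward", t, 1.0, 1.5)  # in area, not central
        part = cs.lane_partition(make_trial([inside, outside]), 2.0)
        assert len(part.clusters) == 2
        assert part.lane_count_central == 1


class TestStages:
    def test_crossing_time_closed_form(self):
        # Approach at 1.25 m/s each from 10 m apart: gap closes at t = 4 s,
        # exactly on the 30 Hz grid.
        t = np.arange(0, 301) / 30.0
        a = make_track("a", "rightward", t, -2.0 + 1.25 * t, 1.0)
        b = make_track("b", "leftward", t, 8.0 - 1.25 * t, 2.0)
        st_ = cs.stage_boundaries(make_trial([a, b]))
        assert st_.t1 == pytest.approx(4.0, abs=1e-9)
        assert st_.t4 == pytest.approx(4.0, abs=1e-9)

    def test_stage3_undefined_when_first_exit_precedes_last_entry(self):
        t = np.arange(0, 901) / 30.0
        fast = make_track("a", "rightward", t, -0.5 + 2.0 * np.minimum(t, 14.0), 1.0)
        slow = make_track("b", "leftward", t, 10.5 - 0.5 * t, 2.0)
        st_ = cs.stage_boundaries(make_trial([fast, slow]))
        assert st_.t2 > st_.t3
        assert not st_.stage3_defined
        assert sorted(st_.stage_intervals) == [1, 2, 4, 5]

    def test_single_group_rejected(self):
        t = np.arange(0, 91) / 30.0
        ds = make_trial([make_track("a", "rightward", t, 5.0, 1.5)])
        with pytest.raises(ValidationError):
            cs.stage_boundaries(ds)


class TestMeanLaneCount:
    def test_single_lane_unidirectional_is_one(self):
        t = np.arange(0, 601) / 30.0
        tracks = [make_track(f"p{k}", "rightward", t, 1.3 * t - 1.3 * k, 1.5)
                  for k in range(6)]
        ds = make_trial(tracks)
        stages = cs.StageBoundaries(t0=1.0, t1=3.0, t2=5.0, t3=6.0, t4=9.0, t5=12.0)
        assert cs.mean_lane_count(ds, stages) == pytest.approx(1.0)

    def test_empty_span_is_nan(self):
        t = np.arange(0, 61) / 30.0
        ds = make_trial([make_track("a", "rightward", t, 5.0, 1.5)])
        stages = cs.StageBoundaries(t0=0, t1=1.0, t2=1.0, t3=1.0, t4=1.0, t5=2.0)
        assert np.isnan(cs.mean_lane_count(ds, stages))
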