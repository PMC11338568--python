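"""Collision risk, curvature, transverse MSD, shoulder rotation."""

import numpy as np
import pytest

import crowdstep as cs
from crowdstep.core import ValidationError
from crowdstep.instability import RiskParams, _tau_pairwise

from conftest import make_track, make_trial


def head_on_trial(gap0=6.0, speed=1.5, dy=0.0):
    t = np.arange(0, 121) / 30.0
    a = make_track("a", "rightward", t, 2.0 + speed * t, 1.5)
    b = make_track("b", "leftward", t, 2.0 + gap0 - speed * t, 1.5 + dy)
    return make_trial([a, b])


class TestTimeToCollision:
    def test_head_on_grid_value(self):
        # 3 m gap closing at 3 m/s reaches 0.6 m after 0.8 s; the first grid
        # step at or beyond that is 27 * 0.03 = 0.81 s.
        ds = head_on_trial()
        tau, lam = cs.time_to_collision(ds, 1.0, "a", "b")
        assert tau == pytest.approx(0.81, abs=1e-12)
        assert lam == pytest.approx(0.81 * 1.5, abs=1e-9)

    def test_receding_pair_none(self):
        t = np.arange(0, 121) / 30.0
        a = make_track("a", "rightward", t, 5.0 + 1.5 * t, 1.0)
        b = make_track("b", "leftward", t, 4.0 - 1.5 * t, 2.0)
        ds = make_trial([a, b])
        assert cs.time_to_collision(ds, 1.5, "a", "b") is None

    def test_already_within_threshold_first_grid_value(self):
        t = np.arange(0, 121) / 30.0
        a = make_track("a", "rightward", t, 5.0 + 0.1 * t, 1.5)
        b = make_track("b", "leftward", t, 5.2 - 0.1 * t, 1.5)
        ds = make_trial([a, b])
        tau, _ = cs.time_to_collision(ds, 1.0, "a", "b")
        assert tau == pytest.approx(0.03)

    def test_lateral_offset_beyond_threshold_none(self):
        ds = head_on_trial(dy=1.0)
        assert cs.time_to_collision(ds, 1.0, "a", "b") is None

    def test_same_group_rejected(self):
        t = np.arange(0, 61) / 30.0
        ds = make_trial([make_track("a", "rightward", t, 1.0, 1.0),
                         make_track("b", "rightward", t, 2.0, 1.0)])
        with pytest.raises(ValidationError):
            cs.time_to_collision(ds, 1.5, "a", "b")

    def test_velocity_undefined_before_one_second(self):
        ds = head_on_trial()
        assert cs.time_to_collision(ds, 0.5, "a", "b") is None

    def test_symmetry_and_translation_invariance(self):
        ds = head_on_trial(gap0=5.0, dy=0.3)
        ab = cs.time_to_collision(ds, 1.0, "a", "b")
        # translated copy
        t = np.arange(0, 121) / 30.0
        a = make_track("a", "rightward", t, 3.5 + 1.5 * t, 1.8)
        b = make_track("b", "leftward", t, 8.5 - 1.5 * t, 2.1)
        ds2 = make_trial([a, b])
        assert cs.time_to_collision(ds2, 1.0, "a", "b") == pytest.approx(ab)
        assert cs.time_to_collision(ds2, 1.0, "b", "a") == pytest.approx(ab)

    def test_matches_grid_scan_oracle(self):
        rng = np.random.default_rng(3)
        params = RiskParams()
        grid = params.tau_grid
        for _ in range(300):
            d0 = rng.uniform(-4, 4, 2)
            dv = rng.uniform(-2, 2, 2)
            tau = _tau_pairwise(d0[None], dv[None], params)[0]
            dist = np.linalg.norm(d0[None] + grid[:, None] * dv[None], axis=1)
            hits = grid[dist <= params.delta_c]
            expected = hits[0] if hits.size else np.nan
            if np.isnan(expected):
                assert np.isnan(tau)
            else:
                assert tau == pytest.approx(expected, abs=1e-9)

    def test_reported_tau_on_exact_grid(self, small_nocue):
        ds, _ = small_nocue
        risk = cs.trial_risk_means(ds)
        ratios = risk.records["tau_s"].to_numpy() / 0.03
        assert np.allclose(ratios, np.round(ratios), atol=1e-9)


class TestTrialRiskMeans:
    def test_parallel_pass_no_records(self):
        ds = head_on_trial(dy=1.0)
        risk = cs.trial_risk_means(ds)
        assert risk.records.empty
        assert np.isnan(risk.mean_tau)

    def test_single_sample_mean(self):
        ds = head_on_trial()
        risk = cs.trial_risk_means(ds)
        assert not risk.records.empty
        # every record of this constant-velocity pair lies on the grid and
        # the trial mean is their average
        assert risk.mean_tau == pytest.approx(risk.records["tau_s"].mean())

    def test_ped_min_mode_smaller_than_record_mean(self, small_nocue):
        ds, _ = small_nocue
        rec = cs.trial_risk_means(ds, RiskParams(mean_mode="records"))
        pmin = cs.trial_risk_means(ds, RiskParams(mean_mode="ped_min"))
        assert pmin.mean_tau <= rec.mean_tau


class TestCurvature:
    def test_straight_track_zero(self):
        t = np.arange(0, 301) / 30.0
        tr = make_track("a", "rightward", t, 1.3 * t, 1.5)
        ser = cs.curvature(tr)
        assert ser.samples.size > 0
        assert np.max(np.abs(ser.samples[:, 1])) <= 1e-12

    def test_circle_closed_form(self):
        w = 0.5
        t = np.arange(0, 301) / 30.0
        tr = make_track("c", "rightward", t, 5 + np.cos(w * t), 1.5 + np.sin(w * t))
        ser = cs.curvature(tr, dt=1.0)
        expected = 2 * np.sin(w * 0.5) / 1.0
        assert np.max(np.abs(ser.samples[:, 1] - expected)) <= 1e-9

    def test_stationary_track_empty(self):
        t = np.arange(0, 121) / 30.0
        ser = cs.curvature(make_track("a", "rightward", t, 5.0, 1.5))
        assert ser.samples.size == 0

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(2)
        t = np.arange(0, 241) / 30.0
        x = 1.2 * t + np.cumsum(rng.normal(0, 0.01, t.size))
        y = 1.5 + np.cumsum(rng.normal(0, 0.01, t.size))
        tr = make_track("a", "rightward", t, x, y)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        rot = cs.PedestrianTrack("a", "rightward", t, tr.xy @ R.T + np.array([3.0, -2.0]))
        np.testing.assert_allclose(
            cs.curvature(tr).samples[:, 1], cs.curvature(rot).samples[:, 1], atol=1e-9
        )

    def test_bounded_by_unit_vector_difference(self, small_nocue):
        ds, _ = small_nocue
        for tr in list(ds.tracks.values())[:6]:
            ser = cs.curvature(tr)
            if ser.samples.size:
                assert np.all(ser.samples[:, 1] <= 2.0 + 1e-12)

    def test_stage_means_straight_trial_zero(self):
        t = np.arange(0, 481) / 30.0
        a = make_track("a", "rightward", t, -2 + 1.3 * t, 1.0)
        b = make_track("b", "leftward", t, 12 - 1.3 * t, 2.0)
        ds = make_trial([a, b])
        stages = cs.stage_boundaries(ds)
        means = cs.stage_mean_curvature(ds, stages)
        for v in means.values():
            assert np.isnan(v) or abs(v) <= 1e-12

    def test_noisier_walking_has_larger_curvature(self):
        means = {}
        for sd in (0.05, 0.15):
            ds, _ = cs.simulate_trial(
                cs.SimConfig(seed=21, n_per_group=8, n_lanes=4, lateral_noise_sd=sd)
            )
            stages = cs.stage_boundaries(ds)
            m = cs.stage_mean_curvature(ds, stages)
            means[sd] = np.nanmean([m.get(1, np.nan), m.get(2, np.nan)])
        assert means[0.15] > means[0.05]


class TestTransverseMSD:
    def geom_track(self, pid, y_fn):
        t = np.arange(0, 301) / 30.0
        return make_track(pid, "rightward", t, 1.0 * t, y_fn(t))

    def test_constant_y_zero(self):
        ds = make_trial([self.geom_track("a", lambda t: np.full(t.size, 1.5))])
        msd = cs.transverse_msd([ds])
        assert np.allclose(msd.d, 0.0)
        assert msd.d[0] == 0.0

    def test_linear_drift_quadratic(self):
        ds = make_trial([self.geom_track("a", lambda t: 1.0 + 0.1 * np.clip(t - 0.0, 0, None))])
        msd = cs.transverse_msd([ds])
        np.testing.assert_allclose(msd.d, 0.01 * msd.t**2, atol=1e-12)

    def test_symmetric_drifts_average_to_same_square(self):
        ds = make_trial([
            self.geom_track("a", lambda t: 1.5 + 0.1 * t),
            self.geom_track("b", lambda t: 1.5 - 0.1 * t),
        ])
        msd = cs.transverse_msd([ds])
        np.testing.assert_allclose(msd.d, 0.01 * msd.t**2, atol=1e-12)

    def test_no_entry_rejected(self):
        t = np.arange(0, 61) / 30.0
        ds = make_trial([make_track("a", "rightward", t, -5.0, 1.5)])
        with pytest.raises(ValidationError):
            cs.transverse_msd([ds])


class TestShoulderRotation:
    def shoulder_trial(self, angle_fn):
        t = np.arange(0, 61) / 30.0
        theta = angle_fn(t)
        pos = np.column_stack([5 + 1.0 * t, np.full(t.size, 1.5)])
        seg = 0.2 * np.column_stack([np.sin(theta), np.cos(theta)])
        tr = cs.PedestrianTrack("a", "rightward", t, pos,
                                shoulder_left=pos - seg, shoulder_right=pos + seg)
        return make_trial([tr])

    def test_parallel_to_transverse_axis_zero(self):
        sr = cs.shoulder_rotation(self.shoulder_trial(lambda t: np.zeros(t.size)))
        assert sr.trial_mean == pytest.approx(0.0, abs=1e-12)

    def test_fixed_thirty_degrees(self):
        sr = cs.shoulder_rotation(self.shoulder_trial(lambda t: np.full(t.size, np.pi / 6)))
        assert sr.trial_mean == pytest.approx(np.pi / 6, abs=1e-12)

    def test_alternating_sign_folds(self):
        sr = cs.shoulder_rotation(
            self.shoulder_trial(lambda t: np.where(np.arange(t.size) % 2 == 0, 1, -1) * np.pi / 6)
        )
        assert sr.trial_mean == pytest.approx(np.pi / 6, abs=1e-12)

    def test_missing_markers_rejected(self):
        t = np.arange(0, 61) / 30.0
        ds = make_trial([make_track("a", "rightward", t, 5.0, 1.5)])
        with pytest.raises(ValidationError, match="a"):
            cs.shoulder_rotation(ds)
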