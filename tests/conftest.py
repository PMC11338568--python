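import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import crowdstep as cs

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


def make_track(ped_id, group, t, x, y, **kwargs):
    t = np.asarray(t, dtype=float)
    return cs.PedestrianTrack(
        ped_id=ped_id,
        group=group,
        t=t,
        xy=np.column_stack([np.broadcast_to(x, t.shape), np.broadcast_to(y, t.shape)]),
        **kwargs,
    )


def make_trial(tracks, steps=(), trial_id="scripted", condition="NO_CUE", **kwargs):
    return cs.TrialDataset(
        trial_id=trial_id,
        condition=condition,
        geometry=cs.CorridorGeometry(),
        tracks={tr.ped_id: tr for tr in tracks},
        steps=list(steps),
        **kwargs,
    )


@pytest.fixture(scope="session")
def small_nocue():
    """One compact free-cadence trial (8 per group, 4 lanes)."""
    return cs.simulate_trial(cs.SimConfig(seed=11, n_per_group=8, n_lanes=4))


@pytest.fixture(scope="session")
def small_cue():
    return cs.simulate_trial(
        cs.SimConfig(seed=12, n_per_group=8, n_lanes=4, cue_mode="metronome_locked")
    )


@pytest.fixture(scope="session")
def chance_trials():
    """Twenty free-cadence trials with uncoupled step frequencies.

    These are the chance-level reference condition: gait phases mutually
    independent, so any synchrony is the geometry of the classification
    windows alone.  Pairs are computed once and reused.
    """
    trials, pairs = [], []
    for k in range(20):
        ds, _ = cs.simulate_trial(
            cs.SimConfig(seed=1000 + k, duration_coupling=0.0, n_lanes=4,
                         lateral_noise_sd=0.12),
            trial_id=f"chance-{k:02d}",
            order_index=k + 1,
        )
        trials.append(ds)
        pairs.append(cs.identify_pairs(ds))
    return trials, pairs
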