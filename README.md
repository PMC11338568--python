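# crowdstep

Analysis pipeline for **footstep synchronization and spatial self-organization
in bidirectional pedestrian flows** — the crossing-corridor experiment in
which two groups of 24 pedestrians walk toward each other through a
10 m × 3 m measurement area, either pacing to a 120 beats min⁻¹ metronome
(CUE) or stepping freely (NO_CUE), while foot-mounted inertial sensors record
every heel strike.

It is written for researchers in pedestrian dynamics and movement
biomechanics who have per-trial trajectory tables (30 Hz), heel-strike event
tables or raw medio-lateral angular-velocity traces (100 Hz), and a trial
manifest — and who want the complete chain from raw streams to
condition-level statistics. A seeded synthetic crowd-and-gait generator with
known ground truth makes every stage testable without any experimental data.

## What it computes

**Gait events.** Heel strikes are extracted from the medio-lateral angular
velocity ω(t) of each foot-mounted sensor: median filter (window 5), then
prominence- and separation-constrained peak picking, optionally gated to
annotated toe-off→heel-strike windows.

**Pairs and lanes.** Pedestrian *i* follows *j* at time *t* when
|**r**ᵢ(t) − **r**ⱼ(t − dt)| < dr with dt = 1 s, dr = 0.7 m. The pedestrian
each walker follows longest over a trial is its *pair*; the undirected
transitive closure of the relation at an instant partitions the crowd into
lanes, counted in the central 3 m × 3 m window and averaged over the
lane-bearing stages of a trial. Stages are bounded by six instants t₀…t₅
(first entry, first front-runner crossing, first exit, last entry, last
crossing, last exit).

**Step synchronization.** A matched strike pair (t_f, t_p) with single-foot
step durations Δt_f, Δt_p is

- *in-phase* when |t_f − t_p| ≤ K,
- *anti-phase* when |t_f − t_p ± (Δt_f + Δt_p)/4| ≤ K,

with K = 0.1 s, and either label additionally requires duration conformity
|Δt_f − Δt_p| ≤ (Δt_f + Δt_p)/8. The chance level is estimated with a
pair-shuffling null: 1000 virtual trials in which each follower is re-paired
with a predecessor from a different trial of the same condition. The
kth-nearest-neighbour strike discrepancy δₖ(t) tracks how far synchrony
extends through a lane.

**Structural instability.** Time to potential collision
τ(t) = min{τₙ ∈ {0.03, …, 9.0 s} : |**f**ᵢ(t,τₙ) − **f**ⱼ(t,τₙ)| ≤ δ_c} for
cross-group pairs under linear extrapolation **f**ᵢ = **r**ᵢ + τₙ**v**ᵢ with
δ_c = 0.6 m, and distance λ = τ·(|**v**ᵢ|+|**v**ⱼ|)/2; trajectory curvature
κ(t) = |**e**(t+dt) − **e**(t)|/dt of the unit velocity vector; transverse
mean squared displacement D(t) = ⟨(y(t) − y(0))²⟩ from measurement-area
entry; shoulder rotation relative to the corridor's transverse axis.

**Statistics.** Welch's t-test with Cohen's d for condition and
actual-vs-null comparisons, Pearson correlation for order trends, and a
machine-readable report with phase histograms, δₖ series and trial-metric
figures.

## Worked example

```python
import crowdstep as cs

cfg = cs.SimConfig(seed=1)          # free cadence (NO_CUE), 6 lanes
ds, gt = cs.simulate_trial(cfg)     # 48 pedestrians + heel strikes
stages = cs.stage_boundaries(ds)
pairs = cs.identify_pairs(ds)
summary = cs.trial_sync_summary(pairs, trial_id=ds.trial_id)
risk = cs.trial_risk_means(ds)
print(f"proportion of synchronized footsteps: {summary.prop_sync:.3f}")
print(f"mean step-duration difference: {summary.mean_duration_diff*1000:.1f} ms")
print(f"mean lane count (stages 2-4): {cs.mean_lane_count(ds, stages):.2f}")
print(f"mean time to potential collision: {risk.mean_tau:.2f} s")
```

prints

```
proportion of synchronized footsteps: 0.363
mean step-duration difference: 33.8 ms
mean lane count (stages 2-4): 6.03
mean time to potential collision: 1.12 s
```

The sync proportion sits at the chance level of the classification windows
(≈ 0.40 for ~1 s step durations) because free-walking gait phases are
mutually independent; the lane count recovers the generator's configured
6-lane structure; τ ≈ 1.1 s reflects how closely opposing lanes pass.
A metronome-locked trial (`cue_mode="metronome_locked"`) instead yields
`prop_sync ≈ 1.0` with a phase histogram concentrated at 0 and ±π.

The same pipeline runs from the shell on trial directories:

```bash
crowdstep simulate --out trial0 --seed 1 --condition NO_CUE
crowdstep analyze --trial trial0 --out summary0.json
crowdstep null --trials trial0 --trials trial1 --condition NO_CUE \
    --n 1000 --seed 2 --out null.csv
crowdstep report --summaries summaries/ --out report/
```

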