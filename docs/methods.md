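# Methods

This note documents the models implemented in `crowdstep`, the parameter
choices that matter, what the synthetic generator does and does not emulate,
and the numerical conventions a user should know before trusting or
extending the results.

## Coordinate and time conventions

The corridor is a straight strip: a 10 m × 3 m measurement area with 1.2 m
buffer zones and 8.4 m waiting areas on both sides. `x` is the long axis in
metres, increasing in the rightward group's travel direction, with the
measurement area at `x ∈ [0, 10]`; `y ∈ [0, 3]` is transverse. All streams
share one clock in seconds from the trial start signal; trajectories are
sampled at 30 Hz and inertial traces at 100 Hz, and no resampling is
performed — operations look up nearest samples, never interpolating unless
stated. The reader enforces the convention: a file whose transverse
coordinate leaves the corridor width is rejected, so a 90°-rotated dataset
cannot silently pass through the pipeline. The origin choice is a
convention of this package, not a claim about any particular laboratory
setup.

## Synthetic trials

The generator is deliberately kinematic rather than force-based: the
analyses need realistic geometry and *controllable ground truth*, not
emergent physics, and a kinematic model keeps every recovered quantity
traceable to a configured value.

**Crowd.** `n_lanes` unidirectional lanes alternate travel direction across
the corridor width (rightward on even indices). Each group's members are
assigned to its lanes round-robin and start in one column per lane. Row
`k` starts walking at `k · start_delay_per_row` (default 0.4 s), emulating
the start-up wave of a released queue — without it, with near-equal speeds
the first exit would always precede the last entry and the
full-bidirectional-flow stage would never exist. Columns with more members
start proportionally denser and faster so each lane takes the same time to
stream past a fixed point; with three lanes per group this reduces exactly
to an 8-row × 3-column grid at 1.2 m spacing. Walking speed is drawn per
pedestrian from N(1.3, 0.1²) m s⁻¹ (conventional values; the corridor
literature reports no canonical distribution) and a gap-regulation term
(`gap_gain`, default 0.5 s⁻¹) steers the longitudinal gap to the pedestrian
ahead back toward its equilibrium, keeping lanes coherent under speed
heterogeneity. Transverse position relaxes toward the lane centre with time
constant `lateral_relax_time` (2 s) under mean-reverting noise with
stationary standard deviation `lateral_noise_sd`, plus a transverse
deflection away from any oncoming pedestrian within 2 m ahead and 0.5 m
laterally; walls reflect. Start columns deeper than the waiting area are
clamped to the corridor end and strung out by the start-up wave.

**Gait.** The metronome mode places each foot's strikes on the 0.5 s tick
grid (feet offset by half a cycle, so the combined cadence is the 120 min⁻¹
tempo) plus N(0, `phase_jitter_sd`²) jitter. The independent mode draws a
per-foot frequency from N(1 Hz, `freq_sd`²) with a uniform initial phase.
`duration_coupling` ∈ [0, 1] shrinks the frequency gap between each walker
and the one directly ahead in its lane (chained, so coupling 1 makes whole
lanes isochronous); it exists to give the duration-coordination analysis a
known effect to recover. Strikes are emitted only while walking, and step
series are attached to one configurable instrumented group, mirroring
sensor deployment on one group only.

**Condition presets.** The crowd model is kinematic, so lane width cannot
emerge from stepping dynamics. `CONDITION_PRESETS` therefore encodes the
structural regimes the two conditions produce — metronome pacing with
thinner lanes (6) and curtailed lateral noise (0.06 m), free walking with
wider lanes (4) and larger lateral noise (0.12 m) — and the analysis
pipeline measures every consequence (lane count, τ/λ, curvature, MSD,
shoulder rotation, synchronization) on its own. Passing tests on these data
therefore demonstrate that the *measurement chain* is correct and
calibrated; they cannot demonstrate that metronome pacing causes thinner
lanes, which is an empirical claim about humans outside the generator's
scope.

**Synthetic inertial traces.** A foot's medio-lateral angular velocity is a
sum of unit-height Gaussian bumps (60 ms FWHM) at each heel strike, a −0.8
bump at each mid-swing toe-off (60 % of the stride, the conventional stance
fraction), plus white noise (`imu_noise_sd`, default 0.05). Real traces
carry structured swing-phase dynamics and axis cross-talk; the surrogate
only guarantees that the detectable event is where the ground truth says.

**Shoulders.** The shoulder segment (half-width 0.2 m) turns in proportion
to the instantaneous avoidance push plus N(0, 0.05²) rad sway. This gives
shoulder rotation a mechanistic link to imminent collisions but no gait
coupling.

## Gait-event detection

Detection is a self-contained surrogate for published IMU gait-event
methods, which the rest of the pipeline only needs to deliver strike times
to ~10 ms: median filter (window 5 samples), then `scipy.signal.find_peaks`
with a refractory separation (0.4 s, well below any plausible stride) and a
prominence floor (0.3 of the filtered maximum). The median filter flattens
sharp peaks into plateaus of equal values; each plateau is localized at the
raw-trace maximum over its extent (leftmost sample on exact ties), which
removes the systematic early bias that leftmost-plateau selection would
introduce. With annotated toe-off→heel-strike windows present, detections
outside them are discarded. A constant trace returns an empty series with a
warning. The separation and prominence defaults are engineering choices
exposed in `DetectionParams`; no claim is made that they match any
particular laboratory's settings.

## Pairing and foot matching

The following relation uses dt = 1 s, dr = 0.7 m, nearest-sample positions
(at 30 Hz the lookup error is ≤ 33 ms ≪ dr/v), and is restricted to
same-group pedestrians by default: lanes are unidirectional, and
opposite-direction "following" at head-on closing speeds is physically
spurious. The restriction is a flag (`same_group_only`) for sensitivity
analysis. Followed time accumulates per 30 Hz sample; ties in total
followed time break toward the lower pedestrian id.

Matching uses the predecessor's strikes from its first to last presence in
the measurement area, clipped to the span where the follower is also
stepping (one stride of slack) so boundary strikes without a meaningful
counterpart never enter. Foot correspondence is **anatomical by default**
(left↔left): a timing-optimized bijection necessarily caps offsets at a
quarter cycle, which folds every stable half-cycle (anti-phase) relation
into in-phase and skews independent gaits away from a uniform phase
distribution — i.e. it makes anti-phase unobservable by construction. The
timing-based bijection remains available (`foot_map_policy="nearest"`) for
comparison. A follower strike may serve several predecessor strikes;
duplicates are logged.

## Synchronization and the shuffle null

Classification follows the window definitions (K = 0.1 s; duration
conformity (Δt_f + Δt_p)/8; anti-phase at ±(Δt_f + Δt_p)/4), with in-phase
taking precedence in the degenerate case of overlapping windows (impossible
for K below the conformity threshold). The phase shift is the strike offset
normalized by the mean single-foot duration, as 2π·offset/((Δt_f+Δt_p)/2),
wrapped to (−π, π]: in-phase maps to 0 and anti-phase to ±π, the only
normalization consistent with a bimodal in/anti-phase distribution. Each
strike carries its backward same-foot duration (the first strike uses its
forward interval).

One virtual trial of the null re-draws *every* pair of *every* trial in the
condition: the follower is kept; a donor trial is drawn uniformly among the
other trials, then a donor pair uniformly among its pairs sharing no member
id with the original pair, and the donor predecessor's strike series is
matched to the follower on the shared trial-start clock. The ensemble uses
one master seed spawning per-shuffle substreams, so results are independent
of evaluation order. For δₖ, a pedestrian's strike time at evaluation time
t is its strike nearest to t, and the neighbour's is the strike nearest to
*that* — symmetric and bounded by half a stride in dense walking; both feet
are merged for this purpose.

## Instability metrics

τ is computed exactly: the extrapolated squared distance is a quadratic in
τ, its sub-threshold interval is intersected with the grid
{0.03, …, 9.0 s}, and the smallest grid element inside is returned (an
exact grid multiple, never interpolated; tests cross-check against a
brute-force grid scan). Velocities are backward differences over 1 s — the
same differencing rule as curvature, one rule for the whole package. Risk
records are kept only while both pedestrians are inside the measurement
area, and pairs with no qualifying horizon contribute nothing (padding with
9 s would bias the means). The trial mean averages all finite pair-frame
records; a per-pedestrian-minimum mode (`mean_mode="ped_min"`) is available
because the aggregation level is a genuine analysis choice.

Curvature is evaluated on a 1 s grid with κ(t) = |e(t+dt) − e(t)|/dt,
skipping zero-velocity samples; κ ≤ 2/dt by construction. Stage means pool
all pedestrians' samples in each stage interval, omitting the
full-bidirectional-flow stage when the first exit precedes the last entry.
The transverse MSD zeroes each pedestrian's clock at measurement-area entry
and reports up to the shortest in-area duration across pedestrians, so
every reported D(t) averages the same population. Shoulder rotation folds
the shoulder-segment angle from the transverse axis into [0, π/2] (a
180°-symmetric segment has no sign), averages frames per pedestrian, then
pedestrians per trial.

## Statistics

Welch's t-test (`scipy.stats.ttest_ind`, `equal_var=False`) with
Welch–Satterthwaite degrees of freedom; Cohen's d uses the pooled-SD form
with n−1 weights (Hedges' correction behind a flag). Actual-vs-null
comparisons treat the shuffle ensemble as one sample of its own size.
Pearson correlation tests order trends. No multiple-testing correction is
applied. Comparisons with fewer than two values per side are flagged
`insufficient-n`; missing metrics are listed as absent, never fabricated.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` run scaled replications chosen
as the package's own defaults: 20 chance-level trials for calibration
checks, 8 trials per condition with 500-shuffle nulls in the acceptance
script, 1000 shuffles where the null ensemble itself is under test, and a
10⁶-draw Monte-Carlo oracle for the window chance level. Uniformity of the
independent-phase distribution is tested on one phase per pair, because
strikes within a pair share a slowly drifting relative phase and pooling
them would violate the chi-square independence assumption. Round-trips
through the CSV formats are exact to 10⁻⁹ (12 significant digits on disk).
Seeds are explicit everywhere; identical seeds reproduce simulations and
null ensembles bitwise.

## Known limitations

- The crowd model has no contact mechanics, overtaking, or emergent lane
  formation; lane structure is configured, not discovered. Condition
  contrasts on synthetic data validate the measurement chain only.
- Strike generation is a renewal process with optional chained frequency
  coupling; it has no step-length/speed coupling, so gait and trajectory
  are linked only through walk start/stop times.
- The IMU surrogate omits swing-phase dynamics; detector defaults are not
  tuned to any real sensor.
- Shoulder rotation responds to avoidance pushes alone, not to gait phase
  or torso dynamics.
- Stage instants are evaluated on the 30 Hz grid; crossing times are exact
  only when the geometry places them on a sample.
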