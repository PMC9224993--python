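# Methods

`defensetrack` re-implements, as a tested pipeline, the quantitative core of
a rodent threat-avoidance study: kinematic classification of defensive
behaviors from pose-estimation output, zone-based scoring of five assays,
isosbestic correction of two-channel fiber photometry, peri-event and
spatial analyses of the corrected signal, and the matching statistics.
Because the study's raw videos and recordings are not part of this
repository, every stage is validated against a synthetic-session generator
that plants known behavior, occupancy, and neural structure.

## Behavior classification

Pose tables carry per-frame x/y/likelihood for four bodyparts (nose, both
ears, tailbase) at a nominal 30 frames/s. The head position is the centroid
of nose and both ears — the upstream protocol says "head" without defining
it, and the centroid is robust to nose dropouts. Coordinates below a
likelihood threshold (default 0.9) are linearly interpolated between
confident neighbors. Positions are boxcar-smoothed (default 5 frames,
~0.17 s) before forward differencing so that pixel-level tracking jitter
cannot push a resting animal over the freezing threshold; whether the
original analysis smoothed positions or velocities is unstated, and
smoothing positions is the choice that preserves the
"smoothing-never-increases-max-speed" guarantee.

The four behavior definitions, with their defaults:

| behavior | definition | parameters |
|---|---|---|
| freeze | head AND tailbase speed < 0.25 cm/s for >= 0.33 s | `freeze_speed_max_cms`, `freeze_min_dur_s` |
| stretch-attend (SAP) | nose-tailbase distance > 1.2 x body length AND tailbase speed < 1 cm/s | `sap_stretch_factor`, `sap_tail_speed_max_cms` |
| approach | signed velocity toward threat > 3 cm/s | `run_speed_min_cms` |
| escape | signed velocity toward threat < -3 cm/s | `run_speed_min_cms` |

Body length is the session median nose-tailbase distance. Conditions are
ANDed per frame and maximal runs become bouts; a single supra-threshold
frame splits a bout. "Approximately 1.2 body lengths" is implemented as
exactly 1.2 (configurable). `postprocess_bouts` exposes gap-merging and
minimum-duration filtering for sensitivity analyses (defaults off). Escape
velocity (flight vigor) is the mean tailbase speed over escape bouts. Jump
counting is not computed kinematically — no kinematic jump definition
exists in the source protocol — and enters only as an optional
manually-annotated column.

## Assay scoring

Zone maps are named polygons in centimetre coordinates (origin lower-left):
open field 34x34 with 25%-side corner squares and a central 50% square; LTE
box 47x47 with a 13x7 burrow replacing one corner; predator corridor 70x25
with the threat point at the rat-wall midpoint, safe zone = the third
nearest the safe wall and threat zone = the distal third (the two-thirds
split is used for photometry zone means); EPM with 30x7 arms (open arms
horizontal); and a 42x20 two-chamber place-test box. The safe/threat
fractions are not stated by the source for the behavioral threat zone;
thirds were chosen for consistency with the photometry definition and are
configurable in the zone JSON. Zone membership uses the head centroid and
closed polygons (boundary counts as inside); entries are debounced at 0.2 s
sustained presence.

LTE trials start at barrier removal; latency is the first frame the head
enters the burrow polygon, floored at one frame period, and no-entry trials
score 61 s (trial limit + 1). The per-animal statistic is mean(5 light-on)
minus mean(5 light-off) latencies. Habituation screening requires strictly
more burrow time than each of the other three corners (ties fail).
Epoch metrics are computed separately inside ON and OFF frame sets with
counts reported per condition (not rates); the EPM protocol analyzes only
the first four of five 2-min epochs (`EpochSchedule.head(4)`).

## Photometry

Raw streams interleave a 470-nm calcium channel with a 405-nm isosbestic
reference; acquisition rates are always read from timestamps. Processing:
de-interleave; interpolate the reference onto the signal clock; ordinary
least-squares fit of reference onto signal over the whole session (a
Theil–Sen variant is available for artifact-heavy sessions);
dF/F = (signal - fitted)/fitted; z-score over the whole session (the source
does not state the normalization window; whole-session is recorded in the
outputs); align to video frames by nearest sample within one sample period.
No filtering is applied by default.

One numerical caveat worth knowing: with white noise on both channels, the
linear interpolation of the reference onto signal timestamps makes adjacent
corrected samples share one reference sample, which induces a small positive
lag-1 autocorrelation (~0.3 at the default gains) in otherwise structureless
data. This is inherent to regression-based correction of an interleaved
stream, not residual artifact; the whiteness test therefore uses
signal-channel noise, and a second test bounds the interpolation leak.

Event analyses: peri-event traces are aligned to bout onsets over a ±5-s
window (events too close to the recording edges are dropped); EPM arm-entry
responses average z-dF/F over the second after entry; spatial tuning bins
approach- or escape-frame z-dF/F into 10 equal-width bins of distance from
the safe wall, and the headline Pearson r is computed on the 10 (bin
center, bin mean) pairs — matching the per-bin presentation with 8 degrees
of freedom — with a sample-level r reported alongside. Empty bins are
excluded pairwise and flagged.

## Statistics

Group contrasts (ON-OFF, CNO-SAL) are compared with two-tailed Student
t-tests using pooled variance — the reported degrees of freedom
(n1 + n2 - 2) identify the pooled rather than Welch form. Correlations are
Pearson. Normality uses a Lilliefors test whose p-value is computed by
seeded Monte-Carlo simulation of the null at the exact sample size
(10,000 replicates by default) rather than table lookup. Multiple
comparisons use Benjamini–Hochberg FDR. Note that BH adjustment is not
idempotent in general (re-applying it to tied adjusted values raises them);
the implementation and tests reflect the true monotonicity properties.
Histology overlap fractions are provided both pooled over animals
(sum of overlaps / sum of denominators) and as per-animal means, with
lPAG + vlPAG counts combined per animal before any fraction is formed;
the two modes differ whenever denominators differ across animals.

## Synthetic sessions

The generator is first-class, tested code; its defaults define the study
conditions used throughout the tests.

Trajectories follow a semi-Markov state machine over {locomote, pause,
freeze, SAP, approach, escape, burrow-dwell}. Dwell times are exponential
(locomote 2–3 s, pause 2 s, SAP 1.5 s means) except freeze bouts, which are
log-normal (median 2 s, sigma 0.8) because the minimum-bout robustness
analysis needs a realistic heavy-tailed immobility distribution; none of
these distributions is a fit to the source data, which prints no bout
statistics. Planted freeze bouts shorter than the 0.33-s definition (or cut
below it by the session end) are converted to pauses: a sub-definition
immobility epoch is, by definition, not a freeze bout and would otherwise
be unrecoverable. Locomotion speed is N(8, 1.5) cm/s clipped to [4, 12];
pauses drift at 1.5 cm/s (above the freeze threshold, below the run
threshold); SAP holds keep a 0.5 cm/s head drift so immobility is never
co-detected.

Corridor sessions evolve in polar coordinates around the threat point
(rat-wall midpoint): tangential states have identically zero signed
velocity toward the threat and radial states exactly the planted run speed,
which is what makes bout-count recovery exact. Escapes are range-limited so
the lateral offset of their ray stays inside the corridor band. The head
centroid is steered directly and ears are placed so centroid(nose, ears)
equals it identically; the tailbase trails rigidly, so tailbase velocity is
discontinuous at heading changes (a deliberate simplification — no
classifier depends on tail acceleration). Trajectories are confined to a
central corridor band and inset boxes in rectangular arenas so all
bodyparts stay inside the arena polygon. Emulated pose noise consists of
Beta(20, 1) likelihoods with optional dropout frames (likelihood < 0.5,
coordinates jittered) to exercise interpolation.

Photometry is emulated at 20 Hz total, alternating channels (the literal
protocol reading; the pipeline never assumes a rate). Both channels share a
double-exponential bleach and a smooth multiplicative motion artifact;
Poisson calcium transients (thinning; difference-of-exponentials kernel,
0.1 s rise, 1 s decay, 5% dF/F amplitude, base rate 0.8 Hz) enter the
signal channel only. The transient rate is modulated linearly in distance
from the safe wall with configurable sign and depth (0.8): sign = -1
reproduces the CCK-like pattern (more active near safety), +1 the
pan-neuronal pattern, and an escape-only mask reproduces escape-locked
tuning.

What the generator does **not** emulate: real pose-estimator error
structure (identity swaps, occlusions), gait or posture dynamics within
states, hemodynamic or wavelength-dependent artifacts, sensor saturation,
and behavioral correlations beyond the state machine. Passing tests
therefore demonstrate correctness of the *computations* under the stated
assumptions, not robustness to every failure mode of real recordings.

## Ground-truth recovery and problem sizes

Recovery tests run the kinematics with `smoothing_window_frames=1` on
noise-free tracks: a 5-frame boxcar spreads each state transition over
several frames by construction, which is incompatible with a one-frame
boundary requirement; smoothing remains the default for jittered data.
Ground-truth zone occupancies and entry times are derived from the emitted
trajectory with plain rectangle arithmetic, independent of the
shapely-based scoring path.

Test problem sizes (chosen to exercise each property at meaningful scale):
40 ten-minute sessions for the bout-duration robustness correlation, 20
three-minute sessions for classifier recovery, 10–40 ten-minute sessions
for photometry recovery and tuning-sign checks, 1,000 random instances per
statistical oracle, and 2,000 samples for the Lilliefors type-I calibration.
The full suite runs in well under a minute on one CPU.

## Known limitations

* The automated classifiers reproduce the stated kinematic rules only; the
  original workflow additionally had experimenters manually check bouts,
  which cannot be reproduced.
* Spatial tuning r on 10 bin means has wide sampling variability in short
  sessions with few runs; the sample-level r is reported alongside.
* The LTE trial builder steers entries to the planted latency with brief
  super-normal speeds when the schedule demands it; latency scoring is
  unaffected.
* `simulate_cohort` varies only seeds and supplied configs; it does not
  model between-animal covariance structure.
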