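# Methods

## The virtual player

The character's two hands are modelled as second-order Kuramoto phase
oscillators on circles in a frontal plane. The state per hand is a
wrapped phase θ (rad) and an angular velocity ω (rad/s); the coupling
acts on the *acceleration*:

- `k_inter` (rad/s², default 0.0075) pulls each virtual hand toward the
  human's *opposite* hand — the crossed pairing is what makes two
  people facing each other move "in mirror". The gain is deliberately
  small: large gains would turn the character into a virtual mirror of
  the participant, small ones keep it moving autonomously while still
  responding.
- `k_intra` (rad/s², default 0.005) couples the character's own hands,
  keeping its bimanual movement coherent.

Integration is explicit Euler at `sample_rate` = 50 Hz (Δt = 0.02 s),
velocity first, then phase with the updated velocity. A second-order
sine-coupled oscillator driven at constant detuning Δω is the pendulum
φ̈ = −K sin φ with φ̇(0) = Δω, so phase lock occurs exactly for
|Δω| ≤ 2√K (the separatrix energy). With K = 0.0075 this gives
0.1732 rad/s; the acceptance script measures the simulator's empirical
threshold by bisection and checks it against an independent
`solve_ivp` integration of the pendulum. No damping exists in the
model, so "lock" means libration: the relative phase oscillates
boundedly around alignment rather than settling to a constant.

**Phase-argument choice.** The circle kinematics is sometimes written
as cos(ω(t)·t), which is discontinuous when ω varies. We integrate the
phase incrementally (θ_k = θ_{k−1} + ω_k Δt), which coincides with the
product form for constant ω and is the only continuous reading; the
constant-ω tests exercise exactly that equivalence.

**Coordinate frame.** Right-handed, ŷ vertical, ẑ lateral (the circle
plane), x̂ the facing axis; the movement plane sits at
`plane_offset` = 0.343 m in front of the character, which stands
`partner_distance` = 1.246 m from the participant. Positions never
leave the plane: the x-component of every sample equals the centre's.

**Radius noise.** Classic one-dimensional gradient (Perlin) noise:
lattice at integer seconds, per-node pseudo-random gradients obtained
by a SplitMix64 hash of (seed, node) — stateless, so any set of query
times gives consistent values — quintic-fade interpolation, single
octave. Raw 1-D gradient noise with unit-bounded gradients has extremes
±0.5; the output is rescaled by 2·amplitude so the signal spans
[−amplitude, +amplitude], with `noise_amplitude` = 0.085 m by default.
The noise is zero at every integer second and C¹ in between. The right
and left hands use independent streams derived from (trial seed, side).
Lattice frequency and octave count are conventions of this
implementation; only the range, the continuity and the 50 Hz sampling
are externally constrained.

**Parameter estimation.** From a training trajectory: centre = mean
position; radius = mean distance to that centre; frequency = mean
derivative of the unwrapped atan2 phase, reported as a positive
magnitude (rotation direction is carried by each side's kinematic sign
convention: the left hand's lateral coordinate is negated). Estimation
refuses trajectories shorter than 2 s or with mean radial distance
below r_min = 0.03 m. On circles spanning whole periods the estimator
is exact to float precision; on 60-s circles with 5 mm Gaussian
position noise it recovers the radius within 0.5 mm and the frequency
within 0.003 rad/s (the tests require 2 mm / 0.02 rad/s).

## The synthetic dyad

No model of the human player is inherited from the experimental work
this package operationalises; everything in `HumanProfile` is our
scaffolding, and it is deliberately simple. Three kinds:

- `constant`: fixed angular velocity — the analytically tractable
  driver used in the locking tests.
- `drifting` (default): ω follows an Ornstein–Uhlenbeck process
  (stationary sd `drift_sd` = 0.3 rad/s, correlation time `drift_tau`
  = 5 s) around `base_omega` = 2.7 rad/s — a human-like slow tempo
  wander.
- `coupled`: the human also adapts toward the character with gain
  `k_human`, using the same crossed sine coupling.

Defaults (radius 0.16 m, ω 2.7 rad/s, centres shoulder-width apart at
chest height, 5 mm position noise) match the magnitudes estimated from
real training trials. What this generator does *not* emulate: motor
signatures, movement segmentation, fatigue, gesture variety, reaction
latencies beyond the one-tick loop delay. Tests passing on these
partners show the machinery is correct, not that real humans behave
this way.

`run_trial` wires one trial per condition. The *human* condition is a
verbatim pass-through of a second simulated human (the oscillator model
is unused); the two oscillator conditions co-simulate human and
character tick by tick with a one-sample (20 ms) phase delay in each
direction, mimicking the networked two-machine setup and avoiding
algebraic loops. With `k_inter` = 0 the co-simulated virtual output is
bit-identical to an open-loop run, which the tests check. In the
*human* condition a `coupled` profile adapts to the partner's recorded
phases; the partner itself is simulated open loop (no mutual two-human
loop — a simplification).

**Button model.** The synchrony-report button is pressed once the
wrapped relative phase between the facing hands has stayed within π/4
for 0.5 s. Both parameters are arbitrary (the real data are subjective
reports) and configurable.

**Questionnaire and sync-time synthesis.** Responses are
round(clip(condition effect + participant intercept + Gaussian noise,
−3, 3)); the intercept sd defaults to half the noise sd so a zero-noise
table is exactly constant. The sync-time generator gives each
participant an idiosyncratic base button tendency, makes a fraction of
them near-ceiling pressers (which is what renders the raw
distributions non-normal), and adds small condition shifts (+2.2 s
coupling, −3.1 s no-coupling relative to the human baseline) under
much larger between-participant spread — the structure that makes
baseline correction worthwhile.

## Synchrony analytics

Phase is extracted geometrically — centred atan2 in the movement plane,
with the left side's lateral coordinate negated — because it inverts
the generative kinematics exactly and is causal, hence implementable in
a real-time loop. A Hilbert-transform variant (analytic signal of the
vertical coordinate, +π/2 convention shift) is available offline.
Samples within r_min = 0.03 m of the centre carry no angular
information and repeat the previous phase (freeze rule), which also
reflects that the character keeps moving when the player stops. The
online phase estimator of the original real-time system is
undocumented; equivalence with it cannot be verified.

The order parameter R(t) = |mean exp(iθ)| is computed relative to the
first stream's phase — mathematically a no-op (rotation invariance),
numerically it makes identical phases give exactly 1.0. Lock detection
unwraps the relative phase, takes |dφ/dt|, smooths it with a centred
moving window (default 2 s) and reports runs below a tolerance
(default 0.1 rad/s).

## Statistical pipeline

Cliff's delta is computed from its definition (normalised difference of
greater/lesser cross-pair counts); the suite checks it against an
exhaustive enumeration oracle. Effect-size labels use cuts
{0.15, 0.33, 0.66} on |δ|; the conventional 0.474 medium/large cut
would label |δ| = 0.5 "large", inconsistent with how the scale is used
for these 7-point items, and the chosen cuts reproduce all ten
published labels. They are configurable.

`compare_paired` gates on Shapiro–Wilk at α = 0.05 — on the margins
for raw condition scores, on the paired differences for derived
difference scores — choosing Wilcoxon signed-rank when normality is
rejected and the paired t otherwise. The Wilcoxon drops zero
differences and uses the normal approximation with continuity
correction for n > 25 (exact p otherwise), matching the default
behaviour of the mainstream scientific Python stack; the statistic is
min(W⁺, W⁻). All-zero differences raise a degenerate-test error, which
`analyze_sync_times` converts into a flagged null result rather than
aborting the whole analysis.

The sync-time analysis is two-stage by design: stage 1 tests the raw
per-participant times (Shapiro per condition, Wilcoxon coupling vs
no-coupling); stage 2 removes each participant's overall
button-pressing tendency by subtracting their *human*-condition time,
then tests the two difference samples (Shapiro each, paired t, Cliff's
delta). Because both stages of a paired design see the same difference
vector, their power differs only through the test choice; the
qualitative gain of stage 2 is that the corrected differences are
normal, admitting the more powerful parametric test.

Per-question comparisons use Wilcoxon signed-rank regardless of the
gate (the responses are ordinal) and report raw p-values with no
multiple-testing correction across the ten questions, matching the
reporting convention of the original analysis; a correction can be
applied downstream.

## Problem sizes and numerics

Trials are 60 s at 50 Hz (3001 samples including t = 0). The
acceptance script uses: 8 bisection steps of 240-s simulations for the
locking threshold (the pendulum oracle uses 12 steps of `solve_ivp` at
rtol 1e−9); 100 seeded trials for the invariants; 100 replicates for
estimator recovery; 1,000 random samples for the delta oracle; 200
replicates for pipeline power and size. Phases are wrapped to (−π, π]
after every step and before every sine; derivatives of phase use
nearest-branch unwrapping. All stochastic components draw from
explicitly seeded generators, and trials are bit-reproducible from
(condition, profile, seed).

## Known limitations

- The undamped dynamics never settle: near-threshold classification of
  lock vs drift depends on the observation horizon (we use 240 s, and
  the acceptance check allows 5% on the threshold).
- Euler integration at 20 ms is part of the model definition, not an
  approximation to be refined; changing the step changes the system.
- The synthetic humans are phase oscillators too, so human/virtual
  asymmetries (anticipation, jerk minimisation, segmentation) are
  absent, and statistics computed on synthetic dyads cannot validate
  claims about real participants.
- The published behavioural statistics (Wilcoxon statistic 210, paired
  t = 2.117, difference means 2.217/−3.124 s) depend on the original
  per-participant data, which are not redistributed here; the pipeline
  implements the exact two-stage procedure and the suite marks that
  comparison as unmet rather than approximating it.
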