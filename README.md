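# mirrorgame

A virtual player for the full-body **mirror game** — the dyadic imitation
task in which two partners face each other and mirror each other's hand
movements — together with a closed-loop dyad simulator, synchrony
analytics, and the statistical pipeline used to compare experimental
conditions.

The package is for researchers in joint action, interpersonal motor
coordination and VR embodiment who want an autonomous character that can
*synchronise with* a human partner rather than merely replay animations,
and who need a fully testable offline stand-in for the human side of the
loop.

## The model

Each of the virtual character's hands traces a circle in a frontal (YZ)
plane:

```
p_R(t) = c_R + r_R(t) cos θ_R(t) ẑ + r_R(t) sin θ_R(t) ŷ
p_L(t) = c_L − r_L(t) cos θ_L(t) ẑ + r_L(t) sin θ_L(t) ŷ
```

with the radius jittered by one-dimensional Perlin (gradient) noise,
`r(t) = r(0) + n(t)`, `n(t) ∈ [−0.085, 0.085]` m, so the motion never
looks perfectly mechanical. The phases are driven by a **second-order
Kuramoto system**: angular velocity integrates a sine coupling toward
the human partner's opposite hand (mirror pairing) and toward the
character's own other hand,

```
ω̇_R = K_inter sin(θ_L^H − θ_R^V) + K_intra sin(θ_L^V − θ_R^V)
ω̇_L = K_inter sin(θ_R^H − θ_L^V) + K_intra sin(θ_R^V − θ_L^V)
```

integrated by explicit Euler at 50 Hz (`ω_k = ω_{k−1} + ω̇ Δt`,
`θ_k = θ_{k−1} + ω_k Δt`). The study conditions are `K_intra = 0.005`
with `K_inter = 0.0075` (*coupling*), `K_inter = 0` (*no coupling*), or
the model unused entirely and another human's movement passed through
(*human*). Circle centres, radii (≈ 0.16 m) and frequencies
(≈ 2.7 rad/s) are estimated from a training trial.

Because the system is an undamped driven pendulum in the relative phase
φ (φ̈ = −K sin φ), the character phase-locks to a steadily moving
partner exactly when the frequency detuning satisfies |Δω| ≤ 2√K_inter
≈ 0.173 rad/s — the property the test suite verifies against an
independent numerical integration.

## Worked example

```bash
mirrorgame simulate --condition coupling --seed 42 --out-dir trial_coupling
mirrorgame analyze  --trial-dir trial_coupling
cat trial_coupling/metrics.csv
```

```
condition,mean_R,lock_fraction,time_pressed_s,ratio
coupling,0.800171,0.000000,22.240000,0.370543
```

`mean_R` is the time-averaged Kuramoto order parameter between the
human's right hand and the character's facing (left) hand — 0.80 means
the pair spent the trial mostly aligned in phase; `lock_fraction` is the
share of the trial with relative-phase drift below 0.1 rad/s (0 here:
the default drifting partner wanders too much for strict lock);
`time_pressed_s` is the simulated synchrony-report button time (22.2 s
of 60), and `ratio` its fraction of the trial.

Statistics on the bundled synthetic fixture data (34 participants, a
−2-point effect injected on questions 7 and 9 in the *no coupling*
condition):

```bash
mirrorgame make-fixtures --seed 0 --out-dir fx
mirrorgame stats --questionnaire fx/questionnaire.csv --sync-times fx/sync_times.csv --out-dir stats_out
```

The questionnaire results recover exactly the injected structure —
question 9 at `p = 0.000002` with Cliff's δ = 0.78 ("large"), question
7 at `p = 0.003` with δ = 0.45 ("medium"), all other questions
negligible — and the sync-time results reproduce the two-stage pattern
the pipeline is built around: the raw *no coupling* margin is
non-normal (Shapiro p = 0.004), both baseline-corrected difference
samples are normal (p = 0.26, 0.19), and the paired t-test on
(coupling − human) vs (no_coupling − human) gives t = 2.54, p = 0.016
with a small effect (δ = 0.19).

## Layout

- `src/mirrorgame/core_model.py` — oscillator dynamics, kinematics,
  Perlin noise, parameter estimation
- `src/mirrorgame/dyad_simulator.py` — synthetic human partners,
  closed-loop trials, button / questionnaire / sync-time synthesis
- `src/mirrorgame/sync_analysis.py` — phase extraction, relative phase,
  order parameter, lock detection, time-in-sync
- `src/mirrorgame/stats_pipeline.py` — Cliff's delta, effect labels,
  normality-gated paired tests, baseline correction
- `src/mirrorgame/io.py`, `cli.py`, `fixtures.py` — CSV formats,
  manifests, command-line interface, fixture suite
- `docs/methods.md` — modelling assumptions, numerical choices and
  limitations
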