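# Methods

## The control problem

`abstractmyo` implements an *abstract* myoelectric control scheme for a
multi-grasp prosthetic hand, offline and fully testable. Two surface-EMG
channels (flexor and extensor carpi radialis by convention) drive a cursor
in the first quadrant of a 2D task space: the normalized mean-absolute
value (MAV) of channel 1 is the x coordinate, of channel 2 the y
coordinate. Four circular targets on an arc correspond to power, a
switchable tripod/pinch slot, point, and hand-open. A target is selected
by holding the cursor inside its disc for a fixed dwell period; a
two-state hand machine (OPEN / CLOSED) gates the resulting commands so no
grasp can fire inadvertently — a closing grasp requires an open hand *and*
a prior visit to the rest basket near the origin, and an open command
requires a closed hand.

The adaptation layer personalizes the angular partition of the quadrant.
The cursor's polar angle *v* at the moment of each decision is the single
feature of a Gaussian Naive Bayes model: for each target, the *v* values
of its correct commands (those without "unexpected grasp" feedback) are
fit with a Gaussian (sample mean, n−1 standard deviation). For each
adjacent pair of targets the customized decision boundary is the angle
where the two prior-weighted class densities are equal:

σ_j² (v−μ_i)² − σ_i² (v−μ_j)² = 2 σ_i² σ_j² [ln(π_i/π_j) + ln(σ_j/σ_i)]

a quadratic in *v* whose root inside (μ_i, μ_j) is taken. With equal
variances and equal priors this reduces to the midpoint (μ_i+μ_j)/2, which
is why the symmetric default geometry yields the default partition
22.5°/45°/67.5° exactly. Unexpected commands form the verification set: a
"correction" is an unexpected command whose angle classifies to the
intended target under the new boundaries.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| sampling rate | 500 | Hz | two-channel EMG device rate |
| band-pass | 20–230 | Hz | 4th-order Butterworth; 230 Hz leaves margin under the 250 Hz Nyquist |
| notch | 50, Q=30 | Hz | mains interference |
| MAV window / step | 150 / 50 | ms | typical myocontrol latency budget; device-tunable |
| calibration | rest median, 95th-pct contraction | — | robust to transients and spikes |
| m_cap | 1.5 | — | overshoot beyond the calibrated maximum stays representable but bounded |
| target angles | 11.25, 33.75, 56.25, 78.75 | deg | bisectors of the default decision regions |
| target center radius / disc radius | 0.7 / 0.13 | task units | discs must not overlap (adjacent center distance 0.273 > 0.26) |
| basket radius | 0.15 | task units | re-arming region |
| dwell | 500 | ms | fixed dwell period, configurable |
| trial timeout | 1500 | ms | familiarization limit; stage cleared at >70% per-target success |
| σ floor | 0.5 | deg | avoids degenerate class spikes from ultra-consistent users |
| priors | equal | — | "equal density" names the class-conditional densities; empirical priors available |

## Virtual user

The simulator replaces the participant and the hardware. A virtual user
aims at each target with Gaussian angular error (σ = 5° by default),
reaches outward from the basket at 1.4 task-units/s with per-sample tremor
noise (σ = 0.01), dwells, returns, and re-arms. With probability 0.15 a
closing reach is mis-aimed: the aim draw is truncated into a neighboring
decision region, modeling combined systematic and random aiming error —
a rate representative of the unexpected-grasp frequencies this task
produces in practice. On a wrong executed grasp the user submits feedback 1–5 s
later, reopens the hand and retries; sessions follow the two-half block
protocol (point, tripod, power, point → point, pinch, power, point) with
the tripod→pinch switch issued as a timestamped remote config update
between the halves.

Reach endpoints that miss every disc are pulled toward the nearest disc
center to just inside the disc edge (0.9 × disc radius). The pull is
always toward the same decision region's center, so it never changes the
classification of a reach; settling near the edge preserves near-boundary
decision angles, which is what makes post-hoc "corrections" reachable.

Raw EMG is emulated as unit-variance band-limited (20–230 Hz) Gaussian
noise amplitude-modulated by the commanded activation envelope, plus a
50 Hz mains component (amplitude 0.05) and white sensor noise (σ = 0.02).
The expected MAV of a constant envelope *a* is a·√(2/π) (rectified
Gaussian mean).

What the simulator does **not** emulate: motor-unit physiology, limb
position and electrode-shift effects, fatigue, learning within a session,
and any internet transport. Passing tests therefore demonstrate the
correctness of the signal chain, decoder, logging and adaptation logic
under the stated behavioral model — not performance on human data.

## Numerical and design choices

- **Zero-phase filtering** (forward–backward) is the default, suiting
  offline analysis; a causal mode exists for closed-loop realism.
- **MAV timestamps** mark the trailing window's end; comparisons against a
  commanded envelope are made at window centers, since a trailing window
  lags the instantaneous envelope by half its length.
- **Angles are linear degrees on [0, 90]** — no circular statistics; the
  quadrant is bounded far from wraparound.
- **Boundary tie-break**: a boundary angle belongs to the higher-indexed
  target (half-open intervals), applied identically in decoding and
  verification.
- **Executed target** of a command is `classify_target(v, boundaries in
  force)` at dwell completion. The dwell selector fires on discs, but the
  command's target follows the angular partition, so remotely updated
  boundaries change behavior mid-session exactly from their timestamp.
  With default boundaries (discs centered on region bisectors) the two
  views coincide.
- **Decision angle at dwell completion**, not onset.
- **Feedback labeling** links each feedback event to the most recent
  unlabeled command strictly before it, with no time bound; links beyond
  60 s raise a QC warning. Labeling is recomputed from scratch on every
  call, making it idempotent.
- **Degenerate fits**: a target with fewer than two training decisions, an
  unordered mean pair, or an adapted set violating 0 < b12 < b23 < b34 <
  90 falls back to the default for the affected boundary (or set), with an
  explicit flag. A density pair with no equal-density root between the
  means falls back to the midpoint with a warning.
- **Serialization** uses ISO-8601 UTC millisecond timestamps and `repr`
  floats, so write∘read∘write is byte-stable; CSV and NDJSON round-trip
  field-for-field, ARFF is a write-only flat command relation.
- **Decisions pool by target index**, not grasp name, across the
  tripod→pinch switch.

## Problem sizes

Simulation-backed checks use 500 decisions per target for boundary
recovery (recovered within ±1° of the symmetric defaults; shifted
partitions within ±1.5°), 1000 random mean/σ pairs for the closed-form
vs. bisection agreement (≤ 1e−6°), 10⁴ random fire events for the gating
invariant, 16-block sessions (64 planned grasps plus retries) for protocol
accounting, and 6000-sample (12 s) EMG records for envelope recovery
(correlation > 0.95 per channel at SNR ≥ 10). These sizes keep the full
suite and the acceptance script in the tens of seconds.

## Known limitations

- The Gaussian aim model (linear in angle, not von Mises) is a
  simplification chosen for consistency with the adaptation model.
- The disc-based dwell geometry leaves small angular gaps between
  adjacent discs; a reach into a gap settles into the nearest disc rather
  than timing out, which slightly concentrates decision angles.
- Calibration returns a percentile, not a population maximum; its value
  on synthetic plateaus sits between the rectified-Gaussian mean and the
  plateau.
- The ARFF export is write-only.
- Whether the original system's classifier used empirical priors, or
  pooled σ across a pair, cannot be determined from the published
  boundary values alone; equal priors and per-class σ are the defaults
  here, with empirical priors available as an option.
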