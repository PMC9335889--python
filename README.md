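# abstractmyo

Offline, testable implementation of an **abstract myoelectric control**
pipeline for multi-grasp prosthetic hands: two-channel EMG conditioning and
mean-absolute-value (MAV) feature extraction, a 2D-cursor decoder with
dwell-based target selection and a gated grasp state machine, timestamped
session logging with user-feedback labeling, and Gaussian-Naive-Bayes
adaptation of the angular decision boundaries from real-life labeled
decisions. A virtual-user simulator stands in for the human participant
and the hardware, so the whole loop runs and is verified without any
recorded data.

It is aimed at researchers in myoelectric control and neuroprosthetics who
want a reproducible reference of this control/adaptation scheme, a
test-bed for boundary-adaptation ideas, or a generator of realistic
labeled session data.

## The model

The normalized MAVs of two forearm muscles place a cursor at (m₁, m₂) in
the first quadrant. Four circular targets carry power, tripod/pinch,
point, and hand-open; holding the cursor in a target's disc for the dwell
period (500 ms) issues that grasp, and a state machine accepts a closing
grasp only when the hand is open and the cursor has re-armed in the rest
basket. Three boundaries partition the cursor angle v ∈ [0°, 90°] into
the four target regions; the defaults are the symmetric partition
(22.5°, 45°, 67.5°).

Adaptation fits, per target, a Gaussian N(μ, σ²) to the decision angles v
of the *correct* commands, and places each customized boundary where the
prior-weighted densities of the adjacent pair are equal — for equal σ and
priors, the midpoint (μᵢ+μⱼ)/2. Commands labeled "unexpected" by user
feedback verify the result: a correction is an unexpected command whose
angle falls in the intended target's new region. See `docs/methods.md`
for the full model, parameter table and design choices.

## Worked example

`examples/03_adapt_boundaries.py` simulates a user who aims ~6° high on
target 1 through a full 16-block pick-and-place session and adapts their
boundaries:

```
| | boundary 1–2 | boundary 2–3 | boundary 3–4 |
|---|---|---|---|
| default | 22.5° | 45.0° | 67.5° |
| customized | 24.8° | 46.0° | 69.0° |

| no. of commands | no. of feedback | no. of corrections |
|---|---|---|
| 140 | 6 | 3 |
```

The 1–2 boundary moves up toward the user's biased aim; of the 6 wrong
grasps they reported during the session, 3 would have been routed to the
intended grasp under the customized boundaries. The other examples walk
the signal chain (`01_signal_chain.py`: calibration, filtering, MAV
normalization, envelope-tracking correlations > 0.95) and the closed-loop
decoder (`02_decode_session.py`: gated command stream, feedback events,
retries).

A thin CLI wraps the same library calls:

```sh
abstractmyo simulate --blocks 16 --seed 7 --out session/
abstractmyo adapt    --bucket session/ --out new_config.yaml
abstractmyo report   --bucket session/ --user P1 --out report/
abstractmyo export   --bucket session/ --format arff --out session.arff
```

## Layout

```
src/abstractmyo/   emg (signal chain) · decoder (cursor/dwell/state machine)
                   session (data bucket, labeling, CSV/NDJSON/ARFF)
                   adaptation (angle models, equal-density boundaries)
                   simulator (virtual users, sessions, synthetic EMG)
                   config · report · manifest · cli
examples/          one narrative script per capability
tests/             unit, property (hypothesis) and acceptance suites
docs/methods.md    model, parameters, numerical choices, limitations
```
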