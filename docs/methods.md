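# Methods

## Problem setting and signal model

The decoder targets a cue-paced motor task: a seated subject, eyes
closed, rests for 10 s and then performs 20 self-paced upper-limb
movements (10 arm lifts, 10 hand reaches) on audible cues separated by
random 5 s or 6 s gaps. EEG is recorded from 16 10–20 electrodes
(Fz, F3, FC2, FC1, FC5, C2, Cz, C1, C3, C5, T3, Cp2, Cp1, Cp5, Pz, P3;
right-earlobe reference) at 500 Hz in microvolts; upper-limb kinematics
(shoulder and elbow flexion/extension angles, hand endpoint) come from
optical capture at 120 Hz and are linearly resampled onto the EEG
clock.

Decoding rests on two well-established EEG phenomena:

* **Movement-related cortical potentials (MRCP)** — slow negative
  shifts over motor cortex that build up before movement onset and
  resolve during execution. They live below ~2 Hz and motivate the
  MRCP-amplitude, delta-power and RMS features on the fronto-central
  FC2/C2 pair.
* **Alpha event-related desynchronization** — attenuation of the
  8–12 Hz rhythm during movement, captured as squared alpha-band
  amplitude on the parietal P3/Pz pair.

## Preprocessing

The common average reference subtracts the instantaneous cross-channel
mean: `e_car_i(t) = e_i(t) − (1/N) Σ_k e_k(t)`. It is idempotent and
forces the channel sum to zero at every sample — both are asserted as
properties.

Bandpass filters are linear-phase Hamming windowed-sinc FIRs. The tap
count is the smallest odd integer at or above `3.3·fs/low` (about three
cycles of the lowest passband frequency — the usual automatic-design
heuristic), capped at a third of the signal length for short inputs.
Because a windowed-sinc crosses its band edge at −6 dB, the cutoffs are
shifted into the transition band (low edge by 0.20·Δf outward, high edge
by 0.275·Δf, with Δf = 3.3·fs/M the Hamming transition width) so that
the nominal band edges sit above −3 dB while 0.5·low and 2·high fall
below −20 dB; the design tests verify this response contract directly.
Offline analysis filters forward–backward (zero phase, reflect-padded);
a causal mode (`y[n] = Σ b_k x[n−k]`, zero history) exists for
real-time parity studies, with group delay `(M−1)/2` samples.

## Features and delay embedding

* MRCP amplitude: the signed 0.1–2.0 Hz trace (μV).
* Delta power: the 0.1–4.0 Hz trace squared (μV²).
* Alpha power: the 8–12 Hz trace squared (μV²).
* RMS: square root of the mean squared 0.1–4 Hz-filtered signal over a
  causal trailing window of `N_a = round(400 ms · fs)` samples (the
  window is causal because a prosthesis controller cannot look ahead;
  the leading `N_a−1` samples use the available shorter prefix). Which
  band feeds the RMS is configurable (`band=None` computes it on the
  CAR-only signal); the 0.1–4 Hz default matches the slow-potential
  family it belongs to.

Channel selection defaults to the fixed pairs above (FC2/C2 for the
slow features, P3/Pz for alpha), reproducing selection-by-inspection of
feature plots. An automatic alternative ranks channels by a
discriminability score — the larger, over the two movement classes, of
|mean(f | class) − mean(f | rest)| / pooled SD — with ties broken on the
channel label so the ranking is independent of input order.

Each selected channel contributes three delay-embedded columns
`[f(t), f(t−L), f(t−2L)]`, `L = round(250 ms · fs)` = 125 samples; rows
exist for `t ≥ 2L`. Two channels × three lags give the 6-wide
single-feature design matrix; concatenating all four features gives the
24-wide combined matrix.

## Intention classifiers

**Backprop network.** One sigmoidal hidden layer (30 units for a single
feature, 80 for the combined matrix) and a sigmoidal output unit mapped
affinely onto [−1, 1]; targets are the class codes (+1 lifting,
−1 reaching, 0 rest). Inputs are z-scored with training-partition
statistics (sigmoid units need bounded inputs; the scaler travels with
the model). Training is full-batch gradient descent on the MSE with
learning rate 1.0 on the batch-mean gradient, classical momentum 0.9,
at most 800 epochs (2000 for the stage-two regressors), stopping early
after 300 consecutive epochs that fail to improve the running best MSE
by 1e-6. Two numerical facts drove these choices: (a) with batch-mean
gradients, small rates never escape the rest-majority plateau — the
network converges to the constant prior output — while rate 1.0 with
momentum descends reliably and its transient overshoot decays within
~100 epochs; (b) the early stop compares against the running best with
a long patience precisely because that transient would otherwise
trigger it mid-plateau. Full-batch updates make the fit invariant to
duplicating training rows and bit-reproducible under a fixed seed.

The continuous output is discretized at ±0.5 (the midpoints toward the
nearest class code); values exactly at a threshold go to rest, the
conservative choice for a prosthesis.

**k-nearest neighbors.** The training rows (z-scored) are stored; a
query is voted on by its k nearest neighbors either by majority or by
similarity weight `Sim = 1/(1+d)`. Neighbor search uses scikit-learn;
the vote rules and tie-breaks are implemented here, and a brute-force
distance-scan oracle in the tests confirms the predictions. Ties go to
rest when rest is among the tied classes, else to the smallest code.
`k ∈ {1, 3, …, 25}`, metric ∈ {euclidean, cityblock, cosine} and both
vote rules are selected by 5-fold cross-validated misclassification on
the training partition (unshuffled folds; ties break toward smaller k,
then metric order, then vote order, so selection is deterministic).

**Train/test split.** Chronological 80/20. Adjacent delay-embedded rows
share samples, so a random split would leak the test set into training;
the chronological split is the conservative protocol. Accuracy is
per-sample over the test segment. For classification the embedded rows
are thinned to one per 4 EEG samples (125 rows/s); the label track is
untouched and the thinning is a configurable problem-size choice
(`PipelineConfig.row_stride`).

**Gating.** A six-row table: whenever the residual limb is not moving
the final output is Rest, otherwise the classifier's output stands.
Limb motion is detected from the shoulder angle — 5-sample median
filter, 100 ms moving average, central-difference velocity over the
same span, |velocity| > 10°/s sustained ≥ 200 ms, with sub-threshold
gaps shorter than 250 ms bridged first. The smoothing beyond the median
filter is required because interpolated marker jitter otherwise
saturates the velocity threshold at rest, and the gap bridging keeps
the outbound and return strokes of one movement (whose velocity crosses
zero at the turnaround) in a single detected span.

## Stage two: distal-motion estimation

The motion database holds one record per EEG-clock sample inside each
labeled movement span plus 0.5 s of adjacent rest: (subject, class
code, shoulder angle at t/t−250 ms/t−500 ms, elbow angle, endpoint
x, y). Estimators are 10-hidden-unit backprop nets with 4 inputs
(class + shoulder triple), min/max-scaled to [0, 1] by training
statistics; the elbow net has one output, the endpoint net two (x and y
jointly — matching one network per target per subject). Training is
leave-one-subject-out; the excluded subject's records never enter the
fit (asserted by id audit), and predictions are bounded by the training
target range because the sigmoid output is mapped onto it. Out-of-range
queries are clipped with a warning.

## Synthetic data: what it emulates, and what it does not

The generator reproduces, per trial: a half-cosine negative MRCP ramp
rising over the 1.5 s before movement onset and decaying over the
movement, placed on FC2 and C2 with class-specific amplitude (defaults
−8 μV lifting, −12 μV reaching) and class-specific lateral weighting
(lifting 1.0/0.8 on FC2/C2, reaching 0.8/1.0) so the two classes are
separable by amplitude and topography; a 10 μV, 10 Hz parietal alpha
oscillation whose envelope drops to 0.4 during movement; and 1/f
(exponent 1) background noise on all 16 channels, default 5 μV RMS —
chosen once so the delta-band noise floor sits below the MRCP
amplitudes, i.e. a decodable but noisy regime; raising it is the
difficulty dial. Movement onset lags the cue by 400 ms; movements last
2.0 s (lift) / 2.4 s (reach) with minimum-jerk shoulder excursions from
5° to 90° whose return mirrors the outbound. Lifting keeps the elbow at
175° (straight arm rotating about the shoulder, 0.6 m); reaching dips
the elbow (depth 50°, minimum at 30° of shoulder excursion, back to
extended by 60°) and drives the endpoint to its plateau within the
first 20° of shoulder motion. Angle noise is 0.5° Gaussian clipped at
3σ (so template properties hold deterministically); subjects differ by
small template perturbations (amplitude ±20%, extended elbow ±2°, dip
depth ±5°, arm length ±3 cm). Everything derives from one integer seed
(per-subject streams via `SeedSequence([seed, subject_index])`) and is
bit-reproducible.

The generator does **not** model eye/muscle artifacts, electrode drift,
non-stationary backgrounds, volume-conduction topography beyond the two
signature pairs, or amputees' altered cortical activations. Passing
tests therefore demonstrate that the pipeline recovers the structure it
assumes when that structure is present (and nothing when it is absent —
the null-world control), not that real-EEG accuracy levels are
guaranteed.

## Statistics

Chance level is either the majority-class prior (`prior_max`) or the
mean accuracy of the fitted predictions against label-shuffled copies
(`permutation`); for a fixed prediction the permutation level equals
Σ_c p_pred(c)·p_truth(c), which the tests verify. Significance is the
one-sided exact binomial tail `P(X ≥ round(acc·n/100))` at success
probability chance/100. Published-style tables aggregate per-subject
accuracies as mean ± population SD (÷N), rounded half-up to one
decimal.

## Problem sizes and runtime choices

Default study: 5 subjects × 20 trials (~125 s of 500 Hz EEG each).
Classification rows at stride 4, motion-database records at stride 8
for the leave-one-subject-out summaries, backprop epoch caps 800
(intention) / 2000 (stage two). These sizes keep a full study — both
classifiers, five feature sets, gating, statistics and ten LOSO fits —
at desk scale while leaving every accuracy and RMSE comfortably inside
the margins the tests assert.

## Known limitations

* The MLP loss surface has a genuine rest-majority plateau; the
  momentum schedule escapes it on the study conditions, but pathological
  feature scalings could still stall inside the epoch cap.
* Per-sample alpha power carries movement information but almost no
  lifting-vs-reaching contrast, so the alpha-only decoder tends to the
  majority class; its value in this design is the combined matrix.
* The limb-motion detector is threshold-based; very slow residual-limb
  movements (< 10°/s) gate to Rest by construction.
* Endpoint coordinates are a stipulated shoulder-centered meter
  convention (x forward, y up); no inverse-kinematic model of a
  specific prosthesis is included.
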