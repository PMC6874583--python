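# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
test surface does and does not establish.

## The classification problem

The package targets single-subject identification of concussion from
single-trial EEG responses to a multi-deviant auditory oddball paradigm.
Each subject hears 600 tones: 82% standards (1000 Hz, 50 ms, 80 dB SPL)
and 6% each of a frequency deviant (1200 Hz), a duration deviant (100 ms)
and an intensity deviant (90 dB SPL), presented pseudo-randomly. Deviant
tones elicit the N2b (fronto-central negativity, ~200 ms) and P300
(centro-parietal positivity, ~300 ms), both of which are attenuated and/or
delayed after mild traumatic brain injury. Intensity-deviant responses are
sequenced for count fidelity but never analysed.

The classifier consumes *observations*: one single trial from each of the
three analysed conditions (standard, FDev, DDev), all 64 channels,
restricted to the 50–700 ms window (S = 332 samples at 512 Hz), stacked
into an N × S matrix with N = 3 × 64 = 192 rows in fixed condition-major
order. With t = 36 trials per condition per subject, a 54-subject cohort
yields 1944 observations; a 19-subject follow-up session yields 684.

## Synthetic cohort generator

No public single-trial dataset exists for this paradigm, so the generator
is the primary test surface. It emulates the *statistical structure the
classifier assumes*, not any particular cohort:

- **Components.** N1 (100 ms, −5 µV, fronto-central), P2 (200 ms, +4 µV,
  central) in all conditions; N2b (220 ms, −4 µV, fronto-central) and P300
  (320 ms, +8 µV, centro-parietal) in deviant conditions only. Waveforms
  are Gaussian in time (SDs 18/25/25/55 ms); topographies are Gaussian
  falloffs (SD 0.045 m) on the 2-D projection of the BioSemi-64 montage.
  Amplitudes and latencies are literature-typical defaults and fully
  configurable; they are not estimates from any specific study.
- **Group effect.** Concussed subjects' N2b/P300 amplitudes are scaled by
  (1 − attenuation) and their peaks delayed. The "strong" preset uses
  attenuation 0.6 and delay 20 ms on both components — a large, clearly
  detectable deficit used for the detectability properties.
- **Variability.** Per-subject log-normal component gains (log-SD 0.2),
  per-trial amplitude variability (SD 0.25 of the mean) and latency jitter
  (SD 10 ms). Between-subject variability exceeding within-subject
  variability is what makes subject-exclusive cross-validation the honest
  protocol.
- **Noise.** Per-channel 1/f background (β = 1, 4 µV SD), a posterior
  10 Hz alpha oscillation with random phase per trial (3 µV), and white
  sensor noise (2 µV). These scales put the single-trial component SNR in
  the "moderate" range: components are invisible in single trials but
  resolvable by spatial filtering. Real EEG additionally has channel-
  correlated noise, artifacts, drifts and non-Gaussian events, none of
  which are simulated — passing tests show the pipeline recovers injected
  structure, not that real-data accuracies would match.
- **Epoch grid.** 614 samples = floor(1.2 s × 512 Hz); sample 102 sits
  exactly at stimulus onset, so the prestimulus interval spans −199.2–0 ms
  and the 50–700 ms analysis window starts 26 = ceil(0.050 × 512) samples
  after onset and spans exactly 332 samples. Baseline correction subtracts
  the prestimulus mean per channel. Epochs are stored in single precision;
  the post-correction baseline mean is zero to storage precision (< 1e-5
  µV), which is the tolerance the tests assert.
- **Sequences.** Pseudo-randomisation enforces at least one standard
  between consecutive deviants (configurable), sampling uniformly over
  valid gap compositions via stars-and-bars; counts are exact.
- **Memory.** Only 48 of the 492 standard epochs are materialised per
  subject by default; trial selection later samples 36 uniformly, so the
  downstream distribution is unchanged while a 40-subject cohort stays
  under ~1 GB.

## Tensor assembly

- Standards are sampled to 36 without replacement (an error if fewer than
  36 exist — the paradigm guarantees them); deviants with more than 36
  surviving trials are subsampled without replacement, and deviants short
  of 36 keep all originals and are bootstrapped (with replacement) up to
  36.
- The window rule is length-based: first sample at/after +50 ms, then
  exactly 332 samples. (A naive half-open 50–700 ms count would give 333;
  the fixed S = 332 forces the length-based rule.)
- Cross-condition pairing of trials into observations is arbitrary by
  design; trials are therefore shuffled independently per condition with a
  seeded generator and paired by index.
- Standardization is per flattened (row, time) feature: means and SDs are
  computed on the training split only and applied as a frozen affine map
  to any other data. Zero-variance features are floored at 1e-8 with a
  warning. A per-channel variant was considered and rejected as the
  default because the feature-wise formulation matches the stated
  protocol; the floor keeps degenerate (e.g. single-observation) fits
  finite.

## The network

Input (B, 192, 332, 1) →

1. three per-condition spatial convolutions, kernel (64, 1), M = 5 maps
   each, ReLU. A (64, 1) kernel is exactly a learned scalp topography; its
   output is that topography's temporal activation. Implemented as matrix
   products (no framework needed);
2. concatenation → 15 maps;
3. valid max-pool over time, pool (1, 10), stride (1, 5):
   floor((332 − 10)/5) + 1 = 65 samples;
4. dense 100, ReLU;
5. dense 2, softmax.

Parameter count: 3·(64·5+5) + 975·100+100 + 100·2+2 = 98 777 (audited in
tests). L2 with λ = 0.25 applies to weights only, added to the mean
cross-entropy as λ‖W‖². Training: 500 Adam steps (α = 5e-4; β₁ = 0.9,
β₂ = 0.999, ε = 1e-7 — fixed here, as only α was prescribed), each step
drawing 160 observations uniformly without replacement (independently
across steps); "one epoch = one 160-observation batch" is read literally,
so 500 epochs = 500 gradient steps. Initialization is seeded
Glorot-uniform; everything is bit-reproducible under a fixed seed.
Numerical notes: computation is single-precision; max-pooling ties route
gradients to the first maximum; batches are gathered in sorted index
order (the same sampled set; order is irrelevant to the gradient).

## Evaluation protocol

- **Folds.** Stratified 10-fold partition of *subjects*: each class is
  shuffled and dealt round-robin across folds, so per-fold class counts
  deviate from proportionality by at most one and classes smaller than k
  are still handled. A leakage audit (every subject in exactly one fold,
  every tensor subject assigned) runs on every CV execution.
- **Aggregation.** A subject is called concussed iff strictly more than
  50% of their 36 trials are classified concussed; an exact 50% tie is
  read as control ("more than" taken literally).
- **Longitudinal.** Second-session observations are never trained on.
  Each returning subject's follow-up trials are scored by the model of the
  fold that held that subject out, making the training set identical
  across the subject's two dates. Follow-up trial accuracy is computed
  against the subject's first-test clinical label, so a recovered
  subject's accuracy can fall below chance by construction.
- **Mixed ANOVA.** Two-way split-plot on per-subject accuracies: Recovery
  (SR/NSR) between subjects, Testing Date within. The default is the
  Type-II formulation (pingouin; verified against R's car/ez behaviour);
  a Type-III path (unweighted group means for the within-factor main
  effect) is available via explicit sums-of-squares projections. With an
  unbalanced between factor the two differ; Type II is the default because
  it matches the conventional repeated-measures output of the common R
  tooling.

On the bundled 19-subject clinical table (8 SR / 11 NSR), the Type-II
Testing-Date effect is F(1,17) = 9.14 (Type III: 8.27), Recovery 4.01,
interaction 0.49 — these are the values the package computes and asserts;
they are fully determined by the published per-subject accuracies.

## Attribution

DeepLIFT-style rescale attribution implemented directly on the network:
linear layers propagate exact multipliers, ReLUs use Δout/Δin (gradient
where Δin ≈ 0), and max-pooling routes each pooled delta to the window
position attaining the maximum on the actual input (falling back to the
largest-|Δ| cell if that position has no delta). Every local rule
satisfies summation-to-delta, so completeness — attributions summing to
f(x) − f(reference) — holds to ~1e-10 in float64; tests assert < 1e-3.

Choices where the protocol was silent: the reference is the all-zero
observation in standardized space (the training mean); the explained score
is the concussed-class pre-softmax logit; the interpreted model is a
single model trained on all data (separate from CV models); the cohort
summary averages |attribution| over all subjects jointly (not per class).
Attributions are computed on per-subject mean observations, and the
summary reshapes to (condition, channel, time) for topographic display.

## Problem sizes used by the test suite

Stochastic acceptance properties run at: three 20+20-subject strong-effect
cohorts with full 10-fold CV (detectability: median subject accuracy
≥ 0.90 over the three cohorts); one 10+10 zero-effect cohort (chance
behaviour within the 95% binomial band); five strong-effect simulations
for attribution localisation (inside/outside mean |attribution| ratio > 1
on the injected N2b/P300 support, required in ≥ 4 of 5); and recovered
subjects re-simulated with the effect removed at the second session
(pooled concussed-fraction drop). Unit tests use 4+4-subject cohorts and
reduced training schedules; they exercise mechanics, not detectability.

## Known limitations

- The generator's scalp topographies use a plane projection of electrode
  positions and Gaussian falloffs; no volume conduction model.
- Channel noise is spatially independent (plus a shared alpha source) —
  real EEG noise is strongly spatially correlated, which would make
  spatial filtering harder than it is here.
- The simulated effect is a clean amplitude/latency change of two
  components; real post-concussive changes are heterogeneous.
- Single-trial accuracies on synthetic cohorts should not be compared
  numerically with published real-data figures; the synthetic SNR was
  chosen once, on plausibility grounds, and not calibrated to reproduce
  any published accuracy.
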