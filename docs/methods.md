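# Methods

This note documents the models, rules, and numerical choices implemented in
`somnoscore`, in the order data flows through the package.

## Time conventions and annotations

All times are seconds from recording start; event intervals are half-open
`[onset, onset + duration)`; hypnogram epochs are 30 s with epoch *i*
covering `[30i, 30(i+1))`. Half-open intervals remove boundary
double-counting: an event ending exactly on an epoch boundary does not touch
the next epoch. The hypnogram must contain `ceil(rec_duration / 30)` epochs.
When the final epoch is partial, it contributes its full 30 s to total sleep
time if at least 15 s of it was recorded, otherwise only its actual length —
a pro-rata rule that avoids inflating TST from a sliver of trailing sleep.

Annotations serialize to a versioned JSON schema (stages, typed events with
onset/duration and desaturation depth). EDF support covers the plain
continuous 16-bit flavour; per-channel physical scaling is chosen from the
data range, so round trips are exact up to one 16-bit quantization step
(EDF's integer encoding makes bit-exact round trips impossible in general).

## Clock alignment

Two simultaneous recordings share a flow signal but disagree by a clock
shift and a slow drift. Both flows are resampled to 10 Hz and the normalized
cross-correlation peak lag is computed in 120-s windows stepped by 60 s
(sub-sample peak position by parabolic interpolation). Windows with peak
correlation below 0.5 are inadmissible; with fewer than two admissible
windows the recording pair is rejected as unalignable, mirroring clinical
practice of excluding recordings that cannot be reliably aligned. Over the
admissible windows a robust line `lag(t) = shift + drift·t` is fitted —
least absolute deviations via iteratively reweighted least squares by
default, Theil–Sen as an option. All of window length, step, admissibility
threshold and fit method are configuration; the defaults were chosen at desk
scale (they recover shifts to a tenth of a second and drifts of a few parts
in 10⁴ on two-hour synthetic pairs, as the acceptance suite measures).
Timestamps map as `t → t(1+drift) + shift`, durations scale by `(1+drift)`.

## The arousal detection network

### Architecture

Three modules of residual blocks; each block stacks dilated 1-D
convolutions (kernel 3, dilations 1, 2, 4, 8 — exponentially increasing, so
a block covers a wide context with few parameters), adds a residual skip,
applies a 1×1 dense projection and max-pools in time.

- **Cardiac module**: raw PPG at 100 Hz → 4 blocks (channels 8/16/16/24,
  pool factors 5/5/2/1) → 3 dense (1×1) layers → IHR in bpm at 2 Hz.
- **Respiratory module**: flow at 10 Hz → 1 block (8 channels, pool 5) →
  features at 2 Hz.
- **Arousal module**: the normalized IHR (a single channel — see below)
  concatenated with the flow features → 3 blocks without pooling (16
  channels; the last block extends dilations to 16) → 2 dense layers →
  sigmoid, an arousal probability at 2 Hz.

Pooling is validated at construction: the cumulative factors must map
100 Hz and 10 Hz exactly to the 2 Hz output grid. The default receptive
field is 85.3 s (~±43 s of temporal context) and construction rejects
configurations outside 80–100 s; a numerical probe in the test suite
verifies that perturbing the input more than 50 s away from an output
sample leaves it unchanged to <1e-6.

The **IHR bottleneck** is a deliberate design: the only cardiac information
the arousal module receives is the scalar IHR estimate, normalized as
`(IHR − 60)/20`. This makes the detector agnostic to the cardiac sensor (a
different front-end regressing IHR from ECG or a pressure pulse could be
swapped in without retraining the arousal module). The alternative wiring —
feeding the cardiac module's penultimate feature maps forward — was
considered and rejected as it couples the arousal head to the PPG-specific
representation.

Channel widths, dense-layer sizes and the dilation schedule are not claims
about any reference system; they are defaults sized so that the rate and
receptive-field invariants hold and training converges in minutes on one
CPU. The layers themselves (dilated convolution, ReLU, max-pool, residual
add, Adam) are implemented in NumPy with hand-written backward passes —
float32, single-threaded-deterministic, and small enough to audit.

### Training

Phase 1 (`cardiac`) trains the cardiac module alone to regress the 2 Hz
reference IHR from PPG windows, with mean absolute error. Each sampled
window is stretch-augmented: a source span of length `L/f` is resampled
onto the `L`-second window and the IHR target divided by `f`, with
`f ~ U(0.8, 1.2)` (so e.g. f = 0.8 turns a 60 bpm segment into 75 bpm). The
augmentation decouples the learned rate estimator from the cohort's
baseline heart-rate distribution.

Phase 2 (`end2end`) freezes the cardiac parameters — asserted by SHA-256
hash before/after — and trains the respiratory and arousal modules against
2 Hz binary sequences marking cortical arousals, with class-weighted binary
cross-entropy (positive weight 6, countering the ~5% positive-sample
fraction). Because the cardiac module is frozen, its IHR output is
precomputed once per record, which dominates the speedup of this phase.

Losses are evaluated only on the central part of each window (20-s margins)
so zero-padding at window edges never contaminates targets. Defaults:
Adam at 3e-3, batches of 8 × 128-s windows, a few hundred steps per phase.
All sampling is driven by a single seeded generator; fixed seeds reproduce
runs bit-identically on one machine.

### Events, thresholds, cross-validation

The probability trace becomes discrete autonomic arousal events as maximal
runs of samples *strictly above* a threshold lasting at least 2 s — at 2 Hz,
4 samples of 0.5 s each. No post-hoc merging of nearby events and no
minimum inter-arousal separation is applied. The threshold is calibrated by
grid search (step 0.01) maximizing event-level F1 pooled over the training
subjects, ties broken toward the larger threshold. Event matching for F1 is
greedy one-to-one in onset order with any interval overlap as the hit
criterion (an onset-within-δ criterion is available); matching is
calibration machinery, not a claim about scoring concordance rules.

Cross-validation is 4-fold, stratified by database (subjects shuffled
within database by a seeded generator and dealt round-robin, so folds hold
25% ± 1 subject per database). Each fold's model is trained and its
threshold calibrated exclusively on the other three folds; every subject is
scored exactly once, by the model from the iteration in which it was in the
validation fold. The run manifest records fold assignment, seeds,
thresholds and cardiac hashes, and the test suite includes a scrambling
probe verifying that a subject's own prediction is invariant to its
training labels.

## Scoring rules

Respiratory events (apneas of any subtype, hypopneas) count only if their
interval intersects at least one sleep-staged epoch. Arousals count if they
start during sleep or within the first or last 15 s of a maximal wake run
(the tolerance captures arousals that lead to awakenings). A hypopnea is
confirmed by a desaturation of depth ≥ 3% whose onset falls within
`[hypopnea onset, hypopnea end + 45 s]` — the window models circulatory
delay to the oximeter; pairing is greedy one-to-one by proximity so one
desaturation cannot confirm two hypopneas — or, for the arousal-augmented
index, by a (wake-filtered) arousal within 5 s of event end. Both windows
are configuration; no published value exists for the auto-scoring system
they emulate. Apneas are never subject to confirmation.

Indices: `REI` divides desaturation-confirmed events (no sleep filter — the
estimated hypnogram is deliberately unused) by recording time; `AHI_est`
and `AHI_est+AutAr` divide sleep-filtered counts by estimated TST; the
reference `AHI_PSG` uses cortical arousals and reference TST. Severity bins
are left-closed at 5, 15, 30. A zero sleep time with events present raises
rather than returning a misleading 0 or infinity.

## Statistics

- **ICC(A,1)**: two-way random effects, absolute agreement, single
  measurement, from the two-way ANOVA mean squares; confidence interval via
  the McGraw–Wong F construction. Absolute agreement (not consistency) is
  the right form for method comparison because it penalizes systematic
  offsets.
- **Bland–Altman**: bias ± 1.96·SD limits of agreement; bias CI via the
  t-based SE `sd/√n`, each limit's CI via the large-sample SE `sd·√(3/n)`.
- **Proportion CIs**: Wilson score with continuity correction, clipped to
  [0, 1].
- **Likelihood ratios**: Simel log-method CIs. Degenerate cells (sens or
  spec of 0 or 1) yield half-open intervals flagged with `nan`/`inf` bounds
  rather than a continuity correction.
- **Cohen's κ**: with Cohen's 1960 large-sample standard error
  `√(p_o(1−p_o)/(n(1−p_e)²))`.
- **Benjamini–Yekutieli**: step-up comparison of sorted p-values against
  `kα/(m·c(m))`, `c(m) = Σ 1/i`, valid under arbitrary dependence; the
  reported critical threshold is the bound at the largest admissible rank.
  Censored p-values ("<0.001") are represented as 0.0005 by default; the
  resulting thresholds are insensitive to any representation ≤ 0.001 (a
  tested property).
- **Paired comparisons**: exact two-sided McNemar on discordant pairs for
  proportions; a seeded subject-level bootstrap (10,000 resamples, shift
  method) for κ and likelihood ratios. The reference study does not name
  its paired tests; these choices are ours and are not used to reproduce
  any printed p-value.

Exact-arithmetic oracles (sympy/Fractions) pin the Wilson, ICC, κ and AUC
implementations to 1e-12 in the test suite; pingouin and scikit-learn serve
as independent cross-checks.

## The synthetic cohort generator

The generator's defaults define the package's standard study conditions:
Markov hypnograms (5-state, 30-s steps, wake start, ~75–85% sleep
efficiency), respiratory events placed in sleep at a Poisson rate per
sleep-hour with durations U(10, 60) s (honouring the 10-s scoring minimum),
a 50/50 apnea/hypopnea split with apnea subtypes 70/20/10
obstructive/central/mixed, desaturations following 60% of hypopneas at
10–30 s lag with depths 3–8%, cortical arousals terminating 70% of events
plus 15/h spontaneous, autonomic arousals accompanying 80% of cortical ones
plus 10% spurious-per-respiratory-event (emulating, e.g., periodic
limb-movement responses without cortical correlate). Per-subject event
rates are drawn from a severity mixture weighted like a sleep-clinic
referral population (12/19/26/43% across none/mild/moderate/severe), so
cohorts span all four classes. The estimated hypnogram is the true one
corrupted by an epoch-wise confusion matrix dominated by wake/sleep errors,
standing in for cardio-respiratory sleep-staging error.

Signals: the IHR is baseline 62 bpm plus slow Gaussian-filtered variability
(SD 2.5 bpm) plus a gamma-like surge (rise ≈ 2 s, decay ≈ 8 s, peak 18 bpm
± 15%) at every autonomic arousal; the PPG integrates IHR/60 into beat
onsets rendered with a fixed two-bump pulse template and 5% amplitude
jitter at 100 Hz; the flow is a frequency-wandering sinusoid at 12–18
breaths/min whose envelope drops to ×0.05 during apneas and ×0.4 during
hypopneas with ≤2-s smoothed transitions; SpO2 carries Gaussian dips at the
annotated desaturations but only its *event list* is consumed downstream.

What this does and does not show: passing tests demonstrate that the
algorithms recover the structure the generator encodes — heart-rate surges
time-locked to arousals, flow reductions during events, a corrupted but
informative hypnogram. Real recordings add cardiac arrhythmia, motion and
contact artifacts, autonomic dysfunction, medication effects, scorer
disagreement, and arousals with atypical autonomic signatures; none of
these are modelled, so synthetic performance numbers (IHR error, event F1)
are upper bounds on, not estimates of, clinical performance. The bundled
published confusion tables are therefore the package's ground truth for the
statistics layer, and the synthetic cohort is the ground truth for the
signal-processing layer.

## Problem sizes

The default test/acceptance problem sizes are deliberate package choices:
two-phase training uses cohorts of 16–20 one-hour subjects (a few hundred
optimizer steps per phase), alignment recovery uses 200 two-hour pairs, the
scoring oracle runs over 500 half-hour annotation sets, and the event
extraction oracle over 1,000 random traces. At these sizes the full suite
runs in minutes on one CPU while every contract is still exercised
end-to-end.

## Known limitations

- The network engine is CPU-scale by design; no GPU path, no mixed
  precision, no data parallelism.
- Only the PPG front-end is implemented; an ECG front-end would be a new
  cardiac module behind the same IHR bottleneck.
- The clock model is linear; nonlinear clock wander is out of scope.
- The generator does not model arrhythmia, artifacts, or the demographic
  structure of any real cohort; spurious-autonomic coupling is a free
  parameter, not a calibrated claim.
- Severity prevalences, association windows and the hypnogram-corruption
  matrix are plausible defaults, not fitted quantities.
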