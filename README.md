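# somnoscore

Autonomic-arousal detection and apnea–hypopnea index (AHI) surrogate scoring
for home sleep apnea tests (HSATs).

## The problem

The AHI — apneas plus hypopneas per hour of sleep — is the primary measure of
sleep-disordered-breathing (SDB) severity, with diagnostic cuts at 5, 15 and
30 events/h. Under the AASM rule, a hypopnea counts only when it is confirmed
by a ≥3% oxygen desaturation *or an arousal*, and the AHI denominator is
total sleep time (TST). Home sleep apnea tests record no neurological
channels, so they can score neither arousals nor sleep: the conventional
surrogate, the respiratory event index (REI, desaturation-confirmed events
per hour of *recording* time), systematically underestimates severity.

`somnoscore` implements the missing pieces from the signals an HSAT does
record — photoplethysmography (PPG) and respiratory flow:

- a dilated-convolutional network that detects **autonomic arousals**
  (transient sympathetic activations visible as heart-rate surges) at 2 Hz,
  built around an **instantaneous-heart-rate (IHR) bottleneck**: the cardiac
  module is trained first to regress IHR from raw PPG, then frozen, so the
  arousal detector is agnostic to the cardiac sensor;
- the HSAT scoring chain producing three AHI surrogates per subject:

  | index | numerator | denominator |
  |---|---|---|
  | `REI` | apneas + desat-confirmed hypopneas | recording time |
  | `AHI_est` | sleep-overlapping apneas + desat-confirmed hypopneas | estimated TST |
  | `AHI_est+AutAr` | as above, hypopneas also confirmable by autonomic arousals | estimated TST |

  with the events-in-wakefulness rules (respiratory events must overlap a
  sleep epoch; arousals must start in sleep or within the first/last 15 s of
  a wake period);
- clock alignment of simultaneous dual recordings (shift + drift estimated
  from windowed cross-correlation of the shared flow signal);
- the full diagnostic-agreement statistics battery: ICC(A,1), Bland–Altman
  limits of agreement, ROC/PR curves, Wilson continuity-corrected intervals,
  Simel likelihood-ratio intervals, Cohen's κ with Cohen's 1960 standard
  error, and the Benjamini–Yekutieli FDR procedure;
- a synthetic cohort generator (Markov hypnograms, Poisson respiratory
  events with desaturation/arousal consequences, IHR-driven PPG pulse
  trains, event-modulated flow) so the whole pipeline is trainable and
  testable without any recordings.

Since clinical polysomnography databases of this kind are proprietary, the
package bundles the severity confusion tables of a published 245-subject
validation study as reference data: the statistics module reproduces every
printed point estimate from the raw counts.

## Worked example

```python
from somnoscore import CohortConfig, gen_cohort, compute_indices

cohort = gen_cohort(CohortConfig(n_subjects=4, rec_duration=4 * 3600.0,
                                 seed=7, with_waveforms=False))
for rec in cohort:
    r = compute_indices(rec)
    print(rec.subject_id, r.ahi_psg, r.rei, r.ahi_est, r.ahi_est_autar)
```

prints (values in events/h):

```
subject  AHI_PSG  REI   AHI_est  AHI_est+AutAr  severity(PSG)
S000       4.6    2.5     3.6        3.9       None
S001      41.9   20.8    30.3       36.6       Severe
S002       5.7    3.2     4.7        5.4       Mild
S003      47.9   23.2    35.1       40.0       Severe
```

The pattern is the clinically relevant one: the REI underestimates the
reference AHI (longer denominator, unconfirmed hypopneas dropped), sleep
filtering with the estimated hypnogram closes most of the gap, and arousal
confirmation closes more of it.

The same statistics applied to the bundled reference confusion tables:

```python
from somnoscore.refdata import reference_confusions
from somnoscore.stats import fourclass_metrics, binary_metrics

cm = reference_confusions()["ahi_cress_autar"]
fc = fourclass_metrics(cm)
m30 = binary_metrics(cm, 30.0)
```

gives four-class accuracy 0.804 with κ 0.716 (0.64, 0.79), and at the
AHI ≥ 30 cut a sensitivity of 0.934 with specificity 0.906 and LR+ 9.99 —
the arousal-augmented surrogate recovers severe SDB that the plain REI
misses (REI sensitivity at the same cut: 0.755).

## Command line

```
somnoscore synth | align | train | detect | events | folds | score |
           evaluate | reference-tables | run-all
```

Each subcommand is a thin wrapper over the library; `run-all` performs the
full experiment (synthesize → stratified 4-fold cross-validation with
two-phase training → detection with per-fold calibrated thresholds →
scoring → evaluation) and writes a manifest with every seed, fold
assignment, threshold and cardiac-parameter hash.

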