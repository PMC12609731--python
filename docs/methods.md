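# Methods

This note documents the models, numerical choices, and limitations of
the `swallow_ersp` package: what each stage computes, why the defaults
are what they are, and what the synthetic-data tests do and do not
demonstrate about real recordings.

## The measurement problem

Volitional swallowing engages the sensorimotor cortex: in the seconds
after a swallow cue, the ongoing alpha (7–13 Hz) and beta (13–30 Hz)
rhythms over C3/Cz/C4 lose power relative to the pre-cue baseline
(event-related desynchronization, ERD). The package quantifies that
suppression from cue-locked EEG and compares it across subject groups
(healthy adults, post-stroke patients without dysphagia, post-stroke
dysphagic patients). Three descriptors carry the comparisons:

* **ERSP(t, f)** — trial-averaged spectral power change relative to the
  pre-cue baseline, in dB; negative values are ERD.
* **ERO(t)** — ERSP averaged over a frequency band,
  `ERO(t) = 1/(f2−f1) ∫ ERSP(t,f) df`; a band-power time course.
* **ERI** — ERO additionally averaged over a time window,
  `ERI = 1/(t2−t1) · 1/(f2−f1) ∬ ERSP df dt`, one scalar (dB) per
  subject × channel × band. Default window 500–2000 ms, the interval
  of maximal swallowing-related ERD.
* **LI** — hemispheric lateralization,
  `LI = (ERI_C3 − ERI_C4)/(ERI_C3 + ERI_C4)`; 0 is bilateral.

## Synthetic cohorts (`synthgen`)

No public recordings of this protocol exist, so the package ships a
generative model that every downstream stage is tested against. One
trial of one channel is

```
x(t) = b(t) + a(t)·(1 − d_α·w(t)) + g(t)·(1 − d_β·w(t))
```

* `b` — 1/f background noise (PSD ∝ 1/f above 1 Hz, zero below; no DC
  drift), RMS `background_scale` = 10 µV by default.
* `a`, `g` — Gaussian oscillators spectrally flat over exactly the
  alpha (7–13 Hz) and beta (13–30 Hz) analysis bands, RMS
  `alpha_amp` = 4 µV, `beta_amp` = 4.5 µV. Flat-in-band spectra make
  the per-band power bookkeeping exact; amplitudes were chosen so that
  the in-band oscillator-to-background power ratio is near 1.7, which
  places preset ERD depths on the dB scale of the reported group
  medians.
* `w(t)` — raised-cosine gate: 0 before `erd_onset_ms` (200 ms) and
  after `erd_offset_ms` (4200 ms, matching ERD that persists to about
  four seconds), 1 on the plateau, 300 ms cosine ramps, jittered
  uniformly ±100 ms per trial.
* `d` — fractional amplitude suppression per channel and band.

Because components are independent and flat in band, the expected
plateau-to-baseline band-power ratio is
`(P_bg + (1−d)²·P_osc)/(P_bg + P_osc)` with `P_bg`, `P_osc` computed
from the same spectral envelopes the generator uses
(`expected_band_powers`). This closed form is the yardstick for the
end-to-end calibration tests (tolerance 0.5 dB at 200 trials).

Group presets encode the qualitative group structure, not published
medians (the study reports summary dB values, not generative
parameters): healthy = deep symmetric ERD in both bands (alpha depth
0.35, beta 0.50 at C3/C4); control = preserved alpha (0.33), reduced
beta (0.25); dysphagic = shallow ERD in both bands with the left
hemisphere weaker than the right (alpha 0.10 vs 0.22, beta 0.12 vs
0.25), which makes |LI| largest in that group. Between-subject
variability jitters depths (SD 0.04) and scales amplitudes (lognormal,
CV 0.15). Randomness is counter-based (Philox keyed on
`(seed, group, subject)`), so cohorts are bit-reproducible and adding
subjects never changes existing ones.

The generator does **not** emulate ocular/muscular artifact
topographies, inter-channel correlation (channels are independent),
head-volume conduction, or non-stationary background — so passing
tests demonstrate the pipeline's numerical correctness and
sensitivity, not robustness to real-world artifacts.

`study_cohort_spec` pins the study conditions: 21/32/50 subjects per
group at 2 kHz. Its desk-scale defaults are 20 trials per subject
(the protocol's valid-swallow minimum; the protocol allows up to 40)
and a reduced 9-channel sensorimotor montage; the full 32-channel,
40-trial layout is one argument away.

## EDF I/O

Classic EDF (16-bit, 1-second records, ASCII headers) with events in a
CSV sidecar, since classic EDF has no annotation channel. The physical
range is symmetric per channel and re-parsed from its own ASCII form,
so the round-trip error is bounded by half a quantization step.
Signals are padded to whole records with the edge value; the true
sample count rides in the header's reserved field and the reader trims
it. Header dates are fixed, making identical inputs byte-identical on
disk. MNE's independent EDF reader is used in the tests to cross-check
the writer.

## Preprocessing

Order: polyphase downsampling to 512 Hz (Kaiser β = 12 design;
passband ripple ~1e−8) → zero-phase Butterworth band-limiting
7–35 Hz → bad-channel rejection/interpolation → epoching
[−1000, 5000) ms around each cue → trial rejection → common average
reference.

* **Filters.** 5th-order Butterworth high- and low-pass sections
  applied forward–backward (effective 10th order, zero phase — ERD
  latencies are not displaced). Measured on sines: ≤0.4% amplitude
  error at 20 Hz, ≥97% attenuation of 1 Hz drift and ≥95% of 50 Hz
  mains after the double pass. A 4th-order section would leave 5.5% of
  a 50 Hz tone, above the 5% residual this stage promises, which is
  why the order is 5.
* **Artifact stage.** The original analysis chain used Artifact
  Subspace Reconstruction plus ICA/ICLabel; those are deliberately out
  of scope. The stand-in rejects a channel when its MAD-scaled robust
  amplitude exceeds `reject_sd` (default 10) times the recording's
  median channel amplitude, then rebuilds it as the
  inverse-distance-weighted mean of its 4 nearest neighbors on the
  azimuthally flattened 10–20 layout (coordinates from MNE's standard
  montage). The norm is per recording rather than cohort-calibrated —
  a cohort-level pass would add cross-subject state for no benefit at
  these thresholds. More than 25% rejected channels marks the
  recording unusable. A trial-level screen drops trials whose peak
  amplitude exceeds the same multiple of the pooled robust norm;
  "valid swallow" = survived epoching and this screen. Subjects with
  fewer than `min_valid_trials` (20) valid swallows are excluded and
  logged.
* **Epoching** is half-open `[−1000, 5000)` ms in samples so every
  trial has the same length; events too close to a recording edge are
  dropped with a warning.

## Time–frequency analysis (`tfr`)

Complex Morlet wavelets on a 7–30 Hz grid (0.5 Hz spacing, 47 bins by
default) with cycle count rising linearly from 3 at 7 Hz to 20 at
30 Hz. Kernels are unit-energy (white-noise power is flat across
frequency; only ratios survive the baselines anyway) and truncated at
±3.5 temporal SD. Convolution runs via FFT; a brute-force time-domain
convolution oracle pins the implementation to rtol 1e−6 in the tests.
Output is decimated to ~200 time points per epoch (the temporal
resolution of the wavelets makes denser sampling redundant).

Cells whose kernel support crosses an epoch edge are **masked**, not
zero-filled, and every later average skips masked cells — this keeps
edge artifacts out of the −1000…0 ms baseline.

Baseline correction is two-stage:

1. **Single-trial, full-epoch**: each trial's power is divided, per
   frequency, by its own mean over all valid times (mean by default,
   median optional). This tames outlier trials before averaging.
2. **Pre-stimulus dB**: the trial average is divided, per frequency,
   by its mean over −1000…0 ms and expressed as `10·log10` of the
   ratio (a power-ratio dB convention). The baseline window must
   contain ≥10 valid samples per frequency; a nonpositive baseline
   mean is an error, since genuine power cannot produce it.

Both corrections are ratios, so the chain is exactly invariant to
per-trial amplitude rescaling.

## Biomarkers

ERO/ERI use trapezoidal quadrature on the native grid (uniform-weight
form: half weights at the included band/window edges), restricted to
unmasked cells; ERI is the time-trapezoid of the ERO trace, so the
nesting identity "ERI = time-average of ERO" holds to rounding. The
printed integral limits of the ERI definition are descending; they are
read as ordinary ascending integration, because a doubly reversed sign
would flip the stated "negative = desynchronization" convention. The
13 Hz edge belongs to both bands, as the band definitions print. The
abstract of the source study quotes slightly different band edges
(8–13/15–30 Hz) than its methods (7–13/13–30 Hz); the methods values
are implemented.

LI is undefined when `|ERI_C3 + ERI_C4|` is below `epsilon` = 1e−3 dB
(the ratio is unbounded there); such subjects are flagged, reported,
and excluded from LI statistics rather than raising.

## Statistics

Two-sided throughout, α = 0.05, no multiplicity correction by default
(the study design is exploratory; Holm and Benjamini–Hochberg are
behind a flag). Per channel × band: Lilliefors and Levene screens,
Kruskal–Wallis omnibus (tie-corrected), all pairwise Mann–Whitney U
post hocs with Cliff's δ. Per group × band: paired C3-vs-C4 Wilcoxon
signed-rank with the rank-biserial r. Per band: LI group comparisons.
Demographic contingency tables: Pearson chi-square without continuity
correction (this choice reproduces the published stroke-laterality
p-value of 0.8392 exactly; the published gender p-value does not
correspond to a plain Pearson test and is not asserted anywhere).

Rank tests use exact enumeration when the relevant sample is ≤12 and
tie-free, otherwise the tie-corrected normal approximation; zero
differences are dropped in the signed-rank test (Wilcoxon's original
treatment). δ is positive when the first sample is stochastically
larger; every report row records the group order. Cliff's δ and the
rank-biserial r are implemented in-package (no installed library
provides them); the battery itself fronts scipy and statsmodels.

## Problem sizes used by the test suite and acceptance script

The cohort-level checks run the full pipeline on the study's group
sizes (21/32/50, 2 kHz acquisition) with the generator's desk-scale
defaults (20 trials/subject, 9-channel montage) — about one minute of
compute. Ensemble calibration uses 200 trials at 512 Hz. The
null-calibration simulation draws 200 replicates of three independent
identically distributed group pairs (n = 20 each) at the biomarker
level — the quantity under test is the rank test's type-I error, which
does not depend on the signal chain upstream of it.

## Known limitations

* The artifact stage is a documented stand-in, interface-compatible
  with a real ASR/ICA chain but much weaker; clean synthetic data
  never exercises it hard.
* Channels are generated independently, so the common average
  reference slightly dilutes per-channel suppression (a ~1/N effect)
  instead of removing a shared reference signal as it would on real
  data; group orderings are unaffected.
* Preset depths reproduce orderings and approximate dB scale, not the
  published medians, which come from non-public patient EEG.
* Only classic EDF is supported (no EDF+/BDF/BrainVision).
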