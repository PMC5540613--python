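# Methods

This note documents the signal model, the processing chain, the numerical
choices behind `propsig`, and what the synthetic validation does and does
not demonstrate.

## Signal model and assumptions

A PROP-evoked tongue recording is modelled as a single-channel voltage
trace x(t) in mV, sampled at f_s = 2048 Hz, consisting of

* a slowly drifting baseline (electrode-tissue potential wander),
* a negative-going depolarization beginning a short delay after stimulus
  application: abrupt onset, approach to a plateau of tens of mV, slow
  relaxation,
* additive disturbances: mains interference, broadband amplifier noise,
  a small bump at stimulus application, occasional tongue-movement
  artefacts.

The analysis assumes exactly one depolarization event, starting within
the first ~1 s after the annotated stimulus-application time, and at
least 5 s of usable pre-stimulus baseline.  Multi-phase events and
repolarization modelling are out of scope.

## Processing chain

**Filtering.** Order-86 (87-tap) linear-phase equiripple low-pass,
passband edge 6 Hz.  The stopband edge (50 Hz) and equal band weights are
our choices — only the order and cut-off are fixed by the method — giving
≈ −37 dB at mains frequency.  The taps are normalized to exactly unit DC
gain so offsets pass unchanged (the raw design has ≈ 0.13 dB DC error).
The filter is applied causally to a reflect-padded signal and shifted by
the 43-sample group delay, so fiducial timing is unbiased; edge
transients stay outside the analysis window.

**Windowing and rates.** The analysis window is [−5 s, +15 s) around
stimulus application.  Decimation to 128 Hz keeps one sample in 16 with
no further anti-aliasing (the signal is already limited to 6 Hz); the
return to 2048 Hz uses polyphase upsampling with mean removal/restoration
so constants survive exactly.

**Onset (knee) detection.** The derivative ẋ uses the five-point
central-difference stencil (x[n−2] − 8x[n−1] + 8x[n+1] − x[n+2])·f_s/12;
the two unsupported samples at each edge are filled with one-sided
differences and excluded from the search.  An alternative all-positive
averaging kernel is selectable via `knee.kernel = "printed"` for
comparison with implementations that sum rather than difference the
taps.  The knee is the first index in the first 6 s of the window where
the moving two-point SD of ẋ, s[k] = |ẋ[k+1] − ẋ[k]|/√2, exceeds
2.1 mV/s, else the first index with s ≥ 0.8·max s.  Both thresholds are
empirical constants of the method and are exposed in configuration; they
implicitly define the acceptable noise floor (see *Synthetic data*).

**Detrending.** Ordinary least squares gives the baseline line on
[window start, knee) and the post-depolarization line on the final 20% of
the window (configurable; the analysed frame ends at stimulus removal,
so this tail stands in for the post-removal trend).  If the pre-stimulus
slope is non-positive *and* the post slope is below 0.2 mV/s, only an
offset is removed so that d(knee) = 0; otherwise the pre-stimulus line is
subtracted from the entire segment.  Slope comparisons are signed.

**Model fitting.** Both model families are fitted to d between the knee
and 15 s after the stimulus:

* exponential sum f_e(t) = a·e^{bt} + c·e^{dt} — fitted by variable
  projection: for fixed rates (b, d) the amplitudes are an exact linear
  least-squares solve, and only the rates are searched (bounded
  least-squares from a two-timescale heuristic plus 8 seeded random
  restarts, tolerances 1e-15).  This is deterministic and recovers
  noiseless parameters to machine precision, unlike a joint 4-parameter
  solve.
* rational f_r(t) = (p₁t² + p₂t + p₃)/(t + q₁) — for fixed q₁ the
  numerator is linear, so the profile objective over q₁ is scanned on log
  grids on both sides of the window (pole margin 2% of the span) and
  refined by bounded scalar minimization.

**Onset refinement and model selection.** The detrended signal is
upsampled to 2048 Hz; each converged model curve (analytic, no
interpolation) is scanned forward for its first positive-to-nonpositive
crossing of the replaced 0 mV baseline near the coarse knee; the earliest
crossing becomes n_k (resolution one sample, 0.488 ms).  If no model
crosses, the coarse knee maps to 2048 Hz and is flagged.  The model with
the lower RMSE against d from n_k onward wins; ties go to the
exponential sum.

**End detection.** On the analytic derivative of the selected model, the
end n_end is the first instant after the derivative-magnitude peak where
d̃′ ≥ −0.02·max|d̃′| (the derivative has flattened), capped at 15 s after
the stimulus for very slow (non-taster-like) responses.  A literal
variant requiring d̃′ ≥ +0.02·max|d̃′| is selectable
(`end.variant = "printed"`) but never fires on monotone decays, which is
why the flattening reading is the default.  For f(t) = 30e^{−t/2} − 30
this yields t_end = 2·ln 50 ≈ 7.824 s, which the tests verify to one
sample.

**Refit.** The selected model is refitted on [n_k, n_end] (time origin at
n_k, initialised from the time-shifted coarse parameters); if the refit
cannot improve the RMSE on that window, or the window is shorter than the
50-sample fit minimum, the shifted coarse model is kept, so the refit
never degrades the fit.

## Features

With d(t) the fitted model on [t_onset, t_end] (d(t_onset) = 0 by
construction of the detrending), the *feature signal* is d·d′, whose
antiderivative is d²/2.  Hence

* f1 = ∫ d′d dt = [d(t_end)² − d(t_onset)²]/2 (mV²) — closed form;
* f2 = d(t_onset) − d(t_end) (mV); for decaying signals f1 = f2²/2;
* f3 = ∫ d dt (mV·s) via the exact antiderivatives (for the rational
  family the polynomial-division form
  p₁t²/2 + (p₂ − p₁q₁)t + (p₃ − p₂q₁ + p₁q₁²)·ln|t + q₁|, valid because
  the pole is excluded from the window);
* f4 = f1/(t_end − t_onset) (mV²/s);
* f5 = d(t_onset) − d(t_onset + 2 s) (mV), evaluated at t_end and flagged
  when the interval is shorter than 2 s.  The 2 s mark is anchored at the
  onset (where the feature-defining zero of d lives), not at the
  stimulus annotation;
* f6 = max of d·d′ on the 2048 Hz grid of the analytic signal (mV²/s);
* f7 = t₁/₂, the time at which the running feature-signal area reaches
  f1/2, found by bisection on the closed-form cumulative to 1e-9 s — a
  tolerance chosen so the induced error in the half-area amplitude
  identity |d(t₁/₂)| = |f2|/√2 stays below 1e-6 relative even for steep
  fits (each bisection evaluation is closed-form, so the cost is nil).

Feature combinations are fixed name→index sets: combo1 = {1,4},
combo2 = {1,2,4}, combo3 = {1,2,4,5}, combo4 = {1,4,5,6},
best1 = {1,2,3,4,5}, best2 = {1,2,4,5,6}, all = {1..7}.  A plain
Pearson feature-vs-LMS correlation report is provided as a utility.

## Classification

Problems: NT vs ST (MT dropped), NT vs Tasters (MT+ST merged),
NT vs MT vs ST, and the diplotype problem.  Classifiers: KNN with k = 10
and cubic (Minkowski order 3) or cosine distance, vote ties broken by the
nearest single neighbour among the tied classes (deterministic and
distance-respecting); and an RBF SVM.  The "ν = 0.5, box constraint 1"
specification mixes ν-SVM and C-SVM vocabularies; the default is a C-SVM
with C = 1 and kernel scale 1 on standardized features, with a ν-SVM
(ν = 0.5) variant behind `classification.svm_variant = "nu"`.  Multiclass
problems are one-vs-one.

Features are z-scored per feature with training-fold statistics before
either classifier — the method is silent on scaling, but cosine and RBF
distances on features spanning mV to mV²·s are meaningless without it
(toggleable).  Evaluation is stratified 20×10-fold cross-validation
(scikit-learn `RepeatedStratifiedKFold`), yielding 200 fold accuracies
summarized by mean, SD (over all 200 folds; per-repeat means are also
reported), linear-interpolation quartiles, and outliers by the
q₃ ± 1.5·IQR rule — flagged, never removed.  Cohorts whose smallest class
has fewer members than k degrade to that many folds with a warning.

## Synthetic data

The generator emulates the measurement conditions the method was designed
for; its defaults are the study conditions used throughout the tests.

* **Waveform.** The clean depolarization is
  f(t′) = S·(e^{−t′/τ_slow} − e^{−t′/τ_fast}), τ_fast ≤ τ_slow
  (default ratio 8), scaled so the peak excursion is −Δamp.  A strict
  two-exponential with f(0) = 0 cannot hold a plateau forever, so the
  "plateau" is the slow-relaxation crest of this bi-exponential — an
  abrupt onset, a negative plateau near −Δamp, then slow recovery, which
  also matches observed post-stimulus relaxation.  Crucially the waveform
  is a member of the fitted exponential-sum family, so onset, parameters
  and all seven features have exact analytic ground truth.
* **Class profiles** (invented calibrations; the method's source reports
  no waveform parameter tables): Δamp ~ U(50,110) mV and rise
  τ ~ U(0.5,3) s for ST; U(5,45) mV, U(8,30) s for NT; U(25,70) mV,
  U(2,12) s for MT — deliberately overlapping both neighbours.  LMS
  ratings are drawn per class (62±12, 29±19, 7±7, clipped to [0,100]);
  diplotypes default to ST→PAV/PAV, MT→PAV/AVI, NT→AVI/AVI.  A
  `separable` profile with disjoint ranges exists for harness checks.
* **Noise.** Baseline noise is 0.5 Hz band-limited wander rescaled to
  `noise_sd` (default 0.3 mV) plus a 10% broadband floor, and 0.1 mV of
  50 Hz mains.  These levels are dictated by the method's own empirical
  constants: with white broadband noise at the same SD, or with ~0.5 mV
  of mains surviving a −37 dB stopband, the derivative moving-SD baseline
  exceeds the 2.1 mV/s knee threshold and onset detection is impossible —
  so the printed thresholds presuppose drift-like baseline noise and the
  strong mains suppression that optically-isolated differential recording
  hardware provides.  Artefacts are raised-cosine bumps (a stimulus bump
  at application, occasional tongue-movement bumps).
* **Timing.** 95 s at 2048 Hz, stimulus at 30 s, removal at 45 s, onset
  delay U(0.1, 0.8) s; baseline slope U(−0.15, 0.05) mV/s.

**What passing tests show.** On this generator the pipeline recovers
noiseless model parameters to machine precision, onsets within tens of
milliseconds under realistic noise, and features within 2% end-to-end;
the classification harness reproduces the expected qualitative structure
(NT vs ST easiest, three-class hardest, shuffled labels at chance).
**What they do not show:** real tongue recordings contain waveform shapes
outside the bi-exponential family, non-stationary artefacts, labelling
noise from the psychophysical reference tests, and inter-subject
correlation structure that no parametric generator reproduces — so
synthetic accuracies say nothing quantitative about accuracy on human
cohorts, and published human-cohort accuracies are not comparable targets.

## Problem sizes and determinism

Validation sizes were chosen to exercise the stated properties at modest
cost: 100 noiseless fits per model family, 200 noisy recordings for onset
timing, 13-per-class cohorts (mirroring the reference cohort size) for
the classification harness, 50 label permutations for the chance check.
Every stochastic component (generator, fit restarts, CV partitions) is
seeded; `scripts/acceptance.py` derives all of its randomness from its
`--seed` argument.

## Known limitations

* The knee detector keys on derivative curvature; very slow non-taster
  responses are detected mainly through the relative threshold and can
  localize poorly in noise — consistent with the method's own reliance on
  fast onsets, but a real limitation for NT delineation.
* The rational model's pole constraint is a margin heuristic; data that
  genuinely want a pole inside the window are fitted with the pole pushed
  to the margin.
* `estimate_trends` requires ≥ 10 baseline samples before the knee;
  `delineate` clamps earlier knees to sample 10 so flat traces degrade to
  near-zero features instead of erroring.
* The post-removal trend is approximated from the tail of the 20 s
  analysis window, since the frame ends at stimulus removal.
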