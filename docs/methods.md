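# Methods

## The problem

The dominant rhythm of resting, eyes-closed EEG — the alpha rhythm — slows
with age, and the broader shape of the power spectrum changes with it.
`eegage` implements a complete analysis chain for quantifying this: five
estimators of the peak alpha frequency (PAF), multivariate regression of
chronological age on the whole 0.1–45 Hz spectrum ("EEG-age"), and a
statistics layer for comparing the resulting brain-age estimates with each
other and with external measures (premorbid IQ from NART errors, general
cognition from QMCI).  Because real recordings are not bundled, a
first-class synthetic-cohort generator plants known ground truth so that
every stage is testable end to end.

## Spectral model

All spectral analysis happens on the log2-amplitude scale,
`0.5·log2(power)`, which tames the low-frequency dominance of EEG spectra.
The parametric model of a spectrum is an aperiodic background plus five
Gaussian band peaks (theta, alpha, beta1, beta2, gamma):

    log2 A(f) = A0·(0.1 f)^m + Σ_i A_i · exp(−½((f − μ_i)/σ_i)²) + k

with constraints m < 0, 0 ≤ A_i ≤ 10, band-specific bounds on the centres
μ_i ((1,7), (7,13), (13,21), (21,29), (29,47) Hz) and maximum widths σ_i
(15, 10, 30, 30, 30 Hz).  The aperiodic term is written so that it equals
A0 at f = 10 Hz; the generator and the fitter share this convention, which
makes round-trip tests exact.  The fit is bound-constrained non-linear
least squares (trust-region reflective, analytic Jacobian) with one
heuristic start (band amplitudes seeded from the residual over an
aperiodic-only fit) plus `n_starts` (default 10) random starts; the
lowest-SSE solution wins.  Optimizer tolerances are 1e-10; on noise-free
self-generated spectra every parameter is recovered to ~1e-13.

## The five PAF estimators

* **N-PAF** — per channel, the highest-amplitude local maximum of the AR
  log2-amplitude spectrum within 7–13 Hz (strict neighbour comparison; band
  endpoints excluded; equal-amplitude ties break to the lower frequency);
  summary = unweighted mean over channels with a peak.
* **D-PAF** — the same peak rule applied to the first SVD component
  (σ₁·v₁, sign fixed so the mean channel loading is positive) of the
  channel-by-frequency matrix.
* **M-PAF** — the fitted alpha Gaussian centre μ₂ of the spectral model,
  fitted to the SVD component.
* **C-PAF** — per-channel peaks of the normalised, Savitzky–Golay-smoothed
  (5th order, 11 bins) Welch spectrum; a channel is admitted only when its
  alpha peak exceeds a linear regression of log power on log frequency over
  1–40 Hz (alpha band excluded) by more than one residual SD; admitted
  peaks are combined with SNR weights (each channel's log-power excess over
  the background line, normalised to sum to one).  Fewer than
  `min_channels` (default 3) admitted channels ⇒ explicit missing value.
* **K-PAF** — per channel, the centre of gravity Σf·a(f)/Σa(f) over an
  individual alpha band delimited by the nearest enclosing local minima
  within a 5–15 Hz search window; channels average with equal weight.
  When a side of the peak has no local minimum before the window edge (the
  ideal case of a peak on a flat background), the window edge itself bounds
  the band — otherwise the textbook symmetric-Gaussian case would be
  undefined.

Estimators never fabricate a value: "no admissible peak" is an explicit
missing state that propagates into the statistics (pairwise deletion).

## Spectral estimation

The AR route uses the covariance method (non-windowed least squares) of
order 256.  The normal equations are assembled exactly in O(N·p + p²) from
first-column cross-products and a shift recursion along diagonals, rather
than forming the (N−p)×p design matrix; tests verify equality with naive
least squares to 1e-10.  The PSD σ²/(fs·|1 + Σ a_k e^{−i2πfk/fs}|²)
(one-sided, ×2) is evaluated on the fixed 0.1–45 Hz grid at 0.1 Hz
resolution.  The Welch route uses 4096 ms Hamming windows with 50% overlap
(2048 samples at 500 Hz, ~0.244 Hz bins), no detrending, density scaling.
"Normalisation" before smoothing divides by mean power over 0.1–45 Hz.

## Preprocessing

Order is fixed: per-channel demean → 3rd-order Savitzky–Golay baseline
spanning 1025 samples (±2.048 s at 500 Hz) → flag samples deviating from
the baseline by more than ±120 μV → greedy channel exclusion (drop the
channel whose removal most lengthens the common clean segment; stop at the
100 s target, at `max_drop` = 16, or when no drop helps) → crop to the
longest segment clean on **all** retained channels (earliest start on
ties) → common-average re-reference.  Within half a window of a record
boundary the baseline is refitted on the truncated window only (no padding,
no extrapolation), so record edges cannot fabricate extremes.
Re-referencing happens after cropping so dropped channels and artifact
stretches never contaminate the average.  Whether the ±120 μV criterion
should apply before or after re-referencing is ambiguous in the method
tradition; here it is applied before (flags must be computable per channel
before a common segment exists).

## EEG-age models

The PLS route regresses age on the SVD component spectra
(participants × 450 frequencies) with PLS1 (NIPALS, internal centring).
The number of factors is chosen by permutation: factor k is kept when its
incremental explained age variance has permutation p-value
(1 + #{null ≥ obs})/(B + 1) ≤ 0.05 over B = 1000 refits with age permuted
(sequential refit; selection stops at the first failure).  This
order-statistic form of the "exceeds the 95% quantile" rule is exactly
sized when (B+1)·level is an integer, which the calibration tests verify.
Frequency importance uses VIP (mean squared VIP = 1 identically).  R-PLS
multiplies the cumulative column weights by |β|/max|β| each iteration and
refits until the surviving set (weights ≥ 1e-3 of the maximum) stabilises
or 50 iterations; the final model is refitted on survivors only.

The tensor route works on participants × channels × frequencies.
PARAFAC-ALS (25 replications of random starts per factor count, 1–10;
relative SSE tolerance 1e-8 or 2500 iterations; lowest-SSE replicate wins)
provides SSE, iteration and core-consistency (CORCONDIA) diagnostics; unit
norm is put on channel and frequency loadings.  Hitting the iteration cap
is a normal stop (overfactored fits on noisy data routinely "swamp"); an
error is raised only when every replicate diverges.  Large tensors may be
Tucker-compressed per mode before ALS (the classic N-way acceleration); the
discarded singular energy is added back into the reported SSE, and tests
confirm the compressed and uncompressed solutions agree.  Tri-PLS1 extracts
per factor the dominant singular pair of Z_jk = Σ_i y_i X_ijk (centred) as
channel/frequency weights, scores participants, deflates, and finally
regresses age on all scores jointly; factors are oriented to correlate
positively with age.

Reported r/RMSE are in-sample, matching the tradition this pipeline
follows; leave-one-out predictions are additionally computed and reported
side by side (`eeg_age_pls_loo`) as an extension, because in-sample
accuracy overstates generalisation.

## Statistics layer

Pearson and partial correlations (residual method, df reduced by the number
of controls); Hotelling–Williams t (df = n−3) for two dependent
correlations sharing a variable, Monte-Carlo calibrated to hold the 0.05
level; Bland–Altman bias, SD of differences, ±1.96·SD limits of agreement
and a proportional-bias slope (differences on pair means); OLS with
in-sample RMSE (divisor n by default — the convention that pairs RMSE with
an in-sample regression line — with the residual-df variant exposed);
paired t tests (zero-variance differences with nonzero mean report signed
infinite t, p = 0).  MINQUE with uniform prior weights (scheme 1) estimates
between-subject, within-subject (channel) and error variance components of
the two-way crossed random-effects layout of per-channel PAF, supporting
missing cells; the solve uses the Woodbury identity so a 60 × 63 grid costs
milliseconds, and on balanced layouts the estimates equal the classical
ANOVA method-of-moments estimators exactly.  Negative raw components are
truncated to zero for the reported proportions only; raw values are kept.
Bayes factors for nested regressions use the Jeffreys–Zellner–Siow
mixture-of-g prior (r scale 0.354) via the one-dimensional integral over g,
computed by adaptive quadrature on the log-g scale with a max-shift for
stability; each model is scored against the intercept-only model and BF01
is the ratio.  Quadrature agrees with Monte-Carlo importance sampling of
the same integral to well under 2%.

## Synthetic cohorts: what they emulate and what they do not

`CohortSpec` defaults describe a 60-participant cohort, 10 per decade from
20–78 years.  The alpha centre follows μ₂ = 10.8 − 0.025·age + N(0, 0.9²)
Hz, clipped to [7.2, 11.8]; the residual SD default of 0.9 Hz puts the
cohort-level M-PAF–age correlation near −0.5, the regime of interest.
NART errors and QMCI are linear-Gaussian in age, planting corr(NART-IQ,
age) ≈ +0.5 and a weak negative corr(QMCI, age); NART-IQ uses the published
conversion 126.41 − 0.9775·errors.  Aperiodic parameters draw from
A0 ∈ [0.8, 1.2], m ∈ [−0.7, −0.5], k ∈ [−0.5, 0.5]: on the log2-amplitude
scale this yields roughly a 60× power drop from 1 Hz to the alpha band —
realistic for resting EEG, steep enough to exercise the aperiodic fit, and
shallow enough that every channel retains a detectable alpha maximum (the
condition under which all five estimators are defined).  Channel alpha
gains follow a linear anterior→posterior gradient (0.70 at Fp to 1.00 at O)
over a 19-channel 10–20 montage; the montage is a parameter, and the
19-channel default keeps a full 60-participant run desk-scale.

Time series are made by inverse-FFT shaping of random phases to the model
amplitude spectrum.  Below 1 Hz the model value is held constant (the
model's power-law blows up as f → 0; the very-low-frequency content of DC
recordings is instead supplied by a separate low-pass random-walk drift,
default 20 μV RMS), and the shaped noise is rescaled to 20 μV RMS.  A
uniform amplitude rescale shifts log2-amplitude by a constant that the
model fit absorbs exactly into the offset k, so planted band parameters are
unaffected.  Transient artifacts are Poisson-placed (default 2/min)
raised-cosine pulses of 150–500 μV and 100–300 ms on random single
channels, and every planted interval is returned as a ledger that the
cleaning tests check against the flag mask.

What the generator does **not** emulate: eye movements and other structured
biological artifacts, electrode impedance effects, non-stationarity within
a recording, realistic channel covariance (channels are independent apart
from the shared spectral shape), or any microstructure beyond the spectral
model.  Passing tests therefore demonstrate that the pipeline recovers what
the spectral model plants — not that it is robust to everything real EEG
contains.

## Problem sizes and numerical choices

The recovery study behind the headline check uses 60 participants × 120 s
× 19 channels per cohort, five cohorts (seeds), with a reduced alpha
scatter of 0.3 Hz ("small" relative to the 0.9 default) so that the
planted −0.025 Hz/year slope dominates sampling noise; the OLS slope of
M-PAF on age, times ten, is reported in Hz/decade.  Unit and calibration
tests use smaller cohorts (6–12 participants, 30–60 s) and 2000-replicate
null simulations.  Degenerate inputs reduce to documented closed forms
throughout (constant responses, identical methods, zero-variance inputs),
and every random draw descends from a single top-level seed, so reruns are
bit-identical.

## Known limitations

* C-PAF's background regression (log power on log frequency, 1–40 Hz) is
  one defensible reading of the "1 SD above the regression" admissibility
  rule; variants (linear frequency, different bands) shift which channels
  are admitted on borderline spectra.
* The tri-PLS tensor uses the channels retained for every participant
  (intersection), so heavy channel exclusion shrinks the channel mode.
* In-sample r/RMSE are optimistic; use the LOO column for an honest
  error estimate.
* EDF files are read (via mne) but not written; delimited text is the
  native on-disk EEG format here.
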