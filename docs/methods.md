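# Methods

This package implements, end to end, a two-part analysis: (1) scoring how well
a person can control a two-class motor-imagery (MI) neurofeedback system from
their EEG, and (2) predicting that aptitude from white-matter microstructure
(regional fractional anisotropy, FA) with a shrinkage discriminant. Because
the kind of data this analysis consumes is rarely shareable, the package ships
generators that synthesize EEG sessions and FA cohorts with the statistical
structure the analysis assumes; every stage is tested against those
generators and against independent small-scale oracles.

## 1. Neurofeedback scoring chain

### Signal model of the EEG generator

`synthetic_data.generate_eeg_session` builds one continuous block:

* Two oscillatory sources at `mu_freq` (default 11 Hz) with slowly varying
  amplitude envelopes (white noise low-passed at 1 Hz, ±25% modulation).
  Source 0 plays the role of the left sensorimotor cortex ("C3-like"),
  source 1 the right ("C4-like").
* Event-related desynchronization (ERD): during the 5-s MI window of each
  trial, the *contralateral* source's amplitude is multiplied by
  `1 − erd_depth` (default 0.5). `erd_depth = 0` injects no effect.
* Fixed mixing: each source projects to the channels through a Gaussian
  spatial profile centred at 1/4 (resp. 3/4) of the channel axis, width 1/8.
  The mixing is deterministic given the channel count, so calibration and
  feedback blocks of the same "subject" share it.
* Background noise: channel-independent 1/f-power noise, scaled so that the
  source-to-noise amplitude ratio at the best-coupled channel equals `snr`
  (default 2).
* Trial layout follows the two-block protocol this analysis targets: a rest
  baseline from −8 s, a cue at −3 s, MI onset at 0 s for 5 s, 20 trials per
  hand in shuffled order, 0–4 s inter-trial jitter, 500 Hz sampling,
  96 channels by default. Amplitudes are expressed in microvolts (10 μV
  source scale).

Not modelled: head-volume conduction, ocular/cardiac artifact morphology,
non-stationary alpha, electrode drift. Consequently, passing tests show that
the *pipeline* recovers a lateralized band-power effect when present at a
given SNR; they do not certify performance on recorded EEG.

### Preprocessing

* Calibration path: zero-phase Hamming-window FIR band-pass 8–30 Hz
  (transition width 25% of the low edge, length by the 3.3/Δf rule), epochs at
  0.5–4.5 s (MI) relative to MI onset, ±500 μV thresholding and
  joint-probability rejection.
* Real-time path: causal 4th-order Butterworth 8–30 Hz. The maximally flat
  Butterworth design is used as such; its passband-edge attenuation is
  verified ≤ 0.5 dB in the tests (a "0.5 dB ripple" cannot occur in a
  Butterworth magnitude response).
* Offline path: 1 Hz high-pass + 40 Hz low-pass FIR on continuous data, then
  variance-based bad-channel flagging (variance > mean + 3 SD across
  channels). Flagged channels are dropped, not interpolated — interpolation
  needs electrode geometry the synthetic data does not have. Independent
  component cleaning is a human-in-the-loop step and is out of scope; the
  offline and online paths therefore differ only in filtering, channel
  removal and rejection.
* Baseline epochs are cut at −7…−3 s relative to MI onset — a 4-s window
  matching the MI window length, lying inside the rest period. The window is
  a configuration value (`session.BASE_WINDOW`), not a constant.
* Joint-probability rejection estimates each channel's value distribution
  with a fixed 100-bin histogram (Laplace-smoothed), sums log-densities per
  epoch and channel, and rejects epochs deviating by > 6 SD on any channel or
  > 2 SD in the all-channel aggregate, in a single pass. Because the density
  is re-estimated on survivors, a second pass may trim a few more epochs;
  exact idempotence is not attainable for z-score-based rejection and is not
  claimed. Amplitude thresholding is exactly idempotent.

### CSP and classifiers

Per-epoch covariances are normalized by their trace and averaged per class;
the generalized eigenproblem `Σ_left w = λ (Σ_left + Σ_right) w` gives
filters sorted by descending λ ∈ [0, 1] (λ and 1−λ swap when the classes
swap). Filter signs are fixed so the largest-magnitude pattern weight is
positive, making serialized models reproducible. A tiny diagonal load
(1e−9 × trace) stabilizes short sessions; a rank-deficient pooled covariance
is rejected instead of silently regularized. One filter per side is selected
from the three most segregating components — by a plausibility callback, by
largest pattern weight on configured motor channels, or (default on synthetic
data) by most extreme eigenvalue.

Features are the log mean band power of 1-s bins shifted by 62.5 ms
(49 bins for a 4-s epoch) on the two CSP-filtered components. Three Fisher
LDA classifiers with equal priors are trained on bin features — baseline vs
left MI (BaseL), baseline vs right MI (BaseR), left vs right (LR) — each as
the arithmetic mean of the weights and biases of 7 stratified-fold fits
("mean classifier"; averaging weights, not posteriors, is the recorded
choice). Base classifiers use the baseline epochs of same-side trials by
default (`side_scope="matching"`), keeping each equation's denominator
restricted to segments that classifier ever sees; pooled baselines are a
switch.

### Performance statistics

With C/T the correct/total segment counts per condition,

    BaseL = 100 (C_B + C_MILeft) / (T_B + T_MILeft)
    BaseR = 100 (C_B + C_MIRight) / (T_B + T_MIRight)
    LR    = 100 (C_MILeft + C_MIRight) / (T_MILeft + T_MIRight)

Each classifier judges its own contrast, so the MI counts entering BaseL/R
come from the Base classifiers' decisions and those entering LR from the LR
classifier. The subject summary is the maximum of the three; ties break in
the order BaseL, BaseR, LR. Cohorts are split at the median of the maxima
(high iff score > median, so 21 subjects split 11 low / 10 high).

## 2. FA cohort model and prediction engine

### Cohort generator

Region means are drawn once per cohort from N(0.5, 0.07) clipped to
[0.30, 0.72] (typical white-matter FA), subject deviations are
N(0, noise_sd²) with `noise_sd = 0.04`. A latent N(0, 1) aptitude score is
median-split into low/high labels. An informative region with signed effect
d has its FA shifted by `noise_sd · d · (g − ½)`, g ∈ {0, 1} the group
indicator: the realized two-group Cohen's d equals the configured d exactly
in expectation, at any d. (The alternative construction — score as a linear
combination of region z-scores — cannot realize |d| ≳ 2.6 after a median
split of a Gaussian score and systematically undershoots the configured
value; the group-shift parameterization was chosen so that "effect size d" is
exact and convergent.) The age–fornix coupling mixes the fornix deviations
with empirically standardized age so the *sample* correlation equals the
target (−0.49 by default) up to the rounding of ages. Covariates emulate a
healthy older cohort: age U(48, 77), education 9–18 y, binary gender,
handedness (76/14/10% right/left/ambidextrous), verbal-fluency and
trail-making scores with plausible means and spreads. Regions other than the
configured ones are mutually independent — real FA tables carry a strong
shared integrity factor the generator does not emulate.

### Shrinkage LDA and CAT scores

Class-centered residuals give pooled variances (df = n−2) and a pooled
correlation matrix computed from exactly standardized residuals, so it has
unit diagonal and is positive semidefinite by construction. Both second
moments are shrunk with analytic MSE-minimizing intensities, clipped to
[0, 1]:

* correlations toward the identity:
  λ⋆ = Σ_{i≠j} V̂ar(r_ij) / Σ_{i≠j} r_ij²;
* variances toward their median, with the analogous ratio.

For truly uncorrelated features λ⋆ → 1 (the target is then the truth); a
genuine correlation signal drives λ⋆ down. Correlation-adjusted t-scores are
τ = (P*)^(−1/2) t, with t the two-sample t-scores on the shrunk variances and
the inverse square root via symmetric eigendecomposition; with P* = I, τ = t
exactly. τ is invariant to per-feature affine rescaling except through the
median-target variance shrinkage (which is not scale-equivariant; forcing
λ_var = 0 restores exact invariance). The discriminant uses
Σ* = D^(1/2) P* D^(1/2) restricted to the selected features, with empirical
class frequencies as priors.

### Selection, cross-validation, significance

Prediction accuracy is the fraction of correct held-out predictions over ten
repeats of stratified fivefold cross-validation, fresh folds per repeat.
Inside every training split, features with |τ| > 4 (threshold on the
*absolute* score, so negative-effect regions are admissible) are selected and
the discriminant is fit on them; the held-out subjects are then predicted.
Two design points deserve explanation:

* Selection thresholds the training split's own CAT scores (one ranking per
  split, as in the standard shrinkage-discriminant cross-validation idiom)
  rather than running a second, nested fold loop inside the split. Both are
  leakage-free; the nested variant was measured to push the informative
  regions' expected |τ| under the threshold at the small training sizes this
  package targets, collapsing otherwise recoverable signal.
  `slda.crossval_select` — the fold-averaged mean |τ| with per-fold inclusion
  frequencies — remains the reporting operation for "variables selected"
  summaries and recovery checks.
* If no feature clears the threshold, the split falls back to the unselected
  discriminant on the full candidate set (the "Variables selected: All"
  model). A majority-class fallback was rejected: under stratified folding
  its accuracy is a deterministic function of the class composition, which is
  invariant under label permutations, so the permutation null degenerates to
  a point mass and the test cannot be calibrated. With the all-features
  fallback the CV statistic varies across permutations and the permutation
  test attains its nominal type-I error (checked in the acceptance suite).
  The p-values remain slightly conservative: the "proportion ≥ observed"
  definition counts ties, and with ~21 effective support points for the
  accuracy the tie mass does not vanish, so E[p] ≈ 0.52–0.53 rather than
  0.5 — a property of the p-definition itself, not of the implementation.

Significance: the group labels are permuted across subjects and the entire
pipeline — selection included — is re-run per permutation;
p = #(null ≥ observed)/n_perm, the literal proportion with no +1 correction,
so the smallest reportable value is 0 and is displayed as "< 1/n_perm". The
exact binomial tail P(X ≥ k | n, ½) is provided for comparison only; it is
anti-conservative for cross-validated accuracies. Partial correlations
between selected regions and the continuous performance score residualize
both on the remaining selected predictors (OLS with intercept) and use a
t-distribution with n − 2 − (k−1) df.

## 3. Numerical choices and degenerate inputs

* Variances are floored at 1e−12 (constant features warn); zero-power bins
  floor at log(1e−20).
* Decision value exactly 0 classifies as the first class (documented tie).
* Stratified folds deal shuffled class indices round-robin; fold counts clamp
  to the smaller class size with a warning.
* All generators and analyses are deterministic given their seeds; fold and
  permutation seeds are separate streams.
* EDF export digitizes to 16 bits per channel at the channel's own physical
  range; events travel in a TRIG channel (1 = left, 2 = right, held 0.1 s).

## 4. Problem sizes used by the test and acceptance suites

Chosen so the full suite exercises every claim at desk scale: null
calibration uses 100 cohorts × 200 permutations with three CV repeats —
fewer repeats leave the accuracy on a 1/21 grid whose ties, under the
"proportion ≥ observed" p-formula, make the p-values visibly conservative,
while three repeats already bring the tie probability down to a few percent —
plus 50 cohorts at the full ten repeats for the chance-level check; recovery
uses 25 cohorts of n = 40 with two d = 1.5 regions; the EEG chain runs 10
sessions at 12 channels and 12 trials per class, which preserves the
study-scale ERD depth and SNR while keeping simulation time modest. The
acceptance script re-runs scaled-down versions of the same computations (its
JSON records the n used for each number).

## 5. Known limitations

* The EEG generator's two-source model makes CSP's job easier than real
  multi-source EEG; channel counts beyond the two mixing bumps add noise
  dimensions only.
* Region FA values are conditionally independent given the group — no global
  integrity factor, no spatial smoothness, no hemispheric symmetry.
* The joint-probability rejector is a reproducible approximation of the
  toolbox behaviour it emulates (histogram density, fixed bins), not a
  re-implementation of it.
* With 21 subjects the permutation p of a single cohort is itself noisy at
  200 permutations; the default for real use is 10,000.
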