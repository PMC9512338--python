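# Methods

## Problem and model

During a radiotherapy fraction the prostate moves — slow baseline drift from
bladder filling, and occasional abrupt excursions from rectal gas.  Real-time
transperineal ultrasound tracking yields, for every fraction, a time-sampled
displacement trace (typically 4 Hz) in the superior–inferior (SI),
anterior–posterior (AP) and left–right (LR) directions, zeroed at the scan
start position.  The internal margin (IM) added around the clinical target
volume must absorb this intra-fraction motion.

`intramargin` treats the per-axis displacement samples as draws from a
two-level nested random-effects model:

    y_pft = m + a_p + b_pf + e_pft
    a_p   ~ N(0, Σ_pt²)      inter-patient (systematic)
    b_pf  ~ N(0, σ_fr²)      inter-fraction within patient
    e_pft ~ N(0, σ_intra²)   intra-fraction residual

with fraction labels meaningful only within a patient, and all components
independent.  Two estimators of (Σ_pt, σ_fr, σ_intra, m) are provided:

* **moment** — the classic definitions used with the van Herk recipe: the
  systematic SD is the sample SD of per-patient mean displacements (all
  samples pooled within patient), the inter-fraction SD is the pooled
  within-patient SD of fraction means, and the intra-fraction SD is the RMS
  of within-fraction SDs.  Because each patient mean carries sampling noise
  of its own fraction means, the moment systematic SD estimates
  sqrt(Σ_pt² + σ_fr²/F) rather than Σ_pt — the well-known overestimation of
  systematic error, which the package demonstrates empirically in its test
  suite.
* **REML** — restricted maximum likelihood for the nested model, which
  separates the three levels correctly and permits boundary estimates
  (Σ_pt = 0).

Margins then follow the effective-error chain for a course of N fractions:

    Σ_eff² = Σ_pt² + σ_fr²/N
    σ_eff² = (1 − 1/N) σ_fr² + σ_intra²
    IM     = 2.5 Σ_eff + 0.7 σ_eff

The finite-N correction moves the part of the inter-fraction variance that
does not average out over a short course into the systematic term.  The
coefficients (2.5, 0.7) are taken as given (they target a 95% minimum CTV
dose for 90% of patients); they are configurable but their dose-population
derivation is not re-derived here.

## REML computation

The restricted log-likelihood is evaluated from per-fraction sufficient
statistics.  With n_pf samples, fraction mean ȳ_pf and within-fraction sum
of squares SS_pf, the within-fraction residual subspace contributes
independent N(0, σ_intra²) terms, and the fraction means follow a one-level
random-effects model with heteroscedastic residual variance
d_pf = σ_fr² + σ_intra²/n_pf and patient covariance Σ_pt² (handled in closed
form by Sherman–Morrison per patient).  One likelihood evaluation is
therefore O(#fractions) regardless of the sampling rate.  The convention is

    ℓ_R = −½ [ (N−1) log 2π + log|V| + log(1'V⁻¹1) + r'V⁻¹r ],

with r the residual around the GLS mean; the test suite verifies this path
against a literal dense-covariance evaluation to 1e-8, and against `lme4` as
an independent reference implementation.

Numerical choices:

* Optimization is derivative-free Nelder–Mead on log-variances, multi-started
  from the moment estimates plus fixed perturbations (deterministic given the
  data), followed by explicit refits with Σ_pt and/or σ_fr pinned to 0; a
  boundary solution is reported whenever it costs at most 1e-7 in
  log-likelihood, so boundary estimates are exact zeros rather than tiny
  positives.
* On balanced designs with interior optima the fit reproduces the
  expected-mean-squares (nested ANOVA) closed form to 1e-6 (asserted in the
  suite).
* Confidence intervals are profile likelihood with the χ²₁ cutoff at the
  requested level (default 0.95), truncated at 0.  Wald intervals are not
  offered: they misbehave at the Σ_pt = 0 boundary.  The profile is traced by
  geometric continuation away from the optimum, warm-starting the nuisance
  optimization at each step — jumping straight to a distant profile point can
  strand the nuisance parameters (e.g. at σ_fr = 0 the residual variance must
  inflate by the sampling factor to absorb the fraction-mean dispersion).
* The mean's CI profiles the three variances at each fixed mean, using the
  restricted criterion augmented with the GLS quadratic term in the mean.
* A degenerate zero-variance cohort (all samples identical) short-circuits to
  zero components with degenerate CIs, so downstream margins are exactly 0.
* An optional thinning stride subsamples within fractions for autocorrelation
  sensitivity checks; the estimators otherwise treat residual samples as
  exchangeable within a fraction, which is the model's central assumption.

The moment estimator reports chi-square (variances) and t (mean, over patient
means) intervals; these are large-sample approximations supplied for
uniformity of the result type, not profile intervals.

## Synthetic cohorts

The generator is the sampling twin of the model above.  Each trace starts
with the zeroing reference sample (identically 0 at t = 0, mirroring the
clinical convention that the position at scan start defines zero); for t > 0
the displacement is m + a_p + b_pf plus stationary intra-fraction noise —
white by default, AR(1) with configurable correlation time for sensitivity
studies.  Because the offsets enter only after the reference sample, the
t > 0 samples are exactly stationary and the configured components are
recoverable; estimation drops the reference sample by default for the same
reason (it is a constraint, not an observation).  Had re-zeroing instead been
implemented by subtracting the first *noisy* sample, the patient and
fraction offsets would cancel entirely — the chosen construction is what
keeps the generator and the estimand consistent.

Optional non-model features emulate real traces:

* **baseline drift** — linear, per-axis rate in mm/min (default 0; published
  kV-tracking studies report drifts up to ~2 mm over 15 min);
* **gas events** — Poisson count per fraction (default rate 0, since gas
  venting before delivery makes them rare), half-sine unipolar pulses on the
  AP axis, peak drawn Exponential with mean amplitude/2 (default scale
  9.7 mm, the magnitude of the largest published excursion; duration 10 s).

Default cohort geometry mirrors a step-and-shoot IMRT cohort: 5 patients ×
37 fractions, 492 s fractions at 4 Hz, with component defaults equal to the
published SS-IMRT column (Σ_pt = (0.00, 0.10, 0.00), σ_fr = (0.41, 0.80,
0.31), σ_intra = (0.34, 0.69, 0.23) mm for SI/AP/LR).  What the generator
does *not* emulate: autocorrelated drift-like trends (beyond the linear
term), bladder-filling physiology, measurement noise of the tracking system,
or any imaging.  Passing recovery tests therefore shows the estimators are
correct under the stated model, not that clinical traces satisfy it.

## Study-sized validation

The suite includes a parameter-recovery study at published-cohort scale:
200 simulated cohorts of 14 patients (fraction counts 12×37 + 26 + 20),
240 s fractions at 4 Hz, truth set to the SS-IMRT AP component column.  It
checks ~95% profile-CI coverage per component (binomial 3σ band) and
relative bias of the point estimates.  240 s was chosen as the fraction
length (the short end of realistic delivery times) to keep the study's
problem size moderate; the per-fraction information about σ_intra is already
enormous at that length, so the choice is immaterial for the conclusions.

Known limitation, measured by that study: with only 14 patients and
Σ_pt = 0.10 mm — i.e. Σ_pt² comparable to the sampling noise of the
patient-level variance — the REML Σ_pt point estimate is biased low by
roughly 5–10% of the truth (boundary truncation at 0 plus the concavity of
the square root).  This is intrinsic to SD estimation near the boundary at
small patient counts, not an implementation defect: the same code at 56
patients shows Σ_pt bias within a couple of percent, and σ_fr / σ_intra are
unbiased to <1% at every size tested.  CI coverage is nominal throughout.

## Unequal fraction counts

Cohorts with per-patient fraction counts are first-class.  For the
effective-error N the default policy is `max` (the full-course prescription,
e.g. N = 37 when some patients were observed for fewer fractions), with
`harmonic` and explicit integers available.  Recomputing the published VMAT
margin column from its printed components matches at N = 37, so the default
reproduces that choice.

## File format and reporting

Cohorts are stored as one long-format CSV (technique, patient_id,
fraction_id, time_s, si_mm, ap_mm, lr_mm) with `#` metadata comments
declaring the sign conventions; numbers are serialized at 1e-6 mm so writing
is canonical and write∘read∘write is byte-stable.  The CLI reports values at
two decimals (mm), matching the field's reporting convention; files keep
full precision.  The statistics are sign-symmetric, so the sign convention
(positive = superior/anterior/left) does not affect any reported SD or
margin.

## Open choices made here

* The rank-sum comparison between techniques operates on per-fraction
  maximum absolute displacements pooled by technique, per axis — the
  fraction is the natural unit for maxima; patient-level pooling is possible
  through the same API by passing patient summaries instead.
* The time-resolved mean-|displacement| curve uses 1 s bins by default.
* `reml_loglik` with a caller-supplied mean keeps the log(1'V⁻¹1) term, so
  fixing the mean at the GLS solution reproduces the profiled value exactly.
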