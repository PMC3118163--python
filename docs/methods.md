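# Methods

This note documents the statistical models behind `mlpacall`, the defaults
and why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions that matter at the edges.

## Data model

An experiment is a dense probe × run matrix of non-negative peak intensities
plus per-run metadata (group `control`/`case`, subject id, replicate index).
"Intensity" is an abstract signal: peak height and peak area both work if
used consistently.  Missing peaks must be encoded as 0 upstream; a probe
that is zero in every run is flagged invalid (it carries no signal) and is
excluded from all-probe divisors.  Replicate structure is declared in the
metadata, never inferred from run-id naming — naming conventions vary across
labs and silent inference is error-prone.  An experiment "has replicates"
iff some subject has at least two runs; methods that need replicates refuse
otherwise with a typed error.

## Normalization

All four methods *divide* by a fitted factor rather than subtracting
residuals, so the output lives on the natural "no change = 1" dosage-ratio
scale that the 0.7/1.33 cutoffs assume.

Fitting units: without replicates, each run is fitted and divided
independently; with replicates, the factor is computed from the subject's
replicate-mean profile and applied uniformly to that subject's runs.  A
subject's normalization factor is a property of the sample, not of the
injection, and dividing each replicate by its own factor would absorb
exactly the within-subject variability the mixed model needs.  A
consequence worth knowing: per-run scale noise largely cancels out of
*subject means* (the divisor is built from the same runs) but remains in the
run-to-run spread.

* **Sum peaks** (`reference_only` / `all_probes` scope): divisor is the sum
  of the chosen peaks.  Exactly invariant (in real arithmetic) to rescaling
  a fitting unit by any c > 0; in floating point the invariance holds
  bitwise for power-of-two factors and to ~1e-15 relative otherwise, because
  addition is not exactly scale-equivariant.  Re-normalizing
  `sum_peaks_controls` output is a fixed point: the second-pass divisor is
  exactly 1 (the reference peaks of a normalized run sum to 1).
* **Slope correction**: per unit, OLS of intensity on probe size over the
  reference probes; every probe is divided by the fitted line at its size,
  so reference probes have expected normalized value 1.  Needs ≥ 2 reference
  probes with distinct sizes.  Fitted values below 1e-12 abort with an error
  naming the probe — a line that crosses zero inside the panel's size range
  means the linear model is wrong for these data, and silent clipping would
  fabricate enormous ratios.
* **Nonlinear (exponential decay)**: per subject, fit
  A·exp(−λ·size) to the reference-probe replicate means by bounded
  nonlinear least squares (λ ≥ 0), weighted by inverse within-subject
  replicate variance.  The two-parameter exponential is the minimal model
  consistent with a monotone, positive, size-driven decay.  Variance weights
  are floored at the 10th percentile of the positive variances so a
  zero-variance probe cannot get infinite weight; when no variance is
  positive (noise-free data) the fit is unweighted.  Initialization is a
  log-linear OLS on the positive means — exact on noiseless data — refined
  with `scipy.optimize.least_squares` (xtol = ftol = 1e-12, iteration cap
  300 function evaluations); non-convergence raises rather than returning a
  partial fit.  Requires replicates and ≥ 3 reference probes (three points
  to constrain two parameters plus residual spread).  One decay is fitted
  per subject; a shared global decay with per-subject amplitudes would be a
  reasonable alternative but couples subjects through a joint fit and was
  not needed for the panel sizes targeted here.

## Calling

All methods code each test probe per case subject as −1/0/+1 and record an
estimate plus the no-change band on the same scale; a probe is called +1
exactly when the estimate strictly exceeds the upper bound (and symmetrically
for −1).  Boundary values are "no change": the cutoffs are described as
"lower than"/"over", which reads as strict, and ties should not create
findings.  Reference probes anchor the null machinery of the band methods
and are reported with call 0.  No multiple-testing correction is applied by
default — the intervals are per-probe, as is conventional for MLPA panels —
and an optional Bonferroni flag across test probes is available.

### Threshold

Dosage ratio per (probe, case subject): the subject's normalized replicate
mean over the mean of the control subjects' replicate means.  Defaults
0.7 (loss) / 1.33 (gain); both configurable, validated as
0 < lower < 1 < upper.

### REX-MLPA

Per case subject (or pooled case mean with `pooled_cases`), regress the case
profile y on the pooled control mean profile x.  Case-on-control is the
regression direction; the two are symmetric for calling purposes but
case-on-control matches the convention of plotting case against control.
The band is a *prediction* interval (t quantile, residual variance, new-
observation term): each probe is classified as an individual new
observation, so the confidence-of-mean band would be too narrow.  The
iteration starts from the reference probes; test probes inside the band join
the inlier set, the line is refitted, and the loop stops when the set is
unchanged.  The inlier update is growth-only — once admitted, a probe stays
in the fitting set — which makes the inlier sequence monotone and guarantees
termination within n_test iterations; the final classification uses the last
fitted band.  A level of 0.95 is the default; the level is a configurable
parameter, not a claim about any particular historical implementation.
Degenerate cases: zero variance in the inlier x values raises; a fit with no
residual degrees of freedom yields an infinite band (everything is an
inlier); a zero residual variance (perfectly collinear data) gets a relative
band floor of 1e-8 × the mean |y| so float rounding cannot manufacture
outliers.  Hitting the iteration cap returns the last iteration's calls with
a warning flag rather than failing.

### Mixed model

Preconditions: ≥ 2 control subjects, ≥ 2 reference probes, and replicates
(≥ 2 runs for ≥ 2 subjects).  The model works on log normalized intensities,
where multiplicative assay noise is additive and (for a signal-proportional
error) homoscedastic across probes, which justifies pooling variance across
the panel.  Response per case subject s and probe p:

    d(p, s) = log x̄_case(p, s) − log x̄_controls(p)

with x̄ denoting replicate means.  The null variance of a subject-mean
profile value, v, is estimated by pooling squared leave-one-out differences
between control subjects over all probes and rescaling by (n_c − 1)/n_c;
this moment estimator coincides with REML for the balanced one-way layout
and, importantly, absorbs the correlations that per-subject normalization
divisors induce (a naive between/within decomposition overstates the
subject-mean variance, because per-run scale noise cancels in subject means
— this was verified directly during development and is why the band is not
built from the replicate-level variance).  The grand mean δ is the average
of d over the case subjects' reference probes, capturing any residual global
shift between groups.  The no-change band is

    δ ± z(level) · sqrt(v · (1 + 1/n_c)),

a z (normal) quantile: v pools on the order of n_probes × n_c terms, so the
effective degrees of freedom are large and a t correction is negligible; the
calibration study below confirms the resulting null call rate.  The band
assumes the case subjects' replicate structure is comparable to the
controls'.  Estimates and bounds are mapped back through exp() to the
dosage-ratio scale (monotone, so the sign rule is preserved).  Degenerate
inputs: if v collapses to ~0 (noise-free data) it is floored at 1e-12 with a
warning, so exact ties are never called; non-positive normalized intensities
(a fully absent peak) are floored a decade below the smallest positive value
before the log, which registers as an extreme loss rather than a crash.
The pooled replicate-level log variance is reported alongside the fit as a
diagnostic of assay precision.

## Synthetic data

The generator emulates the dominant structure of MLPA peak data:

    intensity(p, run) = A·e^(−λ·size_p) · run_factor · multiplier_p · noise

with lognormal per-run factors (sd `run_scale_sd`), lognormal per-cell noise
(sigma chosen so the cell CV equals `within_subject_cv`), and planted
multipliers applied to case subjects only, identically across a subject's
replicates (a genotype belongs to the subject).  Multiplicative noise keeps
intensities positive and errors proportional to signal.  Defaults: 34
probes (9 reference, spread over 90–500 bp), 10 case + 5 control subjects,
A = 1000, λ = 0.004/bp (~5× decay across the size range), run_scale_sd =
0.15, within-subject CV = 5% — a typical well-behaved candidate-gene panel.

Not emulated: stutter peaks and other electrophoresis artifacts,
probe-specific amplification efficiencies beyond the size decay,
batch/plate effects spanning runs, allele-specific signals, and
heteroscedasticity across probes.  Passing tests therefore demonstrate
correctness of the algorithms under a clean multiplicative noise model, not
robustness to every failure mode of real capillary data; on real
experiments, inspection of the normalized reference probes remains
essential.

## Simulation studies

* **Calibration.**  500 null simulations (triplicates, 5% CV) are scored by
  the fraction of truly-null test-probe calls; the mixed model at level 0.95
  lands near 0.05 (slightly above, as expected from estimating v), within
  the binomial 95% band for 500 simulations.
* **Matched-type-I power.**  The power study uses a noisier assay (15% CV)
  — with a 5% CV every method saturates at these effect sizes and the
  comparison is uninformative.  The threshold method is evaluated the way a
  replicate-unaware analysis would run it, on one run per subject; the mixed
  model uses the full triplicates and is rerun at the level matching the
  threshold method's empirical null call rate.  Each power experiment plants
  a gain m and a mirrored loss 1/m, so the asymmetry of the 0.7/1.33 pair
  (they are not reciprocal) affects both methods fairly.  Power is the
  fraction of altered (probe, case-subject) cells called with the correct
  sign.  Simulation sizes (300 null / 250 per effect in the acceptance
  script) keep Monte-Carlo error well below the observed margins.

## Known limitations

* The mixed model calls each case subject marginally; it does not borrow
  strength across case subjects for a shared alteration, nor does it return
  integer copy numbers — calls are relative gain/loss only.
* REX-MLPA's level-monotonicity (wider band ⇒ no new calls) is an empirical
  property verified over randomized fixtures, not a theorem: the refitted
  line differs between levels, so pathological configurations could in
  principle violate it.
* Association testing of called CNAs with phenotypes, interassay QC and
  reference-probe stability selection are out of scope.
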