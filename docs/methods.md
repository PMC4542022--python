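# Methods

## Problem and pipeline

The package targets dichotomous early prediction of severely depressed
left ventricular ejection fraction (LVEF ≤ 25%, the positive class)
from ICU variables available shortly after admission. The full pipeline
is: (1) dichotomize LVEF at 25% (boundary inclusive); (2) remove
measurements outside physiologically possible bounds; (3) aggregate timed
measurements into per-patient window means; (4) min-max normalize each
variable to [0, 1]; (5) split the cohort into equal feature-selection
(FS) and model-assessment (MA) halves; (6) run sequential forward
selection (SFS) with a cross-validated AUC criterion repeatedly on the FS
half and keep the consensus features; (7) assess the consensus model on
the MA half under repeated stratified 5-fold cross-validation.

## Takagi–Sugeno identification

Identification clusters the **input–output product space** `[X, y]`
(the target min-max scaled for clustering only) with Gustafson–Kessel
(GK) clustering, the standard practice for GK-based TS identification:
clusters then capture joint input–output regimes, and on piecewise-linear
targets the per-rule weighted regressions recover the regime slopes
(verified to 5% in the tests). Antecedents are Gaussian membership
functions whose center and width are the membership-weighted mean and SD
of the partition projected onto each input axis; they peak at 1 at the
projected cluster center, matching the smooth unimodal antecedents this
model family produces. Rule activation uses the product t-norm.
Consequents are estimated per rule by membership-weighted least squares
against the label (local estimation — better conditioned than global
joint estimation at a few hundred samples per fold). The binary label is
regressed directly, so the continuous output acts as a class possibility;
the classification threshold is then chosen on the training ROC.

Degenerate inputs and numerical choices:

* GK fuzzy covariances are shrunk toward a scaled identity whenever their
  condition number exceeds 1e12 (clinical variables are frequently
  near-collinear inside a cluster); cluster volumes are fixed at ρ = 1,
  so every norm matrix has unit determinant.
* GK initialization draws per-sample memberships from a symmetric
  Dirichlet, seeded; convergence is declared when the largest membership
  change falls below 1e-6 (cap 200 iterations). The fuzziness exponent
  defaults to m = 2, the conventional choice.
* An input axis with fewer than 3 distinct values (e.g. a binary gender
  column) gets a flat antecedent (constant 1) with a warning — the rule
  then ignores that variable in its activation.
* Rank-deficient weighted regressions fall back to a small ridge with a
  warning. If every rule's activation underflows (< 1e-12, only possible
  far outside the training support after clipping), the output falls back
  to the unweighted mean of the rule consequents.
* Samples at zero induced distance from several cluster centers split
  their membership equally among the tied clusters.
* Scores exactly at the classification threshold map to the positive
  class (`>=` convention, used consistently in every metric).

## Logistic baseline

Plain maximum-likelihood logistic regression fitted by iteratively
reweighted least squares with step halving (penalty-free by default; an
optional ridge is available for separable data). The log-likelihood is
non-decreasing across iterations and convergence requires a score
max-norm below 1e-8. Complete separation — where the unpenalized MLE does
not exist — is detected both by diverging coefficients and by checking
whether the fitted linear predictor perfectly separates the classes, and
is reported as `converged=False` with a warning. Its classification
threshold is chosen on the ROC exactly as for the fuzzy model, so the two
families are compared on the same footing.

## Evaluation

AUC is computed two independent ways — the Mann–Whitney rank identity
(ties counted 1/2) in `auc()`, and trapezoidal integration of the stored
ROC in `roc_curve()` — and the suite asserts their agreement to 1e-12.
The operating threshold maximizes Youden's J = sensitivity +
specificity − 1 (ties broken toward higher sensitivity); the
distance-to-(0,1)-corner criterion is available as an alternative.
Cross-validation is stratified by class per repetition; normalization is
refit on the training folds inside each builder by default (leakage-free),
with a single global normalization available as a literal-replication
mode. Per-fold AUCs are averaged, not pooled. Interval models are
compared by a two-sample Welch t-test on the distributions of
per-repetition mean AUCs against the 0–6 h baseline window (the pooled
test is available; Welch is the default because group variances are not
assumed equal). The Pearson-system check classifies a sample's
(squared-skewness, kurtosis) pair through the standard κ discriminant
with a tolerance band around the type boundaries — gamma-like samples sit
exactly on the type III boundary and would otherwise be assigned
arbitrarily by sampling noise.

## Sequential forward selection

Greedy growth with the cross-validated mean AUC as criterion; all
candidates within a round are scored under the same fold configuration.
A candidate is accepted only if it improves the incumbent by more than
1e-4 ("no improvement" stop); ties break toward the lowest feature index,
making the procedure seed-independent given the folds. Selection is
re-run under many random CV configurations and the **consensus** keeps
features selected in more than half of the runs (quota configurable).
Repetition defaults are desk-scale (50 for selection, 50 for assessment);
the original design's 500 selection repetitions are available through the
configuration. The tests use 2–20 repetitions and cohorts of 250–1000
patients, sizes at which every asserted property is already stable.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes:
one row per ICU stay; a Bernoulli class label at prevalence 115/936
(12.3%); 16 continuous variables drawn from class-conditional truncated
normal distributions with the published group means and SDs; gender as
Bernoulli with class-specific male fractions (64.4% / 52.6%). Truncation
at the physiologic bounds would bias the mean of variables whose bound
sits within ~2 SD of the mean (admission weight, glucose, oxygen
saturation against its 100% ceiling), so the location of the underlying
normal is calibrated by root-finding so the *post-truncation* mean equals
the target; the scale is kept at the published SD (the realized SD is
therefore slightly smaller near a bound, most visibly for oxygen
saturation). Variables are independent within class by default; a
Gaussian copula with a user-supplied correlation matrix is available,
since the source statistics report no covariances. Timed measurement
streams sample each variable on its acquisition grid (vitals hourly,
labs daily) with uniform jitter up to a quarter period and additive
Gaussian observation noise with SD = 25% of the class SD around the
patient's latent value — wide enough that single observations are noisy,
while 6-hour window means concentrate toward the latent value. A
`window_effects` hook can plant time-localized class effects for
harness-level tests.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: informative missingness and irregular
acquisition patterns, within-class correlation between variables (unless
supplied), temporal dynamics such as treatment response after admission,
and any within-class association between features and the label. That
last point matters for interpretation: because features are sampled
conditionally on the class, a cluster that captures one class leaves no
residual gradient toward the label, so fitted consequent slopes on
synthetic cohorts are near zero and discrimination is carried by the rule
offsets and antecedents. Non-trivial consequent coefficients like the
published fitted rules arise only on data with within-class
feature-outcome structure. Cross-validated AUCs on the default generator
(~0.7–0.8) reflect the generator's independent-features geometry, not an
estimate of clinical performance.

## Printed-rule fixture

The two published fitted rules (seven normalized inputs: systolic NBP,
respiratory rate, BUN, hemoglobin, sodium, white blood cells, admission
weight) are shipped as an exactly transcribed `TSModel`. Their antecedent
membership-function parameters were published only graphically, so the
fixture's antecedents default to the constant function 1: consequent-level
arithmetic is exact, while full weighted-sum inference on raw inputs
requires caller-supplied activations. This limitation is inherent to the
source, not a modeling choice.

## Interval-comparison harness

Windows are half-open `[start, end)` hours from admission, so consecutive
6-hour windows are nonoverlapping by construction; the separate
first-hour model (0–1 h) deliberately overlaps the 0–6 h baseline and is
toggled independently of the nonoverlap check. Each window's feature set
is the five regularly acquired vitals (heart rate, diastolic and systolic
NBP, respiratory rate, oxygen saturation) as window means, joined with
the admission constants age and weight; patients lacking any value in the
window are dropped (complete-case analysis — no imputation). Windows left
with fewer positive patients than folds are skipped with a warning.

## Reproducibility

Every stochastic component (generator, GK initialization, fold
assignment, SFS repetition seeds) threads a `numpy` `default_rng` seed;
orchestration spawns per-stage substreams from one master seed, and every
study artifact records the seed and a hash of its configuration. Two runs
with the same configuration and seed produce identical artifacts, which
the test suite asserts end to end.

## Known limitations

* The GK update equations follow the canonical alternating-optimization
  scheme; no cluster-count selection is provided (the rule count is a
  parameter, default 2).
* Coefficient inference (standard errors, Wald tests) for the logistic
  baseline is out of scope; the comparison metric is discrimination.
* The consensus rule operationalizes "most often selected" as frequency
  > 0.5; how many features clear the quota is data-dependent.
* Global (whole-dataset) normalization is provided for literal
  replication but leaks fold information by construction; the default
  refits per fold.
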