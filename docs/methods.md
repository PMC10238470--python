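# Methods

## Model

The smoothing mixture model assumes a population of subjects, each
following one of K latent mean trajectories plus subject-level noise:

    y_it = f_{k(i)}(t) + b_i + e_it,   b_i ~ N(0, σ_b²),  e_it ~ N(0, σ²)

where *f_k* is a smooth function of month estimated nonparametrically and
*k(i)* is the subject's latent class. Classification is *hard*: each
subject belongs to exactly one class, and uncertainty in membership is
deliberately ignored — the E step maximises, rather than averages over,
the class likelihood. This makes the algorithm a classification E–M
(k-means-like) rather than a soft-mixture E–M.

### Class smoothers

Each *f_k* is a P-spline: 6 cubic B-splines on equally spaced knots
spanning the observed month range, with a second-order difference penalty
on adjacent coefficients. With nine monthly support points, six basis
functions are the most flexibility the data can sustain, and the
second-order penalty's null space (constant + linear) preserves linear
gain trends no matter how hard the fit is penalized. The smoothing
parameter λ is reselected by generalized cross-validation on a log-spaced
grid (10⁻⁴..10⁴, 41 points) at every M step; GCV is used because it needs
no tuning constants and no auxiliary estimate of σ². Ties on the grid go
to the smaller λ.

Each class also carries a residual variance σ²_k = RSS/(n − edf), floored
at 10⁻⁶ kg² so that a class of identical trajectories (possible in
noise-free simulations) cannot produce a degenerate likelihood in the E
step. Effective degrees of freedom are tr[B(BᵀB+λP)⁻¹Bᵀ].

Two residual models are available for subject scoring:

* **independent residuals** (default): observations within a subject are
  scored independently around the class curve. This is the
  population-curve classification used everywhere in the package's tests.
* **compound symmetry** (`random_intercept=True`): a subject random
  intercept induces covariance σ_b²·J + σ²·I within a subject; variance
  components are estimated per class by method of moments from
  within-subject residual covariances, and subjects are scored with the
  marginal multivariate normal (Sherman–Morrison closed form). With
  parallel class curves both scorings imply the same decision boundary;
  the option mainly changes the likelihood scale and hence BIC.

### The E–M loop

Initialization ranks subjects by mean observed weight and cuts the
ranking into K contiguous, near-equal groups (larger groups first; ties
in the mean break by subject order), so the whole fit is deterministic —
no seed enters the classifier itself. Convergence requires both an
unchanged membership vector and a relatively stable total log-likelihood
(tolerance 10⁻⁶); because the M step is deterministic, unchanged
memberships imply a stable refit, so the loop typically stops one
iteration after memberships freeze. The iteration cap is 100.

For *fixed* class models, reassignment can only increase each subject's
best log-likelihood; this is asserted on every iteration and recorded in
the results trace. Across iterations the total may still dip slightly
because λ and σ² are re-estimated — the trace records both quantities so
the monotone part of the claim is testable exactly.

An empty class aborts the fit for that candidate K with a
`DegenerateClassError` (recorded, not fatal, during model selection);
silent class-count reduction would corrupt the selection table. An
optional `reseed_empty` mode instead moves the single worst-fitting
subject into the empty class.

### Class-count selection

BIC = −2·LL + p·log(n) with p = Σ_k edf_k + K (one residual variance per
class) and n = total observation count by default (`bic_n="subjects"` is
available; the right n for penalized longitudinal BIC is genuinely
ambiguous). Under hard assignment, splitting any noisy class into two
always buys roughly 0.5·log(variance ratio) log-likelihood per
observation, so raw BIC keeps decreasing well past the generating class
count. The default selection therefore applies a parsimony rule on top of
BIC: choose the candidate at the **elbow** of the BIC curve — the interior
K maximising the second difference BIC(K−1) − 2·BIC(K) + BIC(K+1), i.e.
where per-class improvements drop off hardest. The elbow falls back to
the plain BIC minimum when the minimum is at the smallest candidate, only
two candidates succeed, or the improvements keep accelerating. Two
simpler rules are selectable: `"margin"` (smallest K within a configurable
fraction, default 1%, of the minimum BIC) and `"none"` (BIC minimum).
On three-class synthetic cohorts at study scale the elbow rule recovers
K = 3 in 20/20 seeds while the raw minimum sits at K = 5.

Class medians in the selection table are medians (with IQR) of each
class's subject mean observed weights.

### Relabeling and concordance

After selection, classes are reindexed by ascending fitted-curve mean;
for K = 3 they are labelled low/medium/high. Relabeling is a pure
permutation — likelihoods, BIC and memberships are invariant. The
concordance cross-tab compares a K-quantile grouping on first-month
weight (rank-based, deterministic tie handling) against the model
classes; its diagonal share is reported as a percentage.

## Association stage

For each binary outcome, a crude logistic model contains only class
dummies (medium as reference; for generic K, the middle class rank), and
an adjusted model adds the covariates that pass a univariate screen:
candidate kept iff its single-predictor Wald p-value is strictly below
0.2. A `force_adjust` switch always includes all three candidates
(maternal age, gestational age, gravidity) instead. Estimates are Wald:
OR = exp(β), CI = exp(β ± 1.96·SE), two-sided normal p-values. Fitting is
IRLS (statsmodels GLM, binomial family, tolerance 10⁻⁸, 50 iterations);
complete separation raises an explicit error naming the worst predictor
rather than silently penalizing, since a Firth-style fallback would
change the estimand. Outcomes with fewer than five events are flagged
low-information but still fitted. No multiplicity correction is applied.

## Synthetic cohort generator

The generator emulates the assumed study structure and provides ground
truth for recovery tests:

* n = 877 subjects, months 1..9, three classes in proportions
  38/36/26%. Class sizes are allocated by **largest remainder** (exact,
  deterministic) so recovery tests have exact ground truth; multinomial
  allocation is a switch.
* A shared monotone gain curve (0, 1.6, 3.1, 4.7, 6.3, 7.9, 8.7, 8.8,
  8.9 kg over the month-1 level — total gain 8.9 kg, plateauing after
  month 7); per-class gain curves are a config option. Class baselines
  are set so subject mean weights have medians ≈ 63 / 71.5 / 79.5 kg.
* Subject random intercept SD 2 kg and residual SD 1 kg. These
  within-class scales are plausible choices, not literature values: the
  descriptive tables this structure mirrors report only marginal SDs.
* Covariates: age ~ N(29, 5²) truncated to 18–40, gestational age ~
  N(38, 1²), gravidity ~ 1 + Poisson(1).
* Outcomes: Bernoulli with logit = logit(baseline prevalence) + class
  log-odds (reference class medium, entry 0) + centered covariate
  effects (zero by default). Default prevalences 28.8% (icterus), 3.3%
  (abnormality), 16.9% (NICU), 13.7% (preterm), 15.7% (preeclampsia),
  6.1% (GDM); default class effects are odds ratios of 1.69/1.50/1.77/
  1.82/0.93/0.96 (low vs medium) and 1.44/2.56/1.09/1.11/1.19/1.21
  (high vs medium).
* Composites are the logical OR of independently drawn components.
  Because real components are positively correlated, the simulated
  composite prevalence (~53% for the neonatal composite) exceeds the
  ~33% a real cohort shows — a known gap between generator and reality.
* Missing data: none by default; an MCAR dropout rate is available (each
  observation independently removed, every subject keeps ≥ 1).

### What passing tests do and do not show

With baselines ~8.5 kg apart and a subject-mean SD of √(σ_b² + σ²/9) ≈
2.03 kg, about 1.8% of each class boundary's tail lies beyond the
midpoint. A Bayes-optimal classifier knowing the true curves and
covariance therefore attains a mean adjusted Rand index of ≈ 0.92 at
n = 877 — the information-theoretic ceiling of this scenario. The test
suite checks that the fitted classifier performs at that ceiling (within
0.03 ARI of the oracle), not that it exceeds it; noise-free scenarios
separately verify exact recovery (ARI = 1). Passing these tests shows the
algorithm extracts essentially all class information the simulated data
contain; it does not show that real cohorts are this well separated, that
real gain curves are parallel, or that real outcome components are
independent.

## Numerical choices

* Quantiles everywhere use linear interpolation between order statistics
  (numpy default) — medians/IQRs depend on this convention.
* E-step ties go to the lowest class index; GCV ties to the smallest λ;
  largest-remainder ties to the lowest class index.
* No extrapolation: evaluating a class curve outside the fitted month
  range raises rather than silently extending the spline.
* The E-step monotonicity check (for fixed models) is enforced at run
  time with absolute tolerance 10⁻⁸·(1+|LL|).
* Degenerate inputs: duplicate (subject, month) rows, non-positive or
  implausible (≥ 250 kg) weights, and non-integer months are rejected at
  read time with row numbers.

## Problem sizes used in tests

Unit tests run at n = 60–877 subjects; recovery and selection properties
use 20 seeded replicates of the n = 877 scenario; odds-ratio round trips
use n = 20,000 subjects (20 seeds for bias, 500 replicates for CI
coverage). The full suite and the acceptance script each complete in well
under a minute on one CPU.

## Known limitations

* Only Gaussian trajectories are implemented; the architecture (per-class
  smoother + per-subject likelihood) would extend to Bernoulli/Poisson
  responses but v1 does not.
* No posterior membership probabilities — hard assignment by design.
* BIC bookkeeping for penalized smoothers (edf as parameter count, choice
  of n) is conventional, not canonical; both knobs are exposed.
* The univariate p < 0.2 screen is a heuristic and can drop true
  confounders with small marginal effects; `force_adjust` sidesteps it.
* Figures (spaghetti and fitted-curve plots) are best-effort output and
  excluded from correctness testing.
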