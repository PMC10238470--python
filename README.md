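# trajsmm

Latent-class trajectory analysis of longitudinal maternal weight with a
**smoothing mixture model** (SMM): a hard-assignment E–M algorithm whose
class means are penalized-spline smoothers, followed by logistic-regression
odds ratios of binary pregnancy outcomes across the identified classes.

## The problem

Pregnant women gain weight along broadly parallel but vertically separated
paths. Classifying women into latent *weight trajectory classes* (e.g. low /
medium / high) from nine monthly measurements, and then asking whether class
membership predicts adverse outcomes (icterus, preterm delivery, NICU
admission, preeclampsia, GDM, and composites), requires a clustering method
that (a) does not impose a parametric shape on the mean curve and (b) yields
a single class per subject. The SMM does both: each class mean *f_k(t)* is a
cubic P-spline, and subjects are assigned wholly to the class under which
their observed trajectory has the largest Gaussian log-likelihood.

## The method

For subject *i* with weights *y_it* and class *k* with smoother *f_k* and
residual variance *σ²_k*:

1. **Initialize**: rank subjects by mean observed weight; split into K
   contiguous near-equal groups.
2. **M step**: for each class, fit *f_k* by penalized least squares
   `(BᵀB + λP)β = Bᵀy` on the class's pooled observations — cubic B-splines,
   second-order difference penalty, λ chosen by GCV each pass.
3. **E step**: reassign each subject to `argmax_k Σ_t log N(y_it; f_k(t), σ²_k)`.
4. Iterate until memberships stop changing and the summed best
   log-likelihood is stable.

The class count is chosen over K = 2..5 by BIC
(`−2·LL + p·log n`, `p = Σ_k edf_k + K`) with a parsimony rule: the K at the
*elbow* of the BIC curve, where adding classes stops buying substantial fit.
Finally, crude and adjusted odds ratios per class contrast (medium as
reference) come from maximum-likelihood logistic regression with Wald 95%
intervals; covariates (maternal age, gestational age, gravidity) enter the
adjusted model when a univariate screen gives p < 0.2.

A seeded synthetic-cohort generator reproduces the assumed data structure —
three classes with median weights ≈ 63 / 71.5 / 79.5 kg in proportions
38/36/26%, a shared monotone gain curve plateauing after month 7 (total gain
8.9 kg), subject random intercepts, Gaussian noise, and outcomes linked to
class membership with configurable odds ratios — so the entire pipeline is
testable with known ground truth.

## Worked example

```python
from trajsmm import CohortConfig, generate_cohort, SmoothingMixtureModel, relabel
from trajsmm.synthetic_data import (generate_covariates, generate_outcomes,
                                    default_outcome_config)
from trajsmm.association import run_association

long, labels = generate_cohort(CohortConfig(n_subjects=877, seed=42))
sel = SmoothingMixtureModel(long).select((2, 3, 4, 5))
fit = relabel(sel.selected)
print(fit.summary())
```

```
Smoothing Mixture Model Results
=============================================
classes:            3
subjects:           877
observations:       7893
total log-lik:      -17394.975
BIC:                34945.080
iterations:         7 (converged)

class  label    n    median (IQR)   edf   lambda    sigma2
--------------------------------------------------------------
    1  low      336    63.0 (2.7)   5.15     0.398    5.0637
    2  medium   311    71.6 (2.5)   4.64         1    4.0399
    3  high     230    79.4 (2.7)   4.50         1    5.6695
```

Three classes are selected at the BIC elbow; class medians and sizes match
the generating configuration (63 / 71.5 / 79.5 kg at 38/36/26%). Odds
ratios then quantify outcome risk per contrast:

```python
cov = generate_covariates(877, seed=43)
outcomes = generate_outcomes(labels, cov, default_outcome_config(seed=44))
ors = run_association(fit, outcomes)
print(ors[ors.outcome == "composite_neonatal"].round(3).to_string(index=False))
```

```
           outcome       contrast  n_events  crude_or  crude_lo  crude_hi  p_crude
composite_neonatal  low vs medium       471     1.935     1.415     2.647    0.000
composite_neonatal high vs medium       471     1.454     1.033     2.048    0.032
```

The low-vs-medium crude OR of 1.94 (95% CI 1.42–2.65) recovers the
generator's configured excess risk for the composite's components; the
high-vs-medium contrast shows the weaker configured effect.

The same analysis runs from the shell:

```bash
trajsmm run --seed 1 --out run_dir     # simulate + classify + associate + report
trajsmm fit --data long.csv --k-range 2:5 --out fit_dir
```

## Layout

- `trajsmm.synthetic_data` — seeded cohort, covariate and outcome generators
- `trajsmm.pspline` — P-spline basis, penalized fit, GCV, subject log-likelihood
- `trajsmm.smm` — `SmoothingMixtureModel` / `SMMResults`, E–M loop, BIC
  selection, relabeling, concordance cross-tab
- `trajsmm.association` — logistic fits, odds ratios, confounder screen
- `trajsmm.pipeline` — I/O validation, descriptives, end-to-end runner, report
- `docs/methods.md` — modelling assumptions, defaults and limitations
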