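"""Synthetic longitudinal cohorts with latent weight-trajectory classes.

Emulates the structure of a pregnancy cohort with nine monthly maternal
weight measurements: K latent classes differing by a baseline offset, a
shared monotone gain curve that plateaus after month 7, a subject-level
random intercept, and Gaussian measurement noise. Binary pregnancy outcomes
(icterus, abnormality, NICU admission, preterm delivery, preeclampsia,
gestational diabetes, and the two composites) are linked to class
membership through configurable log-odds, so that estimator round-trip
tests have known ground truth.

Defaults mirror a cohort of 877 women with class proportions 38/36/26%,
class median weights of about 63 / 71.5 / 79.5 kg, and a mean gain of
8.9 kg over the nine months.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .errors import DataValidationError, DomainError

__all__ = [
    "CohortConfig",
    "OutcomeConfig",
    "DEFAULT_GAIN_CURVE",
    "DEFAULT_CLASS_MEDIANS",
    "allocate_classes",
    "class_mean_curve",
    "generate_cohort",
    "generate_covariates",
    "generate_outcomes",
    "default_outcome_config",
]

#: Mean gain (kg) over the month-1 mean at months 1..9. Monotone, plateaus
#: after month 7 (gain slows from 1.6 kg/month early to 0.1 kg/month late).
DEFAULT_GAIN_CURVE = (0.0, 1.6, 3.1, 4.7, 6.3, 7.9, 8.7, 8.8, 8.9)

#: Target class medians (kg) of subject mean weight, per class count.
DEFAULT_CLASS_MEDIANS = {
    2: (65.0, 77.0),
    3: (63.0, 71.5, 79.5),
    4: (62.0, 68.5, 76.0, 84.5),
    5: (60.0, 65.0, 70.0, 76.5, 84.5),
}

_DEFAULT_PROPORTIONS = {3: (0.38, 0.36, 0.26)}


def _baselines_for(n_classes: int, gain_curve) -> tuple[float, ...]:
    """Class baselines such that the subject-mean weight medians land on
    the canonical per-K medians (baseline + mean gain = median)."""
    medians = DEFAULT_CLASS_MEDIANS[n_classes]
    mean_gain = float(np.mean(gain_curve))
    return tuple(m - mean_gain for m in medians)


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings for a synthetic longitudinal weight cohort.

    ``gain_curve`` may be one row (shared across classes, the default:
    parallel curves) or ``n_classes`` rows for class-specific gain shapes.
    Class sizes are allocated deterministically by largest remainder so
    that recovery tests have exact ground truth; set ``multinomial=True``
    for random allocation.
    """

    n_subjects: int = 877
    n_classes: int = 3
    class_proportions: tuple[float, ...] | None = None
    class_baselines: tuple[float, ...] | None = None
    gain_curve: tuple = DEFAULT_GAIN_CURVE
    random_intercept_sd: float = 2.0
    residual_sd: float = 1.0
    months: tuple[int, ...] = tuple(range(1, 10))
    seed: int = 0
    monotone: bool = True
    multinomial: bool = False
    dropout_rate: float = 0.0

    def __post_init__(self):
        if self.n_subjects < self.n_classes:
            raise DomainError("n_subjects must be >= n_classes")
        if self.class_proportions is None:
            props = _DEFAULT_PROPORTIONS.get(
                self.n_classes, (1.0 / self.n_classes,) * self.n_classes
            )
            object.__setattr__(self, "class_proportions", tuple(props))
        if self.class_baselines is None:
            if self.n_classes not in DEFAULT_CLASS_MEDIANS:
                raise DomainError(
                    f"no default baselines for n_classes={self.n_classes}; "
                    "pass class_baselines explicitly"
                )
            object.__setattr__(
                self,
                "class_baselines",
                _baselines_for(self.n_classes, self._gain_row(0)),
            )
        props = np.asarray(self.class_proportions, dtype=float)
        if props.size != self.n_classes:
            raise DomainError("class_proportions length must equal n_classes")
        if np.any(props <= 0) or abs(props.sum() - 1.0) > 1e-9:
            raise DomainError("class_proportions must be positive and sum to 1")
        base = np.asarray(self.class_baselines, dtype=float)
        if base.size != self.n_classes:
            raise DomainError("class_baselines length must equal n_classes")
        if np.any(np.diff(base) <= 0):
            raise DomainError("class_baselines must be strictly increasing")
        gain = np.asarray(self.gain_curve, dtype=float)
        if gain.ndim == 1:
            rows = gain[None, :]
        elif gain.ndim == 2 and gain.shape[0] == self.n_classes:
            rows = gain
        else:
            raise DomainError(
                "gain_curve must have length n_months or shape "
                "(n_classes, n_months)"
            )
        if rows.shape[1] != len(self.months):
            raise DomainError("gain_curve length must match months")
        if self.monotone and np.any(np.diff(rows, axis=1) < 0):
            raise DomainError("gain_curve must be non-decreasing")
        if self.random_intercept_sd < 0 or self.residual_sd < 0:
            raise DomainError("standard deviations must be >= 0")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise DomainError("dropout_rate must be in [0, 1)")
        if len(set(self.months)) != len(self.months) or list(self.months) != sorted(
            self.months
        ):
            raise DomainError("months must be sorted and distinct")

    def _gain_row(self, k0: int) -> np.ndarray:
        gain = np.asarray(self.gain_curve, dtype=float)
        return gain if gain.ndim == 1 else gain[k0]


def class_mean_curve(k: int, t, cfg: CohortConfig):
    """Deterministic class mean weight at month(s) ``t`` for class ``k``
    (1-based): ``class_baselines[k] + gain_curve[t]``."""
    if not 1 <= k <= cfg.n_classes:
        raise DomainError(f"class index {k} outside 1..{cfg.n_classes}")
    t_arr = np.atleast_1d(t)
    month_index = {m: i for i, m in enumerate(cfg.months)}
    try:
        idx = [month_index[int(m)] for m in t_arr]
    except KeyError as exc:
        raise DomainError(f"month {exc.args[0]} not in cfg.months") from exc
    vals = cfg.class_baselines[k - 1] + cfg._gain_row(k - 1)[idx]
    return float(vals[0]) if np.isscalar(t) else vals


def allocate_classes(n: int, proportions) -> np.ndarray:
    """Exact class counts by largest remainder; ties go to the lower class."""
    props = np.asarray(proportions, dtype=float)
    exact = n * props
    counts = np.floor(exact).astype(int)
    short = n - counts.sum()
    if short > 0:
        # stable sort descending on fractional part -> ties favour low index
        frac = exact - counts
        order = np.argsort(-frac, kind="stable")
        counts[order[:short]] += 1
    return counts


def generate_cohort(cfg: CohortConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a long-format cohort and its ground-truth class labels.

    Returns
    -------
    long : DataFrame
        Columns ``subject_id, month, weight_kg`` (tidy, one row per
        observation; rows may be missing under MCAR dropout).
    labels : Series
        Ground-truth class index (1..K) indexed by subject_id.
    """
    rng = np.random.default_rng(cfg.seed)
    n, K = cfg.n_subjects, cfg.n_classes
    months = np.asarray(cfg.months)
    T = months.size

    if cfg.multinomial:
        labels = rng.choice(np.arange(1, K + 1), size=n, p=cfg.class_proportions)
    else:
        counts = allocate_classes(n, cfg.class_proportions)
        labels = np.repeat(np.arange(1, K + 1), counts)
        labels = rng.permutation(labels)

    curves = np.vstack(
        [np.asarray(cfg.class_baselines)[k] + cfg._gain_row(k) for k in range(K)]
    )  # K x T
    b = rng.normal(0.0, cfg.random_intercept_sd, size=n)
    eps = rng.normal(0.0, cfg.residual_sd, size=(n, T))
    W = curves[labels - 1] + b[:, None] + eps  # n x T

    subject_ids = np.arange(1, n + 1)
    long = pd.DataFrame(
        {
            "subject_id": np.repeat(subject_ids, T),
            "month": np.tile(months, n),
            "weight_kg": W.ravel(),
        }
    )
    if cfg.dropout_rate > 0:
        keep = rng.random(n * T) >= cfg.dropout_rate
        keep = keep.reshape(n, T)
        lost = ~keep.any(axis=1)
        if lost.any():  # every subject retains at least one observation
            keep[lost, rng.integers(0, T, size=int(lost.sum()))] = True
        long = long[keep.ravel()].reset_index(drop=True)
    label_series = pd.Series(labels, index=pd.Index(subject_ids, name="subject_id"),
                             name="true_class")
    return long, label_series


def generate_covariates(n: int, seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Maternal covariates: age ~ N(29, 5) truncated to 18-40 years,
    gestational age ~ N(38, 1) weeks, gravidity ~ 1 + Poisson(1)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a, b = (18 - 29) / 5, (40 - 29) / 5
    age = truncnorm.rvs(a, b, loc=29, scale=5, size=n, random_state=rng)
    gest = rng.normal(38.0, 1.0, size=n)
    gravidity = 1 + rng.poisson(1.0, size=n)
    return pd.DataFrame(
        {
            "age": age,
            "gestational_age": gest,
            "gravidity": gravidity.astype(float),
        },
        index=pd.Index(np.arange(1, n + 1), name="subject_id"),
    )


@dataclass(frozen=True)
class OutcomeConfig:
    """Settings linking binary outcomes to latent class membership.

    ``class_log_odds[outcome]`` is a length-K vector of additive log-odds
    relative to the reference class (whose entry must be 0); the baseline
    prevalence applies to the reference class at the covariate centers.
    Composite outcomes are the logical OR of their components.
    """

    outcome_names: tuple[str, ...]
    baseline_prevalence: dict
    class_log_odds: dict
    covariate_effects: dict = field(default_factory=dict)
    covariate_centers: dict = field(
        default_factory=lambda: {"age": 29.0, "gestational_age": 38.0, "gravidity": 2.0}
    )
    composites: dict = field(default_factory=dict)
    reference_class: int = 2
    seed: int = 0

    def __post_init__(self):
        for name in self.outcome_names:
            p = self.baseline_prevalence.get(name)
            if p is None or not 0.0 < p < 1.0:
                raise DomainError(
                    f"baseline_prevalence[{name!r}] must be in (0, 1)"
                )
            lo = np.asarray(self.class_log_odds.get(name, ()), dtype=float)
            if lo.size == 0:
                raise DomainError(f"class_log_odds missing for {name!r}")
            ref = lo[self.reference_class - 1]
            if abs(ref) > 1e-12:
                raise DomainError(
                    f"reference class log-odds must be 0 for {name!r}, got {ref}"
                )
        for comp, members in self.composites.items():
            unknown = set(members) - set(self.outcome_names)
            if unknown:
                raise DomainError(f"composite {comp!r} references unknown {unknown}")


def default_outcome_config(seed: int = 0) -> OutcomeConfig:
    """Defaults for a three-class cohort: prevalences and class effects
    follow the canonical descriptive table (reference = medium class;
    class-1 and class-3 effects are the crude odds ratios vs medium)."""
    or_low = {  # class 1 (low) vs class 2 (medium)
        "icterus": 1.69,
        "abnormality": 1.50,
        "nicu_admission": 1.77,
        "preterm_delivery": 1.82,
        "preeclampsia": 0.93,
        "gdm": 0.96,
    }
    or_high = {  # class 3 (high) vs class 2 (medium)
        "icterus": 1.44,
        "abnormality": 2.56,
        "nicu_admission": 1.09,
        "preterm_delivery": 1.11,
        "preeclampsia": 1.19,
        "gdm": 1.21,
    }
    prevalence = {
        "icterus": 0.288,
        "abnormality": 0.033,
        "nicu_admission": 0.169,
        "preterm_delivery": 0.137,
        "preeclampsia": 0.157,
        "gdm": 0.061,
    }
    names = tuple(prevalence)
    class_log_odds = {
        name: (math.log(or_low[name]), 0.0, math.log(or_high[name]))
        for name in names
    }
    composites = {
        "composite_maternal": ("preterm_delivery", "preeclampsia", "gdm"),
        "composite_neonatal": ("icterus", "abnormality", "nicu_admission"),
    }
    return OutcomeConfig(
        outcome_names=names,
        baseline_prevalence=prevalence,
        class_log_odds=class_log_odds,
        composites=composites,
        reference_class=2,
        seed=seed,
    )


def generate_outcomes(
    labels: pd.Series,
    covariates: pd.DataFrame | None,
    ocfg: OutcomeConfig,
) -> pd.DataFrame:
    """Draw Bernoulli outcomes given class labels and covariates.

    Each outcome's linear predictor is
    ``logit(baseline_prevalence) + class_log_odds[class] + sum_j beta_j
    (x_j - center_j)``; composites are the OR of their drawn components.
    Returns a per-subject table with one 0/1 column per outcome plus the
    covariates.
    """
    rng = np.random.default_rng(ocfg.seed)
    labels = pd.Series(labels)
    n = labels.size
    k0 = labels.to_numpy().astype(int) - 1

    cov_terms = np.zeros(n)
    out = pd.DataFrame(index=labels.index)
    for name in ocfg.outcome_names:
        eta = logit(ocfg.baseline_prevalence[name])
        eta = eta + np.asarray(ocfg.class_log_odds[name], dtype=float)[k0]
        effects = ocfg.covariate_effects.get(name, {})
        if effects:
            if covariates is None:
                raise DataValidationError(
                    f"outcome {name!r} has covariate effects but no covariates given"
                )
            missing_subj = labels.index.difference(covariates.index)
            if len(missing_subj):
                raise DataValidationError(
                    f"covariates missing for subjects {list(missing_subj[:5])}"
                )
            cov = covariates.loc[labels.index]
            for cname, beta in effects.items():
                if cname not in cov.columns:
                    raise DataValidationError(f"covariate {cname!r} not found")
                center = ocfg.covariate_centers.get(cname, 0.0)
                eta = eta + beta * (cov[cname].to_numpy() - center)
        out[name] = (rng.random(n) < expit(eta)).astype(int)
    for comp, members in ocfg.composites.items():
        out[comp] = out[list(members)].max(axis=1)
    if covariates is not None:
        out = out.join(covariates)
    out.index.name = "subject_id"
    return out
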