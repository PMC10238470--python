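"""Odds ratios of binary pregnancy outcomes across trajectory classes.

For each outcome, two logistic models are fitted: a *crude* model with
trajectory-class dummies only (the medium class as reference) and an
*adjusted* model that additionally conditions on the covariates retained
by a univariate screen (candidate kept when its single-predictor Wald
p-value is strictly below 0.2). Estimates are reported as odds ratios with
95% Wald intervals, OR = exp(beta), CI = exp(beta +/- 1.96 SE).

Maximum likelihood is computed by iteratively reweighted least squares
(statsmodels GLM with a binomial family); complete separation is detected
and raised rather than silently regularised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .errors import DataValidationError, DomainError, SeparationError

__all__ = [
    "LogisticFit",
    "ORResult",
    "fit_logistic",
    "odds_ratios",
    "screen_confounders",
    "run_association",
]

DEFAULT_COVARIATES = ("age", "gestational_age", "gravidity")
SCREEN_THRESHOLD = 0.2
Z_95 = 1.96  # conventional normal quantile for 95% Wald intervals
_SEPARATION_COEF = 25.0  # |log-odds| beyond this is numerically degenerate


@dataclass
class LogisticFit:
    """Logistic regression ML fit: coefficients on the log-odds scale,
    their covariance (inverse observed information), and fit diagnostics."""

    params: pd.Series
    cov: pd.DataFrame
    converged: bool
    n: int
    deviance: float

    @property
    def exog_names(self) -> list[str]:
        return list(self.params.index)


@dataclass
class ORResult:
    """One odds-ratio contrast: estimate, 95% Wald CI, two-sided p-value."""

    outcome: str
    contrast: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    adjusted: bool
    covariates_included: tuple = ()
    n_events: int | None = None
    low_information: bool = False


def _as_design(design) -> pd.DataFrame:
    X = pd.DataFrame(design)
    if not X.columns.is_unique:
        raise DataValidationError("design matrix has duplicate column names")
    return X.astype(float)


def fit_logistic(design, y) -> LogisticFit:
    """Fit a logistic regression by IRLS.

    Parameters
    ----------
    design : DataFrame or 2-D array
        Predictor matrix including the intercept column.
    y : array-like of 0/1
        Binary outcomes.

    Raises
    ------
    SeparationError
        On complete/quasi-complete separation (detected either by
        statsmodels or by a diverging coefficient), naming the worst
        predictor.
    DataValidationError
        Constant outcome or more predictors than observations.
    """
    X = _as_design(design)
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise DataValidationError("y must be 1-D and align with the design rows")
    if not np.isin(y, (0.0, 1.0)).all():
        raise DataValidationError("y must be binary 0/1")
    if y.min() == y.max():
        raise DataValidationError("outcome is constant; logistic model undefined")
    if X.shape[0] <= X.shape[1]:
        raise DataValidationError(
            f"n={X.shape[0]} must exceed the {X.shape[1]} predictors"
        )

    glm = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = glm.fit(maxiter=50, tol=1e-8)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError(_worst_predictor(glm, X)) from exc
    params = pd.Series(res.params, index=X.columns)
    worst = params.drop(labels=["const", "intercept"], errors="ignore").abs()
    if len(worst) and worst.max() > _SEPARATION_COEF:
        raise SeparationError(str(worst.idxmax()))
    return LogisticFit(
        params=params,
        cov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        converged=bool(res.converged),
        n=int(X.shape[0]),
        deviance=float(res.deviance),
    )


def _worst_predictor(glm, X: pd.DataFrame) -> str:
    try:
        rough = glm.fit(maxiter=10)
        coefs = pd.Series(rough.params, index=X.columns).drop(
            labels=["const", "intercept"], errors="ignore"
        )
        return str(coefs.abs().idxmax())
    except Exception:
        return str(X.columns[-1])


def wald_interval(beta: float, se: float) -> tuple[float, float, float, float]:
    """(OR, low, high, p) from a log-odds estimate and its standard error."""
    with np.errstate(over="ignore"):  # huge SE -> CI bound overflows to inf
        or_ = float(np.exp(beta))
        lo = float(np.exp(beta - Z_95 * se))
        hi = float(np.exp(beta + Z_95 * se))
    p = float(2.0 * norm.sf(abs(beta) / se)) if se > 0 else 0.0
    return or_, lo, hi, p


def odds_ratios(
    fit: LogisticFit,
    contrasts,
    outcome: str = "",
    adjusted: bool = False,
    covariates_included=(),
) -> list[ORResult]:
    """Odds ratios for named coefficients of a fitted logistic model.

    ``contrasts`` maps coefficient name -> human-readable contrast string
    (or is an iterable of coefficient names).
    """
    if not isinstance(contrasts, dict):
        contrasts = {name: name for name in contrasts}
    results = []
    for name, label in contrasts.items():
        if name not in fit.params.index:
            raise DomainError(f"contrast {name!r} not in fitted coefficients")
        beta = float(fit.params[name])
        se = float(np.sqrt(fit.cov.loc[name, name]))
        or_, lo, hi, p = wald_interval(beta, se)
        results.append(
            ORResult(
                outcome=outcome,
                contrast=label,
                estimate=or_,
                ci_low=lo,
                ci_high=hi,
                p_value=p,
                adjusted=adjusted,
                covariates_included=tuple(covariates_included),
            )
        )
    return results


def screen_confounders(
    outcomes: pd.DataFrame,
    outcome_names,
    candidates=DEFAULT_COVARIATES,
    threshold: float = SCREEN_THRESHOLD,
) -> dict:
    """Univariate confounder screen.

    Each candidate is fitted alone (with intercept) against each outcome;
    it is retained iff its Wald p-value is strictly below ``threshold``.
    Fit failures (e.g. separation) exclude the candidate for that outcome
    and are recorded under the ``"__failures__"`` key.
    """
    missing = [c for c in candidates if c not in outcomes.columns]
    if missing:
        raise DataValidationError(f"candidates not in table: {missing}")
    selected: dict = {}
    failures: dict = {}
    for out in outcome_names:
        keep = []
        for cand in candidates:
            X = pd.DataFrame(
                {"const": 1.0, cand: outcomes[cand].to_numpy(dtype=float)}
            )
            try:
                fit = fit_logistic(X, outcomes[out].to_numpy())
            except (SeparationError, DataValidationError) as exc:
                failures.setdefault(out, {})[cand] = str(exc)
                continue
            beta = float(fit.params[cand])
            se = float(np.sqrt(fit.cov.loc[cand, cand]))
            _, _, _, p = wald_interval(beta, se)
            if p < threshold:  # strict: p == threshold is excluded
                keep.append(cand)
        selected[out] = keep
    if failures:
        selected["__failures__"] = failures
    return selected


def _class_dummies(
    assignments: pd.Series, reference: int, labels: dict | None = None
) -> tuple[pd.DataFrame, dict]:
    """Dummy-code classes vs the reference; returns (dummies, contrast map)."""
    classes = sorted(int(c) for c in pd.unique(assignments))
    if reference not in classes:
        raise DomainError(f"reference class {reference} not present in assignments")

    def name_of(k: int) -> str:
        return labels.get(k, f"class_{k}") if labels else f"class_{k}"

    cols = {}
    contrasts = {}
    for k in classes:
        if k == reference:
            continue
        col = f"traj_{name_of(k)}"
        cols[col] = (assignments == k).astype(float).to_numpy()
        contrasts[col] = f"{name_of(k)} vs {name_of(reference)}"
    return pd.DataFrame(cols, index=assignments.index), contrasts


def run_association(
    assignments,
    outcomes: pd.DataFrame,
    outcome_names=None,
    covariates=DEFAULT_COVARIATES,
    reference: int | None = None,
    class_labels: dict | None = None,
    force_adjust: bool = False,
    screen_threshold: float = SCREEN_THRESHOLD,
) -> pd.DataFrame:
    """Crude and adjusted odds ratios of every outcome per class contrast.

    Parameters
    ----------
    assignments : Series (subject_id -> class index) or SMMResults
        A relabeled three-class fit uses medium (class 2) as reference;
        otherwise the middle class index is used unless ``reference`` is
        given.
    outcomes : DataFrame
        Per-subject binary outcome columns plus covariates, indexed by
        subject_id.
    force_adjust : bool
        Adjust for all candidate covariates regardless of the screen.

    Returns
    -------
    DataFrame with one row per (outcome, contrast): crude and adjusted
    OR, 95% CI bounds, p-values and the covariates actually included.
    """
    if hasattr(assignments, "assignment"):  # SMMResults
        res = assignments
        labels = (
            {k + 1: lab for k, lab in enumerate(res.class_labels)}
            if res.class_labels
            else None
        )
        assignments = res.assignment
        if class_labels is None:
            class_labels = labels
    assignments = pd.Series(assignments)
    common = assignments.index.intersection(outcomes.index)
    if len(common) < len(assignments):
        raise DataValidationError(
            "outcomes table does not cover every assigned subject"
        )
    outcomes = outcomes.loc[assignments.index]

    if reference is None:
        classes = sorted(int(c) for c in pd.unique(assignments))
        if class_labels and "medium" in class_labels.values():
            reference = next(k for k, v in class_labels.items() if v == "medium")
        else:
            reference = classes[(len(classes) - 1) // 2]  # middle curve rank

    if outcome_names is None:
        candidate_cov = set(covariates)
        outcome_names = [
            c
            for c in outcomes.columns
            if c not in candidate_cov
            and set(pd.unique(outcomes[c].dropna())) <= {0, 1}
        ]

    dummies, contrasts = _class_dummies(assignments, reference, class_labels)
    screen = screen_confounders(outcomes, outcome_names, covariates, screen_threshold)

    rows = []
    for out in outcome_names:
        y = outcomes[out].to_numpy(dtype=float)
        n_events = int(y.sum())
        low_info = n_events < 5
        X_crude = pd.concat(
            [pd.Series(1.0, index=assignments.index, name="const"), dummies], axis=1
        )
        crude_fit = fit_logistic(X_crude, y)
        crude = odds_ratios(crude_fit, contrasts, outcome=out, adjusted=False)

        adj_covs = tuple(covariates) if force_adjust else tuple(screen.get(out, ()))
        if adj_covs:
            X_adj = pd.concat([X_crude, outcomes[list(adj_covs)].astype(float)], axis=1)
            adj_fit = fit_logistic(X_adj, y)
        else:
            adj_fit = crude_fit  # identical design -> crude equals adjusted
        adjusted = odds_ratios(
            adj_fit, contrasts, outcome=out, adjusted=True,
            covariates_included=adj_covs,
        )
        for cr, ad in zip(crude, adjusted):
            rows.append(
                {
                    "outcome": out,
                    "contrast": cr.contrast,
                    "n_events": n_events,
                    "low_information": low_info,
                    "crude_or": cr.estimate,
                    "crude_lo": cr.ci_low,
                    "crude_hi": cr.ci_high,
                    "p_crude": cr.p_value,
                    "adj_or": ad.estimate,
                    "adj_lo": ad.ci_low,
                    "adj_hi": ad.ci_high,
                    "p_adj": ad.p_value,
                    "covariates": ",".join(adj_covs),
                }
            )
    return pd.DataFrame(rows)
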