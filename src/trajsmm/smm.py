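"""Smoothing mixture model: hard-assignment E-M over P-spline smoothers.

The model classifies subjects with longitudinal weight measurements into K
latent trajectory classes. Each class has its own penalized-spline mean
curve and residual variance. The algorithm:

1. **Initialize** — rank subjects by their mean observed weight and split
   into K contiguous, near-equal groups.
2. **M step** — fit one P-spline per class on that class's pooled
   (month, weight) observations, reselecting the smoothing parameter by
   GCV each pass.
3. **E step** — reassign every subject to the class whose fitted curve
   gives it the largest Gaussian log-likelihood (ties to the lowest class
   index).
4. Iterate until memberships stop changing and the summed best
   log-likelihood is stable.

Model selection across candidate K uses BIC = -2 LL + p log(n_obs) with
p = sum of class effective degrees of freedom + K residual variances.
Because hard assignment keeps gaining likelihood from splitting classes,
raw BIC tends to favour ever more classes; the default selection therefore
applies a parsimony rule on top of BIC: pick the class count at the elbow
of the BIC curve (its largest second difference), where adding further
classes stops buying substantial fit. A simpler "within a margin of the
BIC minimum" rule is available as an option.

The public surface follows the Model/Results convention: build a
:class:`SmoothingMixtureModel` from a tidy DataFrame, call ``fit`` or
``select``, and read estimates off the returned results object.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pspline
from .errors import ConvergenceError, DataValidationError, DegenerateClassError, DomainError
from .pspline import ClassModel, SplineBasis

__all__ = [
    "SmoothingMixtureModel",
    "SMMResults",
    "SelectionResult",
    "initialize",
    "m_step",
    "e_step",
    "fit_smm",
    "compute_bic",
    "select_K",
    "relabel",
    "crosstab",
]

THREE_CLASS_LABELS = ("low", "medium", "high")


def _to_wide(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(subject_ids, months, n x T weight matrix with NaN for missing)."""
    required = {"subject_id", "month", "weight_kg"}
    missing = required - set(data.columns)
    if missing:
        raise DataValidationError(f"long data missing columns {sorted(missing)}")
    if data.duplicated(["subject_id", "month"]).any():
        raise DataValidationError("duplicate (subject_id, month) observations")
    wide = data.pivot(index="subject_id", columns="month", values="weight_kg")
    wide = wide.sort_index().sort_index(axis=1)
    return (
        wide.index.to_numpy(),
        wide.columns.to_numpy(dtype=float),
        wide.to_numpy(dtype=float),
    )


class SmoothingMixtureModel:
    """Latent-class trajectory model for tidy longitudinal data.

    Parameters
    ----------
    data : DataFrame
        Long format with columns ``subject_id, month, weight_kg``; may be
        unbalanced (missing months for some subjects), but every subject
        needs at least one observation.
    n_basis, degree, penalty_order : int
        P-spline settings for the per-class smoothers (defaults: 6 cubic
        B-splines, second-order difference penalty).
    lambda_grid : array-like, optional
        GCV grid for the smoothing parameter (default 1e-4..1e4, 41 points).
    random_intercept : bool
        When True, each class additionally carries a compound-symmetry
        within-subject covariance estimated by method of moments; the E
        step then scores subjects with the marginal multivariate normal.
    max_iter, tol : convergence controls
        Stop when memberships are unchanged AND the relative change in the
        summed best log-likelihood is below ``tol``; ``max_iter`` caps the
        E-M loop.
    reseed_empty : bool
        When a class empties, move the overall worst-fitting subject into
        it instead of aborting.
    bic_n : {"observations", "subjects"}
        Sample size used in the BIC penalty.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        *,
        n_basis: int = 6,
        degree: int = 3,
        penalty_order: int = 2,
        lambda_grid=None,
        random_intercept: bool = False,
        max_iter: int = 100,
        tol: float = 1e-6,
        reseed_empty: bool = False,
        bic_n: str = "observations",
    ):
        self.data = data
        self.subject_ids, self.months, self.W = _to_wide(data)
        if np.isnan(self.W).all(axis=1).any():
            raise DataValidationError("every subject needs >= 1 observation")
        if bic_n not in ("observations", "subjects"):
            raise DomainError("bic_n must be 'observations' or 'subjects'")
        self.basis = pspline.build_basis(
            self.months, n_basis=n_basis, degree=degree, penalty_order=penalty_order
        )
        self.lambda_grid = (
            pspline.DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid)
        )
        self.random_intercept = random_intercept
        self.max_iter = max_iter
        self.tol = tol
        self.reseed_empty = reseed_empty
        self.bic_n = bic_n
        self.n_subjects = self.W.shape[0]
        self.obs_mask = ~np.isnan(self.W)
        self.obs_per_subject = self.obs_mask.sum(axis=1)
        self.n_obs = int(self.obs_mask.sum())

    @classmethod
    def from_csv(cls, path, **kwargs) -> "SmoothingMixtureModel":
        from .pipeline import read_long_csv

        return cls(read_long_csv(path), **kwargs)

    # ------------------------------------------------------------------ #

    def _initialize(self, K: int) -> np.ndarray:
        if K < 1:
            raise DomainError("K must be >= 1")
        if K > self.n_subjects:
            raise DomainError(f"K={K} exceeds n_subjects={self.n_subjects}")
        means = np.nanmean(self.W, axis=1)
        order = np.argsort(means, kind="stable")  # ties break by subject order
        base, rem = divmod(self.n_subjects, K)
        sizes = [base + 1] * rem + [base] * (K - rem)  # larger groups first
        assign = np.empty(self.n_subjects, dtype=int)
        start = 0
        for k, size in enumerate(sizes, start=1):
            assign[order[start : start + size]] = k
            start += size
        return assign

    def _fit_class(self, member_mask: np.ndarray) -> ClassModel:
        sub = self.W[member_mask]
        mask = self.obs_mask[member_mask]
        rows, cols = np.nonzero(mask)
        months_obs = self.months[cols]
        y = sub[rows, cols]
        lam = pspline.select_lambda(y, self.basis, self.lambda_grid, months=months_obs)
        model = pspline.fit_pspline(y, self.basis, lam, months=months_obs)
        if self.random_intercept:
            resid = y - model.predict(months_obs)
            sb2, s2 = pspline.estimate_variance_components(resid, rows)
            model.sigma_b2 = sb2
            model.sigma2 = s2
        return model

    def _m_step(self, assignment: np.ndarray, K: int, iteration: int | None = None) -> list[ClassModel]:
        models = []
        for k in range(1, K + 1):
            mask = assignment == k
            if not mask.any():
                raise DegenerateClassError(k, iteration)
            models.append(self._fit_class(mask))
        return models

    def _loglik_matrix(self, models: list[ClassModel]) -> np.ndarray:
        """K x n_subjects matrix of per-subject log-likelihoods."""
        K = len(models)
        out = np.empty((K, self.n_subjects))
        m_i = self.obs_per_subject
        for k, model in enumerate(models):
            mu = model.predict(self.months)
            R = self.W - mu  # NaN where unobserved
            sse = np.nansum(R**2, axis=1)
            s2 = model.sigma2
            if model.sigma_b2 is None:
                out[k] = -0.5 * m_i * np.log(2 * np.pi * s2) - sse / (2 * s2)
            else:
                sb2 = model.sigma_b2
                ssum = np.nansum(R, axis=1)
                tau = s2 + m_i * sb2
                logdet = (m_i - 1) * np.log(s2) + np.log(tau)
                quad = sse / s2 - sb2 * ssum**2 / (s2 * tau)
                out[k] = -0.5 * (m_i * np.log(2 * np.pi) + logdet + quad)
        return out

    def _e_step(self, models: list[ClassModel]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ll = self._loglik_matrix(models)
        assign = np.argmax(ll, axis=0) + 1  # argmax -> first max -> lowest index
        per_ll = ll[assign - 1, np.arange(self.n_subjects)]
        return assign, per_ll, ll

    # ------------------------------------------------------------------ #

    def fit(self, n_classes: int) -> "SMMResults":
        """Run the hard-assignment E-M loop for a fixed class count."""
        K = int(n_classes)
        assign = self._initialize(K)
        initial_assign = assign.copy()
        prev_total: float | None = None
        per_ll = None
        trace_rows = []
        converged = False
        models: list[ClassModel] = []
        n_iter = 0

        for it in range(1, self.max_iter + 1):
            n_iter = it
            for k in range(1, K + 1):
                if not np.any(assign == k):
                    if self.reseed_empty and per_ll is not None:
                        worst = int(np.argmin(per_ll))
                        assign[worst] = k
                    else:
                        raise DegenerateClassError(k, it)
            models = self._m_step(assign, K, iteration=it)
            new_assign, per_ll, ll = self._e_step(models)
            total = float(per_ll.sum())
            # For the SAME models, reassignment picks each subject's max,
            # so it can never lose likelihood; enforced on every iteration.
            old_total = float(ll[assign - 1, np.arange(self.n_subjects)].sum())
            if total < old_total - 1e-8 * (1.0 + abs(total)):
                raise RuntimeError(
                    "E step decreased the classification log-likelihood "
                    f"({old_total} -> {total}); this should be impossible"
                )
            n_changed = int(np.sum(new_assign != assign))
            trace_rows.append(
                {
                    "iteration": it,
                    "total_ll": total,
                    "total_ll_previous_assignment": old_total,
                    "n_changed": n_changed,
                }
            )
            ll_stable = prev_total is not None and abs(total - prev_total) <= self.tol * max(
                1.0, abs(prev_total)
            )
            if n_changed == 0 and (prev_total is None or ll_stable):
                # memberships fixed; with a deterministic M step the refit
                # would reproduce these models, so LL is stable too
                converged = True
                break
            assign = new_assign
            prev_total = total

        total_ll = float(per_ll.sum())
        bic = compute_bic_from_parts(total_ll, models, K, self._bic_sample_size())
        return SMMResults(
            model=self,
            n_classes=K,
            class_models=models,
            assignment=pd.Series(
                assign, index=pd.Index(self.subject_ids, name="subject_id"),
                name="class_index",
            ),
            initial_assignment=pd.Series(
                initial_assign, index=pd.Index(self.subject_ids, name="subject_id"),
                name="class_index",
            ),
            per_subject_ll=pd.Series(
                per_ll, index=pd.Index(self.subject_ids, name="subject_id"),
                name="loglik",
            ),
            total_ll=total_ll,
            bic=bic,
            n_iterations=n_iter,
            converged=converged,
            trace=pd.DataFrame(trace_rows),
        )

    def _bic_sample_size(self) -> int:
        return self.n_obs if self.bic_n == "observations" else self.n_subjects

    def select(
        self,
        k_range=(2, 3, 4, 5),
        parsimony: str = "elbow",
        bic_margin: float = 0.01,
    ) -> "SelectionResult":
        """Fit every candidate K, tabulate BIC/LL, and pick the class count.

        ``parsimony`` controls the rule applied on top of BIC:

        * ``"elbow"`` (default): the candidate at the kink of the BIC
          curve — the interior K maximising the second difference
          ``BIC(K-1) - 2 BIC(K) + BIC(K+1)``, i.e. where the per-class BIC
          improvement drops off hardest. Falls back to the BIC minimum
          when the minimum sits at the smallest candidate, only two
          candidates succeed, or no kink exists (improvements keep
          growing).
        * ``"margin"``: the smallest K whose BIC is within ``bic_margin``
          (a fraction of |min BIC|) of the minimum.
        * ``"none"``: the BIC minimum.

        Candidates that abort with an empty class are recorded as failed
        rows in the table, not raised.
        """
        k_range = sorted(int(k) for k in k_range)
        if not k_range:
            raise DomainError("k_range must be non-empty")
        rows = []
        fits: dict[int, SMMResults] = {}
        for K in k_range:
            try:
                res = self.fit(K)
            except DegenerateClassError as exc:
                rows.append(
                    {
                        "n_classes": K,
                        "bic": np.nan,
                        "total_ll": np.nan,
                        "converged": False,
                        "n_iterations": np.nan,
                        "class_medians": None,
                        "error": str(exc),
                    }
                )
                continue
            fits[K] = res
            med = res.class_median_table()
            med_str = "; ".join(
                f"{m:.1f} ({iqr:.1f})" for m, iqr in zip(med["median"], med["iqr"])
            )
            rows.append(
                {
                    "n_classes": K,
                    "bic": res.bic,
                    "total_ll": res.total_ll,
                    "converged": res.converged,
                    "n_iterations": res.n_iterations,
                    "class_medians": med_str,
                    "error": None,
                }
            )
        table = pd.DataFrame(rows)
        if not fits:
            raise ConvergenceError("every candidate class count failed")
        ok = table[table["error"].isna()]
        min_bic = float(ok["bic"].min())
        best_k_bic = int(ok.loc[ok["bic"].idxmin(), "n_classes"])
        selected_k, note = _apply_parsimony(
            ok["n_classes"].to_numpy(int),
            ok["bic"].to_numpy(float),
            parsimony,
            bic_margin,
        )
        return SelectionResult(
            table=table,
            fits=fits,
            best_k_bic=best_k_bic,
            selected_k=selected_k,
            selected=fits[selected_k],
            parsimony_note=note,
        )


def _apply_parsimony(ks: np.ndarray, bics: np.ndarray, rule: str, margin: float):
    """Pick a class count from (K, BIC) pairs; returns (K, note or None)."""
    order = np.argsort(ks)
    ks, bics = ks[order], bics[order]
    best_k = int(ks[np.argmin(bics)])
    if rule == "none" or len(ks) == 1:
        return best_k, None
    if rule == "margin":
        cutoff = bics.min() + margin * abs(bics.min())
        k = int(ks[np.nonzero(bics <= cutoff)[0][0]])
        note = None
        if k != best_k:
            note = (
                f"K={k} chosen on parsimony: its BIC is within "
                f"{100 * margin:.1f}% of the minimum at K={best_k}"
            )
        return k, note
    if rule != "elbow":
        raise DomainError(f"unknown parsimony rule {rule!r}")
    if best_k == ks[0] or len(ks) == 2:
        return best_k, None
    second_diff = bics[:-2] - 2 * bics[1:-1] + bics[2:]  # at interior candidates
    if np.all(second_diff <= 0):  # no kink: improvements keep accelerating
        return best_k, None
    k = int(ks[1:-1][int(np.argmax(second_diff))])
    note = None
    if k != best_k:
        note = (
            f"K={k} chosen at the BIC elbow: gains beyond {k} classes "
            f"drop off, although the BIC minimum sits at K={best_k}"
        )
    return k, note


@dataclass
class SMMResults:
    """A fitted K-class smoothing mixture model.

    Carries the per-class smoothers, the hard assignment, per-subject best
    log-likelihoods, the total LL and BIC, and the iteration trace
    (total LL and number of membership changes per iteration).
    """

    model: SmoothingMixtureModel
    n_classes: int
    class_models: list[ClassModel]
    assignment: pd.Series
    initial_assignment: pd.Series
    per_subject_ll: pd.Series
    total_ll: float
    bic: float
    n_iterations: int
    converged: bool
    trace: pd.DataFrame
    class_labels: tuple | None = None

    # -- derived views -------------------------------------------------- #

    def class_sizes(self) -> pd.Series:
        return self.assignment.value_counts().reindex(
            range(1, self.n_classes + 1), fill_value=0
        )

    def subject_mean_weights(self) -> pd.Series:
        w = np.nanmean(self.model.W, axis=1)
        return pd.Series(w, index=self.assignment.index, name="mean_weight")

    def class_median_table(self) -> pd.DataFrame:
        """Median (and IQR) of subject mean observed weight per class."""
        means = self.subject_mean_weights()
        rows = []
        for k in range(1, self.n_classes + 1):
            vals = means[self.assignment == k]
            if len(vals) == 0:
                rows.append({"class_index": k, "n": 0, "median": np.nan, "iqr": np.nan})
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append(
                {"class_index": k, "n": len(vals), "median": med, "iqr": q3 - q1}
            )
        return pd.DataFrame(rows)

    def predicted_curves(self) -> pd.DataFrame:
        """Fitted class mean curves at the observed months (wide, one
        column per class)."""
        cols = {}
        for k, m in enumerate(self.class_models, start=1):
            name = (
                self.class_labels[k - 1]
                if self.class_labels is not None
                else f"class_{k}"
            )
            cols[name] = m.fitted_curve
        return pd.DataFrame(cols, index=pd.Index(self.model.months, name="month"))

    def assignment_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "class_index": self.assignment,
                "loglik": self.per_subject_ll,
            }
        )
        if self.class_labels is not None:
            df.insert(
                1,
                "class_label",
                [self.class_labels[k - 1] for k in self.assignment],
            )
        return df

    # -- transforms ----------------------------------------------------- #

    def relabel(self) -> "SMMResults":
        """Reindex classes in ascending order of fitted-curve mean.

        Likelihoods and BIC are untouched; only indices (and, for K=3, the
        low/medium/high labels) change.
        """
        order = np.argsort([float(np.mean(m.fitted_curve)) for m in self.class_models])
        perm = np.empty(self.n_classes, dtype=int)  # old (0-based) -> new (1-based)
        perm[order] = np.arange(1, self.n_classes + 1)
        new_models = [copy.copy(self.class_models[i]) for i in order]
        labels = THREE_CLASS_LABELS if self.n_classes == 3 else None
        if labels is not None:
            for lab, m in zip(labels, new_models):
                m.label = lab
        new_assign = self.assignment.map(lambda k: int(perm[k - 1]))
        new_initial = self.initial_assignment  # initial ranking is unrelated
        return SMMResults(
            model=self.model,
            n_classes=self.n_classes,
            class_models=new_models,
            assignment=new_assign.rename("class_index"),
            initial_assignment=new_initial,
            per_subject_ll=self.per_subject_ll,
            total_ll=self.total_ll,
            bic=self.bic,
            n_iterations=self.n_iterations,
            converged=self.converged,
            trace=self.trace,
            class_labels=labels,
        )

    # -- reporting ------------------------------------------------------ #

    def summary(self) -> str:
        lines = [
            "Smoothing Mixture Model Results",
            "=" * 45,
            f"classes:            {self.n_classes}",
            f"subjects:           {self.model.n_subjects}",
            f"observations:       {self.model.n_obs}",
            f"total log-lik:      {self.total_ll:.3f}",
            f"BIC:                {self.bic:.3f}",
            f"iterations:         {self.n_iterations} "
            f"({'converged' if self.converged else 'NOT converged'})",
            "",
            "class  label    n    median (IQR)   edf   lambda    sigma2",
            "-" * 62,
        ]
        med = self.class_median_table()
        for k, m in enumerate(self.class_models, start=1):
            lab = m.label or "-"
            row = med[med["class_index"] == k].iloc[0]
            lines.append(
                f"{k:>5}  {lab:<7}{int(row['n']):>5}  "
                f"{row['median']:>6.1f} ({row['iqr']:.1f})  "
                f"{m.edf:>5.2f}  {m.lambda_:>8.3g}  {m.sigma2:>8.4f}"
            )
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_classes": self.n_classes,
                "total_ll": self.total_ll,
                "bic": self.bic,
                "n_iterations": self.n_iterations,
                "converged": self.converged,
                "class_labels": list(self.class_labels) if self.class_labels else None,
                "class_models": [m.to_dict() for m in self.class_models],
                "class_sizes": self.class_sizes().tolist(),
            },
            indent=2,
        )


@dataclass
class SelectionResult:
    """Outcome of fitting a range of class counts and choosing one."""

    table: pd.DataFrame
    fits: dict
    best_k_bic: int
    selected_k: int
    selected: SMMResults
    parsimony_note: str | None = None


# ---------------------------------------------------------------------- #
# Functional surface (thin wrappers over the Model/Results objects)
# ---------------------------------------------------------------------- #


def initialize(data: pd.DataFrame, K: int, **kwargs) -> pd.Series:
    """Initial rank-based assignment: subjects ordered by mean observed
    weight, split into K contiguous near-equal groups (larger groups
    first; ties in the mean break by subject order)."""
    model = SmoothingMixtureModel(data, **kwargs)
    assign = model._initialize(K)
    return pd.Series(
        assign, index=pd.Index(model.subject_ids, name="subject_id"),
        name="class_index",
    )


def m_step(data: pd.DataFrame, assignment: pd.Series, **kwargs) -> list[ClassModel]:
    """Fit one P-spline per class on the class's pooled observations."""
    model = SmoothingMixtureModel(data, **kwargs)
    assign = pd.Series(assignment).reindex(model.subject_ids).to_numpy()
    if np.isnan(assign.astype(float)).any():
        raise DataValidationError("assignment does not cover every subject")
    return model._m_step(assign.astype(int), int(np.max(assign)))


def e_step(data: pd.DataFrame, models: list[ClassModel], **kwargs):
    """Reassign each subject to its best-likelihood class; returns the
    assignment Series and the achieved per-subject log-likelihoods."""
    model = SmoothingMixtureModel(data, **kwargs)
    assign, per_ll, _ = model._e_step(models)
    idx = pd.Index(model.subject_ids, name="subject_id")
    return (
        pd.Series(assign, index=idx, name="class_index"),
        pd.Series(per_ll, index=idx, name="loglik"),
    )


def fit_smm(data: pd.DataFrame, K: int, **kwargs) -> SMMResults:
    """Convenience one-shot: build the model and run the E-M fit."""
    return SmoothingMixtureModel(data, **kwargs).fit(K)


def compute_bic_from_parts(
    total_ll: float, models: list[ClassModel], K: int, n_obs: int
) -> float:
    if n_obs <= 0:
        raise DomainError("n_obs must be positive")
    p = sum(m.edf for m in models) + K  # smoother edf + one variance per class
    return float(-2.0 * total_ll + p * np.log(n_obs))


def compute_bic(fit: SMMResults, n_obs: int | None = None) -> float:
    """BIC = -2 LL + p log(n_obs), p = sum of class edf + K variances."""
    if n_obs is None:
        n_obs = fit.model._bic_sample_size()
    return compute_bic_from_parts(fit.total_ll, fit.class_models, fit.n_classes, n_obs)


def select_K(
    data: pd.DataFrame,
    K_range,
    parsimony: str = "elbow",
    bic_margin: float = 0.01,
    **kwargs,
) -> SelectionResult:
    """Fit every K in ``K_range`` and choose by BIC plus a parsimony rule."""
    return SmoothingMixtureModel(data, **kwargs).select(
        K_range, parsimony=parsimony, bic_margin=bic_margin
    )


def relabel(fit: SMMResults) -> SMMResults:
    """Reorder classes by ascending fitted-curve mean (low/medium/high
    labels when K=3); likelihood and BIC are invariant."""
    return fit.relabel()


def crosstab(initial: pd.Series, final: pd.Series) -> tuple[pd.DataFrame, float]:
    """K x K contingency table of two assignments over the same subjects,
    plus the concordance percentage (100 * diagonal sum / n)."""
    initial = pd.Series(initial)
    final = pd.Series(final)
    if not initial.index.sort_values().equals(final.index.sort_values()):
        raise DataValidationError("assignments cover different subject sets")
    final = final.reindex(initial.index)
    K = int(max(initial.max(), final.max()))
    classes = range(1, K + 1)
    table = pd.crosstab(initial, final).reindex(
        index=classes, columns=classes, fill_value=0
    )
    table.index.name = "initial"
    table.columns.name = "final"
    n = len(initial)
    concordance = 100.0 * float(np.trace(table.to_numpy())) / n
    return table, concordance
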