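"""Penalized B-spline (P-spline) smoothers for class-level trajectories.

Each latent class's mean weight curve f_k(t) is modelled as a cubic B-spline
on equally spaced knots with a difference penalty on adjacent coefficients
(the Eilers-Marx P-spline). Fitting minimises

    ||y - B beta||^2 + lambda * beta' D'D beta

which has the ridge-type closed form (B'B + lambda P) beta = B'y. The
smoothing parameter is chosen by generalized cross-validation (GCV). The
fitted :class:`ClassModel` also carries a residual variance so that each
subject's trajectory can be scored by a Gaussian log-likelihood — the
quantity the hard-assignment E step of the mixture model maximises.

Two residual models are supported:

* independent residuals (default): observations within a subject are
  treated as independent around the class curve, variance ``sigma2``;
* compound symmetry: a subject-level random intercept with variance
  ``sigma_b2`` induces covariance ``sigma_b2*J + sigma2*I`` within a
  subject; variance components are estimated by method of moments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .errors import DomainError, ExtrapolationError, RankDeficientError

__all__ = [
    "SplineBasis",
    "ClassModel",
    "build_basis",
    "fit_pspline",
    "select_lambda",
    "subject_loglik",
    "estimate_variance_components",
    "DEFAULT_LAMBDA_GRID",
]

#: default GCV grid: 41 log-spaced values covering 1e-4 .. 1e4
DEFAULT_LAMBDA_GRID = np.logspace(-4, 4, 41)

SIGMA2_FLOOR = 1e-6  # kg^2; guards the E step against zero-variance classes


@dataclass(frozen=True)
class SplineBasis:
    """B-spline design and difference penalty on a fixed month grid.

    Attributes
    ----------
    months : ndarray
        Canonical evaluation points (the observation months).
    knots : ndarray
        Full knot vector, equally spaced, extending ``degree`` segments
        beyond each boundary.
    degree : int
        Spline degree (3 = cubic).
    penalty_order : int
        Order of the difference penalty (2 penalises deviation from a
        straight line).
    design : ndarray
        ``len(months) x n_basis`` design matrix.
    penalty : ndarray
        ``n_basis x n_basis`` symmetric PSD penalty matrix ``D'D``.
    """

    months: np.ndarray
    knots: np.ndarray
    degree: int
    penalty_order: int
    design: np.ndarray
    penalty: np.ndarray

    @property
    def n_basis(self) -> int:
        return self.design.shape[1]

    @property
    def month_range(self) -> tuple[float, float]:
        return float(self.months[0]), float(self.months[-1])

    def design_at(self, x) -> np.ndarray:
        """Evaluate the basis at arbitrary points within the fitted range.

        Raises
        ------
        ExtrapolationError
            If any point lies outside ``[min(months), max(months)]``.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        lo, hi = self.month_range
        if np.any(x < lo) or np.any(x > hi):
            bad = x[(x < lo) | (x > hi)]
            raise ExtrapolationError(
                f"months {bad.tolist()} outside fitted range [{lo}, {hi}]; "
                "extrapolation is not supported"
            )
        return BSpline.design_matrix(
            x, self.knots, self.degree, extrapolate=False
        ).toarray()


@dataclass
class ClassModel:
    """One class's fitted smoother plus residual variance.

    ``sigma_b2 is None`` means the independent-residual model; otherwise
    ``sigma2`` is the within-subject variance and ``sigma_b2`` the random
    intercept variance of a compound-symmetry covariance.
    """

    coefficients: np.ndarray
    lambda_: float
    edf: float
    sigma2: float
    fitted_curve: np.ndarray
    n_obs: int
    basis: SplineBasis
    sigma_b2: float | None = None
    label: str | None = None

    def predict(self, months) -> np.ndarray:
        """Class mean curve at the given months (no extrapolation)."""
        return self.basis.design_at(months) @ self.coefficients

    def to_dict(self) -> dict:
        """JSON-serializable summary of the fitted smoother."""
        return {
            "coefficients": self.coefficients.tolist(),
            "lambda": float(self.lambda_),
            "edf": float(self.edf),
            "sigma2": float(self.sigma2),
            "sigma_b2": None if self.sigma_b2 is None else float(self.sigma_b2),
            "knots": self.basis.knots.tolist(),
            "degree": int(self.basis.degree),
            "penalty_order": int(self.basis.penalty_order),
            "months": self.basis.months.tolist(),
            "fitted_curve": self.fitted_curve.tolist(),
            "n_obs": int(self.n_obs),
            "label": self.label,
        }


def build_basis(
    months,
    n_basis: int = 6,
    degree: int = 3,
    penalty_order: int = 2,
) -> SplineBasis:
    """Construct a B-spline basis with equally spaced knots and a
    difference penalty.

    Knots are placed Eilers-Marx style: ``n_basis - degree`` equal segments
    spanning ``[min(months), max(months)]``, extended ``degree`` segments
    past each boundary. Rows of the design matrix sum to one on the
    interior (partition of unity), and the order-2 penalty annihilates
    constant and linear coefficient vectors.
    """
    months = np.asarray(months, dtype=float)
    if months.ndim != 1 or months.size < 2:
        raise DomainError("months must be a 1-D array with at least 2 points")
    if np.any(np.diff(months) < 0):
        raise DomainError("months must be sorted ascending")
    distinct = np.unique(months)
    if distinct.size < 2:
        raise DomainError("need at least 2 distinct months")
    if n_basis < degree + 1:
        raise DomainError(f"n_basis must be >= degree + 1 = {degree + 1}")
    if n_basis > distinct.size + degree:
        raise DomainError(
            f"n_basis={n_basis} exceeds the identifiable maximum "
            f"{distinct.size + degree} for {distinct.size} distinct months"
        )
    if not 0 <= penalty_order < n_basis:
        raise DomainError("penalty_order must be in [0, n_basis)")

    a, b = float(months[0]), float(months[-1])
    n_seg = n_basis - degree
    dx = (b - a) / n_seg
    knots = a + dx * np.arange(-degree, n_seg + degree + 1)

    design = BSpline.design_matrix(
        months, knots, degree, extrapolate=False
    ).toarray()
    diff = np.diff(np.eye(n_basis), n=penalty_order, axis=0)
    penalty = diff.T @ diff
    return SplineBasis(
        months=months,
        knots=knots,
        degree=degree,
        penalty_order=penalty_order,
        design=design,
        penalty=penalty,
    )


def _design_for(basis: SplineBasis, months) -> np.ndarray:
    return basis.design if months is None else basis.design_at(months)


def fit_pspline(
    y,
    basis: SplineBasis,
    lambda_: float,
    months=None,
) -> ClassModel:
    """Fit a penalized spline with fixed smoothing parameter.

    Parameters
    ----------
    y : array-like
        Responses, aligned with ``basis.design`` rows, or with ``months``
        when given.
    basis : SplineBasis
    lambda_ : float
        Non-negative smoothing parameter; 0 gives unpenalized least squares.
    months : array-like, optional
        Observation months when ``y`` does not align with the canonical
        grid (e.g. pooled class observations with repeats).
    """
    y = np.asarray(y, dtype=float)
    X = _design_for(basis, months)
    if y.shape[0] != X.shape[0]:
        raise DomainError(
            f"y has {y.shape[0]} rows but the design has {X.shape[0]}"
        )
    if not np.isfinite(lambda_) or lambda_ < 0:
        raise DomainError("lambda must be finite and >= 0")

    xtx = X.T @ X
    A = xtx + lambda_ * basis.penalty
    if lambda_ == 0:
        rank = np.linalg.matrix_rank(X)
        if rank < basis.n_basis:
            raise RankDeficientError(
                f"design matrix has rank {rank} < n_basis={basis.n_basis}; "
                "the unpenalized system is singular"
            )
    try:
        beta = np.linalg.solve(A, X.T @ y)
        # edf = tr(B (B'B + lambda P)^-1 B') = tr((B'B + lambda P)^-1 B'B)
        edf = float(np.trace(np.linalg.solve(A, xtx)))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise RankDeficientError(f"penalized system is singular: {exc}") from exc

    fitted = X @ beta
    rss = float(np.sum((y - fitted) ** 2))
    n = y.shape[0]
    denom = max(n - edf, 1e-8)
    sigma2 = max(rss / denom, SIGMA2_FLOOR)
    return ClassModel(
        coefficients=beta,
        lambda_=float(lambda_),
        edf=edf,
        sigma2=sigma2,
        fitted_curve=basis.design @ beta,
        n_obs=n,
        basis=basis,
    )


def gcv_score(y, basis: SplineBasis, lambda_: float, months=None) -> float:
    """Generalized cross-validation score n*RSS / (n - tr H)^2."""
    y = np.asarray(y, dtype=float)
    X = _design_for(basis, months)
    xtx = X.T @ X
    A = xtx + lambda_ * basis.penalty
    beta = np.linalg.solve(A, X.T @ y)
    edf = float(np.trace(np.linalg.solve(A, xtx)))
    rss = float(np.sum((y - X @ beta) ** 2))
    n = y.shape[0]
    return n * rss / (n - edf) ** 2


def select_lambda(y, basis: SplineBasis, grid=None, months=None) -> float:
    """Choose the smoothing parameter minimising GCV over a grid.

    Ties (within floating equality) resolve to the smaller lambda; the grid
    is sorted ascending before scoring.
    """
    grid = DEFAULT_LAMBDA_GRID if grid is None else np.sort(
        np.asarray(grid, dtype=float)
    )
    if grid.size == 0:
        raise DomainError("lambda grid must be non-empty")
    if np.any(grid < 0):
        raise DomainError("lambda grid must be non-negative")

    y = np.asarray(y, dtype=float)
    X = _design_for(basis, months)
    xtx = X.T @ X
    xty = X.T @ y
    yty = float(y @ y)
    n = y.shape[0]

    scores = np.full(grid.size, np.inf)
    for i, lam in enumerate(grid):
        A = xtx + lam * basis.penalty
        try:
            beta = np.linalg.solve(A, xty)
            edf = float(np.trace(np.linalg.solve(A, xtx)))
        except np.linalg.LinAlgError:
            continue
        rss = yty - 2.0 * beta @ xty + beta @ xtx @ beta
        rss = max(rss, 0.0)
        denom = (n - edf) ** 2
        if denom <= 0:
            continue
        scores[i] = n * rss / denom
    if not np.any(np.isfinite(scores)):
        raise DomainError("GCV is non-finite on the whole lambda grid")
    return float(grid[int(np.argmin(scores))])


def estimate_variance_components(residuals, subject_ids) -> tuple[float, float]:
    """Method-of-moments (sigma_b2, sigma2) from within-subject residuals.

    sigma_b2 is the average within-subject off-diagonal covariance of the
    residuals; sigma2 is the leftover within-subject variance. Both are
    floored at zero / the variance floor respectively.
    """
    residuals = np.asarray(residuals, dtype=float)
    subject_ids = np.asarray(subject_ids)
    total_var = float(np.mean(residuals**2))
    num = 0.0
    den = 0
    for sid in np.unique(subject_ids):
        r = residuals[subject_ids == sid]
        m = r.size
        if m < 2:
            continue
        s = float(r.sum())
        # mean pairwise product = (sum^2 - sum of squares) / (m (m-1))
        num += (s * s - float(r @ r))
        den += m * (m - 1)
    sigma_b2 = max(num / den, 0.0) if den > 0 else 0.0
    sigma_b2 = min(sigma_b2, total_var)  # cannot exceed the marginal variance
    sigma2 = max(total_var - sigma_b2, SIGMA2_FLOOR)
    return sigma_b2, sigma2


def subject_loglik(months, weights, model: ClassModel) -> float:
    """Gaussian log-likelihood of one subject's observations under a class.

    Independent-residual model (``model.sigma_b2 is None``)::

        sum_t [ -0.5 log(2 pi sigma2) - (y_t - f(t))^2 / (2 sigma2) ]

    Compound-symmetry model: multivariate normal with covariance
    ``sigma_b2 * J + sigma2 * I``, evaluated by the Sherman-Morrison
    closed form.
    """
    months = np.atleast_1d(np.asarray(months, dtype=float))
    weights = np.atleast_1d(np.asarray(weights, dtype=float))
    if months.shape != weights.shape:
        raise DomainError("months and weights must align")
    r = weights - model.predict(months)
    m = r.size
    s2 = model.sigma2
    if model.sigma_b2 is None:
        return float(-0.5 * m * np.log(2 * np.pi * s2) - (r @ r) / (2 * s2))
    sb2 = model.sigma_b2
    tau = s2 + m * sb2
    logdet = (m - 1) * np.log(s2) + np.log(tau)
    quad = (r @ r) / s2 - sb2 * r.sum() ** 2 / (s2 * tau)
    return float(-0.5 * (m * np.log(2 * np.pi) + logdet + quad))
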