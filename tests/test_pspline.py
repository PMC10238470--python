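"""Penalized-spline smoother: oracles, closed forms and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import multivariate_normal

from trajsmm.errors import DomainError, ExtrapolationError, RankDeficientError
from trajsmm.pspline import (
    build_basis,
    fit_pspline,
    gcv_score,
    select_lambda,
    subject_loglik,
)

MONTHS = np.arange(1.0, 10.0)


def deboor(i, k, knots, x):
    """Independent recursive Cox-de Boor evaluation of B_{i,k}(x)."""
    if k == 0:
        return 1.0 if knots[i] <= x < knots[i + 1] else 0.0
    left, right = 0.0, 0.0
    if knots[i + k] > knots[i]:
        left = (x - knots[i]) / (knots[i + k] - knots[i]) * deboor(i, k - 1, knots, x)
    if knots[i + k + 1] > knots[i + 1]:
        right = (
            (knots[i + k + 1] - x)
            / (knots[i + k + 1] - knots[i + 1])
            * deboor(i + 1, k - 1, knots, x)
        )
    return left + right


class TestBasis:
    def test_design_matches_de_boor_recursion(self):
        basis = build_basis(MONTHS, n_basis=6, degree=3)
        # cubic splines are continuous, so nudging the right endpoint
        # inward sidesteps the half-open-interval convention
        for r, m in enumerate(MONTHS):
            x = m - 1e-9 if m == MONTHS[-1] else m
            expected = [deboor(i, 3, basis.knots, x) for i in range(6)]
            np.testing.assert_allclose(basis.design[r], expected, atol=1e-6)

    def test_partition_of_unity_and_shape(self):
        basis = build_basis(MONTHS, n_basis=6, degree=3)
        assert basis.design.shape == (9, 6)
        np.testing.assert_allclose(basis.design.sum(axis=1), 1.0, atol=1e-10)

    def test_penalty_null_space_constant_and_linear(self):
        basis = build_basis(MONTHS, n_basis=6, degree=3, penalty_order=2)
        np.testing.assert_allclose(basis.penalty @ np.ones(6), 0.0, atol=1e-12)
        np.testing.assert_allclose(basis.penalty @ np.arange(6.0), 0.0, atol=1e-12)

    @pytest.mark.parametrize(
        "months, n_basis, err",
        [
            (MONTHS, 20, DomainError),          # more bases than identifiable
            (np.array([1.0]), 6, DomainError),  # single point
            (np.array([3.0, 2.0, 1.0]), 4, DomainError),  # unsorted
        ],
    )
    def test_invalid_configurations(self, months, n_basis, err):
        with pytest.raises(err):
            build_basis(months, n_basis=n_basis)

    def test_no_extrapolation(self):
        basis = build_basis(MONTHS)
        with pytest.raises(ExtrapolationError):
            basis.design_at([0.5])
        with pytest.raises(ExtrapolationError):
            basis.design_at([9.5])


class TestFit:
    def test_matches_brute_force_linear_solve(self):
        rng = np.random.default_rng(42)
        basis = build_basis(MONTHS)
        y = rng.normal(70, 5, size=9)
        lam = 10.0
        model = fit_pspline(y, basis, lam)
        B, P = basis.design, basis.penalty
        beta = np.linalg.inv(B.T @ B + lam * P) @ B.T @ y
        np.testing.assert_allclose(model.coefficients, beta, atol=1e-8)

    @pytest.mark.parametrize("lam", [0.0, 1.0, 1e3])
    def test_linear_data_reproduced_exactly(self, lam):
        # linear trends live in the null space of the order-2 penalty
        y = 60.0 + 1.5 * MONTHS
        model = fit_pspline(y, build_basis(MONTHS), lam)
        np.testing.assert_allclose(model.fitted_curve, y, atol=1e-8)

    def test_lambda_zero_equals_ols(self):
        rng = np.random.default_rng(7)
        basis = build_basis(MONTHS)
        y = rng.normal(70, 5, size=9)
        model = fit_pspline(y, basis, 0.0)
        beta_ols, *_ = np.linalg.lstsq(basis.design, y, rcond=None)
        np.testing.assert_allclose(model.coefficients, beta_ols, atol=1e-8)

    def test_rank_deficiency_at_lambda_zero_is_named(self):
        months = np.array([1.0, 1.0, 2.0, 3.0, 4.0])
        basis = build_basis(months, n_basis=6, degree=3)
        with pytest.raises(RankDeficientError, match="rank"):
            fit_pspline(np.ones(5), basis, 0.0)

    def test_edf_monotone_nonincreasing_in_lambda(self):
        rng = np.random.default_rng(3)
        basis = build_basis(MONTHS)
        y = rng.normal(70, 5, size=9)
        edfs = [fit_pspline(y, basis, lam).edf for lam in np.logspace(-4, 8, 25)]
        assert all(a >= b - 1e-10 for a, b in zip(edfs, edfs[1:]))
        assert all(1.0 <= e <= basis.n_basis + 1e-9 for e in edfs)

    def test_rss_minimal_at_lambda_zero(self):
        rng = np.random.default_rng(11)
        basis = build_basis(MONTHS)
        y = rng.normal(70, 5, size=9)

        def rss(lam):
            m = fit_pspline(y, basis, lam)
            return np.sum((y - m.fitted_curve) ** 2)

        r0 = rss(0.0)
        assert all(r0 <= rss(lam) + 1e-10 for lam in [0.01, 1.0, 100.0])

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        seed=st.integers(0, 10_000),
        lam=st.floats(0.0, 100.0),
        n=st.integers(6, 30),
    )
    def test_ridge_closed_form_property(self, seed, lam, n):
        """fit_pspline equals the explicit ridge solution on random data."""
        rng = np.random.default_rng(seed)
        months = np.sort(rng.choice(MONTHS, size=n, replace=True))
        if np.unique(months).size < 4:
            return
        basis = build_basis(np.unique(months), n_basis=5, degree=3)
        y = rng.normal(70, 5, size=n)
        if lam == 0.0 and np.linalg.matrix_rank(basis.design_at(months)) < 5:
            return
        model = fit_pspline(y, basis, lam, months=months)
        X = basis.design_at(months)
        beta = np.linalg.solve(X.T @ X + lam * basis.penalty, X.T @ y)
        np.testing.assert_allclose(model.coefficients, beta, atol=1e-7)


class TestGCV:
    def test_score_matches_direct_formula(self):
        rng = np.random.default_rng(9)
        basis = build_basis(MONTHS)
        y = rng.normal(70, 5, size=9)
        lam = 3.7
        X, P = basis.design, basis.penalty
        H = X @ np.linalg.inv(X.T @ X + lam * P) @ X.T
        rss = float(np.sum((y - H @ y) ** 2))
        expected = 9 * rss / (9 - np.trace(H)) ** 2
        assert gcv_score(y, basis, lam) == pytest.approx(expected, rel=1e-10)

    def test_singleton_grid_returned(self):
        basis = build_basis(MONTHS)
        assert select_lambda(np.ones(9), basis, grid=[0.5]) == 0.5

    def test_huge_lambda_limits_to_straight_line(self):
        rng = np.random.default_rng(13)
        basis = build_basis(MONTHS)
        y = rng.normal(70, 5, size=9)
        model = fit_pspline(y, basis, 1e12)
        assert model.edf == pytest.approx(2.0, abs=1e-3)

    def test_empty_grid_rejected(self):
        with pytest.raises(DomainError):
            select_lambda(np.ones(9), build_basis(MONTHS), grid=[])


class TestSubjectLoglik:
    def test_zero_residuals_special_variance(self):
        # sigma2 = 1/(2 pi) makes the log-normalisation term vanish
        basis = build_basis(MONTHS)
        y = 60.0 + 1.5 * MONTHS
        model = fit_pspline(y, basis, 1.0)
        model.sigma2 = 1.0 / (2 * np.pi)
        assert subject_loglik(MONTHS, y, model) == pytest.approx(0.0, abs=1e-8)

    def test_shift_changes_loglik_quadratically(self):
        basis = build_basis(MONTHS)
        y = 60.0 + 1.5 * MONTHS
        model = fit_pspline(y, basis, 1.0)
        model.sigma2 = 2.5
        d = 0.8
        ll0 = subject_loglik(MONTHS, y, model)
        ll1 = subject_loglik(MONTHS, y + d, model)
        assert ll1 - ll0 == pytest.approx(-9 * d**2 / (2 * 2.5), rel=1e-10)

    def test_compound_symmetry_matches_mvn_oracle(self):
        basis = build_basis(MONTHS)
        y = 60.0 + 1.5 * MONTHS
        model = fit_pspline(y, basis, 1.0)
        model.sigma2, model.sigma_b2 = 1.3, 2.1
        months = np.array([2.0, 5.0, 8.0])
        obs = np.array([64.0, 66.5, 73.0])
        mu = model.predict(months)
        cov = 2.1 * np.ones((3, 3)) + 1.3 * np.eye(3)
        expected = multivariate_normal.logpdf(obs, mean=mu, cov=cov)
        assert subject_loglik(months, obs, model) == pytest.approx(expected, rel=1e-10)

    def test_month_outside_range_rejected(self):
        basis = build_basis(MONTHS)
        model = fit_pspline(np.ones(9) * 70, basis, 1.0)
        with pytest.raises(ExtrapolationError):
            subject_loglik([10.0], [71.0], model)
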