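"""Hard-assignment E-M classifier: initialization, steps, convergence,
selection, relabeling and concordance."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from trajsmm.errors import DataValidationError, DegenerateClassError, DomainError
from trajsmm.pspline import build_basis, fit_pspline, select_lambda, subject_loglik
from trajsmm.smm import (
    SmoothingMixtureModel,
    compute_bic,
    compute_bic_from_parts,
    crosstab,
    e_step,
    fit_smm,
    initialize,
    m_step,
    relabel,
)
from trajsmm.synthetic_data import CohortConfig, generate_cohort


def balanced_long(bases, months=range(1, 10)):
    rows = [
        {"subject_id": sid, "month": m, "weight_kg": float(b)}
        for sid, b in enumerate(bases, start=1)
        for m in months
    ]
    return pd.DataFrame(rows)


class TestInitialize:
    def test_rank_split_two_groups(self, tiny_long):
        assign = initialize(tiny_long, 2)
        assert assign.loc[[1, 2, 3]].tolist() == [1, 1, 1]
        assert assign.loc[[4, 5, 6]].tolist() == [2, 2, 2]

    def test_single_class(self, tiny_long):
        assert initialize(tiny_long, 1).tolist() == [1] * 6

    def test_near_equal_split_larger_groups_first(self):
        long = balanced_long([60, 61, 62, 63, 64, 65, 66])
        sizes = initialize(long, 3).value_counts().sort_index().tolist()
        assert sizes == [3, 2, 2]

    def test_k_exceeding_subjects_rejected(self, tiny_long):
        with pytest.raises(DomainError):
            initialize(tiny_long, 7)


class TestMStep:
    def test_returns_k_models_matching_standalone_fits(self, tiny_long):
        assign = initialize(tiny_long, 2)
        models = m_step(tiny_long, assign)
        assert len(models) == 2
        # oracle: refit the pooled class observations independently
        months = np.arange(1.0, 10.0)
        basis = build_basis(months)
        pooled = tiny_long[tiny_long["subject_id"].isin([1, 2, 3])]
        y = pooled.sort_values(["subject_id", "month"])["weight_kg"].to_numpy()
        mo = pooled.sort_values(["subject_id", "month"])["month"].to_numpy(float)
        lam = select_lambda(y, basis, months=mo)
        ref = fit_pspline(y, basis, lam, months=mo)
        np.testing.assert_allclose(models[0].coefficients, ref.coefficients, atol=1e-10)

    def test_identical_trajectories_fit_perfectly(self):
        long = balanced_long([70, 70, 70])
        models = m_step(long, initialize(long, 1))
        np.testing.assert_allclose(models[0].fitted_curve, 70.0, atol=1e-6)
        assert models[0].sigma2 == pytest.approx(1e-6)  # variance floor

    def test_empty_class_raises_with_index(self, tiny_long):
        assign = initialize(tiny_long, 2).replace({2: 3})  # class 2 empty
        with pytest.raises(DegenerateClassError) as exc:
            m_step(tiny_long, assign)
        assert exc.value.class_index == 2


class TestEStep:
    def test_matches_exhaustive_per_subject_oracle(self, noisy_cohort):
        _, long, _ = noisy_cohort
        sub = long[long["subject_id"] <= 60]
        models = m_step(sub, initialize(sub, 3))
        assign, per_ll = e_step(sub, models)
        for sid, grp in sub.groupby("subject_id"):
            lls = [
                subject_loglik(
                    grp["month"].to_numpy(float), grp["weight_kg"].to_numpy(), m
                )
                for m in models
            ]
            assert assign.loc[sid] == int(np.argmax(lls)) + 1
            assert per_ll.loc[sid] == pytest.approx(max(lls), rel=1e-12)

    def test_subject_on_curve_wins_with_equal_variance(self):
        long = balanced_long([60, 60, 80, 80])
        models = m_step(long, initialize(long, 2))
        models[0].sigma2 = models[1].sigma2 = 1.0
        assign, _ = e_step(long, models)
        assert assign.tolist() == [1, 1, 2, 2]

    def test_exact_tie_goes_to_lowest_class_index(self, tiny_long):
        models = m_step(tiny_long, initialize(tiny_long, 2))
        duplicated = [models[0], models[0]]  # identical models -> ties
        assign, _ = e_step(tiny_long, duplicated)
        assert assign.tolist() == [1] * 6


class TestFitSMM:
    @pytest.mark.parametrize("K", [2, 3, 4])
    def test_noise_free_recovery_is_exact(self, K):
        cfg = CohortConfig(
            n_subjects=90, n_classes=K, random_intercept_sd=0, residual_sd=0, seed=5
        )
        long, labels = generate_cohort(cfg)
        res = fit_smm(long, K)
        assert adjusted_rand_score(labels, res.assignment) == 1.0
        assert res.n_iterations <= 3 and res.converged

    def test_single_class_total_ll_is_sum_of_subject_logliks(self, tiny_long):
        res = fit_smm(tiny_long, 1)
        assert res.converged and res.n_iterations == 1
        model = res.class_models[0]
        expected = sum(
            subject_loglik(
                grp["month"].to_numpy(float), grp["weight_kg"].to_numpy(), model
            )
            for _, grp in tiny_long.groupby("subject_id")
        )
        assert res.total_ll == pytest.approx(expected, rel=1e-12)

    def test_noisy_recovery_close_to_bayes_oracle(self, noisy_cohort):
        """The fitted assignment should track the information-theoretic
        ceiling: an oracle knowing the true curves and covariance."""
        cfg, long, labels = noisy_cohort
        res = fit_smm(long, 3)
        ari = adjusted_rand_score(labels, res.assignment)

        W = long.pivot(index="subject_id", columns="month", values="weight_kg")
        months = np.arange(1, 10)
        lls = []
        for k in (1, 2, 3):
            mu = cfg.class_baselines[k - 1] + np.asarray(cfg.gain_curve)
            r = (W.to_numpy() - mu)
            s2, sb2, m = 1.0, 4.0, 9
            quad = (r**2).sum(1) / s2 - sb2 * r.sum(1) ** 2 / (s2 * (s2 + m * sb2))
            lls.append(-0.5 * quad)
        oracle = np.argmax(np.vstack(lls), axis=0) + 1
        ari_oracle = adjusted_rand_score(labels, oracle)
        assert ari >= 0.85
        assert ari >= ari_oracle - 0.03

    def test_unbalanced_data_degrades_gracefully(self):
        cfg = CohortConfig(seed=0, dropout_rate=0.3)
        long, labels = generate_cohort(cfg)
        res = fit_smm(long, 3)
        ari = adjusted_rand_score(labels, res.assignment)
        full_long, full_labels = generate_cohort(CohortConfig(seed=0))
        ari_full = adjusted_rand_score(full_labels, fit_smm(full_long, 3).assignment)
        assert ari >= 0.85 and ari >= ari_full - 0.05

    def test_e_step_never_decreases_loglik_and_trace_is_recorded(self, noisy_cohort):
        _, long, _ = noisy_cohort
        res = fit_smm(long, 3)
        t = res.trace
        assert (
            t["total_ll"] >= t["total_ll_previous_assignment"] - 1e-8
        ).all()
        assert t["n_changed"].iloc[-1] == 0
        # after the first M/E round the objective should not deteriorate
        assert res.total_ll >= t["total_ll"].iloc[0] - 1e-6


class TestBIC:
    def test_closed_form(self):
        from types import SimpleNamespace

        models = [SimpleNamespace(edf=1.5), SimpleNamespace(edf=1.5)]
        bic = compute_bic_from_parts(-100.0, models, K=2, n_obs=100)
        assert bic == pytest.approx(200 + 5 * np.log(100), abs=1e-4)  # 223.0259

    def test_monotone_in_parameter_count(self):
        from types import SimpleNamespace

        low = compute_bic_from_parts(-100.0, [SimpleNamespace(edf=2.0)], 1, 100)
        high = compute_bic_from_parts(-100.0, [SimpleNamespace(edf=5.0)], 1, 100)
        assert high > low

    def test_matches_recomputation_from_serialized_fit(self, tiny_long):
        res = fit_smm(tiny_long, 2)
        import json

        blob = json.loads(res.to_json())
        p = sum(m["edf"] for m in blob["class_models"]) + blob["n_classes"]
        expected = -2 * blob["total_ll"] + p * np.log(6 * 9)
        assert res.bic == pytest.approx(expected, rel=1e-12)
        assert compute_bic(res) == pytest.approx(res.bic, rel=1e-12)

    def test_nonpositive_n_rejected(self, tiny_long):
        res = fit_smm(tiny_long, 2)
        with pytest.raises(DomainError):
            compute_bic(res, n_obs=0)


class TestSelection:
    def test_table_has_one_row_per_candidate(self, noise_free_cohort):
        _, long, _ = noise_free_cohort
        sel = SmoothingMixtureModel(long).select((2, 3, 4, 5))
        assert len(sel.table) == 4
        assert sel.selected_k == 3

    def test_degenerate_candidates_recorded_not_fatal(self, noise_free_cohort):
        # noise-free 3-class data collapses K>3 fits into empty classes
        _, long, _ = noise_free_cohort
        sel = SmoothingMixtureModel(long).select((2, 3, 4, 5))
        failed = sel.table[sel.table["error"].notna()]
        assert set(failed["n_classes"]) == {4, 5}

    def test_singleton_range_returns_that_fit(self, noise_free_cohort):
        _, long, _ = noise_free_cohort
        sel = SmoothingMixtureModel(long).select((2,))
        assert sel.selected_k == 2 and sel.selected.n_classes == 2

    def test_margin_rule_requires_closeness(self):
        from trajsmm.smm import _apply_parsimony

        ks = np.array([2, 3, 4, 5])
        bics = np.array([32485.4, 30528.3, 30211.9, 29626.5])
        k_margin, _ = _apply_parsimony(ks, bics, "margin", 0.01)
        assert k_margin == 5  # the gap to K=3 exceeds 1%
        k_elbow, note = _apply_parsimony(ks, bics, "elbow", 0.01)
        assert k_elbow == 3 and "elbow" in note
        k_min, _ = _apply_parsimony(ks, bics, "none", 0.01)
        assert k_min == 5


class TestRelabel:
    def test_orders_by_curve_mean_and_labels_three_classes(self, noise_free_cohort):
        _, long, labels = noise_free_cohort
        res = fit_smm(long, 3)
        rel = relabel(res)
        means = [float(np.mean(m.fitted_curve)) for m in rel.class_models]
        assert means == sorted(means)
        assert rel.class_labels == ("low", "medium", "high")
        # membership composition is preserved under the permutation
        assert adjusted_rand_score(res.assignment, rel.assignment) == 1.0

    def test_likelihood_and_bic_invariant(self, noisy_cohort):
        _, long, _ = noisy_cohort
        res = fit_smm(long, 3)
        rel = relabel(res)
        assert rel.total_ll == res.total_ll
        assert rel.bic == res.bic
        pd.testing.assert_series_equal(rel.per_subject_ll, res.per_subject_ll)

    def test_idempotent(self, noise_free_cohort):
        _, long, _ = noise_free_cohort
        rel = relabel(fit_smm(long, 3))
        again = relabel(rel)
        pd.testing.assert_series_equal(rel.assignment, again.assignment)


class TestCrosstab:
    def idx(self, n):
        return pd.Index(range(1, n + 1), name="subject_id")

    def test_identical_assignments_fully_concordant(self):
        a = pd.Series([1, 2, 3, 1, 2, 3], index=self.idx(6))
        table, conc = crosstab(a, a.copy())
        assert conc == 100.0
        off_diag = table.to_numpy() - np.diag(np.diag(table.to_numpy()))
        assert off_diag.sum() == 0

    def test_cyclic_shift_is_fully_discordant(self):
        a = pd.Series([1, 2, 3, 1, 2, 3], index=self.idx(6))
        b = (a % 3) + 1
        table, conc = crosstab(a, b)
        assert conc == 0.0
        assert table.to_numpy().sum() == 6

    def test_table_sums_to_n_subjects(self, noisy_cohort):
        _, long, labels = noisy_cohort
        res = fit_smm(long, 3)
        table, _ = crosstab(res.initial_assignment, res.assignment)
        assert table.to_numpy().sum() == 877

    def test_subject_mismatch_rejected(self):
        a = pd.Series([1, 2], index=self.idx(2))
        b = pd.Series([1, 2], index=pd.Index([5, 6], name="subject_id"))
        with pytest.raises(DataValidationError):
            crosstab(a, b)
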