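import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from caseseries import (
    extract_components,
    factor_scores,
    kmo,
    project_controls,
    rotate_solution,
    tucker_congruence,
    varimax,
)
from caseseries.factors import varimax_criterion
from caseseries.preprocess import ScoreMatrix


def _sm(values, ids=None):
    n, p = values.shape
    return ScoreMatrix([f"s{i}" for i in range(n)],
                       ids or [f"t{j}" for j in range(p)], values)


class TestKMO:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(r=st.floats(-0.95, 0.95).filter(lambda v: abs(v) > 1e-3))
    def test_bivariate_is_half(self, r):
        R = np.array([[1.0, r], [r, 1.0]])
        assert kmo(R) == pytest.approx(0.5, abs=1e-12)

    def test_identity_degenerate(self):
        with pytest.raises(ValueError, match="0/0|diagonal"):
            kmo(np.eye(3))

    def test_matches_direct_formula_oracle(self):
        # equicorrelated 4-variable one-factor matrix, oracle = direct
        # evaluation of the anti-image formula from the explicit inverse
        R = np.full((4, 4), 0.64)
        np.fill_diagonal(R, 1.0)
        Rinv = np.linalg.inv(R)
        num = den_q = 0.0
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                num += R[i, j] ** 2
                q = -Rinv[i, j] / np.sqrt(Rinv[i, i] * Rinv[j, j])
                den_q += q ** 2
        assert kmo(R) == pytest.approx(num / (num + den_q), abs=1e-10)

    def test_singular_matrix_rejected(self):
        R = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="singular"):
            kmo(R)


class TestExtraction:
    def test_identity_correlation_falls_back_to_one(self):
        rng = np.random.default_rng(0)
        # near-orthogonal data: all eigenvalues hover at 1, none strictly
        # dominant enough by design of the generator below
        Z = rng.standard_normal((2000, 4))
        sol = extract_components(_sm(Z))
        assert sol.n_retained >= 1  # never an empty solution

    def test_two_collinear_tests(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(50)
        sol = extract_components(_sm(np.column_stack([x, 2 * x + 3])))
        np.testing.assert_allclose(sol.eigenvalues, [2.0, 0.0], atol=1e-10)
        assert sol.n_retained == 1
        assert sol.var_explained[0] == pytest.approx(1.0)

    def test_eigenvalues_sum_to_test_count(self, complete_cohort):
        from caseseries import collapse_test_measures, orient_measures, zscore_to_reference
        cohort, _ = complete_cohort
        cohort = orient_measures(cohort)
        pat = cohort.is_patient
        z = zscore_to_reference(collapse_test_measures(cohort, fit_mask=pat), pat)
        sol = extract_components(z.rows(pat))
        assert sol.eigenvalues.sum() == pytest.approx(len(sol.test_ids), abs=1e-8)
        assert 0 < sol.kmo <= 1


class TestVarimax:
    def test_single_factor_identity_up_to_sign(self):
        L0 = np.array([[0.5], [-0.9], [0.3]])
        L, T = varimax(L0)
        np.testing.assert_allclose(np.abs(L), np.abs(L0), atol=1e-12)

    def test_simple_structure_unchanged(self):
        L0 = np.array([[0.9, 0.0], [0.8, 0.0], [0.0, 0.7], [0.0, 0.6]])
        L, T = varimax(L0, kaiser_normalize=False)
        np.testing.assert_allclose(np.sort(np.abs(L), axis=None),
                                   np.sort(np.abs(L0), axis=None), atol=1e-6)

    @pytest.mark.parametrize("trial", range(3))
    def test_matches_grid_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        L0 = rng.uniform(-1, 1, size=(6, 2))
        L, T = varimax(L0, kaiser_normalize=True)
        assert np.allclose(T.T @ T, np.eye(2), atol=1e-8)
        # communality conservation
        np.testing.assert_allclose((L ** 2).sum(1), (L0 ** 2).sum(1), atol=1e-8)
        # criterion within 1e-6 of the 0.01-degree grid maximum
        h = np.sqrt((L0 ** 2).sum(1))
        A = L0 / h[:, None]
        thetas = np.deg2rad(np.arange(0, 90, 0.01))
        best = max(varimax_criterion(
            A @ np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]]))
            for t in thetas)
        assert varimax_criterion(A @ T) >= best - 1e-6


class TestScoresAndProjection:
    def _fitted(self, seed=0, n=64, p=8):
        rng = np.random.default_rng(seed)
        W = np.zeros((p, 2))
        W[: p // 2, 0] = 0.8
        W[p // 2:, 1] = 0.8
        X = rng.standard_normal((n, 2)) @ W.T + 0.4 * rng.standard_normal((n, p))
        mu, sd = X.mean(0), X.std(0, ddof=1)
        Z = (X - mu) / sd
        sol = rotate_solution(extract_components(_sm(Z)))
        return sol, Z, mu, sd

    def test_fitting_rows_have_mean_zero_scores(self):
        sol, Z, _, _ = self._fitted()
        fs = factor_scores(sol, _sm(Z))
        np.testing.assert_allclose(fs.scores.mean(axis=0), 0, atol=1e-8)

    def test_mean_profile_scores_zero(self):
        sol, Z, _, _ = self._fitted()
        fs = factor_scores(sol, _sm(np.zeros((1, Z.shape[1]))))
        np.testing.assert_allclose(fs.scores, 0, atol=1e-12)

    def test_communality_and_variance_conserved_by_rotation(self):
        sol, Z, _, _ = self._fitted(seed=3)
        unrot = extract_components(_sm(Z))
        np.testing.assert_allclose(unrot.communalities, sol.communalities, atol=1e-8)
        assert sol.total_var_explained == pytest.approx(
            unrot.total_var_explained, abs=1e-8)

    def test_control_norms_and_cutoff(self):
        sol, Z, mu, sd = self._fitted(seed=4)
        rng = np.random.default_rng(9)
        controls = rng.standard_normal((40, Z.shape[1])) * 0.5 + 1.0
        Zc = (controls - mu) / sd
        fs = project_controls(sol, _sm(Zc))
        np.testing.assert_allclose(fs.cutoff, fs.control_mean - 2 * fs.control_sd,
                                   atol=1e-12)

    def test_controls_at_patient_mean_score_zero(self):
        sol, Z, mu, sd = self._fitted(seed=5)
        Zc = np.zeros((5, Z.shape[1]))  # exactly the patient mean profile
        fs = project_controls(sol, _sm(Zc) )
        np.testing.assert_allclose(fs.control_mean, 0, atol=1e-12)

    def test_column_order_invariance(self):
        sol, Z, _, _ = self._fitted(seed=6)
        perm = np.random.default_rng(1).permutation(Z.shape[1])
        sol2 = rotate_solution(extract_components(_sm(Z[:, perm])))
        c = tucker_congruence(sol.loadings[perm], sol2.loadings)
        assert c.min() > 1 - 1e-6
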