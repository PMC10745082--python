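import numpy as np
import pytest

from taskdecode.sparse import (
    LoadingMatrix1,
    assemble_stage2_input,
    code_test_set,
    disassemble_stage2_input,
    lasso_code,
    learn_spatial_dictionary,
    reconstruction_error,
)

from ._oracles import kkt_residual, oracle_lasso


class TestLassoCode:
    def test_soft_threshold_on_identity(self):
        alpha = lasso_code(np.array([3.0, 0.05]), np.eye(2), 0.1)
        np.testing.assert_allclose(alpha, [2.9, 0.0], atol=1e-8)

    def test_zero_penalty_is_least_squares(self, rng):
        D = rng.normal(size=(4, 4))
        s = rng.normal(size=4)
        alpha = lasso_code(s, D, 0.0)
        np.testing.assert_allclose(alpha, np.linalg.solve(D, s), atol=1e-8)

    def test_large_penalty_gives_zero(self, rng):
        D = rng.normal(size=(6, 3))
        D /= np.linalg.norm(D, axis=0)
        s = rng.normal(size=6)
        lam = np.abs(D.T @ s).max()
        assert np.all(lasso_code(s, D, lam + 1e-9) == 0)

    def test_negative_penalty_raises(self, rng):
        with pytest.raises(ValueError):
            lasso_code(rng.normal(size=3), np.eye(3), -0.1)

    def test_nan_raises(self):
        with pytest.raises(ValueError):
            lasso_code(np.array([np.nan, 1.0]), np.eye(2), 0.1)

    def test_matches_oracle_small(self, rng):
        for i in range(30):
            t, k = int(rng.integers(4, 13)), int(rng.integers(2, 7))
            D = rng.standard_normal((t, k))
            D /= np.linalg.norm(D, axis=0)
            s = rng.standard_normal(t)
            lam = (0.01, 0.1, 0.5)[i % 3]
            a = lasso_code(s, D, lam)
            np.testing.assert_allclose(a, oracle_lasso(D, s, lam), atol=1e-4)
            assert kkt_residual(D, s, a, lam) < 1e-5

    def test_multicolumn_matches_columnwise(self, rng):
        D = rng.standard_normal((8, 5))
        D /= np.linalg.norm(D, axis=0)
        S = rng.standard_normal((8, 4))
        A = lasso_code(S, D, 0.1)
        for j in range(4):
            np.testing.assert_allclose(A[:, j], lasso_code(S[:, j], D, 0.1), atol=1e-8)

    def test_sparsity_monotone_in_lambda(self, rng):
        D = rng.standard_normal((20, 10))
        D /= np.linalg.norm(D, axis=0)
        s = rng.standard_normal(20)
        nnz = [
            int(np.sum(np.abs(lasso_code(s, D, lam)) > 1e-10))
            for lam in (0.01, 0.05, 0.1, 0.2, 0.5, 1.0)
        ]
        assert nnz == sorted(nnz, reverse=True)


class TestAssemble:
    def _codes(self, p=1, T=2, k1=3, n=10, seed=0):
        rng = np.random.default_rng(seed)
        return [
            LoadingMatrix1(rng.normal(size=(k1, n)), f"s{i}", f"t{j}")
            for i in range(p)
            for j in range(T)
        ]

    def test_shape(self):
        S2, labels = assemble_stage2_input(self._codes())
        assert S2.shape == (10, 6)
        assert len(labels) == 6

    def test_label_index_arithmetic(self):
        _, labels = assemble_stage2_input(self._codes())
        # subject-major, then task, then component: column 3 (0-based) is
        # (subject 0, second task, component 0)
        assert labels[3] == ("s0", "t1", 0)

    def test_round_trip(self):
        codes = self._codes(p=2, T=3)
        S2, labels = assemble_stage2_input(codes)
        back = disassemble_stage2_input(S2, labels)
        for lm in codes:
            np.testing.assert_array_equal(back[(lm.subject_id, lm.task_id)], lm.codes)

    def test_shape_mismatch_raises(self):
        codes = self._codes()
        codes[1] = LoadingMatrix1(np.zeros((4, 10)), "s0", "t1")
        with pytest.raises(ValueError):
            assemble_stage2_input(codes)

    def test_missing_pair_raises(self):
        codes = self._codes(p=2, T=2)[:-1]
        with pytest.raises(ValueError, match="missing"):
            assemble_stage2_input(codes)


def planted_dictionary_problem(seed, n=200, m=400, k2=8, nz=2, noise=0.01):
    """Disjoint-support atoms with 2-sparse codes (parameter-recovery setup)."""
    rng = np.random.default_rng(seed)
    D = np.zeros((n, k2))
    width = n // k2
    for j in range(k2):
        D[j * width : (j + 1) * width, j] = rng.uniform(0.5, 1.0, width)
        D[:, j] /= np.linalg.norm(D[:, j])
    A = np.zeros((k2, m))
    for c in range(m):
        rows = rng.choice(k2, nz, replace=False)
        A[rows, c] = rng.uniform(0.5, 1.5, nz) * rng.choice([-1, 1], nz)
    return D @ A + noise * rng.standard_normal((n, m)), D


def matched_atom_correlations(D_true, D_hat):
    from scipy.optimize import linear_sum_assignment

    C = np.abs(
        D_true.T
        @ D_hat
        / np.outer(
            np.linalg.norm(D_true, axis=0),
            np.maximum(np.linalg.norm(D_hat, axis=0), 1e-12),
        )
    )
    r, c = linear_sum_assignment(-C)
    return C[r, c]


class TestLearnSpatialDictionary:
    def test_atom_constraint_every_iteration(self):
        S, _ = planted_dictionary_problem(0, n=60, m=120, k2=6)
        D, _ = learn_spatial_dictionary(S, 6, 0.05, n_iter=10, seed=0)
        assert max(D.max_atom_norm_history) <= 1.0 + 1e-8

    def test_objective_nonincreasing(self):
        S, _ = planted_dictionary_problem(1, n=60, m=120, k2=6)
        D, _ = learn_spatial_dictionary(S, 6, 0.05, n_iter=10, seed=0)
        obj = D.objective_history
        assert all(obj[i + 1] <= obj[i] + 1e-10 for i in range(len(obj) - 1))

    def test_planted_recovery_two_seeds(self):
        scores = []
        for seed in (0, 2):
            S, D_true = planted_dictionary_problem(seed)
            D_hat, _ = learn_spatial_dictionary(S, 8, 0.05, n_iter=25, seed=seed)
            scores.append(matched_atom_correlations(D_true, D_hat.atoms).mean())
        assert np.mean(scores) >= 0.9

    def test_seed_determinism(self):
        S, _ = planted_dictionary_problem(3, n=40, m=80, k2=4)
        D1, A1 = learn_spatial_dictionary(S, 4, 0.05, n_iter=5, seed=7)
        D2, A2 = learn_spatial_dictionary(S, 4, 0.05, n_iter=5, seed=7)
        np.testing.assert_array_equal(D1.atoms, D2.atoms)
        np.testing.assert_array_equal(A1.codes, A2.codes)

    def test_k2_too_large_raises(self, rng):
        with pytest.raises(ValueError):
            learn_spatial_dictionary(rng.normal(size=(10, 5)), 6, 0.05)

    def test_nonpositive_lambda_raises(self, rng):
        with pytest.raises(ValueError):
            learn_spatial_dictionary(rng.normal(size=(10, 5)), 3, 0.0)


class TestCodeTestSet:
    def _dicts(self, rng, t=40, k1=8, n=60, k2=10):
        Q, _ = np.linalg.qr(rng.standard_normal((t, k1)))
        D2 = rng.standard_normal((n, k2))
        D2 /= np.linalg.norm(D2, axis=0)
        return Q, D2

    def test_exact_recovery_at_tiny_lambda(self, rng):
        D1, _ = self._dicts(rng)
        a = np.zeros((8, 5))
        a[rng.integers(0, 8, 5), np.arange(5)] = rng.uniform(1, 2, 5)
        S = D1 @ a
        a1 = lasso_code(S, D1, 1e-8)
        assert np.abs(a1 - a).max() < 1e-4

    def test_zero_signal_zero_codes(self, rng):
        D1, D2 = self._dicts(rng, n=8)
        cm = code_test_set(np.zeros((40, 8)), D1, 0.1, D2, 0.05)
        assert np.all(cm.codes == 0)

    def test_determinism_identical_subjects(self, rng):
        D1, D2 = self._dicts(rng, n=8)
        S = rng.standard_normal((40, 8))
        c1 = code_test_set(S, D1, 0.1, D2, 0.05)
        c2 = code_test_set(S.copy(), D1, 0.1, D2, 0.05)
        np.testing.assert_array_equal(c1.codes, c2.codes)

    def test_dimension_mismatch_raises(self, rng):
        D1, D2 = self._dicts(rng, n=9)  # D2 rows != n signals columns
        with pytest.raises(ValueError):
            code_test_set(rng.standard_normal((40, 8)), D1, 0.1, D2, 0.05)

    def test_labels_cover_components(self, rng):
        D1, D2 = self._dicts(rng, n=8)
        cm = code_test_set(
            rng.standard_normal((40, 8)), D1, 0.1, D2, 0.05,
            subject_id="s1", task_id="tA",
        )
        assert cm.column_labels == [("s1", "tA", c) for c in range(8)]


class TestReconstructionError:
    def _factorized(self, rng, t=30, k1=6, n=50, k2=8):
        Q, _ = np.linalg.qr(rng.standard_normal((t, k1)))
        D2 = rng.standard_normal((n, k2))
        D2 /= np.linalg.norm(D2, axis=0)
        A2 = np.zeros((k2, k1))
        for c in range(k1):
            rows = rng.choice(k2, 2, replace=False)
            A2[rows, c] = rng.uniform(0.5, 1.5, 2)
        return Q, D2, A2, Q @ (D2 @ A2).T

    def test_self_consistency(self, rng):
        D1, D2, A2, S = self._factorized(rng)
        cm = code_test_set(S, D1, 1e-6, D2, 1e-6)
        assert reconstruction_error(S, D1, D2, cm.codes) < 1e-3

    def test_zero_codes_error_is_one(self, rng):
        D1, D2, A2, S = self._factorized(rng)
        assert reconstruction_error(S, D1, D2, np.zeros_like(A2)) == pytest.approx(1.0)

    def test_permutation_invariance(self, rng):
        D1, D2, A2, S = self._factorized(rng)
        perm = rng.permutation(D2.shape[1])
        e1 = reconstruction_error(S, D1, D2, A2)
        e2 = reconstruction_error(S, D1, D2[:, perm], A2[perm])
        assert e1 == pytest.approx(e2, abs=1e-12)

    def test_zero_signal_raises(self, rng):
        D1, D2, A2, _ = self._factorized(rng)
        with pytest.raises(ValueError):
            reconstruction_error(np.zeros((30, 6)), D1, D2, A2)
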