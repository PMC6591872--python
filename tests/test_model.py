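import dataclasses

import numpy as np
import pytest

from npcmf import HyperParams, NPCMF, WknknParams
from npcmf.model import als_step, fit_factors, objective, predict, svd_init

# ------------------------------------------------------------- oracle


def brute_force_als_step(Y, A, B, Rm, Rd, lam_l, lam_d, lam_t):
    """Independent evaluation of the closed-form fixed-point updates,
    using explicit inverses and no shared code with the solver."""
    k = A.shape[1]
    Ik = np.eye(k)
    inv_a = np.linalg.inv(B.T @ B + lam_l * Ik + lam_d * (A.T @ A))
    A_new = (Y @ B + lam_d * (Rm @ A)) @ inv_a
    inv_b = np.linalg.inv(A_new.T @ A_new + lam_l * Ik + lam_t * (B.T @ B))
    B_new = (Y.T @ A_new + lam_t * (Rd @ B)) @ inv_b
    return A_new, B_new


def random_instance(rng, n=6, m=5, k=3):
    Y = (rng.random((n, m)) < 0.4).astype(float)
    A = rng.normal(size=(n, k))
    B = rng.normal(size=(m, k))
    Rm = rng.random((n, n))
    Rm = (Rm + Rm.T) / 2
    Rd = rng.random((m, m))
    Rd = (Rd + Rd.T) / 2
    return Y, A, B, Rm, Rd


# ------------------------------------------------------------- svd_init


class TestSvdInit:
    def test_rank_one_exact_reconstruction(self):
        u = np.array([[1.0], [2.0], [0.5]])
        v = np.array([[3.0], [1.0]])
        Y = 2.0 * (u / np.linalg.norm(u)) @ (v / np.linalg.norm(v)).T
        pair = svd_init(Y, 1)
        np.testing.assert_allclose(pair.scores, Y, atol=1e-10)

    def test_zero_matrix_gives_zero_factors(self):
        pair = svd_init(np.zeros((4, 3)), 2)
        assert not pair.A.any() and not pair.B.any()

    def test_full_rank_is_exact(self):
        rng = np.random.default_rng(0)
        Y = rng.random((6, 4))
        pair = svd_init(Y, 4)
        assert np.linalg.norm(Y - pair.scores) <= 1e-8 * np.linalg.norm(Y)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(1)
        Y = rng.random((5, 5))
        p1, p2 = svd_init(Y, 3), svd_init(Y, 3)
        np.testing.assert_array_equal(p1.A, p2.A)
        for l in range(3):
            col = p1.A[:, l]
            assert col[np.argmax(np.abs(col))] >= 0

    def test_rank_too_large_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            svd_init(np.zeros((3, 2)), 3)


# ------------------------------------------------------------ objective


class TestObjective:
    def test_all_zero_inputs(self):
        p = HyperParams(k=1, lambda_l=1.0, lambda_d=1.0, lambda_t=1.0)
        z = np.zeros
        assert objective(z((2, 2)), z((2, 1)), z((2, 1)), z((2, 2)), z((2, 2)), p) == 0.0

    def test_vanishing_residuals(self):
        rng = np.random.default_rng(2)
        A, B = rng.normal(size=(4, 2)), rng.normal(size=(3, 2))
        p = HyperParams(k=2, lambda_l=0.0, lambda_d=2.0, lambda_t=3.0)
        val = objective(A @ B.T, A, B, A @ A.T, B @ B.T, p)
        assert val == pytest.approx(0.0, abs=1e-20)

    def test_hand_case(self):
        p = HyperParams(k=1, lambda_l=1.0, lambda_d=0.0, lambda_t=0.0)
        val = objective(np.array([[1.0]]), np.array([[1.0]]), np.array([[0.0]]), np.zeros((1, 1)), np.zeros((1, 1)), p)
        assert val == pytest.approx(2.0)  # residual 1 + ||A||^2 = 1

    def test_shape_mismatch_rejected(self):
        p = HyperParams(k=1)
        with pytest.raises(ValueError):
            objective(np.zeros((2, 2)), np.zeros((3, 1)), np.zeros((2, 1)), np.zeros((3, 3)), np.zeros((2, 2)), p)


# -------------------------------------------------------------- als_step


class TestAlsStep:
    def test_fixed_point_when_unregularized_and_exact(self):
        rng = np.random.default_rng(3)
        A0 = rng.normal(size=(6, 2))
        B0 = rng.normal(size=(5, 2))
        Y = A0 @ B0.T
        p = HyperParams(k=2, lambda_l=0.0, lambda_d=0.0, lambda_t=0.0)
        A1, B1 = als_step(Y, A0, B0, np.zeros((6, 6)), np.zeros((5, 5)), p)
        np.testing.assert_allclose(A1, A0, atol=1e-10)
        np.testing.assert_allclose(B1, B0, atol=1e-10)

    def test_pure_ridge_shrinks_factors(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(5, 2))
        B = rng.normal(size=(4, 2))
        p = HyperParams(k=2, lambda_l=0.5, lambda_d=0.0, lambda_t=0.0)
        A1, B1 = als_step(np.zeros((5, 4)), A, B, np.zeros((5, 5)), np.zeros((4, 4)), p)
        assert np.linalg.norm(A1) < np.linalg.norm(A)
        assert np.linalg.norm(B1) < np.linalg.norm(B)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_independent_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        Y, A, B, Rm, Rd = random_instance(rng)
        lam_l, lam_d, lam_t = rng.random(3)
        p = HyperParams(k=3, lambda_l=lam_l, lambda_d=lam_d, lambda_t=lam_t)
        A1, B1 = als_step(Y, A, B, Rm, Rd, p)
        A_ref, B_ref = brute_force_als_step(Y, A, B, Rm, Rd, lam_l, lam_d, lam_t)
        np.testing.assert_allclose(A1, A_ref, atol=1e-10)
        np.testing.assert_allclose(B1, B_ref, atol=1e-10)

    def test_singular_system_gets_jitter(self):
        # B = 0 with no regularization makes the k x k system singular;
        # jitter keeps the step defined instead of raising immediately
        p = HyperParams(k=2, lambda_l=0.0, lambda_d=0.0, lambda_t=1.0)
        A = np.ones((3, 2))
        B = np.zeros((4, 2))
        A1, B1 = als_step(np.zeros((3, 4)), A, B, np.zeros((3, 3)), np.eye(4), p)
        assert np.isfinite(A1).all() and np.isfinite(B1).all()


# ----------------------------------------------------------- fit_factors


class TestFitFactors:
    def test_max_iter_validation(self):
        with pytest.raises(ValueError):
            HyperParams(k=2, max_iter=0)

    def test_single_iteration_contract(self):
        rng = np.random.default_rng(5)
        Y = (rng.random((6, 5)) < 0.4).astype(float)
        p = HyperParams(k=2, max_iter=1, tol=1e-300)
        pair = fit_factors(Y, np.zeros((6, 6)), np.zeros((5, 5)), p)
        assert pair.iterations_run == 1
        assert len(pair.objective_trace) == 2

    def test_exact_recovery_of_planted_rank2(self):
        rng = np.random.default_rng(6)
        A0 = rng.normal(size=(12, 2))
        B0 = rng.normal(size=(9, 2))
        Y = A0 @ B0.T
        p = HyperParams(k=2, lambda_l=0.0, lambda_d=0.0, lambda_t=0.0, max_iter=100)
        pair = fit_factors(Y, np.zeros((12, 12)), np.zeros((9, 9)), p)
        rel = np.linalg.norm(Y - pair.scores) / np.linalg.norm(Y)
        assert rel < 1e-6

    def test_trace_finite_and_right_length(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            Y, _, _, Rm, Rd = random_instance(rng)
            p = HyperParams(k=2, lambda_l=0.3, lambda_d=0.05, lambda_t=0.05, max_iter=30)
            pair = fit_factors(Y, Rm, Rd, p)
            trace = np.array(pair.objective_trace)
            assert np.isfinite(trace).all()
            assert len(trace) == pair.iterations_run + 1

    def test_bit_reproducible(self):
        rng = np.random.default_rng(8)
        Y, _, _, Rm, Rd = random_instance(rng, n=8, m=7)
        p = HyperParams(k=3, lambda_l=0.5, lambda_d=0.1, lambda_t=0.1)
        p1 = fit_factors(Y, Rm, Rd, p)
        p2 = fit_factors(Y, Rm, Rd, p)
        np.testing.assert_array_equal(p1.A, p2.A)
        np.testing.assert_array_equal(p1.B, p2.B)

    def test_objective_mostly_nonincreasing_after_burn_in(self):
        # the updates are fixed-point, not exact minimizers: monotonicity
        # is checked as a soft property across instances
        rng = np.random.default_rng(9)
        good = 0
        n_instances = 20
        for _ in range(n_instances):
            Y, _, _, Rm, Rd = random_instance(rng, n=8, m=6)
            p = HyperParams(k=2, lambda_l=0.5, lambda_d=0.05, lambda_t=0.05, max_iter=40)
            trace = np.array(fit_factors(Y, Rm, Rd, p).objective_trace)
            tail = trace[3:]
            if len(tail) < 2 or (np.diff(tail) <= 1e-9 * np.maximum(tail[:-1], 1)).all():
                good += 1
        assert good >= 0.95 * n_instances


# --------------------------------------------------------------- predict


class TestPredict:
    def test_hand_product(self):
        from npcmf.model import FactorPair

        pair = FactorPair(A=np.array([[1.0], [0.0]]), B=np.array([[2.0], [3.0]]))
        np.testing.assert_array_equal(predict(pair), [[2.0, 3.0], [0.0, 0.0]])

    def test_orthogonal_rotation_invariance(self):
        from npcmf.model import FactorPair
        from scipy.stats import ortho_group

        rng = np.random.default_rng(10)
        A = rng.normal(size=(5, 3))
        B = rng.normal(size=(4, 3))
        Q = ortho_group.rvs(3, random_state=11)
        p1 = FactorPair(A=A, B=B)
        p2 = FactorPair(A=A @ Q, B=B @ Q)
        np.testing.assert_allclose(predict(p1), predict(p2), atol=1e-12)


# ------------------------------------------------------ model / results


@pytest.fixture(scope="module")
def fitted(default_synthetic):
    d = default_synthetic
    model = NPCMF(
        d.observed, d.sim_mirna, d.sim_disease, params=HyperParams(k=10), wknkn_params=WknknParams()
    )
    return model, model.fit()


class TestNPCMFModel:
    def test_scores_shape_and_summary(self, fitted):
        model, res = fitted
        assert res.scores.shape == model.Y.shape
        text = res.summary()
        assert "NPCMF" in text and "rank k" in text and "iterations" in text

    def test_fit_overrides_do_not_mutate_model(self, fitted):
        model, _ = fitted
        res2 = model.fit(regularizer_mode="semantic", max_iter=5)
        assert res2.params.regularizer_mode == "semantic"
        assert model.params.regularizer_mode == "nearest_profile"

    def test_rank_for_disease_flags_known(self, fitted):
        model, res = fitted
        j = 0
        table = res.rank_for_disease(model.Y.index.disease_ids[j], top_k=10).to_frame()
        assert len(table) == 10
        known_ids = {
            model.Y.index.mirna_ids[i] for i in np.flatnonzero(model.Y.values[:, j] == 1)
        }
        for _, row in table.iterrows():
            assert row["known"] == (row["miRNA"] in known_ids)

    def test_dag_derived_disease_similarity(self, default_synthetic):
        d = default_synthetic
        model = NPCMF(d.observed, d.sim_mirna, dag=d.dag, params=HyperParams(k=5, max_iter=5))
        assert model.sim_disease is not None
        np.testing.assert_allclose(np.diag(model.sim_disease), 1.0)

    def test_semantic_mode_requires_similarities(self, default_synthetic):
        d = default_synthetic
        model = NPCMF(d.observed, params=HyperParams(k=5, regularizer_mode="semantic"))
        with pytest.raises(ValueError, match="semantic"):
            model.fit()

    def test_rank_validation_through_hyperparams(self):
        p = HyperParams(k=10)
        with pytest.raises(ValueError, match="rank"):
            p.resolve_k(4, 4)
        assert dataclasses.replace(p, k=None).resolve_k(100, 80) == 50
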