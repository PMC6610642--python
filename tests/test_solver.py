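"""Objective, initialization, alternating updates, fit, predict, model IO."""

import numpy as np
import pytest

import wgrmf as w
from wgrmf.graph import build_pnn_graph, laplacians, sparsify
from wgrmf.similarity import ValidationError
from wgrmf.solver import initialize, objective, update_sweep
from conftest import tiny_problem


def summation_form_objective(rm, lf, Ld, Lc, hp):
    """Independent recomputation via the explicit double sums, using the
    identity Tr(AᵀL̃A) = Σ_{i,r} L̃(i,r)·⟨a_i, a_r⟩."""
    A, B = lf.A, lf.B
    n, m = rm.shape
    total = 0.0
    for i in range(n):
        for j in range(m):
            if rm.W[i, j] == 1:
                total += (rm.R[i, j] - A[i] @ B[j]) ** 2
    total += hp.lambda_l * (sum(A[i] @ A[i] for i in range(n))
                            + sum(B[j] @ B[j] for j in range(m)))
    total += hp.lambda_d * sum(Ld[i, r] * (A[i] @ A[r])
                               for i in range(n) for r in range(n))
    total += hp.lambda_c * sum(Lc[j, q] * (B[j] @ B[q])
                               for j in range(m) for q in range(m))
    return total


class TestObjective:
    def test_zero_factors_leave_residual_term(self, rng):
        rm, _, _, Ld, Lc = tiny_problem(rng, 4, 5, 2)
        lf = w.LatentFactors(np.zeros((4, 2)), np.zeros((5, 2)),
                             rm.drug_ids, rm.cell_ids)
        hp = w.HyperParams(k=2, lambda_l=0, lambda_d=0, lambda_c=0)
        expected = float(np.sum((rm.W * rm.R) ** 2))
        assert objective(rm, lf, Ld, Lc, hp) == pytest.approx(expected)

    def test_perfect_fit_is_zero(self, rng):
        A = rng.standard_normal((4, 2))
        B = rng.standard_normal((5, 2))
        rm = w.ResponseMatrix([f"d{i}" for i in range(4)],
                              [f"c{j}" for j in range(5)],
                              A @ B.T, np.ones((4, 5)))
        lf = w.LatentFactors(A, B, rm.drug_ids, rm.cell_ids)
        hp = w.HyperParams(k=2, lambda_l=0, lambda_d=0, lambda_c=0)
        assert objective(rm, lf, np.zeros((4, 4)), np.zeros((5, 5)), hp) \
            == pytest.approx(0.0, abs=1e-20)

    def test_matches_summation_form(self, rng):
        """Trace form agrees with the explicit element-wise double sums."""
        for _ in range(5):
            rm, _, _, Ld, Lc = tiny_problem(rng, 5, 6, 2)
            lf = w.LatentFactors(rng.standard_normal((5, 2)),
                                 rng.standard_normal((6, 2)),
                                 rm.drug_ids, rm.cell_ids)
            hp = w.HyperParams(k=2, lambda_l=0.3, lambda_d=0.2, lambda_c=0.4)
            assert objective(rm, lf, Ld, Lc, hp) == pytest.approx(
                summation_form_objective(rm, lf, Ld, Lc, hp), rel=1e-10)

    def test_shape_mismatch(self, rng):
        rm, _, _, Ld, Lc = tiny_problem(rng, 4, 5, 2)
        lf = w.LatentFactors(np.zeros((3, 2)), np.zeros((5, 2)), [], [])
        with pytest.raises(ValidationError):
            objective(rm, lf, Ld, Lc, w.HyperParams(k=2))


class TestInitialize:
    def test_rank1_exact_reconstruction(self, rng):
        u, v = rng.standard_normal(6), rng.standard_normal(8)
        rm = w.ResponseMatrix([f"d{i}" for i in range(6)],
                              [f"c{j}" for j in range(8)],
                              np.outer(u, v), np.ones((6, 8)))
        lf = initialize(rm, k=1)
        np.testing.assert_allclose(lf.A @ lf.B.T, np.outer(u, v), atol=1e-8)

    def test_full_rank_reconstruction(self, rng):
        R = rng.standard_normal((5, 7))
        rm = w.ResponseMatrix([f"d{i}" for i in range(5)],
                              [f"c{j}" for j in range(7)], R, np.ones((5, 7)))
        lf = initialize(rm, k=5)
        assert np.linalg.norm(R - lf.A @ lf.B.T) <= 1e-6 * np.linalg.norm(R)

    @pytest.mark.parametrize("strategy", ["svd", "random"])
    def test_deterministic_given_seed(self, rng, strategy):
        rm, *_ = tiny_problem(rng, 5, 6, 2)
        a = initialize(rm, 2, seed=9, strategy=strategy)
        b = initialize(rm, 2, seed=9, strategy=strategy)
        np.testing.assert_array_equal(a.A, b.A)
        np.testing.assert_array_equal(a.B, b.B)

    def test_k_too_large(self, rng):
        rm, *_ = tiny_problem(rng, 4, 5, 2)
        with pytest.raises(ValidationError):
            initialize(rm, k=5)


class TestUpdateSweep:
    def test_a_rows_solve_per_row_ridge(self, rng):
        """With no graph terms, each updated a_i is the ridge-regression
        solution of the row's observed entries on B (independent oracle)."""
        rm, _, _, Ld, Lc = tiny_problem(rng, 5, 7, 2)
        hp = w.HyperParams(k=2, lambda_l=0.4, lambda_d=0.0, lambda_c=0.0)
        lf = initialize(rm, 2)
        B = lf.B.copy()
        out = update_sweep(rm, lf, Ld, Lc, hp)
        for i in range(5):
            obs = rm.W[i] == 1
            X, y = B[obs], rm.R[i, obs]
            ridge = np.linalg.solve(X.T @ X + hp.lambda_l * np.eye(2), X.T @ y)
            np.testing.assert_allclose(out.A[i], ridge, atol=1e-8)

    def test_projection_onto_orthonormal_basis(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((6, 2)))
        R = rng.standard_normal((4, 6))
        rm = w.ResponseMatrix([f"d{i}" for i in range(4)],
                              [f"c{j}" for j in range(6)], R, np.ones((4, 6)))
        lf = w.LatentFactors(np.zeros((4, 2)), Q, rm.drug_ids, rm.cell_ids)
        hp = w.HyperParams(k=2, lambda_l=0, lambda_d=0, lambda_c=0)
        out = update_sweep(rm, lf, np.zeros((4, 4)), np.zeros((6, 6)), hp)
        np.testing.assert_allclose(out.A, R @ Q, atol=1e-10)

    def test_fixed_point_at_convergence(self, standard_dataset, standard_hp):
        ds = standard_dataset
        hp = w.HyperParams(**{**standard_hp.__dict__, "tol": 1e-12,
                              "max_sweeps": 500})
        lf = w.fit(ds.rm, ds.Sd, ds.Sc, hp)
        Sd = np.clip(ds.Sd.S, 0, None)
        Sc = np.clip(ds.Sc.S, 0, None)
        Ld = laplacians(sparsify(Sd, build_pnn_graph(Sd, hp.p_drug))).L_tilde
        Lc = laplacians(sparsify(Sc, build_pnn_graph(Sc, hp.p_cell))).L_tilde
        again = update_sweep(ds.rm, lf, Ld, Lc, hp)
        assert np.abs(again.A - lf.A).max() < 1e-5
        assert np.abs(again.B - lf.B).max() < 1e-5

    def test_singular_system_names_remedy(self, rng):
        R = rng.standard_normal((3, 4))
        W = np.zeros((3, 4))
        W[0, :2] = 1; W[1, :2] = 1; W[2, :2] = 1
        rm = w.ResponseMatrix(["d0", "d1", "d2"], list("abcd"), R, W)
        lf = w.LatentFactors(np.zeros((3, 3)), np.zeros((4, 3)),
                             rm.drug_ids, rm.cell_ids)
        hp = w.HyperParams(k=3, lambda_l=0.0, lambda_d=0.0, lambda_c=0.0)
        with pytest.raises(ValidationError, match="lambda_l"):
            update_sweep(rm, lf, np.zeros((3, 3)), np.zeros((4, 4)), hp)


class TestFit:
    def test_objective_decreases_and_residual_small(self, rng):
        A = rng.standard_normal((20, 2))
        B = rng.standard_normal((30, 2))
        R = A @ B.T
        rm = w.ResponseMatrix([f"d{i}" for i in range(20)],
                              [f"c{j}" for j in range(30)], R, np.ones((20, 30)))
        ds = w.generate(n=20, m=30, k_true=2, noise_sd=0.0,
                        missing_fraction=0.0, seed=3)
        hp = w.HyperParams(k=2, lambda_l=0.25, lambda_d=0.0, lambda_c=0.0,
                           p_drug=5, p_cell=5)
        lf = w.fit(ds.rm, ds.Sd, ds.Sc, hp)
        traj = lf.objective_trajectory
        assert traj[-1] <= traj[0]
        resid = np.linalg.norm(ds.rm.R - lf.A @ lf.B.T) / np.linalg.norm(ds.rm.R)
        assert resid < 0.05

    def test_converges_with_mask_and_monotone_trajectory(self, rng):
        ds = w.generate(n=20, m=30, k_true=2, noise_sd=0.1,
                        missing_fraction=0.3, seed=11)
        hp = w.HyperParams(k=2, lambda_l=0.5, lambda_d=0.25, lambda_c=0.25,
                           p_drug=5, p_cell=5, max_sweeps=200)
        lf = w.fit(ds.rm, ds.Sd, ds.Sc, hp)
        assert lf.converged and lf.sweeps_run <= 200
        traj = np.array(lf.objective_trajectory)
        assert len(traj) == lf.sweeps_run + 1
        assert (np.diff(traj) <= 1e-8 * np.abs(traj[:-1])).all()

    def test_large_tol_stops_after_one_sweep(self, standard_dataset):
        ds = standard_dataset
        hp = w.HyperParams(k=2, lambda_l=0.25, p_drug=5, p_cell=5, tol=1.0)
        lf = w.fit(ds.rm, ds.Sd, ds.Sc, hp)
        assert lf.sweeps_run == 1
        assert len(lf.objective_trajectory) == 2

    def test_masked_entry_recovery(self, standard_dataset, standard_hp):
        """Predictions on hidden entries track the noiseless truth."""
        ds = standard_dataset
        lf = w.fit(ds.rm, ds.Sd, ds.Sc, standard_hp)
        pred = lf.A @ lf.B.T
        hidden = ds.rm.W == 0
        assert w.pcc(ds.truth_R[hidden], pred[hidden]) >= 0.9
        err = np.abs(pred[hidden] - ds.truth_R[hidden])
        assert np.median(err) < 0.05 * ds.truth_R.std()

    def test_similarity_shape_mismatch(self, standard_dataset):
        ds = standard_dataset
        with pytest.raises(ValidationError):
            w.fit(ds.rm, ds.Sc, ds.Sc, w.HyperParams(k=2, p_drug=5, p_cell=5))

    def test_regularization_monotonicity(self, rng):
        """Larger λl never increases the factor norms at convergence."""
        ds = w.generate(n=15, m=20, k_true=2, noise_sd=0.1,
                        missing_fraction=0.2, seed=5)
        norms = []
        for lam in (0.1, 0.5, 2.0, 8.0):
            hp = w.HyperParams(k=2, lambda_l=lam, lambda_d=0.125,
                               lambda_c=0.125, p_drug=4, p_cell=4,
                               tol=1e-10, max_sweeps=500)
            lf = w.fit(ds.rm, ds.Sd, ds.Sc, hp)
            norms.append(float(np.sum(lf.A**2) + np.sum(lf.B**2)))
        assert all(b <= a + 1e-9 for a, b in zip(norms, norms[1:]))

    def test_graph_term_pulls_neighbors_together(self, rng):
        """A strong drug-graph penalty shrinks latent distances between
        similar drugs relative to the unregularized fit."""
        ds = w.generate(n=15, m=20, k_true=2, noise_sd=0.2,
                        missing_fraction=0.2, seed=8)
        Sd = np.clip(ds.Sd.S, 0, None)
        S_hat = sparsify(Sd, build_pnn_graph(Sd, 4)).S_hat

        def mean_pair_distance(lf):
            pairs = np.argwhere(S_hat > 0)
            return np.mean([np.linalg.norm(lf.A[i] - lf.A[r]) for i, r in pairs])

        base = w.HyperParams(k=2, lambda_l=0.25, lambda_d=0.0, lambda_c=0.0,
                             p_drug=4, p_cell=4, tol=1e-9, max_sweeps=500)
        strong = w.HyperParams(k=2, lambda_l=0.25, lambda_d=8.0, lambda_c=0.0,
                               p_drug=4, p_cell=4, tol=1e-9, max_sweeps=500)
        d0 = mean_pair_distance(w.fit(ds.rm, ds.Sd, ds.Sc, base))
        d1 = mean_pair_distance(w.fit(ds.rm, ds.Sd, ds.Sc, strong))
        assert d1 < d0

    def test_bit_identical_trajectories(self, standard_dataset, standard_hp):
        ds = standard_dataset
        a = w.fit(ds.rm, ds.Sd, ds.Sc, standard_hp)
        b = w.fit(ds.rm, ds.Sd, ds.Sc, standard_hp)
        assert a.objective_trajectory == b.objective_trajectory
        np.testing.assert_array_equal(a.A, b.A)
        np.testing.assert_array_equal(a.B, b.B)


class TestPredict:
    def test_identity_factors(self, rng):
        B = rng.standard_normal((5, 4))
        lf = w.LatentFactors(np.eye(4), B, [f"d{i}" for i in range(4)],
                             [f"c{j}" for j in range(5)])
        np.testing.assert_allclose(w.predict(lf).to_numpy(), B.T)

    def test_outer_product(self):
        a, b = np.array([1.0, 2.0]), np.array([3.0, 4.0, 5.0])
        lf = w.LatentFactors(a[:, None], b[:, None], ["d0", "d1"],
                             ["c0", "c1", "c2"])
        np.testing.assert_allclose(w.predict(lf).to_numpy(), np.outer(a, b))

    def test_labels_attached(self, standard_dataset, standard_hp):
        ds = standard_dataset
        lf = w.fit(ds.rm, ds.Sd, ds.Sc, standard_hp)
        df = w.predict(lf)
        assert list(df.index) == ds.rm.drug_ids
        assert list(df.columns) == ds.rm.cell_ids


def test_model_roundtrip(tmp_path, standard_dataset, standard_hp):
    ds = standard_dataset
    lf = w.fit(ds.rm, ds.Sd, ds.Sc, standard_hp)
    path = tmp_path / "model.json"
    w.save_model(lf, standard_hp, path)
    lf2, hp2 = w.load_model(path)
    np.testing.assert_array_equal(lf.A, lf2.A)
    np.testing.assert_array_equal(lf.B, lf2.B)
    assert lf2.drug_ids == lf.drug_ids and lf2.cell_ids == lf.cell_ids
    assert lf2.objective_trajectory == lf.objective_trajectory
    assert hp2 == standard_hp
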