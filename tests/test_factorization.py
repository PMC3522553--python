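"""Objective, gradients, descent dynamics and prediction of the joint
factorization, each checked against an independent route (scalar loops,
central finite differences, a hand-rolled single-matrix descent)."""

import numpy as np
import pytest

from cmfqsar import (
    ActivityTable,
    CMFImputer,
    FactorModel,
    FitConfig,
    fit_cmf,
    gradients,
    init_factors,
    objective_basic,
    objective_cmf,
    predict,
    simulate_lowrank,
)


def _loop_objective(model, x, y):
    """Element-wise scalar re-evaluation of the joint objective."""
    U, V, W = model.U, model.V, model.W
    total = 0.0
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            if x.mask[i, j]:
                total += 0.5 * (x.values[i, j] - float(U[i] @ V[j])) ** 2
    for i in range(y.shape[0]):
        for j in range(y.shape[1]):
            total += 0.5 * model.lambda1 * (
                y.values[i, j] - float(U[i] @ W[j])) ** 2
    for M in (U, V, W):
        total += 0.5 * model.lambda2 * float((M ** 2).sum())
    return total


def _fd_gradients(model, x, y, h=1e-6):
    out = []
    for name in ("U", "V", "W"):
        M = getattr(model, name)
        g = np.zeros_like(M)
        for i in range(M.shape[0]):
            for j in range(M.shape[1]):
                up, dn = model.copy(), model.copy()
                getattr(up, name)[i, j] += h
                getattr(dn, name)[i, j] -= h
                g[i, j] = (objective_cmf(up, x, y)
                           - objective_cmf(dn, x, y)) / (2 * h)
        out.append(g)
    return out


class TestInit:
    def test_deterministic_per_seed(self):
        a = init_factors(5, 4, 3, 2, FitConfig(seed=9))
        b = init_factors(5, 4, 3, 2, FitConfig(seed=9))
        np.testing.assert_array_equal(a.U, b.U)
        np.testing.assert_array_equal(a.W, b.W)

    def test_zero_scale_gives_zero_factors(self):
        m = init_factors(5, 4, 3, 2, FitConfig(seed=0, init_scale=0.0))
        assert not m.U.any() and not m.V.any() and not m.W.any()

    def test_d_exceeding_min_dimension_rejected(self):
        with pytest.raises(ValueError, match="latent dimension"):
            init_factors(5, 4, 3, 4)


class TestObjectives:
    def test_basic_hand_example(self):
        # residuals [[0,1],[2,3]] -> 14, plus ||U||_F^2 = ||V||_F^2 = 2
        X = ActivityTable(["a", "b"], ["s", "t"],
                          [[1, 2], [3, 4]], np.ones((2, 2)))
        val = objective_basic([[1.0], [1.0]], [[1.0], [1.0]], X, 1.0, 1.0)
        assert val == pytest.approx(18.0)

    def test_basic_zero_factors_sum_of_squares(self, tiny_tables):
        x, _ = tiny_tables
        U = np.zeros((4, 2))
        V = np.zeros((3, 2))
        expected = float((x.mask * x.values ** 2).sum())
        assert objective_basic(U, V, x) == pytest.approx(expected)

    def test_cmf_exact_joint_fit_is_zero(self):
        rng = np.random.default_rng(0)
        U, V, W = (np.abs(rng.standard_normal(s))
                   for s in ((5, 2), (3, 2), (4, 2)))
        x = ActivityTable([f"c{i}" for i in range(5)],
                          [f"t{i}" for i in range(3)],
                          U @ V.T, np.ones((5, 3)))
        m = FactorModel(U, V, W, lambda1=1.0, lambda2=0.0)
        from cmfqsar import DescriptorTable
        y = DescriptorTable([f"c{i}" for i in range(5)],
                            [f"f{i}" for i in range(4)], U @ W.T)
        assert objective_cmf(m, x, y) == pytest.approx(0.0, abs=1e-20)

    @pytest.mark.parametrize("seed", range(4))
    def test_cmf_matches_scalar_loop(self, seed):
        x, y, _ = simulate_lowrank(4, 3, 2, 2, 0.2, 0.2, 0.25, seed=seed)
        m = init_factors(4, 3, 2, 2, FitConfig(seed=seed), 0.4, 0.2)
        assert objective_cmf(m, x, y) == pytest.approx(
            _loop_objective(m, x, y), rel=1e-12)

    def test_shape_mismatch_rejected(self, tiny_tables):
        x, y = tiny_tables
        m = init_factors(5, 3, 2, 2)
        with pytest.raises(ValueError):
            objective_cmf(m, x, y)


class TestGradients:
    @pytest.mark.parametrize("seed", range(6))
    def test_match_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        m, n, r, d = (int(rng.integers(4, 11)), int(rng.integers(2, 5)),
                      int(rng.integers(2, 7)), int(rng.integers(1, 3)))
        d = min(d, m, n, r)
        x, y, _ = simulate_lowrank(m, n, r, d, 0.2, 0.2, 0.2, seed=seed)
        mdl = init_factors(m, n, r, d, FitConfig(seed=seed), 0.7, 0.3)
        ana = gradients(mdl, x, y)
        num = _fd_gradients(mdl, x, y)
        for a, b in zip(ana, num):
            np.testing.assert_allclose(a, b, rtol=1e-5, atol=1e-7)

    def test_zero_at_exact_joint_fit(self):
        rng = np.random.default_rng(1)
        U, V, W = (np.abs(rng.standard_normal(s))
                   for s in ((5, 2), (3, 2), (4, 2)))
        from cmfqsar import DescriptorTable
        x = ActivityTable([f"c{i}" for i in range(5)],
                          [f"t{i}" for i in range(3)],
                          U @ V.T, np.ones((5, 3)))
        y = DescriptorTable([f"c{i}" for i in range(5)],
                            [f"f{i}" for i in range(4)], U @ W.T)
        mdl = FactorModel(U, V, W, lambda1=2.5, lambda2=0.0)
        for g in gradients(mdl, x, y):
            np.testing.assert_allclose(g, 0.0, atol=1e-12)

    def test_empty_mask_no_data_term_in_v(self, tiny_tables):
        x, y = tiny_tables
        x = x.copy()
        x.mask[:] = 0
        mdl = init_factors(4, 3, 2, 2, FitConfig(seed=0), 0.0, 0.0)
        _, gV, _ = gradients(mdl, x, y)
        np.testing.assert_array_equal(gV, 0.0)


class TestFit:
    def test_noiseless_recovery_collapses_objective(self):
        x, y, _ = simulate_lowrank(30, 4, 6, 2, 0.0, 0.0, 0.0, seed=3)
        m0 = init_factors(30, 4, 6, 2, FitConfig(seed=3), 1.0, 1e-6)
        fitted, trace = fit_cmf(x, y, m0, FitConfig(
            max_iter=3000, tol=1e-10, seed=3))
        assert trace.objective_per_iter[-1] < 1e-4 * trace.objective_per_iter[0]

    def test_single_iteration_records_one_step(self, tiny_tables):
        x, y = tiny_tables
        m0 = init_factors(4, 3, 2, 2, FitConfig(seed=0))
        _, trace = fit_cmf(x, y, m0, FitConfig(max_iter=1, seed=0))
        assert len(trace.step_sizes) == 1
        assert trace.stop_reason == "max_iter"

    def test_trace_non_increasing(self, tiny_tables):
        x, y = tiny_tables
        m0 = init_factors(4, 3, 2, 2, FitConfig(seed=5))
        _, trace = fit_cmf(x, y, m0, FitConfig(max_iter=200, seed=5))
        obj = np.array(trace.objective_per_iter)
        assert (np.diff(obj) <= 0).all()
        assert trace.stop_reason in ("max_iter", "tol_reached",
                                     "line_search_stalled")

    def test_row_permutation_symmetry(self):
        x, y, _ = simulate_lowrank(8, 3, 4, 2, 0.1, 0.1, 0.2, seed=11)
        m0 = init_factors(8, 3, 4, 2, FitConfig(seed=11))
        fit_a, tr_a = fit_cmf(x, y, m0, FitConfig(max_iter=60, seed=11))
        perm = np.random.default_rng(0).permutation(8)
        xp = ActivityTable([x.compound_ids[i] for i in perm],
                           x.cellline_ids, x.values[perm], x.mask[perm])
        from cmfqsar import DescriptorTable
        yp = DescriptorTable([y.compound_ids[i] for i in perm],
                             y.feature_names, y.values[perm])
        m0p = m0.copy()
        m0p.U = m0.U[perm]
        fit_b, tr_b = fit_cmf(xp, yp, m0p, FitConfig(max_iter=60, seed=11))
        np.testing.assert_allclose(tr_a.objective_per_iter,
                                   tr_b.objective_per_iter, rtol=1e-12)
        np.testing.assert_allclose(fit_a.U[perm], fit_b.U, rtol=1e-9)

    def test_reduces_to_single_matrix_descent_when_lambda1_zero(self):
        """With lambda1=0 and W0=0 the iterates equal a hand-rolled
        descent on the unscaled single-matrix objective whose line
        search starts at step 1/2 (the joint objective carries a global
        1/2 factor)."""
        x, y, _ = simulate_lowrank(6, 3, 4, 2, 0.1, 0.1, 0.2, seed=2)
        lam = 0.3
        m0 = init_factors(6, 3, 4, 2, FitConfig(seed=2), 0.0, lam)
        m0.W[:] = 0.0
        tol = 1e-9
        fitted, trace = fit_cmf(x, y, m0, FitConfig(max_iter=40, tol=tol,
                                                    seed=2))
        assert not fitted.W.any()

        U, V = m0.U.copy(), m0.V.copy()
        X, mask = x.values, x.mask

        def L3(U, V):
            R = mask * (X - U @ V.T)
            return float((R * R).sum() + lam * (U * U).sum()
                         + lam * (V * V).sum())

        objs = [0.5 * L3(U, V)]
        L = L3(U, V)
        for _ in range(40):
            E = mask * (U @ V.T - X)
            gU = 2 * (E @ V) + 2 * lam * U
            gV = 2 * (E.T @ U) + 2 * lam * V
            gamma = 0.5
            while L3(U - gamma * gU, V - gamma * gV) >= L:
                gamma /= 2
            U, V = U - gamma * gU, V - gamma * gV
            dec = L - L3(U, V)
            L = L3(U, V)
            objs.append(0.5 * L)
            if 0.5 * dec <= tol:
                break
        np.testing.assert_allclose(trace.objective_per_iter, objs, rtol=1e-12)
        np.testing.assert_allclose(fitted.U, U, rtol=1e-10)


class TestPredictAndSerialize:
    def test_rank_one_outer_product(self):
        m = FactorModel([[2.0], [3.0]], [[1.0], [4.0]], [[0.0]])
        np.testing.assert_array_equal(predict(m), [[2, 8], [3, 12]])

    def test_zero_factors_zero_matrix(self):
        m = FactorModel(np.zeros((3, 2)), np.zeros((2, 2)), np.zeros((2, 2)))
        assert not predict(m).any()

    def test_heldout_error_after_noiseless_fit(self):
        x, y, truth = simulate_lowrank(60, 4, 10, 2, 0.0, 0.0,
                                       [0.3, 0, 0, 0], seed=1)
        est = CMFImputer(n_components=2, lambda1=1.0, lambda2=1e-6,
                         max_iter=4000, tol=1e-10, random_state=1).fit(x, y)
        held = x.mask == 0
        err = (est.predict() - truth.U @ truth.V.T)[held]
        assert np.abs(err).max() < 1e-2

    def test_json_roundtrip_exact(self, tmp_path):
        m = init_factors(5, 3, 4, 2, FitConfig(seed=8), 0.25, 0.5)
        p = tmp_path / "model.json"
        m.to_json(p)
        back = FactorModel.from_json(p)
        np.testing.assert_array_equal(back.U, m.U)
        np.testing.assert_array_equal(back.V, m.V)
        np.testing.assert_array_equal(back.W, m.W)
        assert back.lambda1 == m.lambda1 and back.d == m.d


class TestEstimatorAPI:
    def test_get_set_params_roundtrip(self):
        est = CMFImputer(n_components=2, lambda1=0.5)
        params = est.get_params()
        assert params["lambda1"] == 0.5
        est.set_params(lambda2=9.0)
        assert est.lambda2 == 9.0

    def test_transform_keeps_observed_and_fills_missing(self, tiny_tables):
        x, y = tiny_tables
        est = CMFImputer(n_components=2, max_iter=50, random_state=0)
        filled = est.fit(x, y).transform(x)
        obs = x.mask.astype(bool)
        np.testing.assert_array_equal(filled[obs], x.values[obs])
        assert filled[1, 2] == est.predict()[1, 2]
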