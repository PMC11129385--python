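"""Score-based structure learners: score, proximal L1, constrained AL, MTL."""

import numpy as np
import pytest

import metadag as md
from metadag.solvers import (
    SolverConfig,
    fit_joint_mtl,
    fit_notears_l1,
    fit_unconstrained_l1,
    joint_mtl_objective,
    score,
)

TIGHT = SolverConfig(inner_iterations=400)


def make_task(d, edges, n, seed, weight_range=(0.5, 2.0)):
    g = md.sample_dag("ER", d, edges, seed)
    truth = md.assign_weights(g, weight_range, seed + 1000)
    return md.simulate_linear_sem(truth, n, 1.0, seed + 2000), g


def all_3node_dags():
    arcs = [(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)]
    out = []
    for mask in range(64):
        e = np.zeros((3, 3), dtype=bool)
        for k, (i, j) in enumerate(arcs):
            if mask >> k & 1:
                e[i, j] = True
        g = md.BinaryGraph(e)
        if md.is_dag(g):
            out.append(g)
    return out


def best_dag_by_enumeration(X, lam=0.1):
    """Exhaustive oracle: per-DAG least squares over all 25 3-node DAGs."""
    best, best_j = None, np.inf
    for g in all_3node_dags():
        w = np.zeros((3, 3))
        for j in range(3):
            pa = np.nonzero(g.edges[:, j])[0]
            if len(pa):
                w[pa, j] = np.linalg.lstsq(X[:, pa], X[:, j], rcond=None)[0]
        val = score(X, md.WeightedGraph(w), lam)
        if val < best_j:
            best_j, best = val, g
    return best


class TestScore:
    def test_zero_graph(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(7, 3))
        g = md.WeightedGraph(np.zeros((3, 3)))
        assert score(X, g, 0.0) == pytest.approx(0.5 / 7 * np.sum(X**2))

    def test_hand_evaluated_example(self):
        X = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        w = np.zeros((2, 2))
        w[0, 1] = 2.0  # column 2 = 2 * column 1 exactly
        assert score(X, md.WeightedGraph(w), 0.0) == pytest.approx(14 / 6)

    def test_l1_additivity(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 4))
        w = np.abs(rng.normal(size=(4, 4)))
        np.fill_diagonal(w, 0.0)
        lam, delta = 0.3, 0.17
        base = score(X, md.WeightedGraph(w), lam)
        w2 = w.copy()
        w2[0, 1] += delta
        bumped = score(X, md.WeightedGraph(w2), lam)
        resid_change = bumped - base - lam * delta
        # remaining change is the smooth residual part; L1 part is exact
        w3 = w.copy()
        w3[0, 1] += delta
        r2 = score(X, md.WeightedGraph(w3), 0.0) - score(X, md.WeightedGraph(w), 0.0)
        assert resid_change == pytest.approx(r2, abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            score(np.zeros((5, 3)), md.WeightedGraph(np.zeros((4, 4))), 0.1)


class TestUnconstrained:
    def test_closed_form_collinear_columns(self):
        X = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        fit = fit_unconstrained_l1(
            X, cfg=SolverConfig(lambda1=0.0, inner_iterations=5000)
        )
        assert fit.graph.weights[0, 1] == pytest.approx(2.0, abs=1e-4)
        assert fit.graph.weights[1, 0] == pytest.approx(0.5, abs=1e-4)
        assert fit.objective_value < 1e-8

    def test_large_lambda_shrinks_to_zero(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 4))
        n = X.shape[0]
        lam_max = np.abs(X.T @ X / n).max()
        fit = fit_unconstrained_l1(X, cfg=SolverConfig(lambda1=2 * lam_max))
        assert np.all(fit.graph.weights == 0.0)

    def test_objective_not_above_init(self):
        task, _ = make_task(8, 16, 100, 5)
        init = md.WeightedGraph(np.random.default_rng(0).normal(size=(8, 8)) * 0.2
                                * (1 - np.eye(8)))
        cfg = SolverConfig()
        fit = fit_unconstrained_l1(task, init=init, cfg=cfg)
        assert fit.objective_value <= score(task.X, init, cfg.lambda1) + 1e-9

    def test_permutation_equivariance_exact(self):
        task, _ = make_task(6, 12, 200, 6)
        rng = np.random.default_rng(3)
        perm = rng.permutation(6)
        cfg = SolverConfig(inner_iterations=200)
        f1 = fit_unconstrained_l1(task.X, cfg=cfg)
        f2 = fit_unconstrained_l1(task.X[:, perm], cfg=cfg)
        np.testing.assert_allclose(
            f1.graph.weights[np.ix_(perm, perm)], f2.graph.weights, atol=1e-12
        )


class TestConstrained:
    def test_three_node_matches_enumeration(self, jit_warm):
        rng = np.random.default_rng(7)
        agree = 0
        for _ in range(30):
            perm = rng.permutation(3)
            w = np.zeros((3, 3))
            w[perm[0], perm[1]] = rng.uniform(0.5, 2) * rng.choice([-1, 1])
            w[perm[1], perm[2]] = rng.uniform(0.5, 2) * rng.choice([-1, 1])
            task = md.simulate_linear_sem(
                md.WeightedGraph(w), 1000, 1.0, int(rng.integers(2**31))
            )
            fit = fit_notears_l1(task)
            pred = md.threshold_graph(fit.graph, 0.3)
            oracle = best_dag_by_enumeration(task.X)
            agree += np.array_equal(pred.edges, oracle.edges)
        assert agree >= 27  # >= 90%

    def test_converged_residual_within_tolerance(self, jit_warm):
        cfg = SolverConfig()
        for seed in range(5):
            task, _ = make_task(8, 16, 200, seed)
            fit = fit_notears_l1(task, cfg=cfg)
            if fit.converged:
                assert fit.acyclicity_residual <= cfg.h_tolerance
            assert md.is_dag(md.threshold_graph(fit.graph, cfg.threshold_tau))

    def test_structure_recovery_sparse_graphs(self, jit_warm):
        # ER graph with d edges, N=500: near-perfect recovery expected
        ok = 0
        for seed in range(20):
            task, g = make_task(10, 10, 500, seed + 100)
            fit = fit_notears_l1(task)
            shd = md.structural_hamming_distance(
                md.threshold_graph(fit.graph, 0.3), g
            )
            ok += shd <= 3
        assert ok >= 16  # >= 80%

    def test_warm_start_not_worse_than_cold(self, jit_warm):
        # the warm-start premise: initializing at the true graph must not
        # end meaningfully above the cold-start objective
        wins = 0
        for seed in range(50):
            g = md.sample_dag("ER", 10, 30, seed + 1)
            truth = md.assign_weights(g, (0.5, 2.0), seed + 51)
            task = md.simulate_linear_sem(truth, 50, 1.0, seed + 101)
            warm = fit_notears_l1(task, init=truth, cfg=TIGHT)
            cold = fit_notears_l1(task, cfg=TIGHT)
            wins += warm.objective_value <= cold.objective_value + 1e-3
        assert wins >= 40  # >= 80% of replicates

    def test_permutation_equivariance_structure(self, jit_warm):
        task, _ = make_task(8, 16, 1000, 11)
        perm = np.random.default_rng(3).permutation(8)
        cfg = SolverConfig(inner_iterations=2000, inner_pgtol=1e-9)
        f1 = fit_notears_l1(task.X, cfg=cfg)
        f2 = fit_notears_l1(task.X[:, perm], cfg=cfg)
        w1p = f1.graph.weights[np.ix_(perm, perm)]
        # thresholded structure is permutation-equivariant; weights agree
        # to the solver's path-dependent resolution
        assert np.array_equal(np.abs(w1p) > 0.3, np.abs(f2.graph.weights) > 0.3)
        np.testing.assert_allclose(w1p, f2.graph.weights, atol=0.01)

    def test_nnz_monotone_in_lambda(self, jit_warm):
        task, _ = make_task(8, 16, 500, 13)
        nnzs = []
        for lam in (0.02, 0.05, 0.1, 0.3, 0.6):
            fit = fit_notears_l1(task, cfg=SolverConfig(lambda1=lam))
            nnzs.append(md.threshold_graph(fit.graph, 0.3).n_edges)
        assert all(a >= b for a, b in zip(nnzs, nnzs[1:]))

    def test_nonconvergence_returns_result(self, jit_warm):
        task, _ = make_task(8, 16, 100, 17)
        cfg = SolverConfig(inner_iterations=2, max_outer_al=2)
        fit = fit_notears_l1(task, cfg=cfg)  # must not raise
        assert fit.converged in (True, False)


class TestJointMTL:
    def test_single_task_large_delta_penalty_matches_single_fit(self, jit_warm):
        g = md.sample_dag("ER", 6, 10, 5)
        truth = md.assign_weights(g, (0.5, 2.0), 6)
        task = md.simulate_linear_sem(truth, 200, 1.0, 7, task_id="t0")
        cfg = SolverConfig(inner_iterations=400, inner_pgtol=1e-7)
        w0, per = fit_joint_mtl([task], cfg=cfg, delta_penalty=1e6)
        single = fit_notears_l1(task, cfg=cfg)
        assert np.abs(per[0].weights - w0.weights).max() < 1e-6  # delta -> 0
        assert np.abs(w0.weights - single.graph.weights).max() < 1e-3

    def test_identical_tasks_give_identical_graphs(self, jit_warm):
        g = md.sample_dag("ER", 6, 10, 5)
        truth = md.assign_weights(g, (0.5, 2.0), 6)
        base = md.simulate_linear_sem(truth, 100, 1.0, 7)
        tasks = [
            md.TaskDataset(base.X, truth=truth, task_id=f"c{i}") for i in range(3)
        ]
        _, per = fit_joint_mtl(tasks)
        for p in per[1:]:
            assert np.abs(p.weights - per[0].weights).max() < 1e-3

    def test_joint_objective_beats_stacked_independent_fits(self, jit_warm):
        tasks = []
        for s in range(3):
            g = md.sample_dag("ER", 6, 10, s + 10)
            truth = md.assign_weights(g, (0.5, 2.0), s + 20)
            tasks.append(
                md.simulate_linear_sem(truth, 100, 1.0, s + 30, task_id=f"x{s}")
            )
        cfg = SolverConfig()
        w0, per = fit_joint_mtl(tasks, cfg=cfg)
        deltas = [md.WeightedGraph(p.weights - w0.weights) for p in per]
        obj_joint = joint_mtl_objective(tasks, w0, deltas, cfg)
        fits = [fit_notears_l1(t, cfg=cfg) for t in tasks]
        deltas_stacked = [
            md.WeightedGraph(f.graph.weights - w0.weights) for f in fits
        ]
        obj_stacked = joint_mtl_objective(tasks, w0, deltas_stacked, cfg)
        assert obj_joint <= obj_stacked + 1e-9
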