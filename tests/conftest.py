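import numpy as np
import pytest

import metadag as md
from metadag.solvers import SolverConfig


def random_binary_graph(rng: np.random.Generator, d: int, p: float = 0.3) -> md.BinaryGraph:
    """Random directed graph without 2-cycles (direction drawn per pair)."""
    edges = np.zeros((d, d), dtype=bool)
    for i in range(d):
        for j in range(i + 1, d):
            if rng.random() < p:
                if rng.random() < 0.5:
                    edges[i, j] = True
                else:
                    edges[j, i] = True
    return md.BinaryGraph(edges)


def random_dag(rng: np.random.Generator, d: int, p: float = 0.3) -> md.BinaryGraph:
    """Random DAG: edges only forward in a random order."""
    order = rng.permutation(d)
    edges = np.zeros((d, d), dtype=bool)
    for a in range(d):
        for b in range(a + 1, d):
            if rng.random() < p:
                edges[order[a], order[b]] = True
    return md.BinaryGraph(edges)


@pytest.fixture(scope="session")
def jit_warm():
    """Trigger solver JIT compilation once, outside timed assertions."""
    cfg = md.SimulationConfig(d=4, expected_edges=4, n_samples=20, n_tasks=2, seed=0)
    coll = md.generate_task_collection(cfg, 0.5)
    md.fit_notears_l1(coll.test[0], cfg=SolverConfig(inner_iterations=10))
    return True


@pytest.fixture()
def small_collection():
    cfg = md.SimulationConfig(
        d=6, expected_edges=9, n_samples=40, n_tasks=6, task_similarity=0.9, seed=3
    )
    return md.generate_task_collection(cfg, 0.7)
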