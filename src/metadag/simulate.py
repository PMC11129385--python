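"""Synthetic multi-task benchmark generation.

Each task is one patient's structure-learning problem: a ground-truth DAG
and an observation matrix drawn from the linear-Gaussian structural
equation model X[:, j] = X @ W[:, j] + eps_j.  A task collection draws a
base DAG and, per task, perturbs a controllable fraction of its edges, so
the amount of structure shared across patients is an explicit knob
(``task_similarity``; 1 = identical graphs, 0 = independent graphs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Optional

import networkx as nx
import numpy as np

from .graphs import (
    BinaryGraph,
    WeightedGraph,
    is_dag,
    write_adjacency,
)

GraphType = Literal["ER", "SF"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic multi-task benchmark.

    Attributes
    ----------
    graph_type
        "ER" (Erdos-Renyi over a random topological order) or "SF"
        (scale-free preferential attachment, oriented by attachment order).
    d
        Number of variables per graph.
    expected_edges
        Expected edge count; defaults to 3*d.
    n_samples
        Observations N per task.
    n_tasks
        Number of patient tasks M.
    noise_scale
        Standard deviation of the Gaussian SEM noise.
    weight_range
        (low, high) magnitude bounds; edge weights are uniform on
        +-[low, high].
    task_similarity
        Fraction of base-graph edges preserved per task, in [0, 1].
    seed
        Master seed; generation is a pure function of this config.
    """

    graph_type: GraphType = "ER"
    d: int = 10
    expected_edges: Optional[int] = None
    n_samples: int = 50
    n_tasks: int = 50
    noise_scale: float = 1.0
    weight_range: tuple[float, float] = (0.5, 2.0)
    task_similarity: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.expected_edges is None:
            object.__setattr__(self, "expected_edges", 3 * self.d)
        max_edges = self.d * (self.d - 1) // 2
        if not 0 < self.expected_edges <= max_edges:
            raise ValueError(
                f"expected_edges must be in (0, {max_edges}] for d={self.d}, "
                f"got {self.expected_edges}"
            )
        if self.n_samples <= 0 or self.n_tasks <= 0:
            raise ValueError("n_samples and n_tasks must be positive")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")
        low, high = self.weight_range
        if low <= 0 or low > high:
            raise ValueError(f"invalid weight_range {self.weight_range}")
        if not 0.0 <= self.task_similarity <= 1.0:
            raise ValueError("task_similarity must be in [0, 1]")


@dataclass(frozen=True)
class TaskDataset:
    """One patient's observations, optionally paired with the true graph."""

    X: np.ndarray
    truth: Optional[WeightedGraph] = None
    task_id: str = "task"

    def __post_init__(self) -> None:
        x = np.asarray(self.X, dtype=float)
        if x.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if not np.all(np.isfinite(x)):
            raise ValueError(f"task {self.task_id}: X contains non-finite values")
        if self.truth is not None and self.truth.n_nodes != x.shape[1]:
            raise ValueError(
                f"task {self.task_id}: X has {x.shape[1]} columns but truth "
                f"has {self.truth.n_nodes} nodes"
            )
        object.__setattr__(self, "X", x)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_vars(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class TaskCollection:
    """Ordered train/test sets of tasks sharing the same variables."""

    train: tuple[TaskDataset, ...]
    test: tuple[TaskDataset, ...]
    config: Optional[SimulationConfig] = None

    def __post_init__(self) -> None:
        tasks = list(self.train) + list(self.test)
        if not tasks:
            raise ValueError("collection must contain at least one task")
        d = tasks[0].n_vars
        for t in tasks:
            if t.n_vars != d:
                raise ValueError(
                    f"task {t.task_id} has {t.n_vars} variables, expected {d}"
                )
        ids = [t.task_id for t in tasks]
        if len(set(ids)) != len(ids):
            raise ValueError("task_ids must be unique across train and test")
        object.__setattr__(self, "train", tuple(self.train))
        object.__setattr__(self, "test", tuple(self.test))

    @property
    def n_vars(self) -> int:
        return (self.train + self.test)[0].n_vars


def sample_dag(
    graph_type: GraphType, d: int, expected_edges: int, seed: int
) -> BinaryGraph:
    """Draw a random DAG with the requested expected edge count.

    ER mode: draw a uniform random topological order, then include each of
    the d(d-1)/2 forward pairs independently with probability
    ``expected_edges / (d(d-1)/2)`` — acyclic by construction, with the
    exact stated expected edge count.

    SF mode: Barabasi-Albert preferential attachment with
    ``k = round(expected_edges / d)`` attachments per node, edges oriented
    from earlier- to later-attached nodes (expected count ~ k*d for large d).
    """
    max_edges = d * (d - 1) // 2
    if not 0 < expected_edges <= max_edges:
        raise ValueError(
            f"expected_edges={expected_edges} infeasible for d={d} "
            f"(max {max_edges})"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(d)
    adj = np.zeros((d, d), dtype=bool)
    if graph_type == "ER":
        p = expected_edges / max_edges
        upper = rng.random((d, d)) < p
        upper = np.triu(upper, k=1)  # forward in the sampled order
        perm = np.empty_like(order)
        perm[order] = np.arange(d)  # position of node i in the order
        adj = upper[np.ix_(perm, perm)]
    elif graph_type == "SF":
        k = max(1, round(expected_edges / d))
        g = nx.barabasi_albert_graph(d, k, seed=int(rng.integers(2**31)))
        for u, v in g.edges():  # BA node ids follow attachment order
            a, b = (u, v) if u < v else (v, u)
            adj[a, b] = True
        # relabel through a random order so roots are not always node 0
        adj = adj[np.ix_(order, order)]
        perm = np.empty_like(order)
        perm[order] = np.arange(d)
        adj = adj[np.ix_(perm, perm)]
    else:
        raise ValueError(f"unknown graph_type {graph_type!r}")
    np.fill_diagonal(adj, False)
    return BinaryGraph(adj)


def assign_weights(
    g: BinaryGraph, weight_range: tuple[float, float], seed: int
) -> WeightedGraph:
    """Give each edge a weight drawn uniformly from +-[low, high]."""
    low, high = weight_range
    if low <= 0 or low > high:
        raise ValueError(f"invalid weight_range {weight_range}")
    rng = np.random.default_rng(seed)
    d = g.n_nodes
    mag = rng.uniform(low, high, size=(d, d))
    sign = rng.choice([-1.0, 1.0], size=(d, d))
    w = np.where(g.edges, mag * sign, 0.0)
    return WeightedGraph(w, g.node_labels)


def simulate_linear_sem(
    g: WeightedGraph, n_samples: int, noise_scale: float, seed: int,
    task_id: str = "task",
) -> TaskDataset:
    """Sample rows of the linear-Gaussian SEM defined by ``g``.

    Variables are generated in topological order via
    ``X[:, j] = X @ W[:, j] + eps_j`` with i.i.d. Gaussian noise of
    standard deviation ``noise_scale``.
    """
    from .graphs import threshold_graph  # local to avoid cycle at import time

    structure = threshold_graph(g, 0.0)
    nxg = nx.from_numpy_array(structure.edges.astype(int), create_using=nx.DiGraph)
    if not nx.is_directed_acyclic_graph(nxg):
        raise ValueError("graph must be acyclic to simulate a linear SEM")
    order = list(nx.topological_sort(nxg))
    rng = np.random.default_rng(seed)
    d = g.n_nodes
    X = np.zeros((n_samples, d))
    noise = rng.normal(scale=noise_scale, size=(n_samples, d))
    for j in order:
        parents = np.nonzero(g.weights[:, j])[0]
        X[:, j] = X[:, parents] @ g.weights[parents, j] + noise[:, j]
    return TaskDataset(X, truth=g, task_id=task_id)


def _perturb_weighted(
    base: WeightedGraph,
    task_similarity: float,
    weight_range: tuple[float, float],
    rng: np.random.Generator,
    max_retries: int = 100,
) -> WeightedGraph:
    """Rewire each base edge with probability (1 - task_similarity).

    The shared mechanism is weighted: edges the task keeps retain the
    base graph's weights (so the cross-task commonality lives in weight
    space, where the meta-initialization operates); a rewired edge moves
    to a random currently-absent pair and receives a fresh weight.
    Acyclicity is preserved by re-checking after each move.
    """
    low, high = weight_range
    w = base.weights.copy()
    d = base.n_nodes
    edges = list(zip(*np.nonzero(w)))
    for (i, j) in edges:
        if rng.random() >= 1.0 - task_similarity:
            continue
        w[i, j] = 0.0
        # try every currently-free pair in random order; keep the first
        # placement that stays acyclic
        free = [
            (u, v)
            for u in range(d)
            for v in range(d)
            if u != v and w[u, v] == 0.0 and w[v, u] == 0.0
        ]
        placed = False
        order = rng.permutation(len(free))
        for k in order[:max_retries]:
            u, v = free[k]
            w[u, v] = rng.uniform(low, high) * rng.choice([-1.0, 1.0])
            if is_dag(BinaryGraph(w != 0.0, base.node_labels)):
                placed = True
                break
            w[u, v] = 0.0
        if not placed:
            raise RuntimeError(
                "edge rewiring failed to find an acyclic placement "
                f"among {len(free)} free pairs"
            )
    return WeightedGraph(w, base.node_labels)


def generate_task_collection(
    cfg: SimulationConfig, train_fraction: float = 0.8
) -> TaskCollection:
    """Generate the full multi-task benchmark described by ``cfg``.

    One base weighted DAG is drawn; each of the M tasks keeps a fraction
    ``task_similarity`` of its edges with the base weights (the rest are
    rewired and reweighted; at similarity 0 the whole weighted graph is
    redrawn independently — the literal independent-graph-per-patient
    protocol), and is sampled from its own linear SEM.  Tasks are then
    split into train/test by a seeded shuffle.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    if cfg.n_tasks < 2:
        raise ValueError("need at least 2 tasks to split train/test")
    master = np.random.default_rng(cfg.seed)
    base_structure = sample_dag(
        cfg.graph_type, cfg.d, cfg.expected_edges, int(master.integers(2**31))
    )
    base = assign_weights(
        base_structure, cfg.weight_range, int(master.integers(2**31))
    )
    tasks = []
    for m in range(cfg.n_tasks):
        rng = np.random.default_rng(master.integers(2**31))
        if cfg.task_similarity <= 0.0:
            structure = sample_dag(
                cfg.graph_type, cfg.d, cfg.expected_edges,
                int(rng.integers(2**31)),
            )
            truth = assign_weights(
                structure, cfg.weight_range, int(rng.integers(2**31))
            )
        else:
            truth = _perturb_weighted(
                base, cfg.task_similarity, cfg.weight_range, rng
            )
        tasks.append(
            simulate_linear_sem(
                truth, cfg.n_samples, cfg.noise_scale,
                int(rng.integers(2**31)), task_id=f"task{m:03d}",
            )
        )
    split_rng = np.random.default_rng(master.integers(2**31))
    perm = split_rng.permutation(cfg.n_tasks)
    n_train = int(round(train_fraction * cfg.n_tasks))
    n_train = min(max(n_train, 1), cfg.n_tasks - 1)
    train_ids = set(perm[:n_train])
    train = tuple(t for m, t in enumerate(tasks) if m in train_ids)
    test = tuple(t for m, t in enumerate(tasks) if m not in train_ids)
    return TaskCollection(train=train, test=test, config=cfg)


def write_task_collection(coll: TaskCollection, out_dir: str | Path) -> Path:
    """Persist a collection as per-task TSVs plus a JSON manifest.

    Writes ``X_<id>.tsv`` (observations), ``truth_<id>.tsv`` (weighted
    adjacency, when present) and ``collection.json`` listing tasks, split
    membership and the generating config for provenance.  Returns the
    manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"tasks": [], "config": None}
    if coll.config is not None:
        cfg = asdict(coll.config)
        cfg["weight_range"] = list(cfg["weight_range"])
        manifest["config"] = cfg
    for split, tasks in (("train", coll.train), ("test", coll.test)):
        for t in tasks:
            x_file = f"X_{t.task_id}.tsv"
            np.savetxt(out / x_file, t.X, delimiter="\t", fmt="%.17g")
            entry = {"task_id": t.task_id, "split": split, "X": x_file}
            if t.truth is not None:
                truth_file = f"truth_{t.task_id}.tsv"
                write_adjacency(t.truth, out / truth_file)
                entry["truth"] = truth_file
            manifest["tasks"].append(entry)
    path = out / "collection.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path
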