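"""Core graph containers and structural primitives.

A causal graph over D variables is held as a weighted adjacency matrix
``W`` (D x D); a nonzero entry ``W[i, j]`` encodes a directed edge
``X[i] -> X[j]`` with linear effect strength ``W[i, j]``.  Binarized
structures (after magnitude thresholding) are held as boolean matrices.
Everything downstream — simulation, solvers, meta-learning, metrics —
works through these two containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.linalg


def _default_labels(d: int) -> list[str]:
    return [f"X{i}" for i in range(d)]


@dataclass(frozen=True)
class WeightedGraph:
    """Real-valued adjacency matrix with zero diagonal.

    Parameters
    ----------
    weights
        Square (D, D) float array; ``weights[i, j]`` is the linear effect
        of variable ``i`` on variable ``j``.  The diagonal must be zero
        (self-loops are meaningless in a structural equation model).
    node_labels
        Ordered variable identifiers; defaults to ``X0 .. X{D-1}``.
    """

    weights: np.ndarray
    node_labels: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if np.any(np.diag(w) != 0.0):
            raise ValueError("diagonal of weights must be zero")
        object.__setattr__(self, "weights", w)
        labels = self.node_labels
        if labels is None:
            labels = _default_labels(w.shape[0])
        labels = tuple(str(x) for x in labels)
        if len(labels) != w.shape[0]:
            raise ValueError("node_labels length must match matrix dimension")
        object.__setattr__(self, "node_labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def copy_with(self, weights: np.ndarray) -> "WeightedGraph":
        return WeightedGraph(weights, self.node_labels)


@dataclass(frozen=True)
class BinaryGraph:
    """Directed edge structure: ``edges[i, j]`` true means ``X[i] -> X[j]``."""

    edges: np.ndarray
    node_labels: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=bool)
        if e.ndim != 2 or e.shape[0] != e.shape[1]:
            raise ValueError(f"edges must be square, got shape {e.shape}")
        if np.any(np.diag(e)):
            raise ValueError("diagonal of edges must be False")
        object.__setattr__(self, "edges", e)
        labels = self.node_labels
        if labels is None:
            labels = _default_labels(e.shape[0])
        labels = tuple(str(x) for x in labels)
        if len(labels) != e.shape[0]:
            raise ValueError("node_labels length must match matrix dimension")
        object.__setattr__(self, "node_labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.edges.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.edges.sum())

    def skeleton(self) -> np.ndarray:
        """Symmetrized (undirected) edge indicator."""
        return self.edges | self.edges.T

    def to_weighted(self) -> WeightedGraph:
        """Indicator weights (1.0 on edges), e.g. for acyclicity checks."""
        return WeightedGraph(self.edges.astype(float), self.node_labels)


def acyclicity_value(g: WeightedGraph) -> float:
    """Smooth acyclicity measure ``h(W) = tr(exp(W o W)) - D``.

    ``h(W) >= 0`` always, and ``h(W) = 0`` exactly when the nonzero
    pattern of ``W`` admits a topological order (no directed cycle).
    The trace of the matrix exponential of the elementwise square counts
    weighted closed walks of every length, so any cycle contributes a
    strictly positive amount.
    """
    w = np.asarray(g.weights, dtype=float)
    e = scipy.linalg.expm(w * w)
    return float(np.trace(e) - w.shape[0])


def acyclicity_gradient(weights: np.ndarray) -> tuple[float, np.ndarray]:
    """Value and gradient of h at a raw weight matrix (solver hot path)."""
    e = scipy.linalg.expm(weights * weights)
    h = float(np.trace(e) - weights.shape[0])
    grad = e.T * weights * 2.0
    return h, grad


def threshold_graph(g: WeightedGraph, tau: float = 0.3) -> BinaryGraph:
    """Binarize by magnitude: edge (i, j) iff ``|W[i, j]| > tau``."""
    if tau < 0:
        raise ValueError(f"tau must be nonnegative, got {tau}")
    edges = np.abs(g.weights) > tau
    np.fill_diagonal(edges, False)
    return BinaryGraph(edges, g.node_labels)


def is_dag(g: BinaryGraph) -> bool:
    """True iff the directed structure admits a topological order."""
    nxg = nx.from_numpy_array(g.edges.astype(int), create_using=nx.DiGraph)
    return nx.is_directed_acyclic_graph(nxg)


def _pair_edit_cost(p_ij: bool, p_ji: bool, t_ij: bool, t_ji: bool) -> int:
    """Minimal insert/delete/flip edits between one node pair's states."""
    np_, nt = int(p_ij) + int(p_ji), int(t_ij) + int(t_ji)
    if np_ == nt:
        if np_ == 1 and p_ij != t_ij:
            return 1  # direction flip
        return 0
    return abs(np_ - nt)


def structural_hamming_distance(pred: BinaryGraph, truth: BinaryGraph) -> int:
    """Minimal number of edge insertions, deletions or direction flips
    turning ``pred`` into ``truth``; a reversed edge costs exactly 1.

    Node pairs are independent under these edit operations, so the total
    is the sum of per-pair costs.
    """
    if pred.n_nodes != truth.n_nodes:
        raise ValueError(
            f"dimension mismatch: {pred.n_nodes} vs {truth.n_nodes} nodes"
        )
    p, t = pred.edges, truth.edges
    d = p.shape[0]
    iu, ju = np.triu_indices(d, k=1)
    cost = 0
    for i, j in zip(iu, ju):
        cost += _pair_edit_cost(p[i, j], p[j, i], t[i, j], t[j, i])
    return int(cost)


# ---------------------------------------------------------------------------
# Text I/O: weighted adjacency matrices and TSV edge lists

def write_adjacency(g: WeightedGraph, path: str | Path, labels: bool = True) -> None:
    """Write a weighted graph as tab-delimited numeric text (optional header)."""
    df = pd.DataFrame(g.weights, columns=list(g.node_labels))
    df.to_csv(path, sep="\t", index=False, header=labels, float_format="%.17g")


def read_adjacency(path: str | Path) -> WeightedGraph:
    """Read a weighted graph from delimited numeric text.

    A header row of node labels is detected by attempting a float parse of
    the first row; non-numeric tokens are treated as labels.
    """
    with open(path) as fh:
        first = fh.readline()
    delim = "\t" if "\t" in first else ("," if "," in first else None)
    tokens = first.strip().split(delim)

    def _is_float(tok: str) -> bool:
        try:
            float(tok)
        except ValueError:
            return False
        return True

    has_header = not all(_is_float(t) for t in tokens)
    labels = tuple(tokens) if has_header else None
    data = np.loadtxt(
        path, delimiter=delim, skiprows=1 if has_header else 0, ndmin=2
    )
    return WeightedGraph(data, labels)


def write_edge_list(
    g: WeightedGraph | BinaryGraph, path: str | Path
) -> None:
    """Write ``source<TAB>target[<TAB>weight]`` rows (weight for weighted graphs)."""
    weighted = isinstance(g, WeightedGraph)
    mat = g.weights if weighted else g.edges
    labels = g.node_labels
    with open(path, "w") as fh:
        for i, j in zip(*np.nonzero(mat)):
            if weighted:
                fh.write(f"{labels[i]}\t{labels[j]}\t{mat[i, j]:.17g}\n")
            else:
                fh.write(f"{labels[i]}\t{labels[j]}\n")


def read_edge_list(
    path: str | Path, node_labels: Sequence[str]
) -> WeightedGraph:
    """Read a TSV edge list (``source<TAB>target[<TAB>weight]``) over known labels."""
    labels = [str(x) for x in node_labels]
    index = {lab: i for i, lab in enumerate(labels)}
    w = np.zeros((len(labels), len(labels)))
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            src, dst = parts[0], parts[1]
            weight = float(parts[2]) if len(parts) > 2 else 1.0
            w[index[src], index[dst]] = weight
    return WeightedGraph(w, tuple(labels))
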