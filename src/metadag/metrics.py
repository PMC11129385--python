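"""Edge-classification and structural metrics for learned causal graphs.

Each of the d(d-1)/2 variable pairs is treated as a detection problem
with direction taken into account: a predicted edge is a true positive
only when its direction matches the ground truth; a true edge predicted
with the opposite direction counts as *reversed*; a predicted edge whose
pair is absent from the true skeleton is a false positive.  Reversed
edges count against FDR and FPR but not toward TPR — the convention most
structure-learning benchmarks use; it matters when comparing published
tables, so it is stated here rather than buried in code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .graphs import (
    BinaryGraph,
    structural_hamming_distance,
    threshold_graph,
)
from .solvers import FitResult

METRIC_NAMES = ("fdr", "tpr", "fpr", "shd", "nnz")


@dataclass(frozen=True)
class EdgeOutcome:
    """Partition of predicted directed edges against a ground-truth DAG.

    Satisfies ``tp + reversed_ + fp == predicted_total`` always, and
    ``tp + reversed_ + missing == true_total`` whenever the prediction
    contains no 2-cycles.
    """

    tp: int
    reversed_: int
    fp: int
    missing: int
    predicted_total: int
    true_total: int


@dataclass(frozen=True)
class TaskMetrics:
    """One task's metric row."""

    fdr: float
    tpr: float
    fpr: float
    shd: int
    nnz: int
    task_id: str = ""


@dataclass(frozen=True)
class MetricsReport:
    """Per-task metrics plus their mean and dispersion over test tasks.

    ``sd`` holds the population standard deviation per metric; standard
    errors of the mean are available through :meth:`sem`.
    """

    per_task: tuple[TaskMetrics, ...]
    mean: dict[str, float]
    sd: dict[str, float]

    def sem(self) -> dict[str, float]:
        n = max(len(self.per_task), 1)
        return {k: v / np.sqrt(n) for k, v in self.sd.items()}


def classify_edges(pred: BinaryGraph, truth: BinaryGraph) -> EdgeOutcome:
    """Split predicted edges into correct / reversed / off-skeleton.

    - TP: predicted edge present in the truth with the same direction.
    - Reversed: predicted edge whose opposite direction is a true edge.
    - FP: predicted edge whose pair is absent from the true skeleton.
    - Missing: true edges absent from the predicted skeleton.
    """
    if pred.n_nodes != truth.n_nodes:
        raise ValueError(
            f"dimension mismatch: {pred.n_nodes} vs {truth.n_nodes} nodes"
        )
    p, t = pred.edges, truth.edges
    tp = int(np.sum(p & t))
    reversed_ = int(np.sum(p & t.T & ~t))
    fp = int(np.sum(p & ~(t | t.T)))
    missing = int(np.sum(t & ~(p | p.T)))
    return EdgeOutcome(
        tp=tp,
        reversed_=reversed_,
        fp=fp,
        missing=missing,
        predicted_total=int(p.sum()),
        true_total=int(t.sum()),
    )


def compute_rates(o: EdgeOutcome, d: int) -> tuple[float, float, float]:
    """(FDR, TPR, FPR) from an edge-classification outcome.

    FDR = (reversed + fp) / predicted_total,
    TPR = tp / true_total,
    FPR = (reversed + fp) / condition_negatives, where
    condition_negatives = d(d-1)/2 - true_total.  Empty denominators are
    guarded with max(., 1), reporting 0 rather than undefined.
    """
    fdr = (o.reversed_ + o.fp) / max(o.predicted_total, 1)
    tpr = o.tp / max(o.true_total, 1)
    negatives = d * (d - 1) // 2 - o.true_total
    fpr = (o.reversed_ + o.fp) / max(negatives, 1)
    return float(fdr), float(tpr), float(fpr)


def evaluate_prediction(
    pred: BinaryGraph, truth: BinaryGraph, task_id: str = ""
) -> TaskMetrics:
    """All five metrics (FDR, TPR, FPR, SHD, NNZ) for one prediction."""
    o = classify_edges(pred, truth)
    fdr, tpr, fpr = compute_rates(o, pred.n_nodes)
    return TaskMetrics(
        fdr=fdr,
        tpr=tpr,
        fpr=fpr,
        shd=structural_hamming_distance(pred, truth),
        nnz=o.predicted_total,
        task_id=task_id,
    )


def evaluate_collection(
    fits: Sequence[FitResult | BinaryGraph],
    truths: Sequence[BinaryGraph],
    tau: float = 0.3,
) -> MetricsReport:
    """Threshold each fit, score it against its truth, and aggregate.

    Aggregate means are arithmetic means of the per-task values; the
    dispersion is their (population) standard deviation.
    """
    if len(fits) != len(truths):
        raise ValueError(
            f"got {len(fits)} fits but {len(truths)} truth graphs"
        )
    rows = []
    for k, (fit, truth) in enumerate(zip(fits, truths)):
        if isinstance(fit, FitResult):
            pred = threshold_graph(fit.graph, tau)
        else:
            pred = fit
        rows.append(evaluate_prediction(pred, truth, task_id=str(k)))
    arr = {
        name: np.array([getattr(r, name) for r in rows], dtype=float)
        for name in METRIC_NAMES
    }
    return MetricsReport(
        per_task=tuple(rows),
        mean={k: float(v.mean()) for k, v in arr.items()},
        sd={k: float(v.std()) for k, v in arr.items()},
    )
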