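"""End-to-end benchmark protocols: method comparison and parameter sweeps.

A benchmark run generates (or loads) a task collection, runs every
requested method, and scores each on the held-out test tasks:

- decoupled learners (``notears_l1``, ``unconstrained_l1``) fit each test
  task independently from a zero initialization;
- ``mtl`` fits the joint shared-plus-deviation model on the test tasks;
- meta variants (``meta_notears_l1``, ``meta_unconstrained_l1``)
  meta-train the shared initialization on the training tasks, then adapt
  to each test task from the frozen initialization.

Sweeps repeat the comparison along one axis (graph size, samples per
task, number of tasks, meta learning rate, outer steps, L1 strength)
holding everything else fixed.  Every row is reproducible from its
recorded seed and the echoed spec.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np

from .graphs import BinaryGraph, read_adjacency, threshold_graph
from .meta import MetaConfig, meta_adapt, meta_train
from .metrics import METRIC_NAMES, MetricsReport, evaluate_collection
from .simulate import (
    SimulationConfig,
    TaskCollection,
    TaskDataset,
    generate_task_collection,
)
from .solvers import SolverConfig, fit_joint_mtl, fit_notears_l1, fit_unconstrained_l1

Method = Literal[
    "notears_l1",
    "unconstrained_l1",
    "mtl",
    "meta_notears_l1",
    "meta_unconstrained_l1",
]

ALL_METHODS: tuple[Method, ...] = (
    "notears_l1",
    "unconstrained_l1",
    "mtl",
    "meta_notears_l1",
    "meta_unconstrained_l1",
)

SweepVariable = Literal[
    "d", "n_samples", "n_tasks", "meta_lr", "outer_steps", "lambda1", "none"
]


@dataclass(frozen=True)
class BenchmarkSpec:
    """Everything needed to reproduce one benchmark run or sweep."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    methods: tuple[Method, ...] = ("notears_l1", "meta_notears_l1")
    meta: MetaConfig = field(default_factory=MetaConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    train_fraction: float = 0.8
    sweep_variable: SweepVariable = "none"
    sweep_values: tuple = ()
    seeds: tuple[int, ...] = (0,)
    delta_penalty: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sweep_variable != "none" and not self.sweep_values:
            raise ValueError("sweep_values required when sweep_variable is set")
        for m in self.methods:
            if m not in ALL_METHODS:
                raise ValueError(f"unknown method {m!r}")

    @property
    def replicates(self) -> int:
        return len(self.seeds)


@dataclass(frozen=True)
class BenchmarkRow:
    method: str
    sweep_value: object
    seed: int
    report: Optional[MetricsReport]
    error: Optional[str] = None


@dataclass(frozen=True)
class BenchmarkResult:
    rows: tuple[BenchmarkRow, ...]
    spec: BenchmarkSpec

    def mean_metric(
        self, method: str, metric: str, sweep_value: object = None
    ) -> float:
        """Seed-averaged mean of a test-set metric for one method."""
        vals = [
            r.report.mean[metric]
            for r in self.rows
            if r.method == method
            and r.report is not None
            and (sweep_value is None or r.sweep_value == sweep_value)
        ]
        if not vals:
            raise ValueError(
                f"no rows for method={method!r}, sweep_value={sweep_value!r}"
            )
        return float(np.mean(vals))

    def aggregate(self) -> list[dict]:
        """One record per (method, sweep value): mean and sd over seeds."""
        keys = sorted(
            {(r.method, r.sweep_value) for r in self.rows if r.report},
            key=str,
        )
        out = []
        for method, sv in keys:
            rows = [
                r for r in self.rows
                if r.method == method and r.sweep_value == sv and r.report
            ]
            rec = {"method": method, "sweep_value": sv, "n_seeds": len(rows)}
            for metric in METRIC_NAMES:
                vals = np.array([r.report.mean[metric] for r in rows])
                rec[metric] = {
                    "mean": float(vals.mean()),
                    "sd": float(vals.std()),
                }
            out.append(rec)
        return out


def _truth_structures(tasks: Sequence[TaskDataset]) -> list[BinaryGraph]:
    truths = []
    for t in tasks:
        if t.truth is None:
            raise ValueError(f"task {t.task_id} has no ground-truth graph")
        truths.append(threshold_graph(t.truth, 0.0))
    return truths


def run_methods_on_collection(
    coll: TaskCollection,
    methods: Sequence[Method],
    meta_cfg: MetaConfig,
    solver_cfg: SolverConfig,
    delta_penalty: Optional[float] = None,
) -> dict[str, MetricsReport]:
    """Run each method on one collection and score it on the test tasks."""
    truths = _truth_structures(coll.test)
    tau = solver_cfg.threshold_tau
    reports: dict[str, MetricsReport] = {}
    for method in methods:
        if method in ("notears_l1", "unconstrained_l1"):
            fit_fn = fit_notears_l1 if method == "notears_l1" else fit_unconstrained_l1
            fits = [fit_fn(t, init=None, cfg=solver_cfg) for t in coll.test]
            reports[method] = evaluate_collection(fits, truths, tau)
        elif method == "mtl":
            _, per_task = fit_joint_mtl(
                coll.test, cfg=solver_cfg, delta_penalty=delta_penalty
            )
            preds = [threshold_graph(w, tau) for w in per_task]
            reports[method] = evaluate_collection(preds, truths, tau)
        else:  # meta variants
            base = method.removeprefix("meta_")
            cfg = replace(meta_cfg, base_solver=base, solver_cfg=solver_cfg)
            state = meta_train(coll.train, cfg)
            fits = [meta_adapt(state, t, cfg) for t in coll.test]
            reports[method] = evaluate_collection(fits, truths, tau)
    return reports


def run_benchmark(spec: BenchmarkSpec) -> BenchmarkResult:
    """Method comparison over replicate seeds (no sweep).

    Per seed: generate a fresh task collection (sim seed and meta task
    order both derived from the replicate seed), run every method, and
    record the test-set metric report.  A method failure is recorded as
    an error row; the run continues.
    """
    rows: list[BenchmarkRow] = []
    sv = None if spec.sweep_variable == "none" else spec.sweep_values
    for seed in spec.seeds:
        sim = replace(spec.sim, seed=int(seed))
        meta_cfg = replace(spec.meta, task_order_seed=int(seed))
        coll = generate_task_collection(sim, spec.train_fraction)
        for method in spec.methods:
            try:
                report = run_methods_on_collection(
                    coll, [method], meta_cfg, spec.solver, spec.delta_penalty
                )[method]
                rows.append(BenchmarkRow(method, None, int(seed), report))
            except Exception as exc:  # record and continue
                rows.append(
                    BenchmarkRow(method, None, int(seed), None, error=str(exc))
                )
    return BenchmarkResult(rows=tuple(rows), spec=spec)


def _apply_sweep_value(spec: BenchmarkSpec, value) -> BenchmarkSpec:
    var = spec.sweep_variable
    if var == "d":
        # expected edge count follows the 3d convention unless pinned
        sim = replace(spec.sim, d=int(value), expected_edges=None)
        return replace(spec, sim=sim)
    if var == "n_samples":
        return replace(spec, sim=replace(spec.sim, n_samples=int(value)))
    if var == "n_tasks":
        return replace(spec, sim=replace(spec.sim, n_tasks=int(value)))
    if var == "meta_lr":
        return replace(spec, meta=replace(spec.meta, meta_lr=float(value)))
    if var == "outer_steps":
        return replace(spec, meta=replace(spec.meta, outer_steps=int(value)))
    if var == "lambda1":
        return replace(spec, solver=replace(spec.solver, lambda1=float(value)))
    raise ValueError(f"unknown sweep variable {var!r}")


def run_sweep(spec: BenchmarkSpec) -> BenchmarkResult:
    """Repeat the method comparison at each sweep value.

    Everything other than the swept variable is held at the spec's
    defaults; rows are tagged with their sweep value.
    """
    if spec.sweep_variable == "none":
        raise ValueError("run_sweep requires a sweep_variable")
    rows: list[BenchmarkRow] = []
    for value in spec.sweep_values:
        sub = _apply_sweep_value(spec, value)
        res = run_benchmark(replace(sub, sweep_variable="none", sweep_values=()))
        for r in res.rows:
            rows.append(dataclasses.replace(r, sweep_value=value))
    return BenchmarkResult(rows=tuple(rows), spec=spec)


# ---------------------------------------------------------------------------
# Task-collection loading (also the ingestion route for external data such
# as the protein-signaling benchmark prepared as per-task text files)

def load_task_collection(manifest_path: str | Path) -> TaskCollection:
    """Load a collection from a ``collection.json`` manifest.

    The manifest lists tasks with their split membership, observation
    matrix file and optional ground-truth adjacency file (paths relative
    to the manifest).  Dimensions must agree across tasks; missing files,
    NaNs or mismatched dimensions raise an error naming the task.
    """
    path = Path(manifest_path)
    with open(path) as fh:
        manifest = json.load(fh)
    base = path.parent
    cfg = None
    if manifest.get("config"):
        c = dict(manifest["config"])
        c["weight_range"] = tuple(c.get("weight_range", (0.5, 2.0)))
        cfg = SimulationConfig(**c)
    train, test = [], []
    d_expected: Optional[int] = None
    for entry in manifest["tasks"]:
        tid = entry["task_id"]
        x_path = base / entry["X"]
        if not x_path.exists():
            raise FileNotFoundError(f"task {tid}: missing data file {x_path}")
        X = np.loadtxt(x_path, delimiter="\t", ndmin=2)
        if np.isnan(X).any():
            raise ValueError(f"task {tid}: data contains NaNs")
        truth = None
        if entry.get("truth"):
            truth = read_adjacency(base / entry["truth"])
        if d_expected is None:
            d_expected = X.shape[1]
        elif X.shape[1] != d_expected:
            raise ValueError(
                f"task {tid}: has {X.shape[1]} variables, expected {d_expected}"
            )
        task = TaskDataset(X, truth=truth, task_id=tid)
        (train if entry["split"] == "train" else test).append(task)
    return TaskCollection(train=tuple(train), test=tuple(test), config=cfg)


# ---------------------------------------------------------------------------
# Persistence and plotting

def _spec_to_jsonable(spec: BenchmarkSpec) -> dict:
    d = dataclasses.asdict(spec)

    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    return clean(d)


def write_results(result: BenchmarkResult, out_dir: str | Path) -> Path:
    """Persist a benchmark result: results.jsonl, aggregate.json, spec echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "results.jsonl", "w") as fh:
        for r in result.rows:
            rec = {
                "method": r.method,
                "sweep_value": r.sweep_value,
                "seed": r.seed,
                "error": r.error,
            }
            if r.report is not None:
                rec["mean"] = r.report.mean
                rec["sd"] = r.report.sd
                rec["per_task"] = [
                    dataclasses.asdict(t) for t in r.report.per_task
                ]
            fh.write(json.dumps(rec) + "\n")
    with open(out / "aggregate.json", "w") as fh:
        json.dump(result.aggregate(), fh, indent=2)
    with open(out / "spec_echo.json", "w") as fh:
        json.dump(_spec_to_jsonable(result.spec), fh, indent=2)
    return out / "results.jsonl"


def plot_sweep(
    result: BenchmarkResult,
    metrics: Sequence[str] = ("fdr", "shd", "nnz"),
    out_path: str | Path = "sweep.png",
) -> Path:
    """Render metric-vs-sweep-value curves, one panel per metric."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    agg = result.aggregate()
    methods = sorted({rec["method"] for rec in agg})
    fig, axes = plt.subplots(1, len(metrics), figsize=(4.5 * len(metrics), 3.5))
    if len(metrics) == 1:
        axes = [axes]
    for ax, metric in zip(axes, metrics):
        for method in methods:
            recs = [r for r in agg if r["method"] == method]
            recs.sort(key=lambda r: (r["sweep_value"] is None, r["sweep_value"]))
            xs = [r["sweep_value"] for r in recs]
            ys = [r[metric]["mean"] for r in recs]
            es = [r[metric]["sd"] for r in recs]
            ax.errorbar(xs, ys, yerr=es, marker="o", capsize=3, label=method)
        ax.set_xlabel(result.spec.sweep_variable)
        ax.set_ylabel(metric.upper())
    axes[-1].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return Path(out_path)
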