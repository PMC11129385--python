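"""Single-task score-based DAG learners and the joint multi-task baseline.

All learners minimize the penalized least-squares score

    J(W) = 1/(2N) ||X - X W||_F^2 + lambda1 ||W||_1

over weight matrices with zero diagonal.  ``fit_unconstrained_l1`` stops
there (proximal gradient / ISTA); ``fit_notears_l1`` additionally enforces
the smooth acyclicity constraint h(W) = tr(exp(W o W)) - D = 0 by an
augmented-Lagrangian scheme whose smooth subproblems are solved with
L-BFGS-B after splitting W = W+ - W- (both nonnegative), which turns the
L1 term into a linear one.  Every learner accepts an initial graph — the
warm-start hook the meta-learning loop relies on.

``fit_joint_mtl`` is the conventional joint multi-task baseline: a shared
graph W0 plus per-task deviations Delta^i, optimized simultaneously with
acyclicity enforced on each W0 + Delta^i.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._optim import minimize_box
from .graphs import WeightedGraph, acyclicity_gradient
from .simulate import TaskDataset


def _expm_pade(A: np.ndarray) -> np.ndarray:
    """Matrix exponential by Pade(13) scaling-and-squaring.

    Near machine precision for the small dense matrices the solvers
    handle; kept dependency-light so it can be JIT-compiled.
    """
    d = A.shape[0]
    b = (
        64764752532480000.0, 32382376266240000.0, 7771770303897600.0,
        1187353796428800.0, 129060195264000.0, 10559470521600.0,
        670442572800.0, 33522128640.0, 1323241920.0, 40840800.0,
        960960.0, 16380.0, 182.0, 1.0,
    )
    nrm = 0.0
    for i in range(d):
        r = 0.0
        for j in range(d):
            r += abs(A[i, j])
        if r > nrm:
            nrm = r
    s = 0
    while nrm > 5.371920351148152:
        nrm *= 0.5
        s += 1
    As = A / (2.0**s)
    ident = np.eye(d)
    A2 = As @ As
    A4 = A2 @ A2
    A6 = A2 @ A4
    U = As @ (
        A6 @ (b[13] * A6 + b[11] * A4 + b[9] * A2)
        + b[7] * A6 + b[5] * A4 + b[3] * A2 + b[1] * ident
    )
    V = (
        A6 @ (b[12] * A6 + b[10] * A4 + b[8] * A2)
        + b[6] * A6 + b[4] * A4 + b[2] * A2 + b[0] * ident
    )
    E = np.ascontiguousarray(np.linalg.solve(V - U, V + U))
    for _ in range(s):
        E = np.ascontiguousarray(E @ E)
    return E


def _al_obj_grad(
    ws: np.ndarray, gram: np.ndarray, lam: float, rho: float, alpha: float,
    d: int,
):
    """Augmented-Lagrangian objective and gradient in split coordinates.

    ``ws`` stacks W+ then W- (both nonnegative, W = W+ - W-); the L1 term
    is the linear form lam * sum(ws).
    """
    dd = d * d
    wp = ws[:dd].copy().reshape(d, d)
    wn = ws[dd:].copy().reshape(d, d)
    w = wp - wn
    m = gram - gram @ w
    loss = 0.5 * (np.trace(m) - np.sum(w * m))
    E = _expm_pade(w * w)
    h = np.trace(E) - d
    gh = E.T * w * 2.0
    f = loss + lam * np.sum(ws) + 0.5 * rho * h * h + alpha * h
    gw = -m + (rho * h + alpha) * gh
    grad = np.empty(2 * dd)
    grad[:dd] = (gw + lam).ravel()
    grad[dd:] = (-gw + lam).ravel()
    return f, grad


try:  # JIT-compile the hot path when numba is available
    import numba

    _expm_pade = numba.njit(cache=True)(_expm_pade)
    _al_obj_grad = numba.njit(cache=True)(_al_obj_grad)
except Exception:  # pragma: no cover - numba is a hard dependency normally
    pass


@dataclass(frozen=True)
class SolverConfig:
    """Solver hyper-parameters.

    ``lambda1`` is the L1 strength (default 0.1); ``threshold_tau`` the
    magnitude cutoff used when binarizing fitted weights (default 0.3).
    The augmented-Lagrangian schedule (rho_init, rho_growth x10 up to
    rho_max, dual update alpha += rho*h, stop at h <= h_tolerance) follows
    the standard continuous-acyclicity-constrained solver.
    """

    lambda1: float = 0.1
    max_outer_al: int = 100
    h_tolerance: float = 1e-8
    rho_init: float = 1.0
    rho_max: float = 1e16
    rho_growth: float = 10.0
    inner_iterations: int = 50
    inner_pgtol: float = 1e-5
    threshold_tau: float = 0.3

    def __post_init__(self) -> None:
        if self.lambda1 < 0:
            raise ValueError("lambda1 must be nonnegative")
        if self.rho_growth <= 1:
            raise ValueError("rho_growth must exceed 1")
        if self.h_tolerance <= 0:
            raise ValueError("h_tolerance must be positive")
        if self.threshold_tau < 0:
            raise ValueError("threshold_tau must be nonnegative")


@dataclass(frozen=True)
class FitResult:
    """Outcome of one structure-learning solve."""

    graph: WeightedGraph
    objective_value: float
    acyclicity_residual: float
    converged: bool
    iterations_used: int


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, TaskDataset):
        return X.X
    return np.asarray(X, dtype=float)


def score(X, g: WeightedGraph, lambda1: float) -> float:
    """Penalized least-squares objective J(W) for data X and graph g."""
    x = _as_matrix(X)
    if x.shape[1] != g.n_nodes:
        raise ValueError(
            f"dimension mismatch: X has {x.shape[1]} columns, W is "
            f"{g.n_nodes}x{g.n_nodes}"
        )
    n = x.shape[0]
    resid = x - x @ g.weights
    return float(0.5 / n * np.sum(resid**2) + lambda1 * np.abs(g.weights).sum())


def _gram(x: np.ndarray) -> np.ndarray:
    return (x.T @ x) / x.shape[0]


def _sq_loss_grad(gram: np.ndarray, w: np.ndarray) -> tuple[float, np.ndarray]:
    # 1/(2N)||X - XW||_F^2 = 0.5 tr((I-W)^T G (I-W)) with G = X^T X / N
    m = gram @ (np.eye(w.shape[0]) - w)
    loss = 0.5 * float(np.trace(m) - np.sum(w * m))
    grad = -m
    return loss, grad


def _prepare_init(init: Optional[WeightedGraph], d: int) -> np.ndarray:
    if init is None:
        return np.zeros((d, d))
    if init.n_nodes != d:
        raise ValueError(
            f"init graph has {init.n_nodes} nodes, data has {d} variables"
        )
    return init.weights.copy()


def fit_unconstrained_l1(
    X, init: Optional[WeightedGraph] = None, cfg: SolverConfig = SolverConfig()
) -> FitResult:
    """L1-penalized least-squares fit without the acyclicity constraint.

    Proximal-gradient (ISTA) iterations with the exact Lipschitz step
    1/||G||_2, so the objective is non-increasing; the diagonal is pinned
    to zero after every step.  Never raises on non-convergence — returns
    ``converged=False`` when the iteration budget runs out.
    """
    x = _as_matrix(X)
    d = x.shape[1]
    w = _prepare_init(init, d)
    np.fill_diagonal(w, 0.0)
    gram = _gram(x)
    lip = max(float(np.linalg.eigvalsh(gram)[-1]), 1e-12)
    step = 1.0 / lip
    lam = cfg.lambda1
    tol = 1e-7
    converged = False
    it = 0
    for it in range(1, cfg.inner_iterations + 1):
        _, grad = _sq_loss_grad(gram, w)
        w_new = w - step * grad
        w_new = np.sign(w_new) * np.maximum(np.abs(w_new) - step * lam, 0.0)
        np.fill_diagonal(w_new, 0.0)
        delta = float(np.max(np.abs(w_new - w)))
        w = w_new
        if delta < tol:
            converged = True
            break
    graph = WeightedGraph(w, getattr(X, "truth", None) and X.truth.node_labels)
    from .graphs import acyclicity_value  # residual is informative only here

    return FitResult(
        graph=graph,
        objective_value=score(x, graph, lam),
        acyclicity_residual=acyclicity_value(graph),
        converged=converged,
        iterations_used=it,
    )


def _split_boxes(d: int, copies: int = 1):
    """Box-bound arrays for ``copies`` stacked (W+, W-) splits.

    Every entry is nonnegative (nbd=1); diagonals are pinned to zero
    (nbd=2 with lb=ub=0).
    """
    n1 = 2 * d * d
    nbd1 = np.ones(n1, dtype=np.int32)
    diag = np.arange(d) * d + np.arange(d)
    nbd1[diag] = 2
    nbd1[d * d + diag] = 2
    nbd = np.tile(nbd1, copies)
    n = n1 * copies
    return np.zeros(n), np.zeros(n), nbd


def fit_notears_l1(
    X, init: Optional[WeightedGraph] = None, cfg: SolverConfig = SolverConfig()
) -> FitResult:
    """Acyclicity-constrained L1 structure learning (augmented Lagrangian).

    Minimizes J(W) subject to h(W) = tr(exp(W o W)) - D = 0.  The penalty
    rho escalates by ``rho_growth`` whenever the residual fails to shrink
    by a factor of 4; the dual variable follows alpha += rho * h.  Inner
    smooth subproblems start from the current iterate, so passing ``init``
    warm-starts the whole solve.
    """
    x = _as_matrix(X)
    n, d = x.shape
    gram = np.ascontiguousarray(_gram(x))
    w = _prepare_init(init, d)
    np.fill_diagonal(w, 0.0)
    w_split = np.concatenate(
        [np.maximum(w, 0.0).ravel(), np.maximum(-w, 0.0).ravel()]
    )
    lb, ub, nbd = _split_boxes(d)
    lam = cfg.lambda1
    rho, alpha, h = cfg.rho_init, 0.0, np.inf
    outer = 0

    def _h_at(ws: np.ndarray) -> float:
        wmat = ws[: d * d].reshape(d, d) - ws[d * d :].reshape(d, d)
        return acyclicity_gradient(wmat)[0]

    for outer in range(1, cfg.max_outer_al + 1):
        w_new, h_new = None, None
        start = w_split
        while rho < cfg.rho_max:
            w_new = minimize_box(
                lambda ws: _al_obj_grad(ws, gram, lam, rho, alpha, d),
                start,
                lb, ub, nbd,
                maxiter=cfg.inner_iterations,
                pgtol=cfg.inner_pgtol,
            )
            h_new = _h_at(w_new)
            if h_new > 0.25 * h:
                rho *= cfg.rho_growth
                start = w_new  # continue escalation from the latest attempt
            else:
                break
        w_split, h = w_new, h_new
        alpha += rho * h
        if h <= cfg.h_tolerance or rho >= cfg.rho_max:
            break

    wmat = w_split[: d * d].reshape(d, d) - w_split[d * d :].reshape(d, d)
    np.fill_diagonal(wmat, 0.0)
    graph = WeightedGraph(wmat)
    return FitResult(
        graph=graph,
        objective_value=score(x, graph, lam),
        acyclicity_residual=float(h),
        converged=bool(h <= cfg.h_tolerance),
        iterations_used=outer,
    )


def fit_joint_mtl(
    tasks: Sequence[TaskDataset],
    cfg: SolverConfig = SolverConfig(),
    delta_penalty: Optional[float] = None,
) -> tuple[WeightedGraph, list[WeightedGraph]]:
    """Joint multi-task baseline: per-task graph W^i = W0 + Delta^i.

    Minimizes sum_i J_i(W0 + Delta^i) + delta_penalty * sum_i ||Delta^i||_1
    with acyclicity enforced on every W0 + Delta^i.  The L1 terms use the
    convex split surrogate lambda1 * (||W0||_1 + ||Delta^i||_1) per task,
    which upper-bounds lambda1 * ||W0 + Delta^i||_1 and is exact when the
    shared and task-specific parts agree in sign.  ``delta_penalty``
    defaults to ``lambda1``.

    Returns the shared graph and the list of per-task graphs W0 + Delta^i.
    """
    if not tasks:
        raise ValueError("need at least one task")
    d = tasks[0].n_vars
    for t in tasks:
        if t.n_vars != d:
            raise ValueError(f"task {t.task_id} dimension mismatch")
    if delta_penalty is None:
        delta_penalty = cfg.lambda1
    m = len(tasks)
    grams = [_gram(t.X) for t in tasks]
    lam = cfg.lambda1
    dd = d * d
    # layout: [W0+, W0-, D1+, D1-, ..., Dm+, Dm-]
    nvar = 2 * dd * (m + 1)
    ws = np.zeros(nvar)
    lb, ub, nbd = _split_boxes(d, copies=m + 1)
    alphas = np.zeros(m)
    rho, h_max = cfg.rho_init, np.inf

    def unpack(v: np.ndarray):
        w0 = v[:dd].reshape(d, d) - v[dd : 2 * dd].reshape(d, d)
        deltas = []
        for i in range(m):
            off = 2 * dd * (i + 1)
            deltas.append(
                v[off : off + dd].reshape(d, d)
                - v[off + dd : off + 2 * dd].reshape(d, d)
            )
        return w0, deltas

    def objective(v: np.ndarray, rho: float, alphas: np.ndarray):
        w0, deltas = unpack(v)
        f = lam * m * v[: 2 * dd].sum()
        g_w0 = np.zeros((d, d))
        grad = np.zeros_like(v)
        for i in range(m):
            wi = w0 + deltas[i]
            loss, g_loss = _sq_loss_grad(grams[i], wi)
            hval, g_h = acyclicity_gradient(wi)
            gi = g_loss + (rho * hval + alphas[i]) * g_h
            f += loss + 0.5 * rho * hval * hval + alphas[i] * hval
            off = 2 * dd * (i + 1)
            f += (lam + delta_penalty) * v[off : off + 2 * dd].sum()
            grad[off : off + dd] = (gi + lam + delta_penalty).ravel()
            grad[off + dd : off + 2 * dd] = (-gi + lam + delta_penalty).ravel()
            g_w0 += gi
        grad[:dd] = (g_w0 + lam * m).ravel()
        grad[dd : 2 * dd] = (-g_w0 + lam * m).ravel()
        return f, grad

    def residuals(v: np.ndarray) -> np.ndarray:
        w0, deltas = unpack(v)
        return np.array(
            [acyclicity_gradient(w0 + deltas[i])[0] for i in range(m)]
        )

    for _ in range(cfg.max_outer_al):
        hs = None
        while rho < cfg.rho_max:
            ws_new = minimize_box(
                lambda v: objective(v, rho, alphas),
                ws,
                lb, ub, nbd,
                maxiter=cfg.inner_iterations,
                pgtol=cfg.inner_pgtol,
            )
            hs = residuals(ws_new)
            if hs.max() > 0.25 * h_max:
                rho *= cfg.rho_growth
            else:
                break
        ws, h_max = ws_new, hs.max()
        alphas = alphas + rho * hs
        if h_max <= cfg.h_tolerance or rho >= cfg.rho_max:
            break

    w0, deltas = unpack(ws)
    np.fill_diagonal(w0, 0.0)
    shared = WeightedGraph(w0)
    per_task = []
    for i in range(m):
        wi = w0 + deltas[i]
        np.fill_diagonal(wi, 0.0)
        per_task.append(WeightedGraph(wi))
    return shared, per_task


def joint_mtl_objective(
    tasks: Sequence[TaskDataset],
    w0: WeightedGraph,
    deltas: Sequence[WeightedGraph],
    cfg: SolverConfig = SolverConfig(),
    delta_penalty: Optional[float] = None,
) -> float:
    """Evaluate the joint multi-task objective (split surrogate, no AL terms)."""
    if delta_penalty is None:
        delta_penalty = cfg.lambda1
    total = 0.0
    for t, dl in zip(tasks, deltas):
        wi = WeightedGraph(w0.weights + dl.weights)
        n = t.n_samples
        resid = t.X - t.X @ wi.weights
        total += 0.5 / n * np.sum(resid**2)
        total += cfg.lambda1 * (
            np.abs(w0.weights).sum() + np.abs(dl.weights).sum()
        )
        total += delta_penalty * np.abs(dl.weights).sum()
    return float(total)
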