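"""Minimal box-constrained L-BFGS-B driver for the solver hot path.

The augmented-Lagrangian solvers call L-BFGS-B thousands of times on
small problems, where the generic ``scipy.optimize.minimize`` wrapper
adds measurable per-evaluation overhead.  This module drives scipy's
compiled L-BFGS-B routine directly through a bare reverse-communication
loop (mirroring the public wrapper's protocol), and falls back to
``scipy.optimize.minimize`` transparently if the low-level interface is
unavailable.  ``fun`` must return ``(value, gradient)``.
"""

from __future__ import annotations

import numpy as np
import scipy.optimize

try:  # low-level reverse-communication interface
    from scipy.optimize import _lbfgsb as _lb

    _HAVE_LOWLEVEL = hasattr(_lb, "setulb")
except Exception:  # pragma: no cover - depends on scipy build
    _HAVE_LOWLEVEL = False

_TASK_FG = 3  # setulb requests objective and gradient
_TASK_NEW_X = 1  # setulb completed an iteration


def minimize_box(
    fun,
    x0: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    nbd: np.ndarray,
    maxiter: int = 150,
    maxcor: int = 5,
    pgtol: float = 1e-5,
    factr: float = 1e7,
) -> np.ndarray:
    """Minimize fun (value+grad) subject to elementwise box bounds.

    ``nbd`` follows the L-BFGS-B convention: 0 unbounded, 1 lower bound
    only, 2 both bounds, 3 upper bound only.
    """
    n = x0.size
    if not _HAVE_LOWLEVEL:  # pragma: no cover - exercised only on odd builds
        bounds = []
        for i in range(n):
            lo = lb[i] if nbd[i] in (1, 2) else None
            hi = ub[i] if nbd[i] in (2, 3) else None
            bounds.append((lo, hi))
        sol = scipy.optimize.minimize(
            fun,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={
                "maxiter": maxiter,
                "maxcor": maxcor,
                "gtol": pgtol,
                "ftol": factr * np.finfo(float).eps,
            },
        )
        return sol.x

    x = np.array(x0, dtype=np.float64)
    f = np.array(0.0)
    g = np.zeros(n)
    wa = np.zeros(2 * maxcor * n + 5 * n + 11 * maxcor * maxcor + 8 * maxcor)
    iwa = np.zeros(3 * n, dtype=np.int32)
    task = np.zeros(2, dtype=np.int32)
    ln_task = np.zeros(2, dtype=np.int32)
    lsave = np.zeros(4, dtype=np.int32)
    isave = np.zeros(44, dtype=np.int32)
    dsave = np.zeros(29)
    nit = 0
    while True:
        _lb.setulb(
            maxcor, x, lb, ub, nbd, f, g, factr, pgtol, wa, iwa, task,
            lsave, isave, dsave, 20, ln_task,
        )
        if task[0] == _TASK_FG:
            fv, gv = fun(x)
            f = np.asarray(fv, dtype=np.float64)
            g = np.asarray(gv, dtype=np.float64)
        elif task[0] == _TASK_NEW_X:
            nit += 1
            if nit >= maxiter:
                break
        else:
            break
    return x
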