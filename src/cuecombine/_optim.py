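"""Batched Nelder-Mead simplex minimization.

Runs many independent small optimization problems in lockstep so that the
objective can be evaluated as one vectorized call per candidate set.  Used
for parametric-bootstrap refits and power simulations, where thousands of
near-identical psychometric fits would otherwise dominate runtime.  The
algorithm and coefficients mirror the classic (non-adaptive) Nelder-Mead
as implemented in ``scipy.optimize.minimize``; agreement with scipy on
single problems is enforced by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

# standard simplex coefficients: reflection, expansion, contraction, shrink
_RHO = 1.0
_CHI = 2.0
_PSI = 0.5
_SIGMA = 0.5

_NONZDELT = 0.05
_ZDELT = 0.00025


@dataclass
class BatchResult:
    """Outcome of a batched minimization.

    ``x`` has shape (B, d), ``fun`` shape (B,), ``converged`` shape (B,)
    and ``n_iter`` is the total number of lockstep iterations performed.
    """

    x: np.ndarray
    fun: np.ndarray
    converged: np.ndarray
    n_iter: int


def _init_simplex(x0: np.ndarray) -> np.ndarray:
    b, d = x0.shape
    simplex = np.repeat(x0[:, None, :], d + 1, axis=1)
    for j in range(d):
        col = simplex[:, j + 1, j]
        step = np.where(col != 0.0, _NONZDELT * col, _ZDELT)
        simplex[:, j + 1, j] = col + step
    return simplex


def nelder_mead_batch(
    fun: Callable[[np.ndarray, np.ndarray], np.ndarray],
    x0: np.ndarray,
    *,
    xatol: float = 1e-6,
    fatol: float = 1e-6,
    maxiter: int | None = None,
) -> BatchResult:
    """Minimize ``fun`` for a batch of problems simultaneously.

    Parameters
    ----------
    fun
        Vectorized objective ``fun(X, idx) -> values`` where ``X`` has
        shape (m, d) and ``idx`` (length m) gives the problem index of
        each row, so per-problem data can be selected.
    x0
        Starting points, shape (B, d).
    xatol, fatol
        Per-problem convergence: maximum vertex spread and value spread
        of the simplex.
    maxiter
        Lockstep iteration cap; defaults to ``200 * d`` like scipy.
    """
    x0 = np.asarray(x0, dtype=float)
    if x0.ndim != 2:
        raise ValueError("x0 must have shape (n_problems, n_params)")
    b, d = x0.shape
    if maxiter is None:
        maxiter = 200 * d

    simplex = _init_simplex(x0)
    all_idx = np.arange(b)
    fvals = np.empty((b, d + 1))
    for v in range(d + 1):
        fvals[:, v] = fun(simplex[:, v, :], all_idx)

    order = np.argsort(fvals, axis=1, kind="stable")
    fvals = np.take_along_axis(fvals, order, axis=1)
    simplex = np.take_along_axis(simplex, order[:, :, None], axis=1)

    active = np.ones(b, dtype=bool)
    n_iter = 0
    while active.any() and n_iter < maxiter:
        n_iter += 1
        idx = np.flatnonzero(active)
        sub = simplex[idx]          # (m, d+1, d)
        fsub = fvals[idx]           # (m, d+1)
        centroid = sub[:, :-1, :].mean(axis=1)
        worst = sub[:, -1, :]

        xr = centroid + _RHO * (centroid - worst)
        fr = fun(xr, idx)

        new_point = xr.copy()
        new_f = fr.copy()

        # expansion for problems where reflection beat the current best
        expand = fr < fsub[:, 0]
        if expand.any():
            e = np.flatnonzero(expand)
            xe = centroid[e] + _RHO * _CHI * (centroid[e] - worst[e])
            fe = fun(xe, idx[e])
            better = fe < fr[e]
            new_point[e[better]] = xe[better]
            new_f[e[better]] = fe[better]

        # contraction where reflection did not improve on second-worst
        contract = fr >= fsub[:, -2]
        shrink = np.zeros(len(idx), dtype=bool)
        if contract.any():
            c = np.flatnonzero(contract)
            outside = fr[c] < fsub[c, -1]
            xc = np.where(
                outside[:, None],
                centroid[c] + _PSI * _RHO * (centroid[c] - worst[c]),
                centroid[c] - _PSI * (centroid[c] - worst[c]),
            )
            fc = fun(xc, idx[c])
            limit = np.where(outside, fr[c], fsub[c, -1])
            accepted = fc < limit
            new_point[c[accepted]] = xc[accepted]
            new_f[c[accepted]] = fc[accepted]
            shrink[c[~accepted]] = True

        repl = ~shrink
        r = np.flatnonzero(repl)
        sub[r, -1, :] = new_point[r]
        fsub[r, -1] = new_f[r]

        if shrink.any():
            s = np.flatnonzero(shrink)
            best = sub[s, :1, :]
            sub[s, 1:, :] = best + _SIGMA * (sub[s, 1:, :] - best)
            flat = sub[s, 1:, :].reshape(-1, d)
            flat_idx = np.repeat(idx[s], d)
            fsub[s, 1:] = fun(flat, flat_idx).reshape(len(s), d)

        order = np.argsort(fsub, axis=1, kind="stable")
        fsub = np.take_along_axis(fsub, order, axis=1)
        sub = np.take_along_axis(sub, order[:, :, None], axis=1)
        simplex[idx] = sub
        fvals[idx] = fsub

        x_spread = np.abs(sub[:, 1:, :] - sub[:, :1, :]).max(axis=(1, 2))
        f_spread = np.abs(fsub[:, 1:] - fsub[:, :1]).max(axis=1)
        done = (x_spread <= xatol) & (f_spread <= fatol)
        active[idx[done]] = False

    return BatchResult(
        x=simplex[:, 0, :].copy(),
        fun=fvals[:, 0].copy(),
        converged=~active,
        n_iter=n_iter,
    )
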