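"""Compiled numerical kernels for penalized trimmed regression.

All functions operate on contiguous float64 arrays.  The lasso objective
solved here is

    sum_{i in subset} (y_i - z_i' beta)^2 + |subset| * lam * ||beta||_1,

i.e. the penalty is scaled by the number of observations actually used,
so that trimmed and untrimmed fits share one parameterization.  With
lam = 0 the subproblem is solved exactly by least squares.

Subset updates use a stable sort of the squared residuals, so ties at
the h-th order statistic are broken in favor of the lowest observation
index.
"""

import numpy as np
from numba import njit

__all__ = [
    "lasso_cd",
    "fit_subset",
    "smallest_h",
    "concentrate",
    "lts_search",
]


@njit(cache=True)
def _cd_update(G, c, beta, thr, j):
    """One coordinate update; returns |change|."""
    gjj = G[j, j]
    if gjj <= 0.0:
        d = abs(beta[j])
        beta[j] = 0.0
        return d
    rho = c[j]
    for k in range(beta.shape[0]):
        bk = beta[k]
        if bk != 0.0 and k != j:
            rho -= G[j, k] * bk
    if rho > thr:
        bj = (rho - thr) / gjj
    elif rho < -thr:
        bj = (rho + thr) / gjj
    else:
        bj = 0.0
    d = abs(bj - beta[j])
    beta[j] = bj
    return d


@njit(cache=True)
def lasso_cd(G, c, beta, thr, tol, max_sweeps):
    """Coordinate descent on 0.5*beta'G beta - c'beta + thr*||beta||_1
    (up to the constant 0.5 scaling of the quadratic part).

    ``G = Z'Z`` and ``c = Z'y`` of the working subset; ``thr`` is the
    soft-threshold level ``|subset| * lam / 2``.  Uses the usual
    active-set scheme: a full pass over all coordinates followed by
    inner passes restricted to the nonzero ones until stable.  ``beta``
    is updated in place and also returned.  The tolerance is relative to
    the largest coefficient magnitude.
    """
    p = G.shape[0]
    active = np.empty(p, dtype=np.int64)
    sweeps = 0
    while sweeps < max_sweeps:
        delta = 0.0
        maxb = 0.0
        na = 0
        for j in range(p):
            d = _cd_update(G, c, beta, thr, j)
            if d > delta:
                delta = d
            if beta[j] != 0.0:
                active[na] = j
                na += 1
                if abs(beta[j]) > maxb:
                    maxb = abs(beta[j])
        sweeps += 1
        if delta <= tol * (maxb if maxb > 0.0 else 1.0):
            break
        while sweeps < max_sweeps:
            delta = 0.0
            maxb = 0.0
            for t in range(na):
                d = _cd_update(G, c, beta, thr, active[t])
                if d > delta:
                    delta = d
                bj = abs(beta[active[t]])
                if bj > maxb:
                    maxb = bj
            sweeps += 1
            if delta <= tol * (maxb if maxb > 0.0 else 1.0):
                break
    return beta


@njit(cache=True)
def fit_subset(Z, y, idx, lam, beta, tol, max_sweeps):
    """Solve the penalized least-squares problem on the rows ``idx``.

    Writes the solution into ``beta`` (used as warm start when lam > 0).
    """
    Zs = Z[idx]
    ys = y[idx]
    if lam <= 0.0:
        sol = np.linalg.lstsq(Zs, ys, rcond=-1.0)[0]
        for j in range(beta.shape[0]):
            beta[j] = sol[j]
    else:
        G = np.dot(Zs.T, Zs)
        c = np.dot(Zs.T, ys)
        thr = 0.5 * lam * idx.shape[0]
        lasso_cd(G, c, beta, thr, tol, max_sweeps)
    return beta


@njit(cache=True)
def smallest_h(r2, h):
    """Indices of the h smallest entries; ties keep the lowest index."""
    order = np.argsort(r2, kind="mergesort")
    return order[:h]


@njit(cache=True)
def _objective(r2, idx, beta, h, lam):
    obj = 0.0
    for i in idx:
        obj += r2[i]
    pen = 0.0
    for j in range(beta.shape[0]):
        pen += abs(beta[j])
    return obj + h * lam * pen


@njit(cache=True)
def concentrate(Z, y, beta, h, lam, tol, max_sweeps, max_csteps):
    """Iterate concentration steps from ``beta`` to a fixed point.

    Each step refits on the current h-subset and replaces the subset by
    the h observations with smallest squared residuals; the objective is
    non-increasing along the sequence.  Returns (subset, objective,
    n_steps, converged); ``beta`` is updated in place.
    """
    r = y - np.dot(Z, beta)
    r2 = r * r
    idx = smallest_h(r2, h)
    obj = 1.0e300
    n_steps = 0
    converged = False
    while n_steps < max_csteps:
        fit_subset(Z, y, idx, lam, beta, tol, max_sweeps)
        r = y - np.dot(Z, beta)
        r2 = r * r
        new_idx = smallest_h(r2, h)
        new_obj = _objective(r2, new_idx, beta, h, lam)
        n_steps += 1
        same = True
        for k in range(h):
            if new_idx[k] != idx[k]:
                same = False
                break
        idx = new_idx
        if same or new_obj >= obj * (1.0 - 1.0e-12):
            obj = new_obj
            converged = True
            break
        obj = new_obj
    return idx, obj, n_steps, converged


@njit(cache=True)
def lts_search(Z, y, h, lam, elementals, n_keep, tol, max_sweeps, max_csteps):
    """Random-start search for the trimmed objective.

    Fits each elemental subset, applies two warm-up concentration steps,
    keeps the ``n_keep`` best candidates and concentrates them to a
    fixed point.  Returns (beta, subset, objective, total_csteps).
    """
    n, p = Z.shape
    m = elementals.shape[0]
    # The warm-up phase only needs rough candidates, so coordinate descent
    # is capped at a few dozen sweeps there; the surviving candidates are
    # polished at full precision in the concentration phase below.
    warm_sweeps = min(50, max_sweeps)
    betas = np.zeros((m, p))
    objs = np.full(m, 1.0e300)
    for k in range(m):
        beta = np.zeros(p)
        fit_subset(Z, y, elementals[k], lam, beta, tol, warm_sweeps)
        for _ in range(2):
            r = y - np.dot(Z, beta)
            r2 = r * r
            idx = smallest_h(r2, h)
            fit_subset(Z, y, idx, lam, beta, tol, warm_sweeps)
        r = y - np.dot(Z, beta)
        r2 = r * r
        idx = smallest_h(r2, h)
        objs[k] = _objective(r2, idx, beta, h, lam)
        betas[k] = beta
    order = np.argsort(objs, kind="mergesort")
    best_obj = 1.0e300
    best_beta = np.zeros(p)
    best_idx = np.empty(h, dtype=np.int64)
    total = 0
    keep = n_keep if n_keep < m else m
    for t in range(keep):
        beta = betas[order[t]].copy()
        idx, obj, steps, _ = concentrate(
            Z, y, beta, h, lam, tol, max_sweeps, max_csteps
        )
        total += steps
        if obj < best_obj:
            best_obj = obj
            best_beta = beta.copy()
            best_idx = idx.copy()
    return best_beta, best_idx, best_obj, total
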