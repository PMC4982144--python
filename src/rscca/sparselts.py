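"""Sparse least trimmed squares (sparse LTS) regression.

The estimator minimizes the sum of the h smallest squared residuals plus
an L1 penalty scaled by h,

    sum_{i=1}^{h} (r^2)_{i:n} + h * lam * ||beta||_1,

with h = floor(n * (1 - trim_fraction)).  It is computed by a
random-start concentration (C-step) algorithm: elemental subsets of
three observations are fitted, improved by two C-steps each, and the
best candidates are concentrated to a fixed point.  A hard-rejection
reweighting step is applied afterwards to recover efficiency.  Plain
LTS is the lam = 0 special case, and there is no intercept: inputs are
expected to be centered upstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
from scipy.special import comb
from scipy.stats import norm

from . import _kernels as _k
from .exceptions import DegenerateInputError, InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "LTSConfig",
    "RegressionFit",
    "l1_regression",
    "c_step",
    "sparse_lts",
    "sparse_lts_path",
    "reweighted_fit",
    "lts",
    "exhaustive_lts",
    "trimmed_variance_consistency",
    "hard_rejection_consistency",
]


@dataclass(frozen=True)
class LTSConfig:
    """Tuning constants of the sparse LTS concentration algorithm.

    trim_fraction
        Fraction of observations excluded from the criterion; 0.25 gives
        the recommended h = floor(0.75 n).
    n_elemental_subsets, n_keep
        Number of random 3-observation starting subsets and how many of
        the best warm-started candidates are concentrated to a fixed
        point (the standard 500 / 10 construction).
    max_csteps
        Cap on concentration steps per candidate.
    reweight_quantile
        Standard-normal quantile of the hard-rejection cutoff for the
        reweighting step.
    solver_tolerance
        Relative coordinate-change tolerance of the inner lasso solver.
    seed
        Seed for the elemental-subset draws; identical inputs and seed
        give identical fits.
    """

    trim_fraction: float = 0.25
    n_elemental_subsets: int = 500
    n_keep: int = 10
    max_csteps: int = 100
    reweight_quantile: float = 0.9875
    solver_tolerance: float = 1e-8
    seed: int = 0
    max_sweeps: int = 2000

    def __post_init__(self):
        if not 0.0 < self.trim_fraction <= 0.5:
            raise InvalidInputError("trim_fraction must be in (0, 0.5]")
        if self.n_elemental_subsets < 1 or self.n_keep < 1:
            raise InvalidInputError("subset counts must be positive")
        if self.n_keep > self.n_elemental_subsets:
            raise InvalidInputError("n_keep cannot exceed n_elemental_subsets")
        if not 0.5 < self.reweight_quantile < 1.0:
            raise InvalidInputError("reweight_quantile must be in (0.5, 1)")
        if self.max_csteps < 1:
            raise InvalidInputError("max_csteps must be positive")

    def h(self, n: int) -> int:
        """Size of the trimmed subsample, floor(n*(1-trim)), at least 1."""
        return max(1, int(math.floor(n * (1.0 - self.trim_fraction))))


@dataclass
class RegressionFit:
    """Result of one (sparse) LTS regression.

    ``subset`` holds the indices of the h smallest squared residuals
    (ties at the boundary keep the lowest index), ``objective`` is the
    trimmed criterion including the penalty, and ``scale`` a
    consistency-corrected robust residual scale.
    """

    coefficients: np.ndarray
    subset: np.ndarray
    residuals: np.ndarray
    objective: float
    scale: float
    df: int
    lam: float
    reweighted: bool = False

    @property
    def h(self) -> int:
        return self.subset.size


def trimmed_variance_consistency(alpha: float) -> float:
    """Fisher consistency factor for the sqrt of the mean of the
    ceil(alpha*n) smallest squared residuals under normal errors."""
    if alpha >= 1.0:
        return 1.0
    q = norm.ppf((1.0 + alpha) / 2.0)
    return math.sqrt(1.0 - 2.0 * q * norm.pdf(q) / alpha)


def hard_rejection_consistency(quantile: float) -> float:
    """Consistency factor for the residual scale of a hard-rejection
    refit with cutoff Phi^{-1}(quantile)."""
    c = norm.ppf(quantile)
    kept = 2.0 * quantile - 1.0
    return math.sqrt((kept - 2.0 * c * norm.pdf(c)) / kept)


def _validate(Z, y):
    Z = np.ascontiguousarray(Z, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if Z.ndim != 2 or y.ndim != 1 or Z.shape[0] != y.shape[0]:
        raise InvalidInputError("Z must be n x p and y length n")
    if not (np.isfinite(Z).all() and np.isfinite(y).all()):
        raise InvalidInputError("non-finite values in regression inputs")
    return Z, y


def l1_regression(Z, y, lam, subset, *, tol=1e-8, max_sweeps=2000, warm=None):
    """Minimize sum_{i in subset} (y_i - z_i'b)^2 + |subset|*lam*||b||_1.

    With lam = 0 this is the exact least-squares solution on the subset.
    ``warm`` optionally supplies a starting coefficient vector.
    """
    Z, y = _validate(Z, y)
    if lam < 0:
        raise InvalidInputError("lambda must be nonnegative")
    idx = np.asarray(subset, dtype=np.int64).ravel()
    if idx.size == 0:
        raise InvalidInputError("subset must be nonempty")
    beta = np.zeros(Z.shape[1]) if warm is None else np.array(warm, dtype=np.float64)
    _k.fit_subset(Z, y, idx, float(lam), beta, tol, max_sweeps)
    return beta


def _make_fit(beta, Z, y, lam, h, *, reweighted=False, scale=None) -> RegressionFit:
    """Assemble a RegressionFit from coefficients, recomputing residuals,
    the h-subset, the trimmed objective, and (unless given) the
    consistency-corrected trimmed residual scale."""
    residuals = y - Z @ beta
    r2 = residuals**2
    idx = np.sort(np.asarray(_k.smallest_h(r2, h)))
    objective = float(r2[idx].sum() + h * lam * np.abs(beta).sum())
    if scale is None:
        alpha = h / Z.shape[0]
        scale = math.sqrt(r2[idx].mean()) / trimmed_variance_consistency(alpha)
    return RegressionFit(
        coefficients=beta,
        subset=idx,
        residuals=residuals,
        objective=objective,
        scale=float(scale),
        df=int(np.count_nonzero(beta)),
        lam=float(lam),
        reweighted=reweighted,
    )


def c_step(fit: RegressionFit, Z, y, lam, h) -> RegressionFit:
    """One concentration step: refit on ``fit.subset``, recompute the
    residuals on all n observations, and return the fit whose subset is
    the h indices with smallest squared residuals.  The objective never
    increases."""
    Z, y = _validate(Z, y)
    if fit.subset.size != h:
        raise InvalidInputError("fit.subset must have size h")
    beta = l1_regression(Z, y, lam, fit.subset, warm=fit.coefficients)
    return _make_fit(beta, Z, y, lam, h)


def _elemental_subsets(rng, n, m):
    """m random subsets of 3 distinct observation indices."""
    k = min(3, n)
    return np.ascontiguousarray(
        np.argpartition(rng.random((m, n)), k - 1, axis=1)[:, :k].astype(np.int64)
    )


def _check_inputs(Z, y, config):
    n = Z.shape[0]
    if n < 3:
        raise InvalidInputError("at least 3 observations are required")
    if np.ptp(y) == 0.0:
        raise DegenerateInputError("response is constant")
    return config.h(n)


def sparse_lts(Z, y, lam, config: LTSConfig = LTSConfig(), *, warm=None,
               return_raw=False) -> RegressionFit:
    """Sparse LTS estimate at a single penalty value.

    Runs the random-start concentration search (or, when ``warm`` gives
    starting coefficients, concentrates from those) and applies the
    reweighting step.  Deterministic given ``config.seed``.  With
    ``return_raw`` the pre-reweighting fit is returned alongside.
    """
    Z, y = _validate(Z, y)
    h = _check_inputs(Z, y, config)
    lam = float(lam)
    if lam < 0:
        raise InvalidInputError("lambda must be nonnegative")
    if warm is None:
        rng = np.random.default_rng(config.seed)
        elem = _elemental_subsets(rng, Z.shape[0], config.n_elemental_subsets)
        beta, _, _, _ = _k.lts_search(
            Z, y, h, lam, elem, config.n_keep,
            config.solver_tolerance, config.max_sweeps, config.max_csteps,
        )
    else:
        beta = np.array(warm, dtype=np.float64)
        _k.concentrate(
            Z, y, beta, h, lam,
            config.solver_tolerance, config.max_sweeps, config.max_csteps,
        )
    raw = _make_fit(beta, Z, y, lam, h)
    refit = reweighted_fit(raw, Z, y, lam, config)
    return (refit, raw) if return_raw else refit


def reweighted_fit(raw: RegressionFit, Z, y, lam, config: LTSConfig) -> RegressionFit:
    """Hard-rejection reweighting of a raw trimmed fit.

    Observations with |residual|/scale above Phi^{-1}(reweight_quantile)
    get weight zero; the penalized regression is refitted on the
    weight-one set.  Falls back to the raw fit when fewer than two
    observations survive.
    """
    Z, y = _validate(Z, y)
    cutoff = norm.ppf(config.reweight_quantile)
    if raw.scale == 0.0:
        keep = raw.residuals == 0.0
    else:
        keep = np.abs(raw.residuals) / raw.scale <= cutoff
    n_keep = int(keep.sum())
    if n_keep < 2:
        logger.warning(
            "reweighting kept %d observation(s); returning raw fit", n_keep
        )
        return raw
    idx = np.flatnonzero(keep).astype(np.int64)
    beta = l1_regression(
        Z, y, lam, idx,
        tol=config.solver_tolerance, max_sweeps=config.max_sweeps,
        warm=raw.coefficients,
    )
    residuals = y - Z @ beta
    kept_ss = float((residuals[idx] ** 2).sum())
    scale = math.sqrt(kept_ss / n_keep) / hard_rejection_consistency(
        config.reweight_quantile
    )
    return _make_fit(beta, Z, y, lam, raw.h, reweighted=True, scale=scale)


def lts(Z, y, config: LTSConfig = LTSConfig()) -> RegressionFit:
    """Plain least trimmed squares: sparse LTS with lam = 0."""
    return sparse_lts(Z, y, 0.0, config)


def sparse_lts_path(Z, y, lams, config: LTSConfig = LTSConfig(), *, warm_betas=None):
    """Sparse LTS fits along a decreasing penalty grid.

    The full random-start search is run for the first penalty only;
    each subsequent penalty is concentrated from the previous penalty's
    raw solution (and from the caller-supplied ``warm_betas`` when
    given, e.g. the raw solutions of the previous alternation step),
    keeping whichever fixed point has the lower objective.  Returns the
    list of reweighted fits and the array of raw coefficient paths for
    reuse as warm starts.
    """
    Z, y = _validate(Z, y)
    h = _check_inputs(Z, y, config)
    lams = np.asarray(lams, dtype=np.float64)
    if lams.size == 0:
        raise InvalidInputError("empty penalty grid")
    if np.any(np.diff(lams) > 0):
        raise InvalidInputError("penalty grid must be non-increasing")
    tol, sweeps, steps = config.solver_tolerance, config.max_sweeps, config.max_csteps
    p = Z.shape[1]
    raw_betas = np.empty((lams.size, p))
    fits = []
    prev = None
    for k, lam in enumerate(lams):
        candidates = []
        if prev is not None:
            candidates.append(prev.copy())
        if warm_betas is not None:
            candidates.append(np.array(warm_betas[k], dtype=np.float64))
        if not candidates:
            rng = np.random.default_rng(config.seed)
            elem = _elemental_subsets(rng, Z.shape[0], config.n_elemental_subsets)
            beta, _, obj, _ = _k.lts_search(
                Z, y, h, lam, elem, config.n_keep, tol, sweeps, steps
            )
        else:
            beta, obj = None, np.inf
            for cand in candidates:
                _, o, _, _ = _k.concentrate(Z, y, cand, h, lam, tol, sweeps, steps)
                if o < obj:
                    beta, obj = cand, o
        raw_betas[k] = beta
        prev = beta
        raw = _make_fit(beta.copy(), Z, y, lam, h)
        fits.append(reweighted_fit(raw, Z, y, lam, config))
    return fits, raw_betas


def exhaustive_lts(Z, y, lam, h, *, tol=1e-12, max_sweeps=50000):
    """Exact trimmed optimum by enumerating every h-subset.

    Independent oracle for tiny problems (cost C(n, h) penalized least
    squares fits); returns (beta, subset, objective).
    """
    Z, y = _validate(Z, y)
    n = Z.shape[0]
    if comb(n, h) > 2e5:
        raise InvalidInputError("exhaustive enumeration is limited to tiny n")
    best = (None, None, np.inf)
    for subset in combinations(range(n), h):
        idx = np.asarray(subset, dtype=np.int64)
        beta = l1_regression(Z, y, lam, idx, tol=tol, max_sweeps=max_sweeps)
        r2 = (y[idx] - Z[idx] @ beta) ** 2
        obj = float(r2.sum() + h * lam * np.abs(beta).sum())
        if obj < best[2]:
            best = (beta, idx, obj)
    return best
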