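"""Sequential alternating-regression canonical correlation analysis.

Canonical vector pairs are estimated one at a time by alternating
penalized regressions: with the x-side vector a fixed, the y-side
vector b solves a (sparse, trimmed) regression of the variate Xa on Y,
and vice versa, until the trimmed mean of the squared discrepancies
(1/h) sum_{i<=h} (a'x_i - b'y_i)^2_{i:n} stabilizes.  Higher-order
pairs are fitted on deflated matrices (residuals of regressing each
column on the lower-order variates) and re-expressed in the original
variables by one more sparse regression.

Four presets share this algorithm and differ only in the regression
engine, centering, correlation estimator, and initialization:

=================  ============= ========= =========== =================
preset             engine        centering correlation initialization
=================  ============= ========= =========== =================
cca                least-squares mean      pearson     classical-pc1
sparse-cca         lasso         mean      pearson     classical-pc1
robust-cca         lts           median    mcd         spatial-sign-pc1
robust-sparse-cca  sparse-lts    median    mcd         spatial-sign-pc1
=================  ============= ========= =========== =================
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import robuststats as rstat
from . import sparselts as slts
from .exceptions import (
    DegenerateInputError,
    InvalidInputError,
    RankDeficiencyError,
    SelectionError,
)
from .sparselts import LTSConfig, RegressionFit

logger = logging.getLogger(__name__)

__all__ = [
    "EstimatorSpec",
    "PairFit",
    "CCAFit",
    "preset",
    "PRESETS",
    "regress",
    "bic_select",
    "alternate_pair",
    "initial_direction",
    "deflate",
    "reexpress",
    "canonical_correlation",
    "select_rank",
    "fit_cca",
]

_ENGINES = ("least-squares", "lasso", "lts", "sparse-lts")
_TRIMMED = ("lts", "sparse-lts")
_PENALIZED = ("lasso", "sparse-lts")


@dataclass(frozen=True)
class EstimatorSpec:
    """Configuration of one CCA estimator variant.

    ``lambda_grid=None`` (the default) rebuilds the penalty grid at
    every regression: ``n_lambda`` log-spaced values descending from the
    smallest penalty that zeroes all coefficients on the current
    response/design down to ``lambda_min_ratio`` times it, which keeps
    the grid adapted to the data scale.  ``epsilon`` is the relative
    tolerance on the convergence criterion and ``max_iter`` the cap on
    alternation cycles.
    """

    engine: str = "sparse-lts"
    centering: str = "median"
    correlation: str = "mcd"
    init: str = "spatial-sign-pc1"
    lts_config: LTSConfig = field(default_factory=LTSConfig)
    lambda_grid: tuple | None = None
    n_lambda: int = 20
    lambda_min_ratio: float = 1e-3
    epsilon: float = 1e-2
    max_iter: int = 50
    n_init: int = 3

    def __post_init__(self):
        if self.engine not in _ENGINES:
            raise InvalidInputError(f"unknown engine {self.engine!r}")
        if self.centering not in ("mean", "median"):
            raise InvalidInputError(f"unknown centering {self.centering!r}")
        if self.correlation not in ("pearson", "mcd"):
            raise InvalidInputError(f"unknown correlation {self.correlation!r}")
        if self.init not in ("classical-pc1", "spatial-sign-pc1"):
            raise InvalidInputError(f"unknown init {self.init!r}")

    @property
    def trimmed(self) -> bool:
        return self.engine in _TRIMMED

    @property
    def penalized(self) -> bool:
        return self.engine in _PENALIZED

    def with_seed(self, seed: int) -> "EstimatorSpec":
        return replace(self, lts_config=replace(self.lts_config, seed=int(seed)))


# The three comparator presets replicate the published benchmark
# estimators exactly, including their single principal-component-based
# starting value; the robust sparse estimator defaults to a small
# multi-start (n_init=3) because the penalized alternation has
# absorbing spurious fixed points (see fit_cca).
PRESETS = {
    "cca": dict(engine="least-squares", centering="mean",
                correlation="pearson", init="classical-pc1", n_init=1),
    "sparse-cca": dict(engine="lasso", centering="mean",
                       correlation="pearson", init="classical-pc1", n_init=1),
    "robust-cca": dict(engine="lts", centering="median",
                       correlation="mcd", init="spatial-sign-pc1", n_init=1),
    "robust-sparse-cca": dict(engine="sparse-lts", centering="median",
                              correlation="mcd", init="spatial-sign-pc1",
                              n_init=3),
}


def preset(name: str, **overrides) -> EstimatorSpec:
    """EstimatorSpec for one of the four named estimators."""
    if name not in PRESETS:
        raise InvalidInputError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        )
    return EstimatorSpec(**{**PRESETS[name], **overrides})


@dataclass
class PairFit:
    """One canonical vector pair.

    ``u`` and ``v`` are the variates of the stage the pair was accepted
    at: for the first pair the centered data, for higher-order pairs the
    re-expressed variates X a / Y b on the original (centered) matrices.
    """

    a: np.ndarray
    b: np.ndarray
    u: np.ndarray
    v: np.ndarray
    rho: float
    n_iter: int
    converged: bool
    lambda_a: float
    lambda_b: float


@dataclass
class CCAFit:
    """Full sequential CCA fit with r canonical vector pairs."""

    A: np.ndarray
    B: np.ndarray
    U: np.ndarray
    V: np.ndarray
    rho: np.ndarray
    pairs: list
    r: int
    spec: EstimatorSpec
    centers_x: np.ndarray
    centers_y: np.ndarray

    def save(self, directory):
        """Write the fit as CSV blocks plus a key/value summary."""
        import pandas as pd

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, arr in [("A", self.A), ("B", self.B),
                          ("U", self.U), ("V", self.V)]:
            pd.DataFrame(arr).to_csv(directory / f"{name}.csv", index=False)
        pd.DataFrame({"rho": self.rho}).to_csv(directory / "rho.csv", index=False)
        lines = [
            f"r: {self.r}",
            f"engine: {self.spec.engine}",
            f"centering: {self.spec.centering}",
            f"correlation: {self.spec.correlation}",
            f"init: {self.spec.init}",
            f"centers_x: {','.join(f'{c:.10g}' for c in self.centers_x)}",
            f"centers_y: {','.join(f'{c:.10g}' for c in self.centers_y)}",
        ]
        for j, pair in enumerate(self.pairs, start=1):
            lines.append(
                f"pair{j}: rho={pair.rho:.6f} iters={pair.n_iter} "
                f"converged={pair.converged} lambda_a={pair.lambda_a:.6g} "
                f"lambda_b={pair.lambda_b:.6g}"
            )
        (directory / "summary.txt").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# regression dispatch and penalty selection


def _as_xy(Z, y):
    Z = np.ascontiguousarray(Z, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64).ravel()
    if Z.shape[0] != y.shape[0]:
        raise InvalidInputError("Z and y disagree on n")
    return Z, y


def regress(Z, y, lam, spec: EstimatorSpec) -> RegressionFit:
    """Uniform regression front-end for the four engines.

    least-squares ignores lam; lasso fits on the full sample; lts is the
    trimmed engine at lam = 0; sparse-lts is trimmed and penalized.
    """
    Z, y = _as_xy(Z, y)
    n, p = Z.shape
    if spec.engine == "least-squares":
        if p >= n:
            raise RankDeficiencyError(
                "least squares needs p < n; use a penalized engine "
                "(lasso or sparse-lts) for high-dimensional data"
            )
        beta = np.linalg.lstsq(Z, y, rcond=None)[0]
        return slts._make_fit(beta, Z, y, 0.0, n)
    if spec.engine == "lasso":
        beta = slts.l1_regression(
            Z, y, lam, np.arange(n),
            tol=spec.lts_config.solver_tolerance,
            max_sweeps=spec.lts_config.max_sweeps,
        )
        return slts._make_fit(beta, Z, y, float(lam), n)
    if spec.engine == "lts":
        return slts.lts(Z, y, spec.lts_config)
    return slts.sparse_lts(Z, y, lam, spec.lts_config)


def _lambda_grid(Z, y, spec: EstimatorSpec):
    if spec.lambda_grid is not None:
        grid = np.sort(np.asarray(spec.lambda_grid, dtype=np.float64))[::-1]
        if grid.size == 0 or grid[-1] <= 0:
            raise InvalidInputError("lambda_grid must contain positive values")
        return grid
    lam_zero = 2.0 * np.max(np.abs(Z.T @ y)) / Z.shape[0]
    if lam_zero <= 0 or not np.isfinite(lam_zero):
        raise SelectionError("response is orthogonal to every predictor")
    return lam_zero * np.logspace(0.0, math.log10(spec.lambda_min_ratio),
                                  spec.n_lambda)


def _bic(fit: RegressionFit, n: int) -> float:
    mean_r2 = float((fit.residuals[fit.subset] ** 2).mean())
    return n * math.log(max(mean_r2, 1e-300)) + fit.df * math.log(n)


def bic_select(Z, y, spec: EstimatorSpec, *, warm=None, require_nonzero=False,
               return_state=False):
    """Penalty selection by the Bayesian Information Criterion

        BIC(lam) = n log((1/h) sum_{i<=h} (r^2)_{i:n}) + df log(n),

    with h = n for untrimmed engines.  Returns the minimizing penalty
    and its fit.  With ``require_nonzero`` the all-zero fits are
    excluded from selection (a canonical vector must be nonzero).
    ``warm``/``return_state`` thread raw coefficient paths through
    successive calls as warm starts for the trimmed search.
    """
    Z, y = _as_xy(Z, y)
    n = Z.shape[0]
    if not spec.penalized:
        if spec.engine == "lts" and warm is not None:
            # concentrate from the previous alternation step's solution
            # instead of repeating the full random-start search
            fit = slts.sparse_lts(Z, y, 0.0, spec.lts_config, warm=warm)
        else:
            fit = regress(Z, y, 0.0, spec)
        if return_state:
            state = fit.coefficients if spec.engine == "lts" else None
            return 0.0, fit, state
        return 0.0, fit
    grid = _lambda_grid(Z, y, spec)
    state = None
    if spec.engine == "sparse-lts":
        fits, state = slts.sparse_lts_path(
            Z, y, grid, spec.lts_config, warm_betas=warm
        )
    else:  # lasso: convex, simple warm start down the grid
        fits = []
        beta = np.zeros(Z.shape[1])
        for lam in grid:
            beta = slts.l1_regression(
                Z, y, lam, np.arange(n),
                tol=spec.lts_config.solver_tolerance,
                max_sweeps=spec.lts_config.max_sweeps, warm=beta,
            )
            fits.append(slts._make_fit(beta.copy(), Z, y, float(lam), n))
    bics = np.array([_bic(f, n) for f in fits])
    # Guard against the interpolation regime: when the (trimmed) subset
    # can be fitted with about as many parameters as observations the
    # residual term of BIC diverges to -inf and selection would always
    # return the saturated fit.  Fits using more than half the
    # effective sample are therefore excluded; if nothing survives, the
    # sparsest usable fit is taken.
    h_eff = fits[0].h
    dfs = np.array([f.df for f in fits])
    usable = dfs <= max(1, h_eff // 2)
    if require_nonzero:
        usable &= dfs > 0
        if not (dfs > 0).any():
            raise SelectionError("every candidate fit is identically zero")
    if usable.any():
        bics = np.where(usable, bics, np.inf)
        k = int(np.argmin(bics))
    else:
        pos = dfs > 0 if require_nonzero else np.ones_like(dfs, bool)
        k = int(np.flatnonzero(pos)[np.argmin(dfs[pos])])
    if return_state:
        return float(grid[k]), fits[k], state
    return float(grid[k]), fits[k]


# ---------------------------------------------------------------------------
# the alternating algorithm


def _unit(v):
    nrm = np.linalg.norm(v)
    if nrm == 0 or not np.isfinite(nrm):
        raise DegenerateInputError("cannot normalize a zero vector")
    return v / nrm


def canonical_correlation(u, v, spec: EstimatorSpec) -> float:
    """Correlation between two canonical variates: bivariate MCD with
    25 % trimming for the robust variants, Pearson otherwise."""
    u = np.asarray(u, dtype=np.float64).ravel()
    v = np.asarray(v, dtype=np.float64).ravel()
    if u.size < 4:
        raise InvalidInputError("need n >= 4")
    if spec.correlation == "mcd":
        return rstat.mcd_corr2(u, v, seed=spec.lts_config.seed)
    su, sv = u.std(), v.std()
    if su == 0 or sv == 0:
        raise DegenerateInputError("zero-variance canonical variate")
    return float(np.clip(np.corrcoef(u, v)[0, 1], -1.0, 1.0))


def _criterion(Xl, Yl, a, b, h):
    r2 = (Xl @ a - Yl @ b) ** 2
    return float(np.sort(r2)[:h].mean())


def alternate_pair(Xl, Yl, spec: EstimatorSpec, a0) -> PairFit:
    """Alternating regressions for one canonical vector pair on the
    (deflated) matrices Xl, Yl, starting from the x-side direction a0.

    One iteration updates b given a (regression of Xl a on Yl) and a
    given b; each update selects its penalty by BIC and renormalizes to
    unit length.  Iteration stops when the relative change of the
    trimmed mean of squared discrepancies falls below ``spec.epsilon``
    or after ``spec.max_iter`` iterations (last iterate returned with
    ``converged=False``).
    """
    Xl = np.ascontiguousarray(Xl, dtype=np.float64)
    Yl = np.ascontiguousarray(Yl, dtype=np.float64)
    a0 = np.asarray(a0, dtype=np.float64).ravel()
    if a0.shape[0] != Xl.shape[1]:
        raise InvalidInputError("a0 has the wrong length")
    a = _unit(a0)
    b = None
    n = Xl.shape[0]
    h = spec.lts_config.h(n) if spec.trimmed else n
    warm_a = warm_b = None
    lam_a = lam_b = 0.0
    crit_prev = None
    converged = False
    n_iter = 0
    for n_iter in range(1, spec.max_iter + 1):
        u = Xl @ a
        if np.ptp(u) == 0.0:
            raise DegenerateInputError("x-side variate has zero variance")
        lam_b, fit_b, warm_b = bic_select(
            Yl, u, spec, warm=warm_b, require_nonzero=True, return_state=True
        )
        b = _unit(fit_b.coefficients)
        v = Yl @ b
        if np.ptp(v) == 0.0:
            raise DegenerateInputError("y-side variate has zero variance")
        lam_a, fit_a, warm_a = bic_select(
            Xl, v, spec, warm=warm_a, require_nonzero=True, return_state=True
        )
        a = _unit(fit_a.coefficients)
        crit = _criterion(Xl, Yl, a, b, h)
        if crit_prev is not None:
            if crit_prev == 0.0:
                rel = 0.0 if crit == 0.0 else np.inf
            else:
                rel = abs(crit - crit_prev) / crit_prev
            if rel < spec.epsilon:
                converged = True
                break
        crit_prev = crit
    else:
        # routine event (the last iterate is a valid estimate), so not a
        # warning; callers see the flag on the returned pair
        logger.info("alternation did not converge within %d iterations",
                    spec.max_iter)
    a_fixed = rstat.sign_fix(a)
    flip_a = not np.array_equal(a_fixed, a)
    b_fixed = rstat.sign_fix(b)
    flip_b = not np.array_equal(b_fixed, b)
    u = Xl @ a_fixed
    v = Yl @ b_fixed
    rho = canonical_correlation(u, v, spec)
    return PairFit(a=a_fixed, b=b_fixed, u=u, v=v, rho=rho,
                   n_iter=n_iter, converged=converged,
                   lambda_a=lam_a, lambda_b=lam_b)


def _initial_candidates(X, Y, spec: EstimatorSpec, k: int):
    """Candidate starting directions from the first k (robust)
    principal components of Y, each regressed on X; falls back to e1
    when every candidate degenerates."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    Y = np.ascontiguousarray(Y, dtype=np.float64)
    try:
        if spec.init == "spatial-sign-pc1":
            W = rstat.robust_pcs(rstat.median_center(Y)[0], k, "spatial-sign")
        else:
            W = rstat.robust_pcs(Y - Y.mean(axis=0), k, "classical")
    except DegenerateInputError:
        W = np.empty((Y.shape[1], 0))
    candidates = []
    for j in range(W.shape[1]):
        z = Y @ W[:, j]
        if np.ptp(z) == 0.0:
            continue
        try:
            _, fit = bic_select(X, z, spec, require_nonzero=True)
            candidates.append(_unit(fit.coefficients))
        except (DegenerateInputError, SelectionError):
            continue
    if not candidates:
        logger.warning("initial direction fell back to e1")
        e1 = np.zeros(X.shape[1])
        e1[0] = 1.0
        candidates.append(e1)
    return candidates


def initial_direction(X, Y, spec: EstimatorSpec):
    """Starting direction for the x-side canonical vector.

    Computes the first (robust) principal component z1 of Y, regresses
    z1 on X with the spec's engine, and returns the unit-normalized
    coefficients.  Falls back to e1 when the regression degenerates.
    """
    return _initial_candidates(X, Y, spec, 1)[0]


def deflate(X, U_prev, spec: EstimatorSpec):
    """Residuals of a column-by-column regression of X on the
    lower-order canonical variates, with the trimmed (LTS, lam = 0)
    engine for the robust variants and least squares otherwise."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    U_prev = np.ascontiguousarray(U_prev, dtype=np.float64)
    if U_prev.ndim != 2 or U_prev.shape[0] != X.shape[0]:
        raise InvalidInputError("U_prev must be n x (l-1)")
    if np.linalg.matrix_rank(U_prev) < U_prev.shape[1]:
        raise InvalidInputError("U_prev is rank deficient")
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        if spec.trimmed:
            fit = slts.lts(U_prev, X[:, j], spec.lts_config)
            beta = fit.coefficients
        else:
            beta = np.linalg.lstsq(U_prev, X[:, j], rcond=None)[0]
        out[:, j] = X[:, j] - U_prev @ beta
    return out


def reexpress(u_star, X, spec: EstimatorSpec):
    """Express a higher-order variate in the original variables.

    Regresses the deflated-stage variate on the original (centered)
    matrix with the spec's engine (BIC-selected penalty for the sparse
    engines), normalizes the coefficients, and returns (a, X a).
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    u_star = np.asarray(u_star, dtype=np.float64).ravel()
    if np.ptp(u_star) == 0.0:
        raise DegenerateInputError("degenerate variate to re-express")
    if spec.penalized:
        _, fit = bic_select(X, u_star, spec, require_nonzero=True)
        coef = fit.coefficients
    else:
        coef = regress(X, u_star, 0.0, spec).coefficients
    a = _unit(coef)
    return a, X @ a


def select_rank(rho) -> int:
    """Maximum eigenvalue ratio criterion: r = argmax_j |rho_j|/|rho_{j+1}|
    over j = 1..rmax-1, ties resolved at the smallest j."""
    rho = np.abs(np.asarray(rho, dtype=np.float64).ravel())
    if rho.size < 2:
        return 1
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = rho[:-1] / rho[1:]
    ratios = np.where(np.isnan(ratios), -np.inf, ratios)
    return int(np.argmax(ratios)) + 1


def fit_cca(X, Y, spec: EstimatorSpec = EstimatorSpec(), r="auto") -> CCAFit:
    """Fit the sequential alternating-regression CCA.

    Centers both matrices (mean or median per the spec), fits the first
    pair on the centered data, and each higher-order pair on matrices
    deflated against all lower-order variates, re-expressing the result
    in the original variables.  With ``r="auto"`` fits
    rmax = min(p, q, 10) pairs and truncates at the maximum eigenvalue
    ratio criterion.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    Y = np.ascontiguousarray(Y, dtype=np.float64)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise InvalidInputError("X and Y must share the observation dimension")
    n, p = X.shape
    q = Y.shape[1]
    if n < 4:
        raise InvalidInputError("need at least 4 observations")
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise InvalidInputError("non-finite entries in the data")
    if spec.engine == "least-squares" and max(p, q) >= n:
        raise RankDeficiencyError(
            "classical CCA requires n > max(p, q); use sparse-cca or "
            "robust-sparse-cca for high-dimensional data"
        )
    rmax = min(p, q, 10)
    if r == "auto":
        n_pairs = rmax
    else:
        n_pairs = int(r)
        if not 1 <= n_pairs <= rmax:
            raise InvalidInputError(f"r must be in [1, {rmax}]")
    if spec.centering == "median":
        Xc, cx = rstat.median_center(X)
        Yc, cy = rstat.median_center(Y)
    else:
        cx, cy = X.mean(axis=0), Y.mean(axis=0)
        Xc, Yc = X - cx, Y - cy
    pairs = []
    U = np.empty((n, 0))
    V = np.empty((n, 0))
    h_crit = spec.lts_config.h(n) if spec.trimmed else n
    for l in range(n_pairs):
        if l == 0:
            Xd, Yd = Xc, Yc
        else:
            Xd = deflate(Xc, U, spec)
            Yd = deflate(Yc, V, spec)
        # Penalized engines can be absorbed into a spurious sparse fixed
        # point when the starting direction carries no signal (exact
        # zeros never re-enter the alternation), so the alternation is
        # run from directions derived from the first few principal
        # components of Y and the solution with the smallest trimmed
        # discrepancy -- the quantity the estimator minimizes -- wins.
        # Candidates are screened with two alternation cycles (the
        # basins separate quickly); only the best start runs to
        # convergence.
        k_init = spec.n_init if spec.penalized else 1
        candidates = _initial_candidates(Xd, Yd, spec, k_init)
        if len(candidates) > 1:
            screen_spec = replace(spec, max_iter=2)
            scored = []
            for a0 in candidates:
                try:
                    cand = alternate_pair(Xd, Yd, screen_spec, a0)
                except (DegenerateInputError, SelectionError) as exc:
                    logger.info("alternation start discarded: %s", exc)
                    continue
                scored.append((_criterion(Xd, Yd, cand.a, cand.b, h_crit), a0))
            if scored:
                candidates = [min(scored, key=lambda t: t[0])[1]]
        pair = None
        for a0 in candidates:
            try:
                pair = alternate_pair(Xd, Yd, spec, a0)
                break
            except (DegenerateInputError, SelectionError) as exc:
                logger.info("alternation start discarded: %s", exc)
        if pair is None:
            raise DegenerateInputError(
                f"no usable alternation solution for pair {l + 1}"
            )
        if l > 0:
            a, u = reexpress(pair.u, Xc, spec)
            b, v = reexpress(pair.v, Yc, spec)
            a = rstat.sign_fix(a)
            u = Xc @ a
            b = rstat.sign_fix(b)
            v = Yc @ b
            rho = canonical_correlation(u, v, spec)
            pair = replace(pair, a=a, b=b, u=u, v=v, rho=rho)
        pairs.append(pair)
        U = np.column_stack([U, pair.u])
        V = np.column_stack([V, pair.v])
    rho = np.array([pr.rho for pr in pairs])
    if r == "auto":
        r_sel = select_rank(rho)
        pairs = pairs[:r_sel]
        rho = rho[:r_sel]
        U, V = U[:, :r_sel], V[:, :r_sel]
    A = np.column_stack([pr.a for pr in pairs])
    B = np.column_stack([pr.b for pr in pairs])
    return CCAFit(A=A, B=B, U=U, V=V, rho=rho, pairs=pairs, r=len(pairs),
                  spec=spec, centers_x=cx, centers_y=cy)
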