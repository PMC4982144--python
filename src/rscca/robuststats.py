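"""Robust multivariate building blocks.

Median centering, the spatial sign covariance matrix and the robust
first principal component derived from it, the Minimum Covariance
Determinant (MCD) estimator with 25 % trimming (bivariate correlations
and multivariate robust distances), and van der Waerden normal scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.special import comb
from scipy.stats import chi2, norm, rankdata

from .exceptions import DegenerateInputError, InvalidInputError

__all__ = [
    "CovEstimate",
    "median_center",
    "spatial_sign_cov",
    "robust_pc1",
    "robust_pcs",
    "sign_fix",
    "mcd",
    "mcd_corr2",
    "robust_distances",
    "distance_cutoff",
    "normal_scores",
    "mcd_consistency",
]

EXHAUSTIVE_LIMIT = 10_000  # enumerate all h-subsets when C(n, h) is below this


@dataclass
class CovEstimate:
    """Location/scatter estimate with its provenance.

    For ``method="mcd"`` the scatter is the maximum-likelihood
    covariance of the determinant-minimal h-subset (no consistency
    factor applied) and ``subset`` holds that subset.
    """

    location: np.ndarray
    scatter: np.ndarray
    method: str
    subset: np.ndarray | None = None


def _as_matrix(M):
    M = np.asarray(M, dtype=np.float64)
    if M.ndim != 2:
        raise InvalidInputError("expected a 2-d data matrix")
    if not np.isfinite(M).all():
        raise InvalidInputError("non-finite entries in data matrix")
    return M


def median_center(M):
    """Subtract the columnwise median; returns (centered, medians)."""
    M = _as_matrix(M)
    med = np.median(M, axis=0)
    return M - med, med


def spatial_sign_cov(M):
    """Spatial sign covariance (1/n) sum_i s_i s_i' with s_i = m_i/||m_i||.

    Rows with zero norm contribute a zero sign vector.  The input is
    expected to be robustly centered already.
    """
    M = _as_matrix(M)
    norms = np.linalg.norm(M, axis=1)
    S = np.where(norms[:, None] > 0, M / np.where(norms == 0, 1.0, norms)[:, None], 0.0)
    return (S.T @ S) / M.shape[0]


def sign_fix(v):
    """Deterministic sign convention: the entry of largest absolute
    value is positive (ties resolved at the lowest index)."""
    v = np.asarray(v, dtype=np.float64)
    j = int(np.argmax(np.abs(v)))
    return -v if v[j] < 0 else v.copy()


def robust_pcs(M, k: int, method: str = "spatial-sign"):
    """First k eigenvectors (descending eigenvalue) of a (robust)
    covariance estimate of M, as columns.

    ``method="spatial-sign"`` uses the spatial sign covariance (input
    assumed median-centered); ``method="classical"`` uses the ordinary
    covariance matrix.  Only directions with positive eigenvalue are
    returned, each with unit norm and the package-wide sign convention.
    """
    M = _as_matrix(M)
    if method == "spatial-sign":
        C = spatial_sign_cov(M)
    elif method == "classical":
        Mc = M - M.mean(axis=0)
        C = (Mc.T @ Mc) / max(1, M.shape[0] - 1)
    else:
        raise InvalidInputError(f"unknown method {method!r}")
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals, kind="stable")[::-1]
    keep = [j for j in order[:k] if vals[j] > 0 and np.isfinite(vals[j])]
    if not keep:
        raise DegenerateInputError("covariance has no positive eigenvalue")
    return np.column_stack(
        [sign_fix(vecs[:, j] / np.linalg.norm(vecs[:, j])) for j in keep]
    )


def robust_pc1(M, method: str = "spatial-sign"):
    """Leading eigenvector of a (robust) covariance estimate of M; see
    :func:`robust_pcs`."""
    return robust_pcs(M, 1, method)[:, 0]


# ---------------------------------------------------------------------------
# Minimum Covariance Determinant


def _subset_stats(M, subsets):
    """Batched ML mean/covariance over an (m, k) index array."""
    pts = M[subsets]                      # (m, k, d)
    mu = pts.mean(axis=1)                 # (m, d)
    C = pts - mu[:, None, :]
    S = np.einsum("mkd,mke->mde", C, C) / subsets.shape[1]
    return mu, S


def _batched_distances(M, mu, S):
    """Squared Mahalanobis-type distances of every row of M to each
    (mu, S) pair; singular scatters fall back to the pseudo-inverse."""
    try:
        Sinv = np.linalg.inv(S)
    except np.linalg.LinAlgError:
        Sinv = np.linalg.pinv(S)
    D = M[None, :, :] - mu[:, None, :]     # (m, n, d)
    return np.einsum("mnd,mde,mne->mn", D, Sinv, D)


def _logdet(S):
    sign, ld = np.linalg.slogdet(S)
    ld = np.where(sign > 0, ld, -np.inf)
    return ld


def _mcd_exhaustive(M, h):
    n = M.shape[0]
    best_idx, best_ld = None, np.inf
    for subset in combinations(range(n), h):
        idx = np.asarray(subset)
        mu = M[idx].mean(axis=0)
        C = M[idx] - mu
        S = (C.T @ C) / h
        sign, ld = np.linalg.slogdet(S)
        ld = ld if sign > 0 else -np.inf
        if ld < best_ld:
            best_idx, best_ld = idx, ld
    return best_idx


def _mcd_fast(M, h, n_subsets, n_keep, max_csteps, seed):
    n, d = M.shape
    rng = np.random.default_rng(seed)
    k = min(d + 1, n)
    subsets = np.argpartition(rng.random((n_subsets, n)), k - 1, axis=1)[:, :k]
    # two batched warm-up concentration steps from every elemental start
    for _ in range(2):
        mu, S = _subset_stats(M, subsets)
        d2 = _batched_distances(M, mu, S)
        subsets = np.argsort(d2, kind="stable", axis=1)[:, :h]
    mu, S = _subset_stats(M, subsets)
    order = np.argsort(_logdet(S), kind="stable")
    best_idx, best_ld = None, np.inf
    for t in order[: min(n_keep, n_subsets)]:
        idx = subsets[t]
        for _ in range(max_csteps):
            mu, S = _subset_stats(M, idx[None, :])
            d2 = _batched_distances(M, mu, S)[0]
            new_idx = np.argsort(d2, kind="stable")[:h]
            if np.array_equal(np.sort(new_idx), np.sort(idx)):
                idx = new_idx
                break
            idx = new_idx
        _, S = _subset_stats(M, idx[None, :])
        ld = float(_logdet(S)[0])
        if ld < best_ld:
            best_idx, best_ld = idx, ld
    return np.sort(best_idx)


def mcd(M, h=None, *, n_subsets=500, n_keep=10, max_csteps=100, seed=0) -> CovEstimate:
    """Raw MCD location/scatter with subsample size h (default
    floor(0.75 n)).

    Enumerates every h-subset when C(n, h) <= 10^4, otherwise runs the
    fast concentration algorithm from 500 random (d+1)-subsets.  The
    scatter is the ML covariance of the optimal subset without
    consistency correction.
    """
    M = _as_matrix(M)
    n, d = M.shape
    if h is None:
        h = max(1, int(math.floor(0.75 * n)))
    if not d + 1 <= h <= n:
        raise InvalidInputError("need d+1 <= h <= n for the MCD")
    if comb(n, h) <= EXHAUSTIVE_LIMIT:
        idx = _mcd_exhaustive(M, h)
    else:
        idx = _mcd_fast(M, h, n_subsets, n_keep, max_csteps, seed)
    mu = M[idx].mean(axis=0)
    C = M[idx] - mu
    S = (C.T @ C) / h
    return CovEstimate(location=mu, scatter=S, method="mcd", subset=np.asarray(idx))


def mcd_corr2(u, v, *, trim_fraction=0.25, seed=0) -> float:
    """Robust correlation from the bivariate raw MCD scatter with 25 %
    trimming."""
    u = np.asarray(u, dtype=np.float64).ravel()
    v = np.asarray(v, dtype=np.float64).ravel()
    if u.size != v.size or u.size < 4:
        raise InvalidInputError("need two equal-length vectors with n >= 4")
    M = np.column_stack([u, v])
    n = u.size
    h = max(3, int(math.floor((1.0 - trim_fraction) * n)))
    est = mcd(M, h, seed=seed)
    s = est.scatter
    if s[0, 0] <= 0 or s[1, 1] <= 0:
        raise DegenerateInputError("zero variance within the optimal subset")
    r = s[0, 1] / math.sqrt(s[0, 0] * s[1, 1])
    return float(np.clip(r, -1.0, 1.0))


def mcd_consistency(alpha: float, d: int) -> float:
    """Consistency factor multiplying the raw MCD scatter so that it
    estimates the covariance matrix under multivariate normality."""
    q = chi2.ppf(alpha, d)
    return alpha / chi2.cdf(q, d + 2)


def distance_cutoff(d: int, quantile: float = 0.975) -> float:
    """Outlier-flagging cutoff sqrt(chi2_quantile(d))."""
    return math.sqrt(chi2.ppf(quantile, d))


def robust_distances(M, method: str = "mcd", *, trim_fraction=0.25, seed=0):
    """Mahalanobis-type distances from an MCD (or classical)
    location/scatter estimate.

    The MCD scatter uses 25 % trimming and the standard consistency
    correction.  Raises on singular scatter.
    """
    M = _as_matrix(M)
    n, d = M.shape
    if n <= d:
        raise InvalidInputError("need more observations than dimensions")
    if method == "mcd":
        h = max(d + 1, int(math.floor((1.0 - trim_fraction) * n)))
        est = mcd(M, h, seed=seed)
        alpha = h / n
        S = est.scatter * mcd_consistency(alpha, d)
        mu = est.location
    elif method == "classical":
        mu = M.mean(axis=0)
        C = M - mu
        S = (C.T @ C) / (n - 1)
    else:
        raise InvalidInputError(f"unknown method {method!r}")
    try:
        Sinv = np.linalg.inv(S)
    except np.linalg.LinAlgError as exc:
        raise DegenerateInputError("singular scatter matrix") from exc
    if np.linalg.cond(S) > 1e12:
        raise DegenerateInputError("numerically singular scatter matrix")
    D = M - mu
    d2 = np.einsum("nd,de,ne->n", D, Sinv, D)
    return np.sqrt(np.maximum(d2, 0.0))


def normal_scores(M):
    """Van der Waerden normal scores: each column is replaced by
    Phi^{-1}(rank/(n+1)), with average ranks for ties."""
    M = _as_matrix(M)
    n = M.shape[0]
    ranks = np.apply_along_axis(rankdata, 0, M)
    return norm.ppf(ranks / (n + 1.0))
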