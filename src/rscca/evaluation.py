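"""Estimator evaluation: subspace angles, support recovery, trimmed
leave-one-out cross-validation, and residual-based outlier diagnostics."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import subspace_angles

from .ccacore import CCAFit, EstimatorSpec, fit_cca
from .exceptions import DegenerateInputError, InvalidInputError, RSCCAError
from .robuststats import distance_cutoff, robust_distances

logger = logging.getLogger(__name__)

__all__ = [
    "EvalSummary",
    "CVScore",
    "subspace_angle",
    "support_rates",
    "loo_cv",
    "residual_distances",
    "report_frame",
]


@dataclass
class EvalSummary:
    """Monte-Carlo averages over M replicates of one (design, scenario,
    method) cell: mean largest principal angle (radians), true
    positive/negative rates for both canonical vector matrices, and the
    Monte-Carlo standard error of the x-side angle.  ``M`` is the
    effective number of replicates after failures."""

    mean_angle_A: float
    mean_angle_B: float
    tpr_A: float
    tnr_A: float
    tpr_B: float
    tnr_B: float
    M: int
    se_angle_A: float
    se_angle_B: float = float("nan")
    convergence_rate: float = float("nan")
    n_failures: int = 0


@dataclass
class CVScore:
    """Trimmed leave-one-out cross-validation score."""

    score: float
    alpha: float
    r: int
    h: int


def subspace_angle(Ahat, A) -> float:
    """Largest principal angle (radians) between the column spaces."""
    Ahat = np.atleast_2d(np.asarray(Ahat, dtype=np.float64))
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    if Ahat.shape[1] > Ahat.shape[0]:
        Ahat = Ahat.T
    if A.shape[1] > A.shape[0]:
        A = A.T
    for M in (Ahat, A):
        if np.linalg.matrix_rank(M) < M.shape[1]:
            raise InvalidInputError("rank-deficient subspace basis")
    return float(subspace_angles(Ahat, A)[0])


def support_rates(Ahat, A):
    """True positive and true negative rates of the estimated support.

    TPR = #{estimated nonzero & truly nonzero} / #{truly nonzero};
    TNR analogous over the true zeros.  TNR is NaN when the true matrix
    has no zero entries (non-sparse truth).
    """
    Ahat = np.asarray(Ahat)
    A = np.asarray(A)
    if Ahat.shape != A.shape:
        raise InvalidInputError("shape mismatch between estimate and truth")
    est_nz = Ahat != 0
    true_nz = A != 0
    n_pos = int(true_nz.sum())
    n_neg = int((~true_nz).sum())
    tpr = float((est_nz & true_nz).sum() / n_pos) if n_pos else float("nan")
    tnr = float((~est_nz & ~true_nz).sum() / n_neg) if n_neg else float("nan")
    return tpr, tnr


def loo_cv(X, Y, spec: EstimatorSpec, r: int, alpha: float = 0.0) -> CVScore:
    """Trimmed leave-one-out cross-validation

        CV = (1/r) (1/h) sum over the h smallest of
             ||A'_{-i} x_i - B'_{-i} y_i||^2,

    with h = floor(n (1 - alpha)); the h smallest squared discrepancies
    are kept so that outlying observations cannot dominate the score.
    Penalties are re-selected inside every leave-one-out refit.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    n = X.shape[0]
    if n < 8:
        raise InvalidInputError("need at least 8 observations for loo_cv")
    if not 0.0 <= alpha < 0.5:
        raise InvalidInputError("alpha must be in [0, 0.5)")
    disc = []
    for i in range(n):
        keep = np.arange(n) != i
        try:
            fit = fit_cca(X[keep], Y[keep], spec, r=r)
        except RSCCAError as exc:
            logger.warning("leave-one-out refit %d failed (%s); excluded", i, exc)
            continue
        xi = X[i] - fit.centers_x
        yi = Y[i] - fit.centers_y
        disc.append(float(np.sum((fit.A.T @ xi - fit.B.T @ yi) ** 2)))
    disc = np.sort(np.asarray(disc))
    h = max(1, int(np.floor(disc.size * (1.0 - alpha))))
    score = float(disc[:h].mean() / r)
    return CVScore(score=score, alpha=alpha, r=r, h=h)


def residual_distances(X, Y, fit: CCAFit):
    """Robust distances of the canonical residuals X A - Y B.

    Returns (distances, cutoff, flags) where the cutoff is
    sqrt(chi2_{0.975}(r)) and flagged observations lie above it.
    """
    if fit.r < 1:
        raise InvalidInputError("fit must contain at least one pair")
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    R = (X - fit.centers_x) @ fit.A - (Y - fit.centers_y) @ fit.B
    if fit.r == 1:
        R = R.reshape(-1, 1)
    distances = robust_distances(R, "mcd")
    cutoff = distance_cutoff(fit.r)
    return distances, cutoff, distances > cutoff


def report_frame(entries) -> pd.DataFrame:
    """Tabular report from (design, scenario, method, EvalSummary)
    tuples, one row per cell in the layout of the simulation tables."""
    rows = []
    for design, scenario, method, s in entries:
        rows.append({
            "design": design,
            "scenario": scenario,
            "method": method,
            "mean_angle_A": s.mean_angle_A,
            "tpr_A": s.tpr_A,
            "tnr_A": s.tnr_A,
            "mean_angle_B": s.mean_angle_B,
            "tpr_B": s.tpr_B,
            "tnr_B": s.tnr_B,
            "se_angle_A": s.se_angle_A,
            "se_angle_B": s.se_angle_B,
            "M_effective": s.M,
            "convergence_rate": s.convergence_rate,
            "n_failures": s.n_failures,
        })
    return pd.DataFrame(rows)
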