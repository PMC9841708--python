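"""Likelihood-free, PCA-based admixture estimation.

Unphased, diploid-coded calls from polyploid samples violate the genotype
likelihoods that model-based admixture programs assume, so this module
instead follows the latent-subspace strategy: under the admixture (PSD)
model the individual-specific allele-frequency matrix ``F = P Q^T`` has
rank K, dosage data are Binomial(2, F), and F lies in a K-dimensional
subspace recoverable from the data's second-moment structure alone.

The two stages are:

1. ``estimate_individual_frequencies`` — project rows of ``dosage / 2``
   onto the span of the top-K eigenvectors of the samples' second-moment
   matrix.  The binomial sampling noise inflates the diagonal of that
   matrix; subtracting its plug-in estimate (``adjust_noise=True``, the
   default) makes the subspace estimate consistent.
2. ``factorize`` — constrained alternating least squares splitting the
   estimated ``F`` into cluster allele frequencies ``P`` (entries in
   [0, 1]) and memberships ``Q`` (rows on the probability simplex), with
   seeded Dirichlet restarts.

No automatic choice of K is offered when the input had missing data: the
subspace estimate is only an eigen-gap diagnostic on complete data, and
mean imputation distorts it.  The per-K reconstruction objectives are
reported instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from scipy.optimize import linear_sum_assignment

from .matrix import GenotypeMatrix, mean_impute

__all__ = [
    "AdmixtureFit",
    "AdmixtureSweep",
    "estimate_individual_frequencies",
    "factorize",
    "fit_admixture",
    "project_rows_to_simplex",
    "match_columns",
    "mean_q_error",
]

logger = logging.getLogger(__name__)

#: Clipping bound keeping estimated frequencies strictly inside (0, 1).
FREQ_EPS = 1e-6


@dataclass
class AdmixtureFit:
    """Result of one constrained factorisation at a fixed K.

    ``Q`` rows lie on the probability simplex; ``P`` entries are cluster
    allele frequencies in [0, 1].  ``objective_trace`` is the recorded
    mean-squared reconstruction error per accepted iteration and is
    non-increasing by construction.
    """

    K: int
    Q: np.ndarray
    P: np.ndarray
    n_iterations: int
    final_objective: float
    objective_trace: List[float] = field(default_factory=list)
    converged: bool = True


@dataclass
class AdmixtureSweep:
    """Fits for a range of K values, plus per-K objectives."""

    fits: Dict[int, AdmixtureFit]
    had_missing_data: bool

    @property
    def objectives(self) -> Dict[int, float]:
        return {k: fit.final_objective for k, fit in self.fits.items()}


def project_rows_to_simplex(Y: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex.

    Sort-based algorithm; deterministic, O(K log K) per row.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, K = Y.shape
    U = np.sort(Y, axis=1)[:, ::-1]
    css = np.cumsum(U, axis=1) - 1.0
    ks = np.arange(1, K + 1)
    cond = U - css / ks > 0
    rho = K - np.argmax(cond[:, ::-1], axis=1) - 1  # last True index per row
    theta = css[np.arange(n), rho] / (rho + 1.0)
    return np.maximum(Y - theta[:, np.newaxis], 0.0)


def estimate_individual_frequencies(
    gm: GenotypeMatrix, K: int, adjust_noise: bool = True
) -> np.ndarray:
    """Latent-subspace estimate of individual-specific allele frequencies.

    Returns ``F_hat`` (n_sites x n_samples) with entries clipped to
    ``[FREQ_EPS, 1 - FREQ_EPS]``.  Requires a complete matrix (mean-impute
    upstream).  With ``adjust_noise`` the binomial sampling variance is
    subtracted from the diagonal of the second-moment matrix before
    eigendecomposition; switch it off when the input dosages are exact
    (noise-free) frequencies.
    """
    if not gm.is_complete:
        raise ValueError("estimate_individual_frequencies requires a complete matrix")
    n = gm.n_samples
    if not 1 <= K <= n:
        raise ValueError(f"K must be in [1, {n}]")
    X = gm.values.T.astype(float)  # m sites x n samples
    m = X.shape[0]
    G = (X.T @ X) / m
    if adjust_noise:
        # E[x(2-x)]/2m estimates the binomial-noise diagonal under x~Bin(2,f).
        D = (X * (2.0 - X)).sum(axis=0) / (2.0 * m)
        G = G - np.diag(D)
    eigvals, eigvecs = np.linalg.eigh(G)
    order = np.argsort(eigvals)[::-1]
    V = eigvecs[:, order[:K]]
    F_hat = 0.5 * X @ V @ V.T
    return np.clip(F_hat, FREQ_EPS, 1.0 - FREQ_EPS)


def _objective(F: np.ndarray, P: np.ndarray, Q: np.ndarray) -> float:
    R = F - P @ Q.T
    return float(np.mean(R * R))


def _solve_P(F: np.ndarray, Q: np.ndarray) -> np.ndarray:
    # min_P ||F - P Q^T||_F, then box-constrain.
    P, *_ = np.linalg.lstsq(Q, F.T, rcond=None)
    return np.clip(P.T, 0.0, 1.0)


def _solve_Q(F: np.ndarray, P: np.ndarray) -> np.ndarray:
    Qt, *_ = np.linalg.lstsq(P, F, rcond=None)
    return project_rows_to_simplex(Qt.T)


def factorize(
    F_hat: np.ndarray,
    K: int,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
    n_restarts: int = 5,
) -> AdmixtureFit:
    """Constrained alternating least squares: ``F_hat ~ P Q^T``.

    Alternates a least-squares update of P (clipped to [0, 1]) and of Q
    (rows projected onto the simplex), stopping when the relative change of
    the mean-squared reconstruction error drops below ``tol``.  The problem
    is non-convex, so ``n_restarts`` seeded Dirichlet(1, ..., 1)
    initialisations are run and the best final objective kept.  An
    iteration that would increase the objective is rejected (the recorded
    trace is therefore non-increasing); hitting ``max_iter`` flags the fit
    as non-converged rather than raising.
    """
    F_hat = np.asarray(F_hat, dtype=float)
    if F_hat.min() < 0.0 or F_hat.max() > 1.0:
        raise ValueError("F_hat entries must lie in [0, 1]")
    m, n = F_hat.shape
    if K < 1:
        raise ValueError("K must be >= 1")

    if K == 1:
        # Closed form: Q is the all-ones column, P the row means.
        Q = np.ones((n, 1))
        P = F_hat.mean(axis=1, keepdims=True)
        obj = _objective(F_hat, P, Q)
        return AdmixtureFit(
            K=1, Q=Q, P=P, n_iterations=0, final_objective=obj,
            objective_trace=[obj], converged=True,
        )

    rng_master = np.random.default_rng(seed)
    best: Optional[AdmixtureFit] = None
    patience = 5
    for _ in range(n_restarts):
        rng = np.random.default_rng(rng_master.integers(2**31))
        Q = rng.dirichlet(np.ones(K), size=n)
        P = _solve_P(F_hat, Q)
        incumbent = (P, Q)
        incumbent_obj = _objective(F_hat, P, Q)
        trace = [incumbent_obj]
        converged = False
        stalled = 0
        it = 0
        for it in range(1, max_iter + 1):
            # Clip/project steps are not exact constrained minimisers, so a
            # single step can worsen the objective; iterate freely but
            # record (and finally return) the best iterate seen, which
            # keeps the recorded trace non-increasing.
            P = _solve_P(F_hat, Q)
            Q = _solve_Q(F_hat, P)
            obj = _objective(F_hat, P, Q)
            improvement = incumbent_obj - obj
            if obj < incumbent_obj:
                incumbent = (P, Q)
                incumbent_obj = obj
            trace.append(incumbent_obj)
            if improvement < tol * max(incumbent_obj, 1e-300):
                stalled += 1
                if stalled >= patience:
                    converged = True
                    break
            else:
                stalled = 0
        P, Q = incumbent
        fit = AdmixtureFit(
            K=K, Q=Q, P=P, n_iterations=it,
            final_objective=incumbent_obj, objective_trace=trace,
            converged=converged,
        )
        if best is None or fit.final_objective < best.final_objective:
            best = fit
    if not best.converged:
        logger.warning("ALS did not converge in %d iterations at K=%d", max_iter, K)
    return best


def fit_admixture(
    gm: GenotypeMatrix,
    K_min: int,
    K_max: int,
    seed: int = 0,
    adjust_noise: bool = True,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_restarts: int = 5,
) -> AdmixtureSweep:
    """Run the full estimator for each K in ``[K_min, K_max]``.

    Missing data are mean-imputed before subspace estimation; in that case
    the sweep reports per-K objectives but deliberately makes no "best K"
    claim, since the subspace diagnostic is only valid on complete data.
    """
    if not 1 <= K_min <= K_max <= gm.n_samples:
        raise ValueError("need 1 <= K_min <= K_max <= n_samples")
    had_missing = not gm.is_complete
    complete = gm if gm.is_complete else mean_impute(gm)
    fits: Dict[int, AdmixtureFit] = {}
    for K in range(K_min, K_max + 1):
        F_hat = estimate_individual_frequencies(complete, K, adjust_noise=adjust_noise)
        fits[K] = factorize(
            F_hat, K, tol=tol, max_iter=max_iter,
            seed=seed + K, n_restarts=n_restarts,
        )
        logger.info("K=%d: objective %.3e", K, fits[K].final_objective)
    return AdmixtureSweep(fits=fits, had_missing_data=had_missing)


def match_columns(Q_est: np.ndarray, Q_true: np.ndarray) -> np.ndarray:
    """Permute columns of ``Q_est`` to best match ``Q_true``.

    Uses the Hungarian algorithm on column-pair mean absolute error;
    resolves the label-switching ambiguity inherent to mixture models.
    """
    K = Q_true.shape[1]
    cost = np.zeros((K, K))
    for a in range(K):
        for b in range(K):
            cost[a, b] = np.mean(np.abs(Q_est[:, a] - Q_true[:, b]))
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(K, dtype=int)
    perm[cols] = rows
    return Q_est[:, perm]


def mean_q_error(Q_est: np.ndarray, Q_true: np.ndarray) -> float:
    """Permutation-matched mean absolute error between membership matrices."""
    matched = match_columns(Q_est, Q_true)
    return float(np.mean(np.abs(matched - Q_true)))
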