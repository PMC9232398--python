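"""Latent Gaussian copula differential graphical model for binary omics.

Binary alteration calls (CNV out-of-range, mutated/not) are modelled as
thresholded latent non-paranormal variables: ``D_j = I(X_j > C_j)`` with
``X ~ NPN(0, Sigma, f)`` and ``Lambda_j = f_j(C_j)`` the threshold on the
Gaussian scale. Per class, the latent correlation matrix is estimated by
inverting the Kendall's-tau bridge function; the differential network is
the sparse difference of latent precision matrices, estimated directly by

    argmin |Delta|_1  subject to  |(b1 kron b0) vec(Delta) - vec(b1 - b0)|_inf <= lambda_n

solved exactly as a linear program. Note this constraint identifies the
difference with the sign of ``inv(b0) - inv(b1)``; edge support and
magnitudes are unaffected by the sign convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import sparse
from scipy.special import ndtr, ndtri
from scipy.optimize import linprog

from .network import EdgeSet

__all__ = [
    "LatentCorrelationEstimate",
    "DeltaMatrix",
    "bivariate_normal_cdf",
    "bridge",
    "bridge_invert",
    "estimate_thresholds",
    "kendall_tau_matrix",
    "latent_correlation",
    "estimate_delta",
    "select_lambda",
    "delta_edges",
    "low_prevalence_genes",
]

_GL_NODES, _GL_WEIGHTS = leggauss(64)


def bivariate_normal_cdf(h: float, k: float, rho: float) -> float:
    """Standard bivariate normal CDF ``P(X <= h, Y <= k)`` with correlation rho.

    Uses the single-integral identity with the ``t = sin(theta)``
    substitution, which removes the endpoint singularity:

        Phi2(h, k; rho) = Phi(h) Phi(k)
            + (1/2pi) * int_0^{arcsin rho} exp(-(h^2 - 2 h k sin t + k^2)
                                               / (2 cos^2 t)) dt

    evaluated by 64-point Gauss-Legendre quadrature (absolute accuracy well
    below 1e-12 for |rho| <= 1 - 1e-6).
    """
    rho = float(np.clip(rho, -1.0 + 1e-12, 1.0 - 1e-12))
    upper = np.arcsin(rho)
    theta = 0.5 * upper * (_GL_NODES + 1.0)
    w = 0.5 * upper * _GL_WEIGHTS
    cos2 = np.cos(theta) ** 2
    integrand = np.exp(-(h * h - 2.0 * h * k * np.sin(theta) + k * k) / (2.0 * cos2))
    return float(
        ndtr(h) * ndtr(k) + np.sum(w * integrand) / (2.0 * np.pi)
    )


def bridge(sigma: float, lambda_j: float, lambda_k: float) -> float:
    """Population Kendall's tau of the thresholded pair at latent correlation sigma.

    ``tau = 2 (Phi2(Lambda_j, Lambda_k; sigma) - Phi(Lambda_j) Phi(Lambda_k))``;
    strictly increasing in sigma for fixed thresholds.
    """
    return 2.0 * (
        bivariate_normal_cdf(lambda_j, lambda_k, sigma)
        - float(ndtr(lambda_j) * ndtr(lambda_k))
    )


def bridge_invert(
    tau: float, lambda_j: float, lambda_k: float, tol: float = 1e-10
) -> float:
    """Invert the bridge: the unique sigma in (-1, 1) with bridge(sigma) = tau.

    Monotone bisection to ``tol``. A tau outside the attainable range for
    the given thresholds is clamped to a latent correlation of
    ``+-(1 - 1e-6)`` with a warning.
    """
    bound = 1.0 - 1e-6
    if tau == 0.0:
        return 0.0
    lo, hi = -bound, bound
    f_lo = bridge(lo, lambda_j, lambda_k) - tau
    f_hi = bridge(hi, lambda_j, lambda_k) - tau
    if f_lo > 0.0 or f_hi < 0.0:
        warnings.warn(
            f"tau={tau:.4g} outside attainable range for thresholds "
            f"({lambda_j:.3g}, {lambda_k:.3g}); clamping latent correlation",
            stacklevel=2,
        )
        return bound if f_hi < 0.0 else -bound
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if bridge(mid, lambda_j, lambda_k) - tau <= 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def estimate_thresholds(binary: np.ndarray) -> np.ndarray:
    """Latent thresholds ``Lambda_j = Phi^-1(1 - p_j)`` from column one-rates.

    One-rates are Winsorized to ``[1/(2n), 1 - 1/(2n)]`` before inversion so
    degenerate all-0/all-1 columns yield finite thresholds (with a warning).
    """
    d = np.asarray(binary)
    n = d.shape[0]
    p_hat = d.mean(axis=0)
    lo, hi = 1.0 / (2 * n), 1.0 - 1.0 / (2 * n)
    if ((p_hat < lo) | (p_hat > hi)).any():
        warnings.warn("degenerate binary column(s); Winsorizing one-rate", stacklevel=2)
    p_hat = np.clip(p_hat, lo, hi)
    return ndtri(1.0 - p_hat)


def kendall_tau_matrix(binary: np.ndarray) -> np.ndarray:
    """Pairwise Kendall's tau-a of binary columns; diagonal set to 1.

    For 0/1 columns, tau-a has the closed form
    ``2 (n11 n00 - n10 n01) / (n (n - 1))`` with ``nab`` the joint counts;
    ties contribute 0. The raw tau-a of a binary column with itself is below
    1, so the diagonal is overridden to 1 by convention.
    """
    d = np.asarray(binary, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    ones = d
    zeros = 1.0 - d
    n11 = ones.T @ ones
    n00 = zeros.T @ zeros
    n10 = ones.T @ zeros
    tau = 2.0 * (n11 * n00 - n10 * n10.T) / (n * (n - 1))
    np.fill_diagonal(tau, 1.0)
    return tau


@dataclass
class LatentCorrelationEstimate:
    """Rank-based latent correlation estimate for one class's binary layer."""

    tau_hat: np.ndarray
    lambda_hat: np.ndarray
    sigma_hat: np.ndarray
    gene_ids: list[str] | None = None


def _project_correlation(m: np.ndarray, min_eig: float = 1e-3) -> np.ndarray:
    """Nearest-PD repair: eigenvalue clipping + diagonal renormalization."""
    out = (m + m.T) / 2.0
    for _ in range(20):
        vals, vecs = np.linalg.eigh(out)
        if vals.min() >= min_eig:
            break
        out = (vecs * np.maximum(vals, min_eig)) @ vecs.T
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
        np.fill_diagonal(out, 1.0)
    return out


def latent_correlation(
    binary: np.ndarray, gene_ids: list[str] | None = None
) -> LatentCorrelationEstimate:
    """Estimate the latent copula correlation matrix of one class.

    Elementwise bridge inversion of the empirical tau matrix at the
    estimated thresholds, followed by projection to the nearest positive
    definite correlation matrix (eigenvalues clipped at 1e-3).
    """
    d = np.asarray(binary)
    if not np.isin(d, (0, 1)).all():
        raise ValueError("binary matrix must contain only 0/1")
    p = d.shape[1]
    lam = estimate_thresholds(d)
    tau = kendall_tau_matrix(d)
    sigma = np.eye(p)
    for j in range(p):
        for k in range(j + 1, p):
            sigma[j, k] = sigma[k, j] = bridge_invert(tau[j, k], lam[j], lam[k])
    sigma = _project_correlation(sigma)
    return LatentCorrelationEstimate(
        tau_hat=tau, lambda_hat=lam, sigma_hat=sigma, gene_ids=gene_ids
    )


@dataclass
class DeltaMatrix:
    """Sparse symmetric estimate of the latent precision-matrix difference."""

    delta: np.ndarray
    lambda_n: float
    gene_ids: list[str] | None = None

    @property
    def support(self) -> set[tuple[int, int]]:
        p = self.delta.shape[0]
        return {
            (j, k)
            for j in range(p)
            for k in range(j + 1, p)
            if self.delta[j, k] != 0.0
        }


def estimate_delta(
    b1: np.ndarray, b0: np.ndarray, lambda_n: float, gene_ids: list[str] | None = None
) -> DeltaMatrix:
    """Direct estimation of the precision difference by linear programming.

    Solves ``min sum |Delta_jk|`` subject to
    ``|(b0 Delta b1)_jk - (b1 - b0)_jk| <= lambda_n`` for every (j, k) —
    the Kronecker-vec form of the elementwise-infinity constraint. Exact for
    the post-screening problem sizes (p <= 50). The solution is symmetrized
    by keeping, per pair, the entry of smaller magnitude (conservative for
    support).
    """
    if lambda_n < 0:
        raise ValueError("lambda_n must be >= 0")
    b1 = np.asarray(b1, dtype=float)
    b0 = np.asarray(b0, dtype=float)
    if b1.shape != b0.shape or b1.ndim != 2 or b1.shape[0] != b1.shape[1]:
        raise ValueError("b1 and b0 must be square matrices of equal dimension")
    p = b1.shape[0]
    if p > 50:
        raise ValueError(
            f"p={p} too large for the exact LP solver (max 50); screen harder"
        )
    if np.allclose(b1, b0):
        return DeltaMatrix(np.zeros((p, p)), lambda_n, gene_ids)

    m = p * p
    # variables: x (vec Delta, m) then t (abs values, m); minimize sum t
    cost = np.concatenate([np.zeros(m), np.ones(m)])
    a_kron = np.kron(b1, b0)  # vec(b0 Delta b1) = kron(b1, b0) vec(Delta)
    c_vec = (b1 - b0).ravel(order="F")
    eye = sparse.identity(m, format="csr")
    zero = sparse.csr_matrix((m, m))
    a_ub = sparse.vstack(
        [
            sparse.hstack([eye, -eye]),       #  x - t <= 0
            sparse.hstack([-eye, -eye]),      # -x - t <= 0
            sparse.hstack([sparse.csr_matrix(a_kron), zero]),   #  Ax <= c + lam
            sparse.hstack([sparse.csr_matrix(-a_kron), zero]),  # -Ax <= -c + lam
        ],
        format="csr",
    )
    b_ub = np.concatenate(
        [np.zeros(m), np.zeros(m), c_vec + lambda_n, -c_vec + lambda_n]
    )
    res = linprog(
        cost,
        A_ub=a_ub,
        b_ub=b_ub,
        bounds=[(None, None)] * m + [(0, None)] * m,
        method="highs",
    )
    if not res.success:
        raise RuntimeError(f"LP solver failed: {res.message}")
    raw = res.x[:m].reshape((p, p), order="F")
    # min-magnitude symmetrization
    pick_lower = np.abs(raw.T) < np.abs(raw)
    sym = np.where(pick_lower, raw.T, raw)
    sym = np.where(np.abs(sym) < 1e-11, 0.0, sym)  # strip solver dust
    sym = (sym + sym.T) / 2.0
    return DeltaMatrix(sym, lambda_n, gene_ids)


def select_lambda(
    b1: np.ndarray,
    b0: np.ndarray,
    n1: int,
    n0: int,
    grid: list[float] | None = None,
    c: float = 2.0,
) -> float:
    """Constraint level for :func:`estimate_delta`.

    Default ``lambda_n = c sqrt(log p / min(n1, n0))`` with c = 2. If a grid
    is given, the fits are scanned and the sparsest solution whose
    reconstruction residual stays within 10% of the tightest fit's residual
    is chosen (stability heuristic).
    """
    p = b1.shape[0]
    if grid is None:
        return float(c * np.sqrt(np.log(p) / min(n1, n0)))
    if not grid:
        raise ValueError("grid must be nonempty")
    grid = sorted(float(g) for g in grid)
    if len(grid) == 1:
        return grid[0]
    fits = {lam: estimate_delta(b1, b0, lam) for lam in grid}

    def residual(dm: DeltaMatrix) -> float:
        return float(np.max(np.abs(b0 @ dm.delta @ b1 - (b1 - b0))))

    r_ref = residual(fits[grid[0]])
    best = grid[0]
    for lam in grid:
        if residual(fits[lam]) <= 1.1 * r_ref + 1e-12:
            best = lam
    return best


def delta_edges(
    dm: DeltaMatrix, tol: float = 1e-6, layer: str = "binary"
) -> EdgeSet:
    """Edge set of pairs with ``|Delta_jk| > tol`` (diagonal excluded)."""
    p = dm.delta.shape[0]
    genes = dm.gene_ids or [f"g{k}" for k in range(p)]
    es = EdgeSet(layer=layer)
    for j in range(p):
        for k in range(j + 1, p):
            if abs(dm.delta[j, k]) > tol:
                es.add(genes[j], genes[k], abs(float(dm.delta[j, k])))
    return es


def low_prevalence_genes(binary: np.ndarray, min_count: int = 2) -> np.ndarray:
    """Column indices with fewer than ``min_count`` ones or zeros.

    Near-constant binary columns give degenerate Kendall's tau and are
    dropped from differential-precision estimation by the caller.
    """
    d = np.asarray(binary)
    ones = d.sum(axis=0)
    return np.flatnonzero(np.minimum(ones, d.shape[0] - ones) < min_count)
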