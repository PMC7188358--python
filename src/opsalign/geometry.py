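"""Affine-invariant Riemannian geometry of SPD matrices.

Spatial covariances of zero-mean EEG trials are symmetric positive-definite
(SPD) matrices.  Under the affine-invariant metric the distance between two
SPD matrices is

    delta_R(C1, C2) = || Log(C1^{-1} C2) ||_F = [ sum_i log^2(lambda_i) ]^{1/2}

with lambda_i the eigenvalues of C1^{-1} C2.  This module provides the
distance, the geodesic, matrix powers, the batch Karcher (Frechet) mean and
the recursive (inductive) mean update used for streaming re-centering.

All functions take and return plain ``numpy.ndarray`` objects; validity is
checked on entry with :func:`validate_spd`.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import eigh

__all__ = [
    "validate_spd",
    "spectrum",
    "trial_covariance",
    "matrix_power",
    "riemannian_distance",
    "geodesic",
    "riemannian_mean",
    "recursive_mean_update",
    "MeanConvergenceError",
]

#: relative symmetry tolerance admitted on construction
SYM_RTOL = 1e-10


class MeanConvergenceError(RuntimeError):
    """Karcher-mean iteration failed to reach tolerance.

    Carries the gradient Frobenius norm at the last iterate.
    """

    def __init__(self, gradient_norm: float, max_iter: int):
        self.gradient_norm = gradient_norm
        super().__init__(
            f"Riemannian mean did not converge within {max_iter} iterations "
            f"(last gradient norm {gradient_norm:.3e})"
        )


def validate_spd(C: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Check that ``C`` is symmetric positive definite; return it symmetrized.

    Symmetry is required to relative tolerance 1e-10; eigenvalues must be
    strictly positive and finite.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"{name} must be square, got shape {C.shape}")
    if not np.all(np.isfinite(C)):
        raise ValueError(f"{name} contains non-finite entries")
    scale = max(np.abs(C).max(), 1.0)
    if np.abs(C - C.T).max() > SYM_RTOL * scale:
        raise ValueError(f"{name} is not symmetric to relative tolerance {SYM_RTOL}")
    C = 0.5 * (C + C.T)
    w = np.linalg.eigvalsh(C)
    if w[0] <= 0:
        raise ValueError(
            f"{name} is not positive definite (smallest eigenvalue {w[0]:.3e})"
        )
    return C


def spectrum(C: np.ndarray) -> np.ndarray:
    """Eigenvalues of a symmetric matrix in descending order."""
    return np.linalg.eigvalsh(C)[::-1]


def trial_covariance(E: np.ndarray, mode: str = "plain", *, ridge: bool = True) -> np.ndarray:
    """Spatial covariance of one zero-mean trial ``E`` (channels x samples).

    mode="plain" gives C = E E^T / N_s, the scaling consistent with the
    1/sqrt(N_s) factor of the time-series re-centering transform.
    mode="trace_normalized" gives C = E E^T / tr(E E^T) (unit trace), the
    per-trial normalization used when averaging class covariances for CSP.

    If the smallest eigenvalue falls below 1e-10 * trace / N_c a ridge of
    that size is added so downstream matrix functions stay defined; with
    ``ridge=False`` a rank-deficient trial raises instead.
    """
    E = np.asarray(E, dtype=float)
    if E.ndim != 2:
        raise ValueError(f"trial must be 2-D (channels x samples), got {E.shape}")
    n_c, n_s = E.shape
    if n_s < n_c:
        raise ValueError(f"trial needs at least as many samples ({n_s}) as channels ({n_c})")
    G = E @ E.T
    if mode == "plain":
        C = G / n_s
    elif mode == "trace_normalized":
        tr = np.trace(G)
        if tr <= 0:
            raise ValueError("zero-energy trial cannot be trace-normalized")
        C = G / tr
    else:
        raise ValueError(f"unknown covariance mode {mode!r}")
    C = 0.5 * (C + C.T)
    floor = 1e-10 * np.trace(C) / n_c
    w = np.linalg.eigvalsh(C)
    if w[0] < floor:
        if not ridge:
            raise ValueError(
                f"rank-deficient trial covariance (min eigenvalue {w[0]:.3e}); "
                "enable ridge to regularize"
            )
        C = C + floor * np.eye(n_c)
    return C


def _eig_fun(C: np.ndarray, fun) -> np.ndarray:
    """Apply a scalar function to the spectrum of a symmetric matrix."""
    w, U = eigh(C)
    out = (U * fun(w)) @ U.T
    return 0.5 * (out + out.T)


def matrix_power(C: np.ndarray, t: float) -> np.ndarray:
    """Fractional matrix power C^t of an SPD matrix via eigendecomposition."""
    if not np.isfinite(t):
        raise ValueError("power exponent must be finite")
    C = validate_spd(C)
    return _eig_fun(C, lambda w: w**t)


def logm(C: np.ndarray) -> np.ndarray:
    """Matrix logarithm of an SPD matrix."""
    return _eig_fun(validate_spd(C), np.log)


def expm(S: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix."""
    S = np.asarray(S, dtype=float)
    return _eig_fun(0.5 * (S + S.T), np.exp)


def riemannian_distance(C1: np.ndarray, C2: np.ndarray) -> float:
    """Affine-invariant distance delta_R(C1, C2).

    Computed from the symmetric pencil C1^{-1/2} C2 C1^{-1/2}, which shares
    the spectrum of C1^{-1} C2 but keeps the eigenproblem symmetric.
    """
    C1 = validate_spd(C1, "C1")
    C2 = validate_spd(C2, "C2")
    if C1.shape != C2.shape:
        raise ValueError(f"dimension mismatch: {C1.shape} vs {C2.shape}")
    w, U = eigh(C1)
    isqrt = (U * (1.0 / np.sqrt(w))) @ U.T
    lam = np.linalg.eigvalsh(isqrt @ C2 @ isqrt)
    return float(np.sqrt(np.sum(np.log(lam) ** 2)))


def geodesic(M: np.ndarray, C: np.ndarray, t: float) -> np.ndarray:
    """Point at fraction ``t`` along the affine-invariant geodesic M -> C.

    Closed form: M^{1/2} (M^{-1/2} C M^{-1/2})^t M^{1/2}.  ``t`` must lie in
    [0, 1]; out-of-range values raise rather than clamp silently.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"geodesic parameter t={t} outside [0, 1]")
    M = validate_spd(M, "M")
    C = validate_spd(C, "C")
    if M.shape != C.shape:
        raise ValueError(f"dimension mismatch: {M.shape} vs {C.shape}")
    w, U = eigh(M)
    sqrt = (U * np.sqrt(w)) @ U.T
    isqrt = (U * (1.0 / np.sqrt(w))) @ U.T
    inner = isqrt @ C @ isqrt
    out = sqrt @ _eig_fun(0.5 * (inner + inner.T), lambda x: x**t) @ sqrt
    return 0.5 * (out + out.T)


def riemannian_mean(
    Cs,
    weights=None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> np.ndarray:
    """Karcher mean of a set of SPD matrices.

    Fixed-point gradient iteration: starting from the arithmetic mean, each
    step maps the matrices to the tangent space at the current iterate,
    averages, and maps back with step size 1.  Converged when the Frobenius
    norm of the tangent-space mean is <= ``tol``.  Weights are accepted for
    generality but the decoding pipeline only uses the unweighted mean.
    """
    Cs = [validate_spd(C, f"Cs[{i}]") for i, C in enumerate(Cs)]
    if len(Cs) == 0:
        raise ValueError("cannot average an empty set of matrices")
    n = len(Cs)
    if any(C.shape != Cs[0].shape for C in Cs):
        raise ValueError("all matrices must share one dimension")
    if weights is None:
        w_ = np.full(n, 1.0 / n)
    else:
        w_ = np.asarray(weights, dtype=float)
        if w_.shape != (n,) or np.any(w_ < 0) or w_.sum() <= 0:
            raise ValueError("weights must be a nonnegative vector matching the set")
        w_ = w_ / w_.sum()
    if n == 1:
        return Cs[0]
    M = sum(wi * Ci for wi, Ci in zip(w_, Cs))
    stack = np.stack(Cs)
    grad_norm = np.inf
    for _ in range(max_iter):
        w, U = eigh(M)
        sqrt = (U * np.sqrt(w)) @ U.T
        isqrt = (U * (1.0 / np.sqrt(w))) @ U.T
        whitened = isqrt @ stack @ isqrt
        logs = np.stack([_eig_fun(0.5 * (Wi + Wi.T), np.log) for Wi in whitened])
        T = np.tensordot(w_, logs, axes=1)
        grad_norm = float(np.linalg.norm(T, "fro"))
        if grad_norm <= tol:
            return 0.5 * (M + M.T)
        M = sqrt @ expm(T) @ sqrt
        M = 0.5 * (M + M.T)
    raise MeanConvergenceError(grad_norm, max_iter)


def recursive_mean_update(M_i: np.ndarray, C_next: np.ndarray, i: int) -> np.ndarray:
    """Inductive Riemannian mean step M_{i+1} = geodesic(M_i, C_{i+1}, 1/(i+1)).

    ``i`` is the number of trials already absorbed into ``M_i`` (so i >= 1;
    the stream is initialized with M_1 = C_1).  The inductive mean is
    order-dependent but converges in probability to the batch Karcher mean
    for i.i.d. draws.
    """
    if i < 1:
        raise ValueError(f"recursive update requires i >= 1 prior trials, got {i}")
    return geodesic(M_i, C_next, 1.0 / (i + 1))
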