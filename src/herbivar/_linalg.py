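"""Small shared helpers for 2x2 covariance matrices."""
from __future__ import annotations

import numpy as np

SYM_TOL = 1e-8
PSD_TOL = 1e-10


def as_matrix(M, name: str = "matrix") -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.shape != (2, 2):
        raise ValueError(f"{name} must be 2x2, got shape {M.shape}")
    return M


def require_symmetric(M, name: str = "matrix") -> np.ndarray:
    M = as_matrix(M, name)
    if abs(M[0, 1] - M[1, 0]) > SYM_TOL * max(1.0, float(np.abs(M).max())):
        raise ValueError(f"{name} is not symmetric: off-diagonals {M[0, 1]} != {M[1, 0]}")
    return 0.5 * (M + M.T)


def require_psd(M, name: str = "matrix") -> np.ndarray:
    """Validate symmetry and positive semi-definiteness; return symmetrized copy."""
    M = require_symmetric(M, name)
    lam = np.linalg.eigvalsh(M)
    if lam[0] < -PSD_TOL * max(1.0, lam[-1] if lam[-1] > 0 else 1.0):
        raise ValueError(f"{name} is not positive semi-definite: smallest eigenvalue {lam[0]:.3e}")
    return M


def symmetrize_clip_psd(M: np.ndarray, tol: float = PSD_TOL):
    """Symmetrize and clip negative eigenvalues at zero.

    Returns (repaired matrix, repaired flag). The flag is True only when the
    eigenvalue clip actually changed the matrix beyond ``tol``.
    """
    S = 0.5 * (M + M.T)
    lam, Q = np.linalg.eigh(S)
    if lam[0] >= -tol:
        return S, False
    lam = np.clip(lam, 0.0, None)
    return (Q * lam) @ Q.T, True


def sample_mvn(rng: np.random.Generator, mean, cov, size=None) -> np.ndarray:
    """Multivariate-normal draw tolerating exactly singular (PSD) covariances."""
    cov = np.asarray(cov, dtype=float)
    lam, Q = np.linalg.eigh(0.5 * (cov + cov.T))
    lam = np.clip(lam, 0.0, None)
    A = Q * np.sqrt(lam)
    shape = (cov.shape[0],) if size is None else (size, cov.shape[0])
    z = rng.standard_normal(shape)
    return np.asarray(mean, dtype=float) + z @ A.T
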