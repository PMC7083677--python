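"""Krzanowski shared-subspace comparison of posterior G-matrix distributions.

For each group the first k eigenvectors of its genetic covariance span a
subspace A_t; the summary matrix H = sum_t A_t A_t' has eigenvalues between 0
and the number of groups m, with values near m indicating a common subspace.
The null distribution is built by pooling each draw's genotype breeding-value
vectors across the groups, randomly reassigning genotypes to groups, and
recomputing group covariances from the shuffled vectors.  Groups are judged
to share the subspace when the 95% HPD intervals of the observed and
randomized eigenvalues overlap.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._linalg import require_symmetric

EIG_TIE_TOL = 1e-12

VERDICT_SHARED = "shared"
VERDICT_DIVERGED = "diverged"


def leading_eigenvectors(G, k: int = 1) -> np.ndarray:
    """First k eigenvectors (descending eigenvalue) with a canonical sign.

    The sign convention makes the first nonzero component of each column
    positive.  For (near-)degenerate spectra the eigenbasis is ambiguous; the
    lexicographically smallest canonical-sign vectors are returned.
    """
    G = require_symmetric(G, "G")
    dim = G.shape[0]
    if not 1 <= k <= dim // 2:
        raise ValueError(f"k must satisfy 1 <= k <= dim/2 = {dim // 2}, got {k}")
    lam, Q = np.linalg.eigh(G)
    order = np.argsort(lam)[::-1]
    lam, Q = lam[order], Q[:, order]
    scale = max(1.0, float(abs(lam[0])))
    if abs(lam[0] - lam[-1]) <= EIG_TIE_TOL * scale:
        cols = [_canonical_sign(Q[:, j]) for j in range(dim)]
        cols.sort(key=tuple)
        return np.column_stack(cols[:k])
    A = Q[:, :k].copy()
    for j in range(k):
        A[:, j] = _canonical_sign(A[:, j])
    return A


def _canonical_sign(v: np.ndarray) -> np.ndarray:
    nz = np.flatnonzero(np.abs(v) > 1e-12)
    if nz.size and v[nz[0]] < 0:
        return -v
    return v.copy()


def spectrum_is_degenerate(G) -> bool:
    lam = np.linalg.eigvalsh(require_symmetric(G, "G"))
    return bool(abs(lam[-1] - lam[0]) <= EIG_TIE_TOL * max(1.0, abs(lam[-1])))


def krzanowski_H(subspaces) -> np.ndarray:
    """H = sum_t A_t A_t' over the groups' k-dimensional eigenvector bases."""
    mats = [np.atleast_2d(np.asarray(A, dtype=float)) for A in subspaces]
    if len(mats) < 2:
        raise ValueError("need at least two subspaces")
    shape = mats[0].shape
    if any(A.shape != shape for A in mats):
        raise ValueError("all subspaces must have equal shape")
    H = sum(A @ A.T for A in mats)
    return 0.5 * (H + H.T)


def h_eigenvalues(H: np.ndarray, m: int) -> np.ndarray:
    """Eigenvalues of H sorted descending, clipped to the exact [0, m] bound."""
    lam = np.linalg.eigvalsh(H)[::-1]
    return np.clip(lam, 0.0, float(m))


def h_eigenvalue_posterior(g_draws_a, g_draws_b, k: int = 1) -> np.ndarray:
    """Per-draw H eigenvalues for two paired posterior G-matrix sequences.

    Draw i of the first group is paired with draw i of the second; unequal
    lengths are truncated to the shorter with a warning.
    """
    A = np.asarray(g_draws_a, dtype=float)
    B = np.asarray(g_draws_b, dtype=float)
    if len(A) != len(B):
        warnings.warn(
            f"posterior lengths differ ({len(A)} vs {len(B)}); pairing up to the shorter",
            stacklevel=2,
        )
        n = min(len(A), len(B))
        A, B = A[:n], B[:n]
    out = np.empty((len(A), A.shape[1]))
    for i in range(len(A)):
        H = krzanowski_H([leading_eigenvectors(A[i], k), leading_eigenvectors(B[i], k)])
        out[i] = h_eigenvalues(H, m=2)
    return out


def randomized_null(
    breeding_values,
    group_sizes: tuple[int, int],
    n_shuffles: int = 1,
    k: int = 1,
    seed=None,
) -> np.ndarray:
    """Null H eigenvalues from randomly regrouped breeding-value vectors.

    ``breeding_values`` holds, per retained draw, the pooled genotype
    breeding-value 2-vectors of both groups (shape (draws, n_total, 2)).  For
    every draw and shuffle, genotypes are randomly reassigned to groups of the
    observed sizes, each group's G is the sample covariance of its vectors,
    and the H eigenvalues are recorded.
    """
    bv = np.asarray(breeding_values, dtype=float)
    if bv.ndim != 3 or bv.shape[2] != 2:
        raise ValueError("breeding_values must have shape (draws, n_genotypes, 2)")
    n_a, n_b = group_sizes
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs >= 2 genotypes (covariance undefined otherwise)")
    if n_a + n_b != bv.shape[1]:
        raise ValueError(
            f"pooled genotype count {bv.shape[1]} != sum of group sizes {n_a + n_b}"
        )
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty((bv.shape[0] * n_shuffles, 2))
    row = 0
    for i in range(bv.shape[0]):
        for _ in range(n_shuffles):
            perm = rng.permutation(n_a + n_b)
            Ga = np.cov(bv[i, perm[:n_a]], rowvar=False)
            Gb = np.cov(bv[i, perm[n_a:]], rowvar=False)
            H = krzanowski_H([leading_eigenvectors(Ga, k), leading_eigenvectors(Gb, k)])
            out[row] = h_eigenvalues(H, m=2)
            row += 1
    return out


def hpd_interval(samples, prob: float) -> tuple[float, float]:
    """Shortest contiguous interval containing ceil(prob * n) sorted samples."""
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    if not 0 < prob < 1:
        raise ValueError("prob must be in (0, 1)")
    n = len(x)
    if n < 10:
        raise ValueError(f"need at least 10 samples for an HPD interval, got {n}")
    m = int(np.ceil(prob * n))
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))  # ties resolve to the lowest start
    return float(x[i]), float(x[i + m - 1])


def hpd_excludes_zero(samples, prob: float = 0.95) -> bool:
    lo, hi = hpd_interval(samples, prob)
    return not (lo <= 0.0 <= hi)


#: absolute slack when testing interval overlap; absorbs floating-point
#: eigenvalue error in otherwise-identical subspaces without affecting any
#: scientifically meaningful separation
OVERLAP_TOL = 1e-6


def _intervals_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] <= b[1] + OVERLAP_TOL and b[0] <= a[1] + OVERLAP_TOL


@dataclass
class SubspaceResult:
    """Observed vs randomized H-eigenvalue posteriors and the verdict."""

    k: int
    observed: np.ndarray  # (draws, 2) eigenvalue samples
    randomized: np.ndarray
    observed_hpd: list[tuple[float, float]]
    randomized_hpd: list[tuple[float, float]]
    verdicts: list[str]  # per eigenvalue
    prob: float = 0.95
    degenerate_draws: int = 0

    @property
    def verdict(self) -> str:
        """Overall call: diverged if any eigenvalue's HPD intervals are disjoint."""
        return VERDICT_DIVERGED if VERDICT_DIVERGED in self.verdicts else VERDICT_SHARED

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "prob": self.prob,
            "observed_hpd": [list(map(float, iv)) for iv in self.observed_hpd],
            "randomized_hpd": [list(map(float, iv)) for iv in self.randomized_hpd],
            "verdicts": self.verdicts,
            "verdict": self.verdict,
            "degenerate_draws": self.degenerate_draws,
            "observed_median": [float(np.median(self.observed[:, j])) for j in range(2)],
            "randomized_median": [float(np.median(self.randomized[:, j])) for j in range(2)],
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path


def compare_groups(
    posterior_a,
    posterior_b,
    k: int = 1,
    n_shuffles: int = 1,
    seed=None,
    prob: float = 0.95,
    g_draws_a=None,
    g_draws_b=None,
) -> SubspaceResult:
    """Full Krzanowski comparison of two groups' posteriors.

    ``posterior_a``/``posterior_b`` expose ``G`` (draws, 2, 2) and
    ``breeding_values`` (draws, n, 2).  ``g_draws_*`` may override the
    G-matrix draws (e.g. with observed-scale transforms) while the
    randomization null always operates on the latent breeding values.
    """
    Ga = np.asarray(posterior_a.G if g_draws_a is None else g_draws_a, dtype=float)
    Gb = np.asarray(posterior_b.G if g_draws_b is None else g_draws_b, dtype=float)
    observed = h_eigenvalue_posterior(Ga, Gb, k)
    degenerate = sum(
        spectrum_is_degenerate(Ga[i]) or spectrum_is_degenerate(Gb[i])
        for i in range(min(len(Ga), len(Gb)))
    )

    bv_a = posterior_a.breeding_values
    bv_b = posterior_b.breeding_values
    S = min(len(bv_a), len(bv_b))
    pooled = np.concatenate([bv_a[:S], bv_b[:S]], axis=1)
    null = randomized_null(
        pooled, (bv_a.shape[1], bv_b.shape[1]), n_shuffles=n_shuffles, k=k, seed=seed
    )

    obs_hpd = [hpd_interval(observed[:, j], prob) for j in range(2)]
    null_hpd = [hpd_interval(null[:, j], prob) for j in range(2)]
    verdicts = [
        VERDICT_SHARED if _intervals_overlap(o, r) else VERDICT_DIVERGED
        for o, r in zip(obs_hpd, null_hpd)
    ]
    return SubspaceResult(
        k=k,
        observed=observed,
        randomized=null,
        observed_hpd=obs_hpd,
        randomized_hpd=null_hpd,
        verdicts=verdicts,
        prob=prob,
        degenerate_draws=int(degenerate),
    )
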