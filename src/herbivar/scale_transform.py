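"""Latent-to-observed-scale transformation for the Poisson log-link model.

Variance components of a GLMM live on the latent (link) scale.  For a Poisson
model with log link the observed-scale genetic covariance is obtained by
scaling each latent entry with the population-averaged derivative of the
inverse link,

    G_obs[s, t] = Psi_s * G_lat[s, t] * Psi_t,
    Psi_t = mean_i exp(mu_it + sigma2_t / 2),

where ``mu_it`` is the fixed part of observation i's linear predictor and
``sigma2_t`` the total latent variance of trait t (genetic + population +
garden + residual).  ``G_obs`` is the covariance of the additive (linear in
breeding value) component of the expected counts; a brute-force Monte-Carlo
construction of the same quantity is provided as an independent oracle.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._linalg import require_psd, require_symmetric, sample_mvn

logger = logging.getLogger(__name__)

EXPONENT_MAX = 700.0  # exp overflow guard for float64


@dataclass
class LatentSummary:
    """Fixed-part linear predictors and total latent covariance for one draw."""

    mu: np.ndarray  # (n, 2) fixed-part predictors, one row per observation
    Sigma: np.ndarray  # (2, 2) total latent covariance
    weights: np.ndarray | None = None  # optional averaging weights over rows

    def __post_init__(self):
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        if self.mu.shape[1] != 2:
            raise ValueError("mu must have two trait columns")
        self.Sigma = require_symmetric(self.Sigma, "Sigma")
        if (np.diag(self.Sigma) < 0).any():
            raise ValueError("total latent variances must be non-negative")
        if self.weights is None:
            self.weights = np.full(len(self.mu), 1.0 / len(self.mu))
        else:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (len(self.mu),) or (w < 0).any() or w.sum() <= 0:
                raise ValueError("weights must be non-negative, one per mu row")
            self.weights = w / w.sum()


def expected_observed_mean(mu, sigma2):
    """E[exp(eta)] for eta ~ N(mu, sigma2): the lognormal mean exp(mu + sigma2/2)."""
    mu = np.asarray(mu, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if (sigma2 < 0).any():
        raise ValueError("sigma2 must be non-negative")
    arg = mu + sigma2 / 2.0
    if (arg > EXPONENT_MAX).any():
        raise ValueError(
            f"expected observed mean overflows: max exponent {float(np.max(arg)):.1f} > {EXPONENT_MAX}"
        )
    return np.exp(arg)


def link_scale_factors(latent: LatentSummary) -> np.ndarray:
    """Psi_t: weighted average over observations of exp(mu_it + sigma2_t/2)."""
    s2 = np.diag(latent.Sigma)
    vals = expected_observed_mean(latent.mu, s2[None, :])
    return latent.weights @ vals


def latent_to_observed_G(G_lat, latent: LatentSummary) -> np.ndarray:
    """Scale a latent genetic covariance to the observed (count) scale."""
    G = require_psd(G_lat, "G_lat")
    psi = link_scale_factors(latent)
    return np.outer(psi, psi) * G


def observed_phenotypic_cov(latent: LatentSummary) -> np.ndarray:
    """Observed-scale phenotypic covariance of the counts.

    cov(z_s, z_t) = lambda_s lambda_t (exp(Sigma_st) - 1) + [s == t] lambda_t,
    with lambda_t the expected observed mean of trait t.  The diagonal always
    exceeds lambda_t when the latent variance is positive (overdispersion).
    """
    lam = link_scale_factors(latent)
    C = np.outer(lam, lam) * (np.exp(latent.Sigma) - 1.0)
    return C + np.diag(lam)


def mc_oracle_transform(G_lat, latent: LatentSummary, n_draws: int, seed) -> np.ndarray:
    """Brute-force Monte-Carlo estimate of the observed-scale genetic covariance.

    Simulates breeding values and latent noise, forms each genotype's expected
    counts, and takes the covariance of their additive component (the linear
    regression of expected counts on breeding values).  Estimates the same
    quantity as :func:`latent_to_observed_G` without using the lognormal
    moment identity, so it serves as an independent oracle.
    """
    if n_draws < 10_000:
        raise ValueError("n_draws must be at least 10,000 for a stable oracle")
    G = require_psd(G_lat, "G_lat")
    rng = np.random.default_rng(seed)

    # non-genetic latent variance per trait
    s2_noise = np.clip(np.diag(latent.Sigma) - np.diag(G), 0.0, None)
    n_noise = min(int(n_draws), 200_000)
    eps = rng.standard_normal((n_noise, 2)) * np.sqrt(s2_noise)
    # E over noise and fixed parts of exp(mu + eps), brute force
    base = latent.weights @ np.exp(latent.mu)  # E over fixed parts of exp(mu)
    noise_factor = np.exp(eps).mean(axis=0)
    c = base * noise_factor

    u = sample_mvn(rng, np.zeros(2), G, size=int(n_draws))
    m = c * np.exp(u)  # genotype-level expected counts

    uc = u - u.mean(axis=0)
    mc = m - m.mean(axis=0)
    # additive component: regression of expected counts on breeding values
    B, *_ = np.linalg.lstsq(uc, mc, rcond=None)
    cov_u = (uc.T @ uc) / (len(u) - 1)
    G_obs = B.T @ cov_u @ B
    return 0.5 * (G_obs + G_obs.T)


def transform_posterior(posterior, data=None, sub_thin: int = 1):
    """Observed-scale genetic covariance for each retained posterior draw.

    Parameters
    ----------
    posterior:
        A :class:`~herbivar.animal_model.PosteriorSet` (or any object with
        ``G``, ``R``, ``P_pop``, ``Q_garden``, ``fixed`` arrays and the fitted
        design information).
    data:
        Optional observation table; defaults to the fixed-part design stored
        on the posterior.
    sub_thin:
        Keep every ``sub_thin``-th draw (e.g. 100 on 1,000 draws emulates a
        ten-matrix observed-scale posterior).
    Returns
    -------
    (G_obs, kept_indices):
        Array of observed-scale matrices (one per kept draw, order preserved)
        and the retained draw indices.  Draws whose transform overflows are
        excluded and counted in the log.
    """
    if sub_thin < 1:
        raise ValueError("sub_thin must be >= 1")
    n = posterior.n_draws
    if n == 0:
        raise ValueError("posterior has no retained draws")
    if data is not None:
        log_leaves = np.log(np.asarray(data["total_leaves"], dtype=float))
    else:
        log_leaves = posterior.log_leaves
    idx = np.arange(0, n, sub_thin)
    out = []
    kept = []
    failures = 0
    for i in idx:
        mu = posterior.fixed_part(i, log_leaves)
        Sigma = posterior.total_latent_cov(i)
        try:
            out.append(latent_to_observed_G(posterior.G[i], LatentSummary(mu=mu, Sigma=Sigma)))
            kept.append(i)
        except ValueError:
            failures += 1
    if failures:
        logger.warning("transform_posterior: %d draw(s) failed and were excluded", failures)
    return np.array(out), np.array(kept, dtype=int)


def summarize_observed_G(G_draws: np.ndarray, prob: float = 0.95):
    """Posterior median and HPD per entry, Table-style (v11, cov, v22)."""
    from .subspace import hpd_interval  # local import to avoid a cycle

    entries = {
        "lace_variance": G_draws[:, 0, 0],
        "covariance": G_draws[:, 0, 1],
        "other_variance": G_draws[:, 1, 1],
    }
    rows = []
    for name, x in entries.items():
        lo, hi = hpd_interval(x, prob) if len(x) >= 10 else (np.nan, np.nan)
        rows.append(
            {
                "entry": name,
                "median": float(np.median(x)),
                "hpd_lower": float(lo),
                "hpd_upper": float(hi),
            }
        )
    import pandas as pd

    return pd.DataFrame(rows)
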