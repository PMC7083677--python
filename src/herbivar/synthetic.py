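"""Synthetic clonal reciprocal-transplant datasets with known genetic architecture.

The generator draws, for every plant ``i`` and trait ``t``, a latent linear
predictor

    eta_it = intercept_t + c * log(L_i) + u_{g(i),t} + p_{pop(i),t}
             + q_{gard(i),t} + e_it,

where ``L_i`` is the plant's total leaf count (negative binomial), ``u`` are
genotype breeding values with covariance ``G_lat``, ``p``/``q`` are
population/garden effects, and ``e`` is a plant-level residual.  Observed
counts are Poisson(exp(eta)).  The lace-bug count is a weighted damage score
which is then decomposed into per-level damaged-leaf counts so that the
weighted sum over levels reconstructs the score exactly.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._linalg import require_psd, sample_mvn
from .design import DesignSpec, TrueParams
from .preprocess import OBSERVATION_COLUMNS, validate_observations
from . import scale_transform

ETA_MAX = 30.0  # exp(30) ~ 1e13 counts: far outside any plausible experiment


def _as_rng(seed) -> np.random.Generator:
    if seed is None:
        raise ValueError("a seed is required: synthetic datasets must be reproducible")
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_breeding_values(G_lat, genotype_ids, seed) -> dict[str, np.ndarray]:
    """Independent bivariate-normal breeding values with covariance ``G_lat``."""
    G = require_psd(G_lat, "G_lat")
    rng = _as_rng(seed)
    ids = list(genotype_ids)
    draws = sample_mvn(rng, np.zeros(2), G, size=len(ids))
    return {gid: draws[i] for i, gid in enumerate(ids)}


def _decompose_score(score: int, capacity: int, weights, probs, rng) -> tuple[int, int, int]:
    """Split a lace-bug score into damaged-leaf counts for levels (b, c, d).

    Levels are drawn one leaf at a time with probabilities ``probs``,
    restricted to choices that keep the remaining score representable within
    the remaining leaf capacity.  Requires positive integer weights for the
    damaged levels with min weight 1 (the default 0,1,2,3 scoring).
    """
    w = np.asarray(weights[1:], dtype=int)
    probs = np.asarray(probs, dtype=float)
    counts = np.zeros(3, dtype=int)
    remaining = int(score)
    cap = int(capacity)
    wmax = int(w.max())
    while remaining > 0:
        if cap <= 0:
            raise RuntimeError("score decomposition ran out of leaf capacity")
        feasible = (w <= remaining) & (remaining - w <= wmax * (cap - 1))
        p = probs * feasible
        level = int(rng.choice(3, p=p / p.sum()))
        counts[level] += 1
        remaining -= int(w[level])
        cap -= 1
    return tuple(int(c) for c in counts)


def _validate_decomposable_weights(weights) -> None:
    w = weights[1:]
    if weights[0] != 0:
        raise ValueError("dataset generation requires the undamaged level to carry weight 0")
    if any(float(x) != int(x) or x < 1 for x in w):
        raise ValueError("dataset generation requires positive integer weights for damaged levels")
    if min(int(x) for x in w) != 1:
        raise ValueError("dataset generation requires a damaged level with weight 1")


def simulate_dataset(design: DesignSpec, params: TrueParams, seed) -> pd.DataFrame:
    """Simulate one full experiment; one row per ramet.

    Row count is populations x genotypes_per_population x gardens x
    ramets_per_genotype_per_garden.
    """
    if seed is None:
        raise ValueError("a seed is required: synthetic datasets must be reproducible")
    _validate_decomposable_weights(params.category_weights)
    rng = np.random.default_rng(seed)

    pops = list(design.populations)
    gardens = list(design.gardens)
    origin_of_pop = dict(pops)
    n_geno = design.genotypes_per_population

    # genotype breeding values; with env_G they are drawn per garden country
    genotype_ids = design.genotype_ids()
    geno_origin = {
        gid: origin_of_pop[gid.rsplit("-g", 1)[0]] for gid in genotype_ids
    }
    garden_countries = sorted({c for _, c in gardens})
    bv: dict[tuple[str, str], np.ndarray] = {}
    if params.env_G is not None:
        for gc in garden_countries:
            for gid in genotype_ids:
                G = params.genetic_cov_for(geno_origin[gid], gc)
                bv[(gid, gc)] = sample_mvn(rng, np.zeros(2), G)
    else:
        for gid in genotype_ids:
            G = params.genetic_cov_for(geno_origin[gid], "__none__")
            u = sample_mvn(rng, np.zeros(2), G)
            for gc in garden_countries:
                bv[(gid, gc)] = u

    pop_eff = {p: sample_mvn(rng, np.zeros(2), params.P_pop) for p, _ in pops}
    gard_eff = {g: sample_mvn(rng, np.zeros(2), params.Q_garden) for g, _ in gardens}

    mean, disp = design.leaf_count_model
    p_nb = disp / (disp + mean)

    rows = []
    for pop_id, origin in pops:
        for j in range(1, n_geno + 1):
            gid = f"{pop_id}-g{j:02d}"
            for garden_id, garden_country in gardens:
                n_r = design.ramets_per_genotype_per_garden
                L = rng.negative_binomial(disp, p_nb, size=n_r)
                L = np.maximum(L, 1)
                e = sample_mvn(rng, np.zeros(2), params.R_lat, size=n_r)
                eta = (
                    params.intercepts
                    + params.offset_coefficient * np.log(L)[:, None]
                    + bv[(gid, garden_country)]
                    + pop_eff[pop_id]
                    + gard_eff[garden_id]
                    + e
                )
                if (eta > ETA_MAX).any():
                    raise ValueError(
                        f"latent predictor overflow (max eta={eta.max():.2f} > {ETA_MAX}); "
                        "check intercepts/offset/covariance scales"
                    )
                lam = np.exp(eta)
                z = rng.poisson(lam)
                wmax = int(max(params.category_weights))
                for r in range(n_r):
                    leaves = int(L[r])
                    score = min(int(z[r, 0]), wmax * leaves)
                    nb, nc, nd = _decompose_score(
                        score, leaves, params.category_weights, params.level_probs, rng
                    )
                    other = min(int(z[r, 1]), leaves)
                    rows.append(
                        (
                            gid,
                            pop_id,
                            origin,
                            garden_id,
                            garden_country,
                            leaves - (nb + nc + nd),
                            nb,
                            nc,
                            nd,
                            other,
                            leaves,
                        )
                    )
    df = pd.DataFrame(rows, columns=list(OBSERVATION_COLUMNS))
    return validate_observations(df)


def leaf_count_distribution(design: DesignSpec, tail: float = 1e-10):
    """Support and probabilities of the (>=1-truncated) total-leaf model."""
    mean, disp = design.leaf_count_model
    p_nb = disp / (disp + mean)
    dist = stats.nbinom(disp, p_nb)
    lmax = int(dist.ppf(1.0 - tail))
    support = np.arange(1, lmax + 1)
    pmf = dist.pmf(support)
    pmf[0] += dist.pmf(0)  # draws of zero are clipped up to one leaf
    return support, pmf / pmf.sum()


def latent_summary_for(params: TrueParams, design: DesignSpec) -> "scale_transform.LatentSummary":
    """LatentSummary implied by the generative parameters and leaf model."""
    support, pmf = leaf_count_distribution(design)
    mu = params.intercepts + params.offset_coefficient * np.log(support)[:, None]
    Sigma = params.G_lat + params.P_pop + params.Q_garden + params.R_lat
    return scale_transform.LatentSummary(mu=mu, Sigma=Sigma, weights=pmf)


def true_observed_G(params: TrueParams, design: DesignSpec) -> np.ndarray:
    """Observed-scale genetic covariance implied by the true parameters.

    Uses the same analytic transform as the posterior pipeline, so it serves
    as an oracle for end-to-end parameter-recovery tests.
    """
    return scale_transform.latent_to_observed_G(params.G_lat, latent_summary_for(params, design))


@dataclass
class GMatrixDraws:
    """A minimal posterior-like bundle of G draws with their breeding values."""

    G: np.ndarray  # (draws, 2, 2)
    breeding_values: np.ndarray  # (draws, n_genotypes, 2)


def sample_covariance_posterior(G_lat, n_genotypes: int, n_draws: int, seed) -> GMatrixDraws:
    """Pseudo-posterior built from repeated sampling under a known G.

    Each draw simulates ``n_genotypes`` breeding values from N(0, G_lat) and
    records their sample covariance.  Used to study the calibration and power
    of the subspace comparison without running the MCMC sampler.
    """
    G = require_psd(G_lat, "G_lat")
    if n_genotypes < 2:
        raise ValueError("need at least 2 genotypes per draw")
    rng = _as_rng(seed)
    bv = np.stack(
        [sample_mvn(rng, np.zeros(2), G, size=n_genotypes) for _ in range(n_draws)]
    )
    Gs = np.empty((n_draws, 2, 2))
    for i in range(n_draws):
        Gs[i] = np.cov(bv[i], rowvar=False)
    return GMatrixDraws(G=Gs, breeding_values=bv)


def write_dataset(
    df: pd.DataFrame,
    path: str | Path,
    design: DesignSpec | None = None,
    params: TrueParams | None = None,
    seed: int | None = None,
) -> Path:
    """Write the observation CSV plus a JSON provenance sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(".provenance.json")
    provenance = {
        "seed": seed,
        "design": design.to_dict() if design is not None else None,
        "true_params": params.to_dict() if params is not None else None,
        "n_rows": int(len(df)),
    }
    sidecar.write_text(json.dumps(provenance, indent=2, sort_keys=True))
    return path
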