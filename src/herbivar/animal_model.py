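"""Bayesian bivariate Poisson animal model for clonal count data.

The model for plant i and trait t (t = lace-bug score, other-herbivore
damaged leaves) is

    z_it ~ Poisson(exp(eta_it))
    eta_it = beta_t + beta_L,t * log(L_i) + u_{g(i),t} + p_{pop(i),t}
             + q_{gard(i),t} + e_it

with genotype breeding values u ~ N(0, G), population effects p ~ N(0, P),
garden effects q ~ N(0, Q), and plant-level residuals e ~ N(0, R), each an
unstructured 2x2 covariance with an inverse-Wishart prior.  Because the
genotypes are clonal replicates with an identity relationship matrix, G is a
broad-sense genetic covariance.

Sampling is Metropolis-within-Gibbs: the latent predictors eta are updated
per observation and trait by adaptive random-walk Metropolis under their
conditional Gaussian prior; given eta, all location effects have conjugate
Gaussian full conditionals and all covariance components conjugate
inverse-Wishart full conditionals.  Proposal scales adapt toward 0.44
acceptance during burn-in and are frozen afterwards.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._linalg import require_psd, symmetrize_clip_psd, sample_mvn
from .preprocess import DEFAULT_WEIGHTS, LEVEL_COLUMNS, lace_bug_damage_score

logger = logging.getLogger(__name__)

COMPONENTS = ("G", "R", "P_pop", "Q_garden")
ACCEPT_RANGE = (0.1, 0.7)


@dataclass
class PriorSpec:
    """Priors: diffuse normals for fixed effects, inverse-Wishart for covariances."""

    fixed_effect_variance: float = 1e8
    iw_nu: float = 2.002
    iw_V: np.ndarray = field(default_factory=lambda: 0.002 * np.eye(2))
    #: optional per-component (nu, V) overrides, keyed by component name.
    overrides: dict[str, tuple[float, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self):
        if self.fixed_effect_variance <= 0:
            raise ValueError("fixed_effect_variance must be positive")
        self.iw_V = require_psd(self.iw_V, "iw_V")
        if self.iw_nu <= 1:
            raise ValueError("iw_nu must exceed dimension - 1 = 1")
        for name, (nu, V) in self.overrides.items():
            if name not in COMPONENTS:
                raise ValueError(f"unknown component {name!r}; expected one of {COMPONENTS}")
            if nu <= 1:
                raise ValueError(f"override nu for {name} must exceed 1")
            self.overrides[name] = (float(nu), require_psd(V, f"iw_V[{name}]"))

    def for_component(self, name: str) -> tuple[float, np.ndarray]:
        return self.overrides.get(name, (self.iw_nu, self.iw_V))

    def to_dict(self) -> dict:
        return {
            "fixed_effect_variance": self.fixed_effect_variance,
            "iw_nu": self.iw_nu,
            "iw_V": self.iw_V.tolist(),
            "overrides": {k: [nu, np.asarray(V).tolist()] for k, (nu, V) in self.overrides.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PriorSpec":
        d = dict(d)
        if "iw_V" in d:
            d["iw_V"] = np.asarray(d["iw_V"], dtype=float)
        if "overrides" in d:
            d["overrides"] = {
                k: (float(nu), np.asarray(V, dtype=float)) for k, (nu, V) in d["overrides"].items()
            }
        return cls(**d)


def retained_sample_count(n_iter: int, burn_in: int, thin: int) -> int:
    """Number of retained MCMC draws: floor((n_iter - burn_in) / thin)."""
    if thin < 1:
        raise ValueError("thin must be >= 1")
    if burn_in < 0:
        raise ValueError("burn_in must be non-negative")
    if burn_in >= n_iter:
        raise ValueError("burn_in must be smaller than n_iter (chain would be empty)")
    count = (n_iter - burn_in) // thin
    if count == 0:
        raise ValueError("chain schedule retains no draws (empty chain)")
    return count


@dataclass
class ChainConfig:
    """MCMC schedule; the default mirrors a 65,000-step chain with 15,000
    burn-in thinned every 50 steps, retaining 1,000 draws."""

    n_iter: int = 65_000
    burn_in: int = 15_000
    thin: int = 50
    seed: int | None = None
    adapt_interval: int = 25
    target_accept: float = 0.44
    initial_scale: float = 0.5

    def __post_init__(self):
        retained_sample_count(self.n_iter, self.burn_in, self.thin)
        if not 0 < self.target_accept < 1:
            raise ValueError("target_accept must be in (0, 1)")
        if self.initial_scale <= 0:
            raise ValueError("initial_scale must be positive")

    @property
    def n_retained(self) -> int:
        return retained_sample_count(self.n_iter, self.burn_in, self.thin)

    def to_dict(self) -> dict:
        return {
            "n_iter": self.n_iter,
            "burn_in": self.burn_in,
            "thin": self.thin,
            "seed": self.seed,
            "adapt_interval": self.adapt_interval,
            "target_accept": self.target_accept,
            "initial_scale": self.initial_scale,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ChainConfig":
        return cls(**dict(d))


def sample_iw_component(effect_vectors, nu: float, V, rng, jitter: float = 1e-8) -> np.ndarray:
    """Conjugate inverse-Wishart draw given Gaussian effect vectors.

    Draws from IW(nu + n, V + S) where S is the cross-product matrix of the
    ``n x 2`` effect array.  A singular scale matrix is jittered and warned
    about rather than failing.
    """
    E = np.atleast_2d(np.asarray(effect_vectors, dtype=float))
    if E.size == 0:
        E = np.zeros((0, 2))
    if E.shape[1] != 2:
        raise ValueError("effect_vectors must have two trait columns")
    n = E.shape[0]
    V = require_psd(V, "V")
    df = nu + n
    if df <= 1:
        raise ValueError("inverse-Wishart degrees of freedom must exceed dimension - 1")
    scale = V + E.T @ E
    try:
        chol_inv = np.linalg.cholesky(np.linalg.inv(scale))
    except np.linalg.LinAlgError:
        warnings.warn("singular inverse-Wishart scale matrix; adding jitter", stacklevel=2)
        scale = scale + jitter * np.eye(2)
        chol_inv = np.linalg.cholesky(np.linalg.inv(scale))
    # Bartlett decomposition of a Wishart(df, scale^-1) draw; its inverse is IW
    A = np.zeros((2, 2))
    A[0, 0] = np.sqrt(rng.chisquare(df))
    A[1, 1] = np.sqrt(rng.chisquare(df - 1))
    A[1, 0] = rng.standard_normal()
    LA = chol_inv @ A
    W = LA @ LA.T
    out = np.linalg.inv(W)
    return 0.5 * (out + out.T)


@dataclass
class PosteriorSet:
    """Ordered posterior draws from one model fit."""

    G: np.ndarray  # (S, 2, 2)
    R: np.ndarray
    P_pop: np.ndarray
    Q_garden: np.ndarray
    fixed: np.ndarray  # (S, k, 2) fixed-effect coefficients per trait
    breeding_values: np.ndarray  # (S, n_genotypes, 2)
    genotype_ids: list[str]
    log_leaves: np.ndarray  # (n_obs,)
    offset_pinned: bool
    chain: ChainConfig | None = None
    dropped_components: tuple[str, ...] = ()
    acceptance_rates: dict = field(default_factory=dict)
    proposal_scales: dict = field(default_factory=dict)
    psd_repairs: int = 0
    warnings_: list[str] = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.G.shape[0]

    @property
    def n_genotypes(self) -> int:
        return self.breeding_values.shape[1]

    def fixed_part(self, i: int, log_leaves=None) -> np.ndarray:
        """Fixed-part linear predictors mu (n_obs x 2) for draw i."""
        logL = self.log_leaves if log_leaves is None else np.asarray(log_leaves, dtype=float)
        B = self.fixed[i]
        if self.offset_pinned:
            mu = B[0][None, :] + logL[:, None]
        else:
            mu = B[0][None, :] + logL[:, None] * B[1][None, :]
        return mu

    def total_latent_cov(self, i: int) -> np.ndarray:
        return self.G[i] + self.R[i] + self.P_pop[i] + self.Q_garden[i]

    def validate(self) -> None:
        S = self.n_draws
        for name in COMPONENTS:
            arr = getattr(self, name)
            if arr.shape != (S, 2, 2):
                raise ValueError(f"{name} draws have shape {arr.shape}, expected ({S}, 2, 2)")
            if not np.allclose(arr, np.swapaxes(arr, 1, 2), atol=1e-8):
                raise ValueError(f"{name} contains asymmetric draws")
            eig = np.linalg.eigvalsh(arr)
            if (eig < -1e-10).any():
                raise ValueError(f"{name} contains non-PSD draws (min eigenvalue {eig.min():.3e})")
        if self.breeding_values.shape != (S, len(self.genotype_ids), 2):
            raise ValueError("breeding-value array shape inconsistent with genotype list")
        if self.chain is not None and S != self.chain.n_retained:
            raise ValueError(
                f"retained draw count {S} != schedule count {self.chain.n_retained}"
            )

    # --- persistence -----------------------------------------------------

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in COMPONENTS:
            arr = getattr(self, name)
            pd.DataFrame(
                {
                    "draw_index": np.arange(self.n_draws),
                    "v11": arr[:, 0, 0],
                    "cov": arr[:, 0, 1],
                    "v22": arr[:, 1, 1],
                }
            ).to_csv(directory / f"{name}.csv", index=False, float_format="%.10g")
        S, n_g, _ = self.breeding_values.shape
        bv = pd.DataFrame(
            {
                "draw_index": np.repeat(np.arange(S), n_g),
                "genotype_id": np.tile(np.asarray(self.genotype_ids, dtype=object), S),
                "bv_lace": self.breeding_values[:, :, 0].ravel(),
                "bv_other": self.breeding_values[:, :, 1].ravel(),
            }
        )
        bv.to_csv(directory / "breeding_values.csv", index=False, float_format="%.10g")
        k = self.fixed.shape[1]
        fx = pd.DataFrame(
            self.fixed.reshape(S, 2 * k),
            columns=[f"b{j}_{t}" for j in range(k) for t in ("lace", "other")],
        )
        fx.insert(0, "draw_index", np.arange(S))
        fx.to_csv(directory / "fixed_effects.csv", index=False, float_format="%.10g")
        meta = {
            "genotype_ids": list(self.genotype_ids),
            "log_leaves": self.log_leaves.tolist(),
            "offset_pinned": self.offset_pinned,
            "chain": self.chain.to_dict() if self.chain else None,
            "dropped_components": list(self.dropped_components),
            "acceptance_rates": self.acceptance_rates,
            "proposal_scales": self.proposal_scales,
            "psd_repairs": self.psd_repairs,
            "warnings": self.warnings_,
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=2))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "PosteriorSet":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        comps = {}
        for name in COMPONENTS:
            t = pd.read_csv(directory / f"{name}.csv")
            arr = np.empty((len(t), 2, 2))
            arr[:, 0, 0] = t["v11"]
            arr[:, 0, 1] = arr[:, 1, 0] = t["cov"]
            arr[:, 1, 1] = t["v22"]
            comps[name] = arr
        bv_t = pd.read_csv(directory / "breeding_values.csv")
        genotype_ids = meta["genotype_ids"]
        S = comps["G"].shape[0]
        bv = np.empty((S, len(genotype_ids), 2))
        order = {g: i for i, g in enumerate(genotype_ids)}
        gi = bv_t["genotype_id"].map(order).to_numpy()
        di = bv_t["draw_index"].to_numpy()
        bv[di, gi, 0] = bv_t["bv_lace"]
        bv[di, gi, 1] = bv_t["bv_other"]
        fx_t = pd.read_csv(directory / "fixed_effects.csv").drop(columns="draw_index")
        k = fx_t.shape[1] // 2
        fixed = fx_t.to_numpy().reshape(S, k, 2)
        return cls(
            **comps,
            fixed=fixed,
            breeding_values=bv,
            genotype_ids=genotype_ids,
            log_leaves=np.asarray(meta["log_leaves"], dtype=float),
            offset_pinned=meta["offset_pinned"],
            chain=ChainConfig.from_dict(meta["chain"]) if meta["chain"] else None,
            dropped_components=tuple(meta["dropped_components"]),
            acceptance_rates=meta["acceptance_rates"],
            proposal_scales=meta["proposal_scales"],
            psd_repairs=meta["psd_repairs"],
            warnings_=meta["warnings"],
        )


def _codes(values) -> tuple[np.ndarray, list]:
    cat = pd.Categorical(values)
    return cat.codes.astype(np.intp), list(cat.categories)


def _grouped_effect_update(resid, codes, n_levels, Rinv, prior_cov_inv, rng):
    """Conjugate draw of per-level 2-vector effects given Gaussian 'data' resid."""
    sums = np.zeros((n_levels, 2))
    np.add.at(sums, codes, resid)
    counts = np.bincount(codes, minlength=n_levels).astype(float)
    out = np.empty((n_levels, 2))
    for n_c in np.unique(counts):
        mask = counts == n_c
        prec = n_c * Rinv + prior_cov_inv
        cov = np.linalg.inv(prec)
        L = np.linalg.cholesky(cov)
        means = sums[mask] @ Rinv.T @ cov.T
        z = rng.standard_normal((int(mask.sum()), 2))
        out[mask] = means + z @ L.T
    return out


def fit_bivariate_animal_model(
    records: pd.DataFrame,
    priors: PriorSpec | None = None,
    chain: ChainConfig | None = None,
    weights=DEFAULT_WEIGHTS,
    pin_offset: bool = False,
    prior_only: bool = False,
) -> PosteriorSet:
    """Fit the bivariate Poisson animal model to one group subset.

    ``records`` must contain genotype/population/garden labels, the four
    lace-level leaf counts (or a precomputed ``lace_score`` column),
    ``other_damaged_leaves`` and ``total_leaves``.  With ``pin_offset`` the
    leaf-count coefficient is fixed at 1 (a true offset); otherwise it is a
    fixed effect with a diffuse normal prior.  ``prior_only`` disables the
    likelihood, turning the sampler into a Gibbs chain on the prior (used to
    verify the covariance updates against the prior distribution).
    """
    priors = priors or PriorSpec()
    chain = chain or ChainConfig()
    if chain.seed is None:
        raise ValueError("ChainConfig.seed is required for a reproducible fit")
    rng = np.random.default_rng(chain.seed)

    n = len(records)
    if "lace_score" in records.columns:
        y1 = records["lace_score"].to_numpy(dtype=float)
    else:
        y1 = lace_bug_damage_score(records[list(LEVEL_COLUMNS)].to_numpy(), weights)
    y2 = records["other_damaged_leaves"].to_numpy(dtype=float)
    y = np.column_stack([y1, y2])
    logL = np.log(records["total_leaves"].to_numpy(dtype=float))

    g_idx, genotype_ids = _codes(records["genotype_id"])
    p_idx, pop_ids = _codes(records["population_id"])
    q_idx, garden_ids = _codes(records["garden_id"])
    n_g, n_p, n_q = len(genotype_ids), len(pop_ids), len(garden_ids)

    reps = np.bincount(g_idx)
    if n_g < 2 or reps.min() < 2:
        raise ValueError(
            f"need >=2 genotypes with >=2 replicates each; got {n_g} genotypes, "
            f"min replicates {reps.min() if n_g else 0}"
        )

    dropped = []
    notes: list[str] = []
    use_pop, use_gard = n_p >= 2, n_q >= 2
    if not use_pop:
        dropped.append("P_pop")
        notes.append("population effect dropped: single population level")
    if not use_gard:
        dropped.append("Q_garden")
        notes.append("garden effect dropped: single garden level")
    for note in notes:
        logger.info(note)

    # fixed design per trait: intercept (+ log leaves unless pinned as offset)
    if pin_offset:
        X = np.ones((n, 1))
        offset = logL
    else:
        X = np.column_stack([np.ones(n), logL])
        offset = np.zeros(n)
    k = X.shape[1]
    XtX = X.T @ X
    prior_b_prec = np.eye(2 * k) / priors.fixed_effect_variance

    # state
    eta = np.log(y + 0.5)
    B = np.linalg.lstsq(X, eta - offset[:, None], rcond=None)[0]  # (k, 2)
    u = np.zeros((n_g, 2))
    p_eff = np.zeros((n_p, 2))
    q_eff = np.zeros((n_q, 2))
    covs = {name: 0.1 * np.eye(2) for name in COMPONENTS}

    scales = np.full(2, chain.initial_scale)
    acc = np.zeros(2)
    prop_count = np.zeros(2)
    acc_post = np.zeros(2)
    prop_post = np.zeros(2)

    S = chain.n_retained
    store = {name: np.empty((S, 2, 2)) for name in COMPONENTS}
    store_fixed = np.empty((S, k, 2))
    store_bv = np.empty((S, n_g, 2))
    repairs = 0
    s_i = 0

    nu_V = {name: priors.for_component(name) for name in COMPONENTS}

    def location_mean():
        m = X @ B + offset[:, None] + u[g_idx]
        if use_pop:
            m = m + p_eff[p_idx]
        if use_gard:
            m = m + q_eff[q_idx]
        return m

    with np.errstate(over="ignore"):
        for it in range(1, chain.n_iter + 1):
            if prior_only:
                # Gibbs on the joint prior: effects from N(0, C), C from IW
                u = sample_mvn(rng, np.zeros(2), covs["G"], size=n_g)
                covs["G"] = sample_iw_component(u, *nu_V["G"], rng)
                if use_pop:
                    p_eff = sample_mvn(rng, np.zeros(2), covs["P_pop"], size=n_p)
                    covs["P_pop"] = sample_iw_component(p_eff, *nu_V["P_pop"], rng)
                if use_gard:
                    q_eff = sample_mvn(rng, np.zeros(2), covs["Q_garden"], size=n_q)
                    covs["Q_garden"] = sample_iw_component(q_eff, *nu_V["Q_garden"], rng)
                e = sample_mvn(rng, np.zeros(2), covs["R"], size=n)
                covs["R"] = sample_iw_component(e, *nu_V["R"], rng)
            else:
                R = covs["R"]
                M = location_mean()
                # --- latent predictor update (adaptive random-walk MH) ---
                for t in (0, 1):
                    o = 1 - t
                    rho = R[t, o] / R[o, o]
                    cond_mean = M[:, t] + rho * (eta[:, o] - M[:, o])
                    cond_var = max(R[t, t] - rho * R[t, o], 1e-12)
                    prop = eta[:, t] + scales[t] * rng.standard_normal(n)
                    cur = eta[:, t]
                    logr = (
                        y[:, t] * (prop - cur)
                        - (np.exp(prop) - np.exp(cur))
                        - ((prop - cond_mean) ** 2 - (cur - cond_mean) ** 2) / (2 * cond_var)
                    )
                    accept = np.log(rng.random(n)) < logr
                    eta[accept, t] = prop[accept]
                    a = accept.mean()
                    acc[t] += a
                    prop_count[t] += 1
                    if it > chain.burn_in:
                        acc_post[t] += a
                        prop_post[t] += 1

                if it <= chain.burn_in and it % chain.adapt_interval == 0:
                    rate = acc / prop_count
                    scales *= np.exp(0.66 * (rate - chain.target_accept))
                    acc[:] = 0.0
                    prop_count[:] = 0.0

                # --- conjugate location updates given eta ---
                Rinv = np.linalg.inv(R)
                base = X @ B + offset[:, None]
                pop_part = p_eff[p_idx] if use_pop else 0.0
                gard_part = q_eff[q_idx] if use_gard else 0.0

                resid = eta - base - pop_part - gard_part
                u = _grouped_effect_update(resid, g_idx, n_g, Rinv, np.linalg.inv(covs["G"]), rng)
                if use_pop:
                    resid = eta - base - u[g_idx] - gard_part
                    p_eff = _grouped_effect_update(
                        resid, p_idx, n_p, Rinv, np.linalg.inv(covs["P_pop"]), rng
                    )
                    pop_part = p_eff[p_idx]
                if use_gard:
                    resid = eta - base - u[g_idx] - pop_part
                    q_eff = _grouped_effect_update(
                        resid, q_idx, n_q, Rinv, np.linalg.inv(covs["Q_garden"]), rng
                    )
                    gard_part = q_eff[q_idx]

                resid = eta - offset[:, None] - u[g_idx] - pop_part - gard_part
                prec = np.kron(Rinv, XtX) + prior_b_prec
                rhs = (X.T @ (resid @ Rinv)).ravel(order="F")
                cov_b = np.linalg.inv(prec)
                Lb = np.linalg.cholesky(cov_b)
                b_vec = cov_b @ rhs + Lb @ rng.standard_normal(2 * k)
                B = b_vec.reshape(k, 2, order="F")

                # --- conjugate covariance updates ---
                covs["G"] = sample_iw_component(u, *nu_V["G"], rng)
                if use_pop:
                    covs["P_pop"] = sample_iw_component(p_eff, *nu_V["P_pop"], rng)
                if use_gard:
                    covs["Q_garden"] = sample_iw_component(q_eff, *nu_V["Q_garden"], rng)
                E = eta - X @ B - offset[:, None] - u[g_idx] - pop_part - gard_part
                covs["R"] = sample_iw_component(E, *nu_V["R"], rng)

            # --- retain ---
            if it > chain.burn_in and (it - chain.burn_in) % chain.thin == 0:
                for name in COMPONENTS:
                    M_c = covs[name]
                    if name in dropped:
                        M_c = np.zeros((2, 2))
                    M_c, repaired = symmetrize_clip_psd(M_c)
                    repairs += int(repaired)
                    store[name][s_i] = M_c
                store_fixed[s_i] = B
                store_bv[s_i] = u
                s_i += 1

    rates = {}
    if not prior_only and prop_post.min() > 0:
        rates = {f"eta_trait{t}": float(acc_post[t] / prop_post[t]) for t in (0, 1)}
    warn_list = list(notes)
    for name, r in rates.items():
        if not ACCEPT_RANGE[0] <= r <= ACCEPT_RANGE[1]:
            msg = (
                f"{name} acceptance rate {r:.3f} outside {ACCEPT_RANGE} after burn-in; "
                "inspect traces before trusting this fit"
            )
            warnings.warn(msg, stacklevel=2)
            warn_list.append(msg)
    if repairs:
        warn_list.append(f"{repairs} covariance draw(s) required PSD repair")

    ps = PosteriorSet(
        G=store["G"],
        R=store["R"],
        P_pop=store["P_pop"],
        Q_garden=store["Q_garden"],
        fixed=store_fixed,
        breeding_values=store_bv,
        genotype_ids=[str(g) for g in genotype_ids],
        log_leaves=logL,
        offset_pinned=pin_offset,
        chain=chain,
        dropped_components=tuple(dropped),
        acceptance_rates=rates,
        proposal_scales={f"eta_trait{t}": float(scales[t]) for t in (0, 1)},
        psd_repairs=repairs,
        warnings_=warn_list,
    )
    ps.validate()
    return ps


def lag1_autocorrelation(x) -> float:
    """Lag-1 sample autocorrelation; NaN for a (near-)constant series."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    v = x.var()
    if v < 1e-300:
        return float("nan")
    x0 = x - x.mean()
    return float((x0[:-1] * x0[1:]).mean() / v)


def chain_diagnostics(samples) -> pd.DataFrame:
    """Per-parameter lag-1 autocorrelation, effective sample size and flags.

    ``samples`` may be a PosteriorSet or a mapping of name -> 1-D sample array.
    Parameters with |lag-1 autocorrelation| > 0.1 at the retained (thinned)
    resolution are flagged, as are degenerate (constant) chains.
    """
    import arviz as az

    if isinstance(samples, PosteriorSet):
        named = {}
        for name in COMPONENTS:
            arr = getattr(samples, name)
            if name in samples.dropped_components:
                continue
            named[f"{name}_v11"] = arr[:, 0, 0]
            named[f"{name}_cov"] = arr[:, 0, 1]
            named[f"{name}_v22"] = arr[:, 1, 1]
    else:
        named = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    rows = []
    for name, x in named.items():
        if len(x) < 10:
            raise ValueError("need at least 10 retained draws for diagnostics")
        r1 = lag1_autocorrelation(x)
        degenerate = not np.isfinite(r1)
        ess = float("nan") if degenerate else float(az.ess(np.asarray(x)))
        rows.append(
            {
                "parameter": name,
                "lag1_autocorr": r1,
                "ess": ess,
                "mean": float(np.mean(x)),
                "sd": float(np.std(x)),
                "flagged": bool(degenerate or abs(r1) > 0.1),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)
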