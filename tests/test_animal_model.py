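import numpy as np
import pandas as pd
import pytest

from herbivar import (
    ChainConfig,
    PosteriorSet,
    PriorSpec,
    chain_diagnostics,
    fit_bivariate_animal_model,
    retained_sample_count,
    sample_iw_component,
)
from herbivar.animal_model import lag1_autocorrelation

from conftest import TRUE_G


@pytest.mark.parametrize(
    "n_iter, burn_in, thin, expected",
    [
        (65_000, 15_000, 50, 1_000),
        (65_000, 15_000, 5_000, 10),
        (6_500, 1_500, 5, 1_000),
    ],
)
def test_retained_sample_count(n_iter, burn_in, thin, expected):
    assert retained_sample_count(n_iter, burn_in, thin) == expected


def test_retained_sample_count_rejects_degenerate_schedules():
    with pytest.raises(ValueError, match="empty"):
        retained_sample_count(100, 100, 1)
    with pytest.raises(ValueError, match="thin"):
        retained_sample_count(100, 50, 0)
    with pytest.raises(ValueError, match="empty chain"):
        retained_sample_count(100, 90, 50)


def test_chain_config_requires_valid_schedule():
    with pytest.raises(ValueError):
        ChainConfig(n_iter=100, burn_in=100, thin=1)


def test_iw_prior_mean():
    """With no data, draws come from the prior: mean V / (nu - 3) for 2x2."""
    nu, V = 10.0, np.array([[7.0, 1.4], [1.4, 3.5]])
    rng = np.random.default_rng(0)
    draws = np.array([sample_iw_component(np.zeros((0, 2)), nu, V, rng) for _ in range(10_000)])
    assert np.allclose(draws.mean(axis=0), V / (nu - 3.0), rtol=0.07)


def test_iw_conjugacy_limit():
    """Data dominating the prior: posterior mean approaches S / (n + nu - 3)."""
    rng = np.random.default_rng(1)
    E = rng.standard_normal((200, 2)) * 50.0
    S = E.T @ E
    nu, V = 4.0, 0.01 * np.eye(2)
    draws = np.array([sample_iw_component(E, nu, V, rng) for _ in range(4_000)])
    expected = (V + S) / (200 + nu - 3.0)
    assert np.allclose(draws.mean(axis=0), expected, rtol=0.1)


def test_iw_draw_always_symmetric_psd():
    rng = np.random.default_rng(2)
    for _ in range(200):
        M = sample_iw_component(rng.standard_normal((5, 2)), 2.002, 0.002 * np.eye(2), rng)
        assert np.array_equal(M, M.T)
        assert np.linalg.eigvalsh(M)[0] > 0


def test_lag1_autocorrelation_closed_form():
    """AR(1) with coefficient 0.5 has lag-1 autocorrelation 0.5."""
    rng = np.random.default_rng(3)
    x = np.empty(20_000)
    x[0] = 0.0
    eps = rng.standard_normal(len(x))
    for i in range(1, len(x)):
        x[i] = 0.5 * x[i - 1] + eps[i]
    assert abs(lag1_autocorrelation(x) - 0.5) < 0.1


def test_diagnostics_white_noise_and_constant():
    rng = np.random.default_rng(4)
    rep = chain_diagnostics({"iid": rng.standard_normal(1_000), "const": np.ones(1_000)})
    rep = rep.set_index("parameter")
    assert abs(rep.loc["iid", "lag1_autocorr"]) < 0.1
    assert not rep.loc["iid", "flagged"]
    assert rep.loc["const", "degenerate"]
    assert rep.loc["const", "flagged"]


def test_diagnostics_require_enough_draws():
    with pytest.raises(ValueError, match="10"):
        chain_diagnostics({"x": np.arange(5.0)})


def test_fit_requires_seed_and_replication(small_subset):
    with pytest.raises(ValueError, match="seed"):
        fit_bivariate_animal_model(small_subset, chain=ChainConfig(n_iter=200, burn_in=50, thin=1))
    single = small_subset.groupby("genotype_id").head(1)
    with pytest.raises(ValueError, match="replicates"):
        fit_bivariate_animal_model(
            single, chain=ChainConfig(n_iter=200, burn_in=50, thin=1, seed=1)
        )


def test_posterior_draws_are_symmetric_psd(jp_jp_fit):
    for name in ("G", "R", "P_pop", "Q_garden"):
        arr = getattr(jp_jp_fit, name)
        assert np.allclose(arr, np.swapaxes(arr, 1, 2))
        assert np.linalg.eigvalsh(arr).min() >= -1e-10
    assert jp_jp_fit.n_draws == jp_jp_fit.chain.n_retained
    assert jp_jp_fit.breeding_values.shape == (jp_jp_fit.n_draws, 30, 2)


def test_parameter_recovery_single_replicate(jp_jp_fit):
    """Posterior median of G within 50% of truth elementwise; HPD covers truth."""
    from herbivar import hpd_interval

    med = np.median(jp_jp_fit.G, axis=0)
    assert np.all(np.abs(med - TRUE_G) <= 0.5 * np.abs(TRUE_G))
    for (i, j) in [(0, 0), (0, 1), (1, 1)]:
        lo, hi = hpd_interval(jp_jp_fit.G[:, i, j], 0.95)
        assert lo <= TRUE_G[i, j] <= hi


def test_acceptance_rates_tracked_and_adapted(jp_jp_fit):
    for rate in jp_jp_fit.acceptance_rates.values():
        assert 0.1 <= rate <= 0.7


def test_all_zero_counts_do_not_crash(small_subset):
    zero = small_subset.copy()
    for col in ("lace_lvl_b", "lace_lvl_c", "lace_lvl_d", "other_damaged_leaves"):
        zero[col] = 0
    zero["lace_lvl_a"] = zero["total_leaves"]
    ps = fit_bivariate_animal_model(
        zero, chain=ChainConfig(n_iter=600, burn_in=100, thin=2, seed=7)
    )
    # no genetic signal: variance posterior stays near the prior's low range
    assert np.median(ps.G[:, 0, 0]) < 0.1
    assert np.median(ps.G[:, 1, 1]) < 0.1


def test_single_level_garden_dropped(small_subset):
    one_garden = small_subset[small_subset["garden_id"] == small_subset["garden_id"].iloc[0]]
    ps = fit_bivariate_animal_model(
        one_garden, chain=ChainConfig(n_iter=400, burn_in=100, thin=2, seed=8)
    )
    assert "Q_garden" in ps.dropped_components
    assert np.all(ps.Q_garden == 0.0)


def test_poor_acceptance_warns(small_subset):
    with pytest.warns(UserWarning, match="acceptance rate"):
        ps = fit_bivariate_animal_model(
            small_subset,
            chain=ChainConfig(
                n_iter=300, burn_in=40, thin=2, seed=9, initial_scale=80.0, adapt_interval=1000
            ),
        )
    assert any("acceptance" in w for w in ps.warnings_)


def test_prior_only_sampling_recovers_prior_mean(small_subset):
    """With the likelihood disabled the G draws follow the inverse-Wishart prior."""
    nu, V = 10.0, 7.0 * np.array([[0.8, 0.1], [0.1, 0.4]])
    priors = PriorSpec(overrides={"G": (nu, V)})
    ps = fit_bivariate_animal_model(
        small_subset,
        priors=priors,
        chain=ChainConfig(n_iter=4_000, burn_in=500, thin=1, seed=10),
        prior_only=True,
    )
    assert np.allclose(ps.G.mean(axis=0), V / (nu - 3.0), rtol=0.15, atol=0.02)


def test_two_chains_converge(jp_jp_subset):
    """Gelman-Rubin scale reduction < 1.1 for G entries across two seeds."""
    chains = [
        fit_bivariate_animal_model(
            jp_jp_subset, chain=ChainConfig(n_iter=4_000, burn_in=1_500, thin=2, seed=s)
        )
        for s in (21, 22)
    ]
    for (i, j) in [(0, 0), (0, 1), (1, 1)]:
        draws = np.array([c.G[:, i, j] for c in chains])
        m, n = draws.shape
        W = draws.var(axis=1, ddof=1).mean()
        B = n * draws.mean(axis=1).var(ddof=1)
        rhat = np.sqrt(((n - 1) / n * W + B / n) / W)
        assert rhat < 1.1, f"G[{i},{j}] rhat {rhat}"


def test_posterior_save_load_round_trip(jp_jp_fit, tmp_path):
    jp_jp_fit.save(tmp_path / "post")
    back = PosteriorSet.load(tmp_path / "post")
    assert np.allclose(back.G, jp_jp_fit.G)
    assert np.allclose(back.breeding_values, jp_jp_fit.breeding_values)
    assert back.genotype_ids == jp_jp_fit.genotype_ids
    assert back.offset_pinned == jp_jp_fit.offset_pinned
    back.validate()


def test_diagnostics_on_fit(jp_jp_fit):
    rep = chain_diagnostics(jp_jp_fit).set_index("parameter")
    assert {"G_v11", "G_cov", "G_v22"} <= set(rep.index)
    # the genetic component must mix well; nuisance components (few levels)
    # are allowed higher autocorrelation
    assert rep.loc[["G_v11", "G_cov", "G_v22"], "ess"].min() > 100
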