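import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from herbivar import (
    compare_groups,
    h_eigenvalue_posterior,
    hpd_excludes_zero,
    hpd_interval,
    krzanowski_H,
    leading_eigenvectors,
    randomized_null,
)
from herbivar.subspace import h_eigenvalues
from herbivar.synthetic import sample_covariance_posterior


def _random_psd(rng):
    A = rng.standard_normal((2, 2))
    return A @ A.T + 1e-6 * np.eye(2)


def test_leading_eigenvector_axis_aligned():
    v = leading_eigenvectors(np.diag([2.0, 1.0]), k=1)
    assert np.allclose(v, [[1.0], [0.0]])
    assert np.linalg.norm(v) == pytest.approx(1.0)


def test_leading_eigenvector_validation():
    with pytest.raises(ValueError, match="symmetric"):
        leading_eigenvectors(np.array([[1.0, 0.5], [0.0, 1.0]]), k=1)
    with pytest.raises(ValueError, match="k must"):
        leading_eigenvectors(np.eye(2), k=2)


def test_leading_eigenvector_tie_break_deterministic():
    """Equal eigenvalues resolve to the lexicographically smallest sign-fixed vector."""
    a = leading_eigenvectors(np.eye(2), k=1)
    b = leading_eigenvectors(2.0 * np.eye(2), k=1)
    assert np.array_equal(a, b)
    assert np.linalg.norm(a) == pytest.approx(1.0)


def test_leading_eigenvector_unit_norm_random():
    rng = np.random.default_rng(0)
    for _ in range(50):
        v = leading_eigenvectors(_random_psd(rng), k=1)
        assert np.linalg.norm(v) == pytest.approx(1.0)
        # canonical sign: first nonzero component positive
        nz = np.flatnonzero(np.abs(v[:, 0]) > 1e-12)
        assert v[nz[0], 0] > 0


def test_H_identical_vectors():
    a = np.array([[0.6], [0.8]])
    H = krzanowski_H([a, a])
    assert np.allclose(h_eigenvalues(H, 2), [2.0, 0.0])


def test_H_orthogonal_vectors():
    H = krzanowski_H([np.array([[1.0], [0.0]]), np.array([[0.0], [1.0]])])
    assert np.allclose(H, np.eye(2))
    assert np.allclose(h_eigenvalues(H, 2), [1.0, 1.0])


@settings(derandomize=True, max_examples=60, deadline=None)
@given(theta=st.floats(0.0, np.pi))
def test_H_eigenvalues_closed_form(theta):
    """Two unit vectors at angle theta give eigenvalues 1 +/- |cos theta|."""
    a = np.array([[1.0], [0.0]])
    b = np.array([[np.cos(theta)], [np.sin(theta)]])
    lam = h_eigenvalues(krzanowski_H([a, b]), 2)
    assert lam == pytest.approx([1.0 + abs(np.cos(theta)), 1.0 - abs(np.cos(theta))], abs=1e-9)


def test_H_shape_mismatch_rejected():
    with pytest.raises(ValueError, match="equal shape"):
        krzanowski_H([np.ones((2, 1)), np.ones((3, 1))])
    with pytest.raises(ValueError, match="two"):
        krzanowski_H([np.ones((2, 1))])


@settings(derandomize=True, max_examples=50, deadline=None)
@given(seed=st.integers(0, 10_000), flip_a=st.booleans(), flip_b=st.booleans())
def test_H_invariant_to_eigenvector_sign(seed, flip_a, flip_b):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((2, 1))
    a /= np.linalg.norm(a)
    b = rng.standard_normal((2, 1))
    b /= np.linalg.norm(b)
    H1 = krzanowski_H([a, b])
    H2 = krzanowski_H([-a if flip_a else a, -b if flip_b else b])
    assert np.allclose(H1, H2)


def test_trace_and_bounds_on_random_psd_pairs():
    rng = np.random.default_rng(1)
    for _ in range(500):
        Ga, Gb = _random_psd(rng), _random_psd(rng)
        H = krzanowski_H([leading_eigenvectors(Ga, 1), leading_eigenvectors(Gb, 1)])
        assert np.trace(H) == pytest.approx(2.0, abs=1e-9)
        lam = h_eigenvalues(H, 2)
        assert 0.0 <= lam[1] <= lam[0] <= 2.0
        # closed form against the leading-eigenvector angle
        cos = abs(float(leading_eigenvectors(Ga, 1)[:, 0] @ leading_eigenvectors(Gb, 1)[:, 0]))
        assert lam[0] == pytest.approx(1.0 + cos, abs=1e-9)


def test_h_eigenvalue_posterior_identical_groups(jp_jp_fit):
    """Feeding the same posterior to both slots gives h1 = 2 in every draw."""
    eig = h_eigenvalue_posterior(jp_jp_fit.G, jp_jp_fit.G)
    assert np.allclose(eig[:, 0], 2.0)
    assert np.allclose(eig[:, 1], 0.0)


def test_h_eigenvalue_posterior_truncates_with_warning(jp_jp_fit):
    with pytest.warns(UserWarning, match="lengths differ"):
        eig = h_eigenvalue_posterior(jp_jp_fit.G[:50], jp_jp_fit.G)
    assert eig.shape == (50, 2)
    assert eig.max() <= 2.0


def test_randomized_null_contract():
    draws = sample_covariance_posterior(np.eye(2), 10, 20, seed=3)
    pooled = np.concatenate([draws.breeding_values, draws.breeding_values], axis=1)
    null = randomized_null(pooled, (10, 10), n_shuffles=2, k=1, seed=4)
    assert null.shape == (40, 2)
    assert null.min() >= 0.0 and null.max() <= 2.0
    again = randomized_null(pooled, (10, 10), n_shuffles=2, k=1, seed=4)
    assert np.array_equal(null, again)
    with pytest.raises(ValueError, match=">= 2"):
        randomized_null(pooled, (1, 19), seed=1)
    with pytest.raises(ValueError, match="group sizes"):
        randomized_null(pooled, (9, 10), seed=1)


def test_hpd_interval_uniform_grid():
    """Exhaustive window search on 1..100 at 95%: all windows tie, lowest start wins."""
    samples = np.arange(1, 101, dtype=float)
    assert hpd_interval(samples, 0.95) == (1.0, 95.0)


def test_hpd_interval_constant_and_small_samples():
    lo, hi = hpd_interval(np.full(50, 3.3), 0.95)
    assert lo == hi == 3.3
    with pytest.raises(ValueError, match="10 samples"):
        hpd_interval(np.arange(5), 0.95)
    with pytest.raises(ValueError, match="prob"):
        hpd_interval(np.arange(20), 1.5)


def test_hpd_interval_matches_arviz_on_normal_sample():
    import arviz as az

    rng = np.random.default_rng(6)
    x = rng.normal(2.0, 1.0, size=5_000)
    lo, hi = hpd_interval(x, 0.95)
    ref = az.hdi(x, hdi_prob=0.95)
    assert lo == pytest.approx(ref[0], abs=0.02)
    assert hi == pytest.approx(ref[1], abs=0.02)


def test_hpd_interval_symmetric_sample_centred_on_mode():
    rng = np.random.default_rng(7)
    x = rng.normal(0.0, 1.0, size=20_000)
    lo, hi = hpd_interval(x, 0.9)
    q_lo, q_hi = np.quantile(x, [0.05, 0.95])
    assert lo == pytest.approx(q_lo, abs=0.1)
    assert hi == pytest.approx(q_hi, abs=0.1)


def test_hpd_excludes_zero():
    rng = np.random.default_rng(8)
    assert hpd_excludes_zero(np.arange(1, 101, dtype=float), 0.95)
    sym = np.concatenate([rng.normal(0, 1, 500), -rng.normal(0, 1, 500)])
    assert not hpd_excludes_zero(sym, 0.95)
    assert hpd_excludes_zero(rng.normal(3.0, 1.0, size=1_000), 0.95)


def test_compare_groups_same_posterior_is_shared(jp_jp_fit):
    res = compare_groups(jp_jp_fit, jp_jp_fit, seed=9)
    assert res.verdict == "shared"
    assert np.allclose(res.observed[:, 0], 2.0)


def test_compare_groups_verdict_invariant_to_order():
    GA = np.array([[2.0, 0.0], [0.0, 0.1]])
    GB = np.array([[0.05, 0.0], [0.0, 0.5]])
    a = sample_covariance_posterior(GA, 25, 80, seed=10)
    b = sample_covariance_posterior(GB, 25, 80, seed=11)
    r1 = compare_groups(a, b, seed=12)
    r2 = compare_groups(b, a, seed=12)
    assert r1.verdict == r2.verdict == "diverged"
    # observed eigenvalues do not depend on group labels
    assert np.allclose(r1.observed, r2.observed)


def test_subspace_result_serialization(tmp_path):
    a = sample_covariance_posterior(np.diag([1.0, 0.2]), 15, 50, seed=13)
    b = sample_covariance_posterior(np.diag([1.0, 0.2]), 15, 50, seed=14)
    res = compare_groups(a, b, seed=15)
    d = res.to_dict()
    assert d["verdict"] in ("shared", "diverged")
    assert len(d["observed_hpd"]) == 2
    path = res.save(tmp_path / "res.json")
    assert path.exists()
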