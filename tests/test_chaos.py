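"""Correlation-dimension estimators: embedding, pair statistics, fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import csneuron as cs
from csneuron.chaos import (
    CorrelationCurve,
    correlation_sum,
    default_omega_grid,
    default_r_grid,
    estimate_d2,
    fit_d2,
    normalize_and_embed,
    rotational_spectrum,
)
from csneuron.fixtures import FixtureSpec, fixture_points, fixture_series


def test_normalize_and_embed_example():
    emb = normalize_and_embed([500, 1000, 250], w=2)
    assert emb.normalization_max == 1000
    assert emb.vectors.tolist() == [[0.5, 1.0], [1.0, 0.25]]


def test_embed_constant_series_gives_identical_vectors():
    emb = normalize_and_embed(np.full(50, 7), w=5)
    assert np.all(emb.vectors == 1.0)
    assert emb.n_vectors == 46


def test_embed_rejects_short_series():
    with pytest.raises(ValueError, match="short"):
        normalize_and_embed([1, 2, 3], w=23)


def test_identical_vectors_degenerate_statistics():
    emb = normalize_and_embed(np.full(40, 3), w=4)
    c = correlation_sum(emb, np.array([0.1, 1.0]), n_pairs=10_000, seed=0)
    assert np.all(c.c == 1.0)
    s = rotational_spectrum(emb, np.array([0.0, 10.0]), n_pairs=10_000, seed=0)
    assert np.all(s.s == 1.0)
    est = fit_d2(c)
    assert est.d2 == 0.0 and not est.is_chaotic


def test_two_vectors_step_in_correlation_sum():
    emb = cs.EmbeddedSeries(np.array([[0.0, 0.0], [0.3, 0.4]]), 2, 1.0)
    c = correlation_sum(emb, np.array([0.4, 0.6]), n_pairs=10)
    assert c.c.tolist() == [0.0, 1.0]  # the single pair is at distance 0.5


def test_spectrum_is_one_at_omega_zero():
    emb = fixture_points(FixtureSpec("uniform_segment", 100, seed=1))
    s = rotational_spectrum(emb, np.array([0.0, 1.0, 10.0]), n_pairs=10_000, seed=0)
    assert s.s[0] == pytest.approx(1.0)


def _brute_force_curves(vectors, r_grid, omega_grid):
    n = len(vectors)
    dists = []
    for i in range(n - 1):
        for j in range(i + 1, n):
            dists.append(np.linalg.norm(vectors[i] - vectors[j]))
    dists = np.array(dists)
    c = np.array([(dists <= r).mean() for r in r_grid])
    s = np.array([np.exp(-0.5 * (w * dists) ** 2).mean() for w in omega_grid])
    return c, s


def test_pair_statistics_match_brute_force_exactly():
    """With full pair coverage the estimators equal the O(n^2) double loop."""
    rng = np.random.default_rng(42)
    vectors = rng.random((10, 4))
    emb = cs.EmbeddedSeries(vectors, 4, 1.0)
    r_grid, om_grid = default_r_grid(20), default_omega_grid(20)
    c_ref, s_ref = _brute_force_curves(vectors, r_grid, om_grid)
    c = correlation_sum(emb, r_grid, n_pairs=45, seed=0)
    s = rotational_spectrum(emb, om_grid, n_pairs=45, seed=0)
    assert c.exhaustive and s.exhaustive
    assert np.allclose(c.c, c_ref, rtol=0, atol=1e-15)
    assert np.allclose(s.s, s_ref, rtol=0, atol=1e-12)


def test_estimator_determinism_under_seed():
    isis = fixture_series(FixtureSpec("two_frequency_quasiperiodic", 2000, seed=3))
    a = estimate_d2(isis, "correlation_sum", n_pairs=50_000, seed=7)
    b = estimate_d2(isis, "correlation_sum", n_pairs=50_000, seed=7)
    assert a.d2 == b.d2 and a.ci90 == b.ci90


def test_exact_power_law_recovered_perfectly():
    r = default_r_grid(30)
    curve = CorrelationCurve(r=r, c=r**0.8, n_pairs=10**9, seed=None)
    est = fit_d2(curve)
    assert est.d2 == pytest.approx(0.8, abs=1e-12)
    assert est.r_squared == pytest.approx(1.0, abs=1e-12)
    assert est.is_chaotic


def test_constant_series_classified_non_chaotic():
    est = estimate_d2(fixture_series(FixtureSpec("constant", 200)), "correlation_sum",
                      w=10, n_pairs=10_000, seed=0)
    assert est.d2 == 0.0 and not est.is_chaotic


def test_method_agreement_on_quasiperiodic_series():
    """The two estimators agree closely on a well-converged 1-D attractor."""
    isis = fixture_series(FixtureSpec("two_frequency_quasiperiodic", 5000, seed=5))
    ec = estimate_d2(isis, "correlation_sum", n_pairs=200_000, seed=1)
    er = estimate_d2(isis, "rotational_spectrum", n_pairs=200_000, seed=1)
    assert abs(ec.d2 - er.d2) <= 0.05
    assert ec.is_chaotic and er.is_chaotic  # non-zero dimension detected


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    n=st.integers(5, 60),
    w=st.integers(2, 8),
)
def test_curve_monotonicity_properties(seed, n, w):
    """C(r) is nondecreasing in r and in [0,1]; S(Omega) is nonincreasing
    with S(0) = 1 -- for any point cloud."""
    rng = np.random.default_rng(seed)
    emb = cs.EmbeddedSeries(rng.random((n, w)), w, 1.0)
    c = correlation_sum(emb, default_r_grid(25), n_pairs=500, seed=seed)
    assert np.all(np.diff(c.c) >= 0)
    assert np.all((c.c >= 0) & (c.c <= 1))
    s = rotational_spectrum(emb, np.concatenate([[0.0], default_omega_grid(25)]),
                            n_pairs=500, seed=seed)
    assert s.s[0] == pytest.approx(1.0)
    assert np.all(np.diff(s.s) <= 1e-12)
    # the Gaussian kernel underflows to exactly 0 at very large Omega
    assert np.all((s.s >= 0) & (s.s <= 1 + 1e-12))


def test_fixture_dimensions_recovered():
    """Synthetic sets of known dimension 0/1/2 are recovered by both
    estimators (1e4 points, 1e5 pairs; the 2-D patch needs the full point
    count for its small-distance statistics)."""
    for kind, n, lo, hi in [
        ("uniform_segment", 4000, 0.9, 1.1),
        ("uniform_square", 10_000, 1.8, 2.2),
        ("two_frequency_quasiperiodic", 4000, 0.9, 1.1),
    ]:
        emb = fixture_points(FixtureSpec(kind, n, seed=11))
        for method in ("correlation_sum", "rotational_spectrum"):
            est = cs.estimate_d2_points(emb, method, n_pairs=100_000, seed=2)
            assert lo <= est.d2 <= hi, (kind, method, est.d2)
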