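"""Interference-escape density, cdf and likelihood checks.

The reference implementations here (series densities via scipy.stats,
subset-sum likelihood via itertools) are coded independently of the
package's vectorized path and share no helpers with it.
"""

import itertools
import math

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import gamma as gamma_dist

from xoinfer.core import HSParameters, IntervalData
from xoinfer.model import (
    CompiledDataset,
    chiasma_gap_cdf,
    dataset_loglik,
    first_gap_cdf,
    first_gap_density,
    interference_gap_cdf,
    interference_gap_density,
    meiosis_loglik,
)

# ---------------------------------------------------------------- reference

_K_REF = 200


def f_star_ref(y: float, nu: float, q: float) -> float:
    k = np.arange(1, _K_REF + 1)
    return float(np.sum(0.5**k * gamma_dist.pdf(y, a=k * nu, scale=1.0 / (2 * q * nu))))


def F_star_ref(y: float, nu: float, q: float) -> float:
    k = np.arange(1, _K_REF + 1)
    return float(np.sum(0.5**k * gamma_dist.cdf(y, a=k * nu, scale=1.0 / (2 * q * nu))))


def g_star_ref(y: float, nu: float, q: float) -> float:
    return q * (1.0 - F_star_ref(y, nu, q))


def G_star_ref(y: float, nu: float, q: float) -> float:
    val, _ = integrate.quad(g_star_ref, 0.0, y, args=(nu, q), limit=200)
    return val


def hs_loglik_ref(positions, length, nu, p) -> float:
    """Subset-enumeration likelihood, straight from the model definition."""
    q = 1.0 - p
    total = 0.0
    n = len(positions)
    for mask in itertools.product([0, 1], repeat=n):
        escape = [positions[i] for i in range(n) if mask[i]]
        chain = [positions[i] for i in range(n) if not mask[i]]
        term = p ** len(escape) * math.exp(-p * length)
        if not chain:
            term *= 1.0 - G_star_ref(length, nu, q)
        else:
            term *= g_star_ref(chain[0], nu, q)
            for a, b in zip(chain, chain[1:]):
                term *= f_star_ref(b - a, nu, q)
            term *= 1.0 - F_star_ref(length - chain[-1], nu, q)
        total += term
    return math.log(total)


# ------------------------------------------------------------------- tests


def test_nu1_collapse_to_exponential():
    """At nu=1 thinning a rate-2q Poisson gives exponential(q) gaps."""
    params = HSParameters(1.0, 0.5)
    ys = np.array([0.0, 0.1, 0.5, 1.0, 2.0, 5.0])
    expected = params.q * np.exp(-params.q * ys)
    np.testing.assert_allclose(
        interference_gap_density(ys, params), expected, atol=1e-9
    )
    # memoryless: forward recurrence equals the gap density itself
    np.testing.assert_allclose(
        first_gap_density(ys, params), expected, atol=1e-9
    )


@pytest.mark.parametrize("nu", [1.0, 5.0, 10.0, 20.0])
@pytest.mark.parametrize("q", [0.5, 0.9, 1.0])
def test_densities_normalize(nu, q):
    params = HSParameters(nu, 1.0 - q)
    for dens in (interference_gap_density, first_gap_density):
        val, _ = integrate.quad(lambda y: dens(y, params), 0, np.inf, limit=200)
        assert abs(val - 1.0) < 1e-6


def test_f_star_mean_is_inverse_q():
    params = HSParameters(10.0, 0.05)
    mean, _ = integrate.quad(
        lambda y: y * interference_gap_density(y, params), 0, np.inf, limit=200
    )
    assert abs(mean - 1.0 / params.q) < 1e-6


def test_first_gap_density_at_zero_equals_q():
    assert first_gap_density(0.0, HSParameters(10.0, 0.0)) == pytest.approx(1.0, abs=1e-9)
    assert first_gap_density(0.0, HSParameters(7.0, 0.2)) == pytest.approx(0.8, abs=1e-9)


def test_cdf_boundary_and_tail():
    params = HSParameters(10.0, 0.05)
    assert interference_gap_cdf(0.0, params) == 0.0
    assert first_gap_cdf(0.0, params) == 0.0
    far = 50.0 / params.q
    assert interference_gap_cdf(far, params) >= 1.0 - 1e-9
    assert chiasma_gap_cdf(far, params) >= 1.0 - 1e-9


def test_cdfs_monotone_to_one():
    params = HSParameters(7.0, 0.1)
    ys = np.linspace(0.0, 12.0, 400)
    for cdf in (interference_gap_cdf, first_gap_cdf):
        vals = np.asarray(cdf(ys, params))
        assert np.all(np.diff(vals) >= -1e-12)
        assert vals[-1] > 1.0 - 1e-6
    assert np.all(np.asarray(interference_gap_density(ys, params)) >= 0.0)


def test_first_gap_cdf_matches_quadrature():
    params = HSParameters(10.0, 0.05)
    for y in np.linspace(0.05, 2.0, 100):
        assert first_gap_cdf(y, params) == pytest.approx(
            G_star_ref(y, params.nu, params.q), abs=1e-7
        )


def test_interference_pathway_requires_q_positive():
    params = HSParameters(5.0, 1.0)
    with pytest.raises(ValueError):
        interference_gap_density(0.5, params)
    with pytest.raises(ValueError):
        first_gap_cdf(0.5, params)


def test_negative_argument_rejected():
    params = HSParameters(5.0, 0.1)
    with pytest.raises(ValueError):
        interference_gap_cdf(-0.1, params)
    # positions outside [0, L] rejected at construction
    with pytest.raises(ValueError):
        IntervalData((1.5,), 1.0)


def test_zero_crossover_meiosis_is_poisson_void_at_nu1():
    """nu=1 makes the whole process unit-rate Poisson: log P(0 events) = -L."""
    for L in (0.3, 0.8, 1.7):
        for p in (0.0, 0.3, 0.7, 1.0):
            assert meiosis_loglik(
                IntervalData((), L), HSParameters(1.0, p)
            ) == pytest.approx(-L, abs=1e-8)


def test_single_crossover_pure_interference_collapses():
    params = HSParameters(7.0, 0.0)
    y, L = 0.3, 1.0
    expected = math.log(g_star_ref(y, 7.0, 1.0)) + math.log(
        1.0 - F_star_ref(L - y, 7.0, 1.0)
    )
    assert meiosis_loglik(IntervalData((y,), L), params) == pytest.approx(
        expected, rel=1e-9
    )


def test_loglik_matches_bruteforce_enumeration():
    """Vectorized subset-sum equals independent enumeration, 1e-10 relative."""
    rng = np.random.default_rng(1234)
    for _ in range(200):
        n = int(rng.integers(0, 4))
        L = float(rng.uniform(0.5, 1.5))
        pos = tuple(np.sort(rng.uniform(0.0, L, size=n)))
        nu = float(rng.uniform(0.8, 15.0))
        p = float(rng.uniform(0.0, 0.3))
        ours = meiosis_loglik(IntervalData(pos, L), HSParameters(nu, p))
        ref = hs_loglik_ref(pos, L, nu, p)
        assert ours == pytest.approx(ref, rel=1e-10)


def test_dataset_loglik_additive_and_p_invariant_at_nu1():
    data = [IntervalData((0.2, 0.7), 1.0), IntervalData((), 0.8)]
    params = HSParameters(9.0, 0.08)
    single = sum(meiosis_loglik(d, params) for d in data)
    assert dataset_loglik(data, params) == pytest.approx(single, rel=1e-12)
    assert dataset_loglik(data + data, params) == pytest.approx(2 * single, rel=1e-12)
    # nu=1: the mixture is unit-rate Poisson regardless of the (p, q) split
    base = dataset_loglik(data, HSParameters(1.0, 0.0))
    for p in (0.3, 0.7, 1.0):
        assert dataset_loglik(data, HSParameters(1.0, p)) == pytest.approx(
            base, abs=1e-8
        )


def test_likelihood_dominance_at_truth():
    """Truth parameters beat misspecified ones on a large simulated sample."""
    from xoinfer.simulate import simulate_crossover_positions

    rng = np.random.default_rng(55)
    truth = HSParameters(10.0, 0.05)
    _, pos, _ = simulate_crossover_positions(truth, 1.0, 10_000, rng)
    compiled = CompiledDataset([IntervalData(tuple(x), 1.0) for x in pos])
    at_truth = compiled.loglik(truth)
    assert at_truth > compiled.loglik(HSParameters(5.0, 0.05))
    assert at_truth > compiled.loglik(HSParameters(10.0, 0.3))


def test_crossover_count_guard():
    with pytest.raises(ValueError):
        CompiledDataset([IntervalData(tuple(np.linspace(0.01, 0.99, 13)), 1.0)])
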