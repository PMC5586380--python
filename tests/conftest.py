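import numpy as np
import pytest

from rholandscape import RhoMap


@pytest.fixture
def simple_map() -> RhoMap:
    """Two intervals: 100 bp at 0.01, 300 bp at 0.001 (weighted mean 0.00325)."""
    return RhoMap("chr1", [100, 200, 500], [0.01, 0.001])


def per_base_mean(rho_map: RhoMap, lo: float, hi: float) -> float:
    """Brute-force per-base average rate over [lo, hi) — enumeration oracle."""
    total = 0.0
    weight = 0.0
    for left, right, rate in zip(
        rho_map.positions[:-1], rho_map.positions[1:], rho_map.rates
    ):
        for base in range(int(left), int(right)):
            if lo <= base < hi:
                total += rate
                weight += 1.0
    if weight == 0:
        raise ValueError("empty region")
    return total / weight


def random_rho_map(rng: np.random.Generator, n_snps: int = 12) -> RhoMap:
    positions = np.cumsum(rng.integers(1, 50, size=n_snps)) + 1
    rates = rng.gamma(1.0, 0.01, size=n_snps - 1)
    return RhoMap("chrT", positions, rates)
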