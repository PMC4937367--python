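"""Shared fixtures and independent oracles for the test suite."""

from decimal import Decimal, getcontext

import numpy as np
import pytest

from cer import EventSeries


def poisson_cdf_oracle(k: int, lam: float) -> float:
    """Direct term-by-term Poisson CDF in 60-digit decimal arithmetic.

    Independent of the package's implementation: sums
    exp(-lam) * lam^i / i! for i = 0..k exactly as written.
    """
    getcontext().prec = 60
    lam_d = Decimal(str(lam))
    term = (-lam_d).exp()
    total = term
    for i in range(1, k + 1):
        term = term * lam_d / i
        total += term
    return float(total)


def count_er_oracle(x: np.ndarray, y: np.ndarray, tau: int) -> int:
    """Brute-force enumeration of lagged coincidences."""
    return sum(
        1 for t in range(tau, len(x)) if x[t] == 1 and y[t - tau] == 1
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20160708)


@pytest.fixture
def random_pair(rng):
    """Two independent stationary channels at event probability 0.3."""
    def make(n=5000, p=0.3):
        return (
            EventSeries((rng.random(n) < p).astype(int), label="A"),
            EventSeries((rng.random(n) < p).astype(int), label="B"),
        )

    return make
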