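"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own numerics: the
noncentral-hypergeometric oracle enumerates the support with exact integer
binomial coefficients (and exact powers of 2 when the odds ratio is a power
of 2), and the NPMLE oracle is a zooming exhaustive search over the mixing
simplex. They exist so the EM / log-space implementations are checked against
arithmetic that cannot share their bugs.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest

from trialref import ContingencyTable


def log_bigint(n: int) -> float:
    """Natural log of a (possibly huge) positive integer without overflow."""
    if n <= 0:
        raise ValueError("positive integer required")
    shift = max(n.bit_length() - 53, 0)
    return math.log(n >> shift) + shift * math.log(2.0)


def log_fraction(f: Fraction) -> float:
    return log_bigint(f.numerator) - log_bigint(f.denominator)


def oracle_log_likelihood(table: ContingencyTable, omega: float) -> float:
    """Brute-force noncentral hypergeometric log pmf via direct summation.

    Exact rational arithmetic when e^omega is an exact power of two
    (omega = k*log 2), otherwise float summation with exact integer binomials
    — adequate for the small tables used in oracle tests.
    """
    n_a, n_b, m, x_a = table.n_a, table.n_b, table.m, table.x_a
    lo, hi = max(0, m - n_b), min(n_a, m)
    ratio = omega / math.log(2.0)
    if abs(ratio - round(ratio)) < 1e-12:
        k = int(round(ratio))
        theta = Fraction(2) ** k
        num = math.comb(n_a, x_a) * math.comb(n_b, m - x_a) * theta**x_a
        den = sum(
            math.comb(n_a, t) * math.comb(n_b, m - t) * theta**t
            for t in range(lo, hi + 1)
        )
        return log_fraction(Fraction(num, den))
    num = math.comb(n_a, x_a) * math.comb(n_b, m - x_a) * math.exp(omega * x_a)
    den = sum(
        math.comb(n_a, t) * math.comb(n_b, m - t) * math.exp(omega * t)
        for t in range(lo, hi + 1)
    )
    return math.log(num) - math.log(den)


def oracle_simplex_search(kernels: np.ndarray, rounds: int = 7) -> float:
    """Max of sum_i log(K_i . v) over the 3-point simplex by zooming grid search.

    ``kernels`` has 3 columns. Independent of the EM solver: plain evaluation
    over a refined lattice of (v0, v1) with v2 = 1 - v0 - v1.
    """
    assert kernels.shape[1] == 3

    def objective(v0: float, v1: float) -> float:
        v2 = 1.0 - v0 - v1
        if v0 < 0 or v1 < 0 or v2 < -1e-15:
            return -math.inf
        mix = kernels @ np.array([v0, v1, max(v2, 0.0)])
        if np.any(mix <= 0):
            return -math.inf
        return float(np.log(mix).sum())

    best = (1 / 3, 1 / 3)
    width, step = 1.0, 0.02
    best_val = objective(*best)
    for _ in range(rounds):
        g0 = np.arange(max(0.0, best[0] - width / 2), min(1.0, best[0] + width / 2) + step, step)
        g1 = np.arange(max(0.0, best[1] - width / 2), min(1.0, best[1] + width / 2) + step, step)
        for v0 in g0:
            for v1 in g1:
                val = objective(v0, v1)
                if val > best_val:
                    best_val, best = val, (v0, v1)
        width, step = 4 * step, step / 10
    return best_val


def random_table(rng: np.random.Generator, max_n: int = 150) -> ContingencyTable:
    n_a = int(rng.integers(1, max_n + 1))
    n_b = int(rng.integers(1, max_n + 1))
    x_a = int(rng.integers(0, n_a + 1))
    x_b = int(rng.integers(0, n_b + 1))
    return ContingencyTable(x_a=x_a, y_a=n_a - x_a, x_b=x_b, y_b=n_b - x_b)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
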