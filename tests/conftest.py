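"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's dynamic programs: they
enumerate structures exhaustively (folding, duplexes), sum binomial terms
with exact rational arithmetic (count test), or re-check stated rules
literally (degradome categories), and are only feasible at small sizes.
"""

from __future__ import annotations

import functools
import random
from fractions import Fraction
from math import comb

import pytest

from stagemir import folding as F


# --------------------------------------------------------------------------
# exhaustive single-strand structure enumeration
# --------------------------------------------------------------------------

def enumerate_structures(seq: str):
    """All nested pair sets over ``seq`` (min hairpin loop enforced)."""
    codes = F.encode(seq)
    n = len(codes)

    def pairable(i, j):
        return j - i - 1 >= F.MIN_HAIRPIN and \
            F.pair_index(int(codes[i]), int(codes[j])) >= 0

    @functools.lru_cache(maxsize=None)
    def structs(lo, hi):
        if hi - lo < F.MIN_HAIRPIN + 2:
            return [()]
        out = list(structs(lo + 1, hi))
        for j in range(lo + F.MIN_HAIRPIN + 1, hi):
            if pairable(lo, j):
                for a in structs(lo + 1, j):
                    for b in structs(j + 1, hi):
                        out.append(((lo, j),) + a + b)
        return out

    return structs(0, n)


def brute_force_mfe(seq: str) -> float:
    best = 0.0
    for s in enumerate_structures(seq):
        if s:
            best = min(best, F.structure_energy(seq, list(s)))
    return best


# --------------------------------------------------------------------------
# exhaustive duplex enumeration
# --------------------------------------------------------------------------

def brute_force_duplex(x: str, y: str) -> float:
    n, m = len(x), len(y)
    best = 0.0

    def rec(pairs, i0, j1):
        nonlocal best
        try:
            e = F.duplex_structure_energy(x, y, pairs)
        except ValueError:
            return
        best = min(best, e)
        for i in range(i0, n):
            for j in range(0, j1):
                rec(pairs + [(i, j)], i + 1, j)

    rec([], 0, m)
    return best


# --------------------------------------------------------------------------
# exact-rational conditional binomial oracle
# --------------------------------------------------------------------------

def exact_test_oracle(count_a: int, total_a: int, count_b: int, total_b: int) -> float:
    """Direct summation with exact rational arithmetic."""
    n = count_a + count_b
    if n == 0:
        return 1.0
    p = Fraction(total_a, total_a + total_b)
    q = 1 - p
    pmf = [comb(n, k) * p**k * q**(n - k) for k in range(n + 1)]
    obs = pmf[count_a]
    return float(min(Fraction(1), sum(v for v in pmf if v <= obs)))


# --------------------------------------------------------------------------
# literal re-check of the degradome category rules
# --------------------------------------------------------------------------

def category_oracle(abundances: dict[int, int], position: int) -> int:
    """The five stated rules, checked one by one in order."""
    a = abundances[position]
    occupied = sorted(abundances.values())
    if a == 1:
        return 4
    maximum = max(occupied)
    n_at_max = sum(1 for v in occupied if v == maximum)
    k = len(occupied)
    if k % 2 == 1:
        median = occupied[k // 2]
    else:
        median = (occupied[k // 2 - 1] + occupied[k // 2]) / 2
    if a == maximum and maximum > 1 and n_at_max == 1:
        return 0
    if a == maximum and maximum > 1:
        return 1
    if a > median:
        return 2
    return 3


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------

@pytest.fixture(scope="session")
def fixture_tables():
    from stagemir.pipeline import load_fixtures
    return load_fixtures()


@pytest.fixture
def rng():
    return random.Random(20260928)


@pytest.fixture(scope="session")
def small_simulation():
    """A reduced, seeded simulation shared by fast tests."""
    from stagemir import synthetic_data as syn
    cfg = syn.SimulationConfig(seed=11, read_depth=100_000,
                               n_known_mirnas=12, n_novel_loci=2,
                               n_pirna_species=50, contig_length=6000)
    genome, loci, truth = syn.simulate_genome(cfg)
    libs = syn.simulate_stage_libraries(cfg, genome, truth)
    return cfg, genome, loci, truth, libs
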