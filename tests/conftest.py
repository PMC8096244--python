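"""Shared fixtures: hand-built octads and independent statistical oracles."""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pytest

from meiorec.simulate import P1, P2, MarkerMap, OctadGenotypes


def build_octad(calls, positions=None, chrom_length=None) -> OctadGenotypes:
    """Construct an octad from an 8 x M matrix of {0, 1, -1} codes."""
    calls = np.asarray(calls, dtype=np.int8)
    m = calls.shape[1]
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    positions = np.asarray(positions, dtype=np.int64)
    if chrom_length is None:
        chrom_length = int(positions[-1]) + 100
    marker_map = MarkerMap(
        "chrI", positions, np.full(m, "A"), np.full(m, "C"), chrom_length
    )
    return OctadGenotypes(marker_map, calls)


def mendelian_octad(m: int, positions=None) -> OctadGenotypes:
    """An octad with 4:4 segregation at every marker (no events)."""
    calls = np.empty((8, m), dtype=np.int8)
    calls[0:4] = P1
    calls[4:8] = P2
    return build_octad(calls, positions)


def mann_whitney_enumeration(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumeration over all labelings.

    Valid for untied samples.  p = 2 * min(P(U <= u), P(U >= u)), capped at 1.
    """
    x = list(x)
    y = list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "enumeration oracle requires no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1, n = len(x), len(pooled)
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    us = [
        sum(rs) - n1 * (n1 + 1) / 2
        for rs in combinations(range(1, n + 1), n1)
    ]
    total = len(us)
    p_le = sum(u <= u_obs for u in us) / total
    p_ge = sum(u >= u_obs for u in us) / total
    return float(u_obs), min(1.0, 2 * min(p_le, p_ge))


def fisher_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by summing hypergeometric outcome probabilities
    no larger than the observed one (integer-exact via binomial coefficients)."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0
    denom = comb(n, c1)
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    # integer numerators avoid float comparisons of tied probabilities
    num_obs = comb(r1, a) * comb(n - r1, c1 - a)
    acc = sum(
        comb(r1, x) * comb(n - r1, c1 - x)
        for x in range(lo, hi + 1)
        if comb(r1, x) * comb(n - r1, c1 - x) <= num_obs
    )
    return acc / denom


def bh_step_up(pvals):
    """Hand step-up BH adjustment: adj_i = min_{j>=rank(i)} p_(j) * n / j."""
    p = list(pvals)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
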