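"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from breakscape.genome import GenomeSpec
from breakscape.simulate import SimConfig


@pytest.fixture
def small_genome() -> GenomeSpec:
    return GenomeSpec(chromosomes=(("chr1", 1_000_000),
                                   ("chr2", 500_000)))


@pytest.fixture
def sim_config() -> SimConfig:
    return SimConfig(seed=7)


# ---------------------------------------------------------------------
# Brute-force oracles (kept deliberately naive and independent of the
# library's own interval/statistics code paths)
# ---------------------------------------------------------------------

def perbase_consensus_oracle(replicate_sets, min_width, universe=10_000):
    """Per-base indicator intersection over a small coordinate universe."""
    chroms = {c for s in replicate_sets for c, _, _ in s}
    out = []
    for chrom in sorted(chroms):
        cover = np.ones(universe, dtype=bool)
        for s in replicate_sets:
            mask = np.zeros(universe, dtype=bool)
            for c, a, b in s:
                if c == chrom:
                    mask[a:b] = True
            cover &= mask
        # extract runs
        padded = np.concatenate([[False], cover, [False]])
        diff = np.diff(padded.astype(int))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        for a, b in zip(starts, ends):
            if b - a >= min_width:
                out.append((chrom, int(a), int(b)))
    return out


def quadratic_overlap_oracle(dsbs, breakpoints, window=0):
    """Every (dsb, junction end) pair, by exhaustive scan."""
    hits = []
    for bp in breakpoints:
        for idx, end in enumerate((bp.end1, bp.end2), start=1):
            for (c, s, e) in dsbs:
                if end.chrom == c and s - window <= end.pos < e + window:
                    hits.append(((c, s, e), bp.source_id, idx))
    return sorted(hits)


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive enumeration with exact rationals."""
    from fractions import Fraction
    from math import comb

    n = a + b + c + d
    K, N = a + c, a + b
    denom = comb(n, N)
    probs = {}
    for x in range(max(0, N - (n - K)), min(N, K) + 1):
        probs[x] = Fraction(comb(K, x) * comb(n - K, N - x), denom)
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))
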