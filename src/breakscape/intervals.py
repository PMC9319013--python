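"""Interval set algebra: replicate consensus, cross-line partitioning,
and per-chromosome DSB density.

"Identified in every replicate" is operationalized as the per-base
intersection of the replicate indicator functions - order-independent
and brute-force checkable. Intervals are (chrom, start, end), 0-based
half-open, kept sorted and non-overlapping within a set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeSpec

Interval = tuple[str, int, int]


def merge_intervals(intervals: list[Interval]) -> list[Interval]:
    """Sort and merge touching/overlapping intervals."""
    out: list[Interval] = []
    for c, s, e in sorted(intervals):
        if out and out[-1][0] == c and s <= out[-1][2]:
            out[-1] = (c, out[-1][1], max(out[-1][2], e))
        else:
            out.append((c, s, e))
    return out


def _intersect_two(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Intersection of two sorted non-overlapping interval lists."""
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        ca, sa, ea = a[i]
        cb, sb, eb = b[j]
        if ca < cb:
            i += 1
            continue
        if cb < ca:
            j += 1
            continue
        s, e = max(sa, sb), min(ea, eb)
        if s < e:
            out.append((ca, s, e))
        if ea <= eb:
            i += 1
        else:
            j += 1
    return out


@dataclass
class ConsensusSet:
    """Per-base every-replicate consensus intervals for one cell line."""

    line_label: str
    consensus_peaks: list[Interval]
    provenance: list[list[list[int]]] = field(default_factory=list)
    # provenance[k][r] = indices of replicate r's peaks overlapping
    # consensus interval k

    def __len__(self) -> int:
        return len(self.consensus_peaks)


@dataclass
class SetPartition:
    common: list[Interval]
    a_specific: list[Interval]
    b_common: list[Interval]
    b_specific: list[Interval]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "common": len(self.common),
            "a_specific": len(self.a_specific),
            "b_common": len(self.b_common),
            "b_specific": len(self.b_specific),
        }


def consensus(replicate_peak_sets: list[list[Interval]],
              min_width: int = 50, line_label: str = "") -> ConsensusSet:
    """Regions covered by every replicate, merged, filtered by width.

    Each replicate set must be sorted and non-overlapping. Raises on an
    empty replicate list (a consensus of nothing is undefined).
    """
    if not replicate_peak_sets:
        raise ValueError("at least one replicate peak set is required")
    sets = [merge_intervals(list(s)) for s in replicate_peak_sets]
    inter = sets[0]
    for s in sets[1:]:
        inter = _intersect_two(inter, s)
    inter = merge_intervals(inter)
    peaks = [(c, s, e) for c, s, e in inter if e - s >= min_width]
    provenance = [
        [
            [i for i, (rc, rs, re) in enumerate(rep)
             if rc == c and rs < e and s < re]
            for rep in sets
        ]
        for c, s, e in peaks
    ]
    return ConsensusSet(line_label=line_label, consensus_peaks=peaks,
                        provenance=provenance)


def _overlaps_any(iv: Interval, others: list[Interval],
                  min_overlap: int) -> bool:
    c, s, e = iv
    for oc, os, oe in others:
        if oc == c and min(e, oe) - max(s, os) >= min_overlap:
            return True
    return False


def partition(a: ConsensusSet, b: ConsensusSet,
              min_overlap: int = 1) -> SetPartition:
    """Common/specific split of two consensus sets.

    An interval of A is "common" iff it overlaps at least ``min_overlap``
    bp of some interval of B; symmetric for B. Counts satisfy
    |common| + |a_specific| = |consensus(A)| exactly.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    a_common, a_spec, b_common, b_spec = [], [], [], []
    for iv in a.consensus_peaks:
        (a_common if _overlaps_any(iv, b.consensus_peaks, min_overlap)
         else a_spec).append(iv)
    for iv in b.consensus_peaks:
        (b_common if _overlaps_any(iv, a.consensus_peaks, min_overlap)
         else b_spec).append(iv)
    return SetPartition(common=a_common, a_specific=a_spec,
                        b_common=b_common, b_specific=b_spec)


def density_per_chromosome(peaks: list[Interval],
                           genome: GenomeSpec) -> pd.DataFrame:
    """Peak count and count per Mb for each chromosome (2 decimals)."""
    rows = []
    for chrom, length in genome.chromosomes:
        n = sum(1 for c, _, _ in peaks if c == chrom)
        rows.append({
            "chrom": chrom,
            "count": n,
            "per_mb": round(n / (length / 1e6), 2),
        })
    return pd.DataFrame(rows)


# -- BED I/O ----------------------------------------------------------

def read_bed(path) -> list[Interval]:
    out: list[Interval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return sorted(out)


def write_bed(intervals: list[Interval], path) -> None:
    with open(path, "w") as fh:
        for c, s, e in intervals:
            fh.write(f"{c}\t{s}\t{e}\n")
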