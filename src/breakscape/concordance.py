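"""DSB x structural-variant / CNV-boundary concordance.

Intersects recurrent DSB intervals with SV junction ends and CNV
boundaries, reports per-region hit counts ("k of n intra junctions"),
and calibrates expectation with a within-chromosome permutation null.
Counting is per junction END (a DSB overlapping both ends of one event
contributes one hit per end).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import Interval, merge_intervals
from .simulate import substream
from .sv import PairedBreakpoint


@dataclass(frozen=True)
class OverlapHit:
    dsb: Interval
    chrom: str
    pos: int
    end_index: int      # 1 or 2
    source_id: str
    svclass: str


def dsb_sv_overlap(dsbs: list[Interval],
                   breakpoints: list[PairedBreakpoint],
                   window: int = 0) -> list[OverlapHit]:
    """All (DSB, junction end) pairs where the end's coordinate lies in
    ``[start - window, end + window)`` of the DSB."""
    hits: list[OverlapHit] = []
    for bp in breakpoints:
        for idx, end in enumerate(bp.ends, start=1):
            for dsb in dsbs:
                c, s, e = dsb
                if end.chrom == c and s - window <= end.pos < e + window:
                    hits.append(OverlapHit(
                        dsb=dsb, chrom=end.chrom, pos=end.pos,
                        end_index=idx, source_id=bp.source_id,
                        svclass=bp.svclass))
    return hits


def dsb_cnv_overlap(dsbs: list[Interval],
                    cnv_boundaries: list[tuple[str, int]],
                    window: int = 15_000) -> list[tuple[Interval, str, int]]:
    """DSBs hitting CNV boundaries within +-window bp (default one CNV
    bin: boundary positions are only bin-resolved)."""
    hits = []
    for chrom, pos in cnv_boundaries:
        for dsb in dsbs:
            c, s, e = dsb
            if chrom == c and s - window <= pos < e + window:
                hits.append((dsb, chrom, pos))
    return hits


def region_report(hits: list[OverlapHit], region: Interval,
                  all_breakpoints: list[PairedBreakpoint]) -> dict:
    """"k of n intra junctions and j of m inter junctions in region".

    n/m count junction ENDS of each class whose coordinate falls in the
    region; k/j count those ends that a DSB also hits.
    """
    rc, rs, re = region

    def in_region(chrom, pos):
        return chrom == rc and rs <= pos < re

    n = m = 0
    region_ends = set()
    for bp in all_breakpoints:
        for idx, end in enumerate(bp.ends, start=1):
            if in_region(end.chrom, end.pos):
                region_ends.add((bp.source_id, idx))
                if bp.svclass == "intra":
                    n += 1
                else:
                    m += 1
    hit_ends = {(h.source_id, h.end_index): h.svclass for h in hits
                if (h.source_id, h.end_index) in region_ends}
    k = sum(1 for v in hit_ends.values() if v == "intra")
    j = sum(1 for v in hit_ends.values() if v == "inter")
    return {
        "region": {"chrom": rc, "start": rs, "end": re},
        "intra_hit": k, "intra_total": n,
        "inter_hit": j, "inter_total": m,
        "summary": f"{k} of {n} intra junctions and {j} of {m} "
                   f"inter junctions in region",
    }


def _count_end_hits(dsbs_by_chrom: dict[str, np.ndarray],
                    ends: list[tuple[str, int]], window: int) -> int:
    """Number of junction ends falling inside any (extended) DSB."""
    count = 0
    for chrom, pos in ends:
        ivs = dsbs_by_chrom.get(chrom)
        if ivs is None or ivs.size == 0:
            continue
        # ivs is an (n, 2) array of [start - window, end + window)
        i = np.searchsorted(ivs[:, 0], pos, side="right") - 1
        if i >= 0 and pos < ivs[i, 1]:
            count += 1
        elif i + 1 < len(ivs) and ivs[i + 1, 0] <= pos < ivs[i + 1, 1]:
            count += 1
    return count


def permutation_null(dsbs: list[Interval],
                     breakpoints: list[PairedBreakpoint],
                     genome, n_perm: int = 1000, seed: int = 0,
                     window: int = 0) -> dict:
    """Permutation calibration of the DSB-SV end overlap count.

    Each permutation redraws DSB start positions uniformly within their
    own chromosome, preserving interval lengths and non-overlap
    (collisions rejection-resampled). The empirical p uses the add-one
    rule ``(1 + #{null >= observed}) / (n_perm + 1)`` and is therefore
    never zero.
    """
    ends = [(e.chrom, e.pos) for bp in breakpoints for e in bp.ends]
    observed = _count_end_hits(_index_dsbs(dsbs, window), ends, window)
    if not ends:
        return {"observed": 0, "null_mean": 0.0, "p": 1.0, "n_perm": n_perm}

    rng = substream(seed, "permutation")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in dsbs:
        by_chrom.setdefault(c, []).append((s, e))
    chrom_len = {name: length for name, length in genome.chromosomes}

    null_counts = np.empty(n_perm, dtype=np.int64)
    for it in range(n_perm):
        shuffled: list[Interval] = []
        for chrom, ivs in by_chrom.items():
            L = chrom_len[chrom]
            placed: list[tuple[int, int]] = []
            # longest first reduces rejection churn
            for s, e in sorted(ivs, key=lambda iv: iv[0] - iv[1]):
                w = e - s
                if w >= L:
                    placed.append((0, L))
                    continue
                for _ in range(10_000):
                    ns = int(rng.integers(0, L - w + 1))
                    ne = ns + w
                    if not any(ns < pe and ps < ne for ps, pe in placed):
                        placed.append((ns, ne))
                        break
                else:
                    raise RuntimeError(
                        f"could not place shuffled DSBs on {chrom}")
            shuffled.extend((chrom, s, e) for s, e in placed)
        null_counts[it] = _count_end_hits(
            _index_dsbs(shuffled, window), ends, window)
    p = (1 + int(np.sum(null_counts >= observed))) / (n_perm + 1)
    return {
        "observed": int(observed),
        "null_mean": float(null_counts.mean()),
        "p": float(p),
        "n_perm": n_perm,
    }


def _index_dsbs(dsbs: list[Interval], window: int
                ) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in merge_intervals(list(dsbs)):
        by_chrom.setdefault(c, []).append((s - window, e + window))
    return {c: np.array(sorted(ivs), dtype=np.int64).reshape(-1, 2)
            for c, ivs in by_chrom.items()}
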