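"""Copy-number profiling from binned read counts.

Log2 ratios against the genome-wide median, optional GC correction,
recursive binary segmentation with a two-sample t-statistic stopping
rule, gain/loss calls, and CNV-boundary extraction. Deterministic by
construction; ties in the split scan break toward the leftmost
maximizing position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

AUTOSOME_EXEMPT = ("chrX", "chrY", "X", "Y")


@dataclass(frozen=True)
class CnvSegment:
    chrom: str
    start_bin: int      # half-open in bin units
    end_bin: int
    start_bp: int
    end_bp: int
    mean_log2: float
    n_bins: int
    call: str = "neutral"
    is_autosome: bool = True


def bin_and_log2(counts: np.ndarray, pseudo: float = 0.5,
                 gc: np.ndarray | None = None,
                 median: float | None = None) -> np.ndarray:
    """Per-bin log2 ratio against the (genome-wide) median count.

    ``ratio[i] = log2((count[i] + pseudo) / (median + pseudo))``. When a
    per-bin GC fraction is supplied, counts are first flattened against
    the GC trend with a running-median correction; otherwise GC
    correction is skipped with a log message.
    """
    counts = np.asarray(counts, dtype=float)
    if gc is not None:
        counts = _gc_correct(counts, np.asarray(gc, dtype=float))
    else:
        log.info("no per-bin GC provided: skipping GC correction")
    med = float(np.median(counts)) if median is None else median
    return np.log2((counts + pseudo) / (med + pseudo))


def _gc_correct(counts: np.ndarray, gc: np.ndarray,
                n_windows: int = 25) -> np.ndarray:
    """Divide out the count-vs-GC trend (running median over GC order)."""
    order = np.argsort(gc, kind="stable")
    sorted_counts = counts[order]
    win = max(5, len(counts) // n_windows) | 1
    trend = pd.Series(sorted_counts).rolling(
        win, center=True, min_periods=1).median().to_numpy()
    overall = float(np.median(counts))
    factor = np.empty_like(counts)
    factor[order] = np.maximum(trend, 1e-9) / max(overall, 1e-9)
    return counts / factor


def _t_statistics(x: np.ndarray) -> np.ndarray:
    """Two-sample equal-variance t at every internal split of x.

    Returns |t| for splits 1..n-1 (left = x[:k], right = x[k:]).
    """
    n = len(x)
    k = np.arange(1, n)
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    sum_l, sum_r = csum[:-1], csum[-1] - csum[:-1]
    sq_l, sq_r = csq[:-1], csq[-1] - csq[:-1]
    n_l, n_r = k, n - k
    mean_l, mean_r = sum_l / n_l, sum_r / n_r
    ss_l = sq_l - n_l * mean_l ** 2
    ss_r = sq_r - n_r * mean_r ** 2
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled = np.sqrt(np.maximum(ss_l + ss_r, 0) / max(df, 1))
        se = pooled * np.sqrt(1.0 / n_l + 1.0 / n_r)
        t = np.abs(mean_l - mean_r) / se
    # zero pooled variance with distinct means: infinitely strong split
    t = np.where((se == 0) & (mean_l != mean_r), np.inf, t)
    t = np.where((se == 0) & (mean_l == mean_r), 0.0, t)
    return t


def _segment_recursive(x: np.ndarray, offset: int, t_threshold: float,
                       min_seg_bins: int, bounds: list[int]) -> None:
    n = len(x)
    if n < 2 * min_seg_bins:
        return
    t = _t_statistics(x)
    # admissible splits keep both sides >= min_seg_bins
    k = np.arange(1, n)
    admissible = (k >= min_seg_bins) & (n - k >= min_seg_bins)
    if not admissible.any():
        return
    t_adm = np.where(admissible, t, -np.inf)
    best = int(np.argmax(t_adm))      # argmax takes leftmost maximum
    if not np.isfinite(t_adm[best]) and t_adm[best] < 0:
        return
    if t_adm[best] < t_threshold:
        return
    split = best + 1
    _segment_recursive(x[:split], offset, t_threshold, min_seg_bins, bounds)
    bounds.append(offset + split)
    _segment_recursive(x[split:], offset + split, t_threshold,
                       min_seg_bins, bounds)


def segment(log2_ratios: np.ndarray, chrom: str = "chr?",
            bin_size: int = 15_000, t_threshold: float = 5.0,
            min_seg_bins: int = 5, merge_delta: float = 0.1,
            chrom_length: int | None = None) -> list[CnvSegment]:
    """Recursive binary segmentation of one chromosome's log2 ratios.

    At each recursion the split maximizing the two-sample t-statistic
    between left and right means is accepted iff |t| >= ``t_threshold``
    and both sides hold at least ``min_seg_bins`` bins; adjacent
    segments closer than ``merge_delta`` in mean are then merged.
    Chromosomes shorter than ``2 * min_seg_bins`` yield one segment with
    a warning.
    """
    x = np.asarray(log2_ratios, dtype=float)
    n = len(x)
    if n == 0:
        return []
    if n < 2 * min_seg_bins:
        log.warning("%s has %d bins < 2*min_seg_bins: single segment",
                    chrom, n)
        bounds: list[int] = []
    else:
        bounds = []
        _segment_recursive(x, 0, t_threshold, min_seg_bins, bounds)
        bounds.sort()
    edges = [0] + bounds + [n]

    # merge adjacent segments with |delta mean| < merge_delta
    merged_edges = [0]
    for i in range(1, len(edges) - 1):
        left = x[merged_edges[-1]:edges[i]]
        right = x[edges[i]:edges[i + 1]]
        if abs(left.mean() - right.mean()) < merge_delta:
            continue
        merged_edges.append(edges[i])
    merged_edges.append(n)

    segs = []
    for s, e in zip(merged_edges[:-1], merged_edges[1:]):
        start_bp = s * bin_size
        end_bp = e * bin_size
        if chrom_length is not None:
            end_bp = min(end_bp, chrom_length)
        segs.append(CnvSegment(
            chrom=chrom, start_bin=s, end_bin=e,
            start_bp=start_bp, end_bp=end_bp,
            mean_log2=float(x[s:e].mean()), n_bins=e - s,
            is_autosome=chrom not in AUTOSOME_EXEMPT,
        ))
    return segs


def call_segments(segments: list[CnvSegment], loss_max: float = -0.3,
                  gain_min: float = 0.3) -> list[CnvSegment]:
    """Label each segment loss / neutral / gain by its mean log2 ratio."""
    out = []
    for seg in segments:
        if seg.mean_log2 <= loss_max:
            call = "loss"
        elif seg.mean_log2 >= gain_min:
            call = "gain"
        else:
            call = "neutral"
        out.append(replace(seg, call=call))
    return out


def boundaries(segments: list[CnvSegment],
               min_delta: float = 0.3) -> list[tuple[str, int]]:
    """CNV breakpoints: bp positions between adjacent same-chromosome
    segments that differ in call or by at least ``min_delta`` in mean."""
    out: list[tuple[str, int]] = []
    by_chrom: dict[str, list[CnvSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start_bin)
        for left, right in zip(segs[:-1], segs[1:]):
            if (left.call != right.call
                    or abs(left.mean_log2 - right.mean_log2) >= min_delta):
                out.append((chrom, right.start_bp))
    return out


def segments_to_table(segments: list[CnvSegment],
                      sample: str = "sample") -> pd.DataFrame:
    """SEG-style table."""
    return pd.DataFrame([{
        "sample": sample, "chrom": s.chrom, "start": s.start_bp,
        "end": s.end_bp, "n_bins": s.n_bins,
        "mean_log2": s.mean_log2, "call": s.call,
        "is_autosome": s.is_autosome,
    } for s in segments])
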