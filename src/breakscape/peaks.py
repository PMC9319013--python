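"""DSB peak calling from Break-seq coverage.

A transparent Poisson local-background caller: per-bin upper-tail
Poisson p-values against the maximum of the genome-wide mean rate and
two local flanking-window rates (5 kb and 10 kb, excluding the candidate
bin), Benjamini-Hochberg correction pooled genome-wide, then merging of
significant bins into peaks. Break-seq counts are first divided by a
smoothed DNA-seq copy-number ratio so that copy-number dosage does not
masquerade as breakage signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .tracks import CoverageTrack
from .stats import bh_fdr

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeakCall:
    chrom: str
    start: int
    end: int
    summit_bin: int
    score: float          # int(min(1000, 10 * -log10 q)) when exported
    pvalue: float
    qvalue: float
    normalized_signal_mean: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("peak end must exceed start")


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    """Centered running median with edge shrinkage."""
    if len(x) == 0:
        return x.astype(float)
    s = pd.Series(x)
    return s.rolling(window, center=True, min_periods=1).median().to_numpy()


def normalize_by_copy_number(break_track: CoverageTrack,
                             dna_track: CoverageTrack,
                             floor: float = 0.25,
                             smooth_bins: int = 51) -> CoverageTrack:
    """Divide Break-seq counts by the local DNA copy-number ratio.

    ``cn_ratio[i] = running_median(dna[i], 51 bins) / median(dna)``;
    normalized counts are ``break[i] / max(cn_ratio[i], floor)``. Totals
    are deliberately not conserved - normalization rescales dosage out
    of the signal.
    """
    if not break_track.same_binning(dna_track):
        raise ValueError("Break-seq and DNA-seq tracks have different binning")
    dna_all = dna_track.all_counts()
    if len(dna_all) == 0 or np.all(dna_all == 0):
        raise ValueError("DNA track is empty or all-zero")
    genome_median = float(np.median(dna_all))
    if genome_median <= 0:
        raise ValueError("DNA track genome-wide median is not positive")

    new_counts = {}
    for chrom in break_track.chroms:
        smoothed = _running_median(dna_track.counts[chrom], smooth_bins)
        cn_ratio = smoothed / genome_median
        new_counts[chrom] = break_track.counts[chrom] / np.maximum(cn_ratio, floor)
    return break_track.copy_with_counts(new_counts)


def _local_lambda(counts: np.ndarray, bin_size: int,
                  window_bp: int) -> np.ndarray:
    """Mean count over the flanking window on both sides of each bin,
    excluding the bin itself."""
    half = max(1, window_bp // bin_size // 2)
    csum = np.concatenate([[0.0], np.cumsum(counts)])
    n = len(counts)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    total = csum[hi] - csum[lo]
    width = hi - lo
    # exclude the candidate bin
    total = total - counts
    width = width - 1
    with np.errstate(invalid="ignore"):
        lam = np.where(width > 0, total / np.maximum(width, 1), np.nan)
    # single-bin chromosomes: fall back to the bin's own count
    return np.where(np.isnan(lam), counts, lam)


def call_peaks(track: CoverageTrack, q_max: float = 0.05,
               local_windows: tuple[int, int] = (5_000, 10_000),
               min_width_bins: int = 2, merge_gap: int = 500
               ) -> list[PeakCall]:
    """Call peaks against a Poisson local background.

    Per-bin ``p = P(X >= count)`` at ``lambda = max(genome mean, local
    flanking means)``; q-values by Benjamini-Hochberg pooled over all
    bins genome-wide; significant bins with gaps <= ``merge_gap`` bp are
    merged; peaks narrower than ``min_width_bins`` are discarded. The
    summit is the maximum-count bin.
    """
    all_counts = track.all_counts()
    if len(all_counts) == 0:
        log.warning("empty coverage track: no peaks to call")
        return []
    genome_mean = float(all_counts.mean())

    pvals_per_chrom = {}
    for chrom in track.chroms:
        counts = track.counts[chrom]
        lam = np.full(counts.shape, genome_mean)
        for w in local_windows:
            lam = np.maximum(lam, _local_lambda(counts, track.bin_size, w))
        # P(X >= c) with non-integer normalized counts: tail at ceil(c)
        k = np.ceil(counts).astype(np.int64)
        pvals_per_chrom[chrom] = poisson.sf(k - 1, np.maximum(lam, 1e-12))

    qvals = bh_fdr(np.concatenate([pvals_per_chrom[c] for c in track.chroms]))
    offsets = np.cumsum([0] + [len(track.counts[c]) for c in track.chroms])

    peaks: list[PeakCall] = []
    for ci, chrom in enumerate(track.chroms):
        q = qvals[offsets[ci]:offsets[ci + 1]]
        p = pvals_per_chrom[chrom]
        counts = track.counts[chrom]
        starts, ends = track.starts[chrom], track.ends[chrom]
        sig = np.flatnonzero(q <= q_max)
        if sig.size == 0:
            continue
        # merge significant bins whose genomic gap is <= merge_gap
        runs: list[list[int]] = [[sig[0]]]
        for i in sig[1:]:
            prev = runs[-1][-1]
            if starts[i] - ends[prev] <= merge_gap:
                runs[-1].append(i)
            else:
                runs.append([i])
        for run in runs:
            bins = np.array(run)
            if len(bins) < min_width_bins:
                continue
            summit = int(bins[np.argmax(counts[bins])])
            best = int(bins[np.argmin(p[bins])])
            peaks.append(PeakCall(
                chrom=chrom,
                start=int(starts[bins[0]]),
                end=int(ends[bins[-1]]),
                summit_bin=summit,
                score=float(min(1000.0, 10.0 * -np.log10(max(q[best], 1e-300)))),
                pvalue=float(p[best]),
                qvalue=float(q[best]),
                normalized_signal_mean=float(counts[bins].mean()),
            ))
    return peaks


def peaks_to_bed(peaks: list[PeakCall], path) -> None:
    with open(path, "w") as fh:
        for i, pk in enumerate(peaks):
            fh.write(f"{pk.chrom}\t{pk.start}\t{pk.end}\tpeak_{i}\t"
                     f"{int(pk.score)}\t.\n")


def peaks_to_table(peaks: list[PeakCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": pk.chrom, "start": pk.start, "end": pk.end,
        "summit_bin": pk.summit_bin, "score": pk.score,
        "pvalue": pk.pvalue, "qvalue": pk.qvalue,
        "normalized_signal_mean": pk.normalized_signal_mean,
    } for pk in peaks])
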