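"""Parameter-recovery and calibration benchmarks on the synthetic
pipeline.

Each function generates its inputs from a seed, runs the corresponding
analysis stage, and measures recovery of the planted truth. These are
the quantitative checks behind the package's validation suite and the
reproduction script; problem sizes are chosen so the full battery runs
in minutes on one core.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import kstest

from . import cnv
from .concordance import permutation_null
from .genome import GenomeSpec, build_genome
from .intervals import merge_intervals
from .peaks import call_peaks
from .pipeline import aggregate_cnv_bins
from .simulate import (DELETION, SimConfig, TruthSet, default_genome,
                       simulate_coverage, simulate_expression,
                       simulate_survival_cohort, substream)
from .sv import make_breakpoint
from .survival import optimize_cutoff


# ---------------------------------------------------------------------
# DSB peak recovery and null calibration
# ---------------------------------------------------------------------

def peak_recovery(seed: int = 17, n_hotspots: int = 40,
                  hotspot_width: int = 400, genome_len: int = 2_000_000,
                  q_max: float = 0.05) -> dict:
    """Recall/precision of the peak caller against planted hotspots
    (fold 8 over background 5 per 100 bp bin)."""
    genome = GenomeSpec(chromosomes=(("chr1", genome_len),))
    cfg = SimConfig(seed=seed, background_rate=5.0, hotspot_fold=8.0)
    rng = substream(seed, "benchmark-hotspots")
    truth = TruthSet()
    truth.cnv_truth["B"] = [("chr1", 0, genome_len, 2.0)]
    placed: list[tuple[int, int]] = []
    while len(placed) < n_hotspots:
        s = int(rng.integers(0, genome_len - hotspot_width))
        e = s + hotspot_width
        if not any(s < pe + 1000 and ps - 1000 < e for ps, pe in placed):
            placed.append((s, e))
    truth.hotspots = [("chr1", s, e, "B", cfg.hotspot_fold)
                      for s, e in sorted(placed)]

    track = simulate_coverage(genome, truth, cfg, "B", 0)
    peaks = call_peaks(track, q_max=q_max)

    def overlaps(a, b):
        return a[0] < b[1] and b[0] < a[1]

    truth_ivs = [(s, e) for _, s, e, _, _ in truth.hotspots]
    peak_ivs = [(p.start, p.end) for p in peaks]
    recall = np.mean([any(overlaps(t, p) for p in peak_ivs)
                      for t in truth_ivs])
    precision = np.mean([any(overlaps(p, t) for t in truth_ivs)
                         for p in peak_ivs]) if peak_ivs else 0.0
    return {"recall": float(recall), "precision": float(precision),
            "n_hotspots": n_hotspots, "n_peaks": len(peaks)}


def null_false_positive_fraction(seed: int = 17, n_bins: int = 100_000,
                                 alpha: float = 0.05) -> dict:
    """Fraction of pure-Poisson bins with per-bin p <= alpha (must stay
    below alpha + 3 SE: the Poisson tail is super-uniform)."""
    from scipy.stats import poisson
    from .peaks import _local_lambda

    rng = substream(seed, "benchmark-null")
    counts = rng.poisson(5.0, size=n_bins).astype(float)
    lam = np.full(n_bins, counts.mean())
    for w in (5_000, 10_000):
        lam = np.maximum(lam, _local_lambda(counts, 100, w))
    p = poisson.sf(np.ceil(counts) - 1, lam)
    frac = float(np.mean(p <= alpha))
    return {"fraction": frac, "alpha": alpha, "n_bins": n_bins,
            "bound": alpha + 3 * float(np.sqrt(alpha * (1 - alpha) / n_bins))}


# ---------------------------------------------------------------------
# Consensus exactness
# ---------------------------------------------------------------------

def _perbase_oracle(sets, min_width, universe):
    cover = np.ones(universe, dtype=bool)
    for s in sets:
        mask = np.zeros(universe, dtype=bool)
        for _, a, b in s:
            mask[a:b] = True
        cover &= mask
    padded = np.concatenate([[False], cover, [False]])
    diff = np.diff(padded.astype(int))
    return [("chr1", int(a), int(b))
            for a, b in zip(np.flatnonzero(diff == 1),
                            np.flatnonzero(diff == -1))
            if b - a >= min_width]


def consensus_exactness(seed: int = 12, n_trials: int = 20,
                        n_intervals: int = 100) -> dict:
    """Sweep-based consensus vs the per-base indicator oracle on random
    100-interval replicate sets, plus the partition counting identity."""
    from .intervals import ConsensusSet, consensus, partition

    rng = substream(seed, "benchmark-consensus")
    universe = 200_000
    mismatches = 0
    arithmetic_violations = 0
    for _ in range(n_trials):
        sets = []
        for _ in range(4):
            starts = np.sort(rng.choice(universe - 1000, size=n_intervals,
                                        replace=False))
            sets.append(merge_intervals(
                [("chr1", int(s), int(s) + int(rng.integers(50, 900)))
                 for s in starts]))
        got = consensus(sets, min_width=50).consensus_peaks
        if got != _perbase_oracle(sets, 50, universe):
            mismatches += 1
        a = ConsensusSet("A", consensus(sets[:2], min_width=50).consensus_peaks)
        b = ConsensusSet("B", consensus(sets[2:], min_width=50).consensus_peaks)
        part = partition(a, b)
        if part.counts["common"] + part.counts["a_specific"] != \
                len(a.consensus_peaks):
            arithmetic_violations += 1
    return {"n_trials": n_trials, "oracle_mismatches": mismatches,
            "arithmetic_violations": arithmetic_violations}


# ---------------------------------------------------------------------
# CNV boundary recovery
# ---------------------------------------------------------------------

def cnv_boundary_recovery(n_seeds: int = 100, tol_bins: int = 2,
                          base_seed: int = 10_000) -> dict:
    """Fraction of seeds for which both edges of the planted one-arm
    deletion are localized within +-tol_bins coarse bins."""
    genome = default_genome()
    edges_bp = DELETION
    hits = 0
    for s in range(n_seeds):
        cfg = SimConfig(seed=base_seed + s)
        truth = TruthSet()
        truth.cnv_truth["B"] = [
            ("chr1", 0, genome.length_of("chr1"), 2.0),
            ("chr16A", 0, DELETION[0], 2.0),
            ("chr16A", DELETION[0], DELETION[1], 1.0),
            ("chr16A", DELETION[1], genome.length_of("chr16A"), 2.0),
        ]
        track = simulate_coverage(genome, truth, cfg, "B", 0, assay="dnaseq")
        coarse = aggregate_cnv_bins(track, genome)
        med = float(np.median(np.concatenate(list(coarse.values()))))
        segs = []
        for chrom in track.chroms:
            ratios = cnv.bin_and_log2(coarse[chrom], median=med)
            segs.extend(cnv.segment(ratios, chrom=chrom,
                                    bin_size=genome.bin_size_cnv,
                                    chrom_length=genome.length_of(chrom)))
        bounds = [pos for chrom, pos in cnv.boundaries(cnv.call_segments(segs))
                  if chrom == "chr16A"]
        tol = tol_bins * genome.bin_size_cnv
        if all(any(abs(b - e) <= tol for b in bounds) for e in edges_bp):
            hits += 1
    return {"hit_rate": hits / n_seeds, "n_seeds": n_seeds,
            "tol_bins": tol_bins}


def segment_means_exact(seed: int = 7) -> dict:
    """Largest deviation between segment means and recomputed member-bin
    means on a noisy multi-step profile."""
    rng = substream(seed, "benchmark-segmeans")
    x = np.concatenate([rng.normal(0, 0.3, 80), rng.normal(-1, 0.3, 120),
                        rng.normal(0.4, 0.3, 60)])
    segs = cnv.segment(x, chrom="chr1")
    err = max(abs(s.mean_log2 - float(x[s.start_bin:s.end_bin].mean()))
              for s in segs)
    return {"max_abs_error": err, "n_segments": len(segs)}


# ---------------------------------------------------------------------
# Concordance calibration
# ---------------------------------------------------------------------

def concordance_oracle_agreement(seed: int = 14) -> dict:
    """Sweep-based overlap hits vs the quadratic brute-force scan."""
    from .concordance import dsb_sv_overlap

    rng = substream(seed, "benchmark-overlap")
    dsbs = []
    pos = 0
    for _ in range(50):
        pos += int(rng.integers(100, 2000))
        dsbs.append((f"chr{rng.integers(1, 4)}", pos,
                     pos + int(rng.integers(50, 800))))
    bps = [make_breakpoint(f"chr{rng.integers(1, 4)}",
                           int(rng.integers(0, 60_000)),
                           f"chr{rng.integers(1, 4)}",
                           int(rng.integers(0, 60_000)),
                           source_id=f"s{i}") for i in range(30)]
    got = sorted((h.dsb, h.source_id, h.end_index)
                 for h in dsb_sv_overlap(dsbs, bps))
    oracle = []
    for bp in bps:
        for idx, end in enumerate((bp.end1, bp.end2), start=1):
            for (c, s, e) in dsbs:
                if end.chrom == c and s <= end.pos < e:
                    oracle.append(((c, s, e), bp.source_id, idx))
    return {"mismatches": int(got != sorted(oracle)), "n_hits": len(got)}


def permutation_calibration(n_seeds: int = 200, n_perm: int = 199,
                            base_seed: int = 20_000) -> dict:
    """Under a fully random fixture the permutation p is uniform
    (Kolmogorov-Smirnov check across seeds)."""
    genome = GenomeSpec(chromosomes=(("chr1", 1_000_000),))
    pvals = []
    for s in range(n_seeds):
        rng = substream(base_seed + s, "benchmark-perm-fixture")
        placed = []
        while len(placed) < 30:
            a = int(rng.integers(0, 995_000))
            if not any(a < pe and ps < a + 5000 for ps, pe in placed):
                placed.append((a, a + 5000))
        dsbs = [("chr1", a, b) for a, b in sorted(placed)]
        bps = [make_breakpoint("chr1", int(rng.integers(0, 1_000_000)),
                               "chr1", int(rng.integers(0, 1_000_000)),
                               source_id=f"s{i}") for i in range(100)]
        out = permutation_null(dsbs, bps, genome, n_perm=n_perm,
                               seed=base_seed + s)
        pvals.append(out["p"])
    ks = kstest(pvals, "uniform")
    return {"ks_statistic": float(ks.statistic), "ks_p": float(ks.pvalue),
            "n_seeds": n_seeds, "n_perm": n_perm}


def planted_colocation_p(seed: int = 20, n_perm: int = 1000) -> dict:
    """Empirical p on a fixture with breakpoint ends planted inside the
    DSB intervals (must be small)."""
    genome = GenomeSpec(chromosomes=(("chr1", 2_000_000),))
    rng = substream(seed, "benchmark-perm-planted")
    dsbs = [("chr1", int(s), int(s) + 400)
            for s in sorted(rng.choice(1_990_000, 12, replace=False))]
    bps = [make_breakpoint("chr1", s + 100, "chr1",
                           int(rng.integers(0, 2_000_000)),
                           source_id=f"s{i}")
           for i, (_, s, _) in enumerate(dsbs[:8])]
    out = permutation_null(dsbs, bps, genome, n_perm=n_perm, seed=seed)
    return {"p": out["p"], "observed": out["observed"],
            "null_mean": out["null_mean"]}


# ---------------------------------------------------------------------
# Differential-expression recovery
# ---------------------------------------------------------------------

def de_recovery(seed: int = 23, n_genes: int = 2000, n_planted: int = 20,
                log2fc: float = 4.0) -> dict:
    """Sensitivity and empirical FDR for planted +-4 log2FC genes at
    n=4 per group, mean count 500, detected at q <= 0.05 with the
    fold-change sign."""
    from .expression import anova_de, groups_from_columns, normalize_counts

    genome = GenomeSpec(chromosomes=(("chr1", 12_000_000),))
    genes = build_genome(genome, n_genes, seed=0, mean_gene_span=2_000,
                         rng=substream(seed, "genes"))
    cfg = SimConfig(seed=seed)
    gene_ids = [g.gene_id for g in genes]
    idx = substream(seed, "benchmark-de").choice(len(gene_ids),
                                                 size=n_planted,
                                                 replace=False)
    de_truth = [(gene_ids[i], log2fc if k % 2 == 0 else -log2fc)
                for k, i in enumerate(idx)]
    mat = simulate_expression(genes, de_truth, cfg, baseline_mean=500.0)
    res = anova_de(normalize_counts(mat),
                   groups_from_columns(mat.columns),
                   alpha=0.05, fc_min=1.0)
    planted = dict(de_truth)
    called = res[res["direction"] != "ns"]
    tp = sum(1 for g, row in called.iterrows()
             if g in planted and np.sign(planted[g]) ==
             (1 if row["direction"] == "up" else -1))
    fp = len(called) - tp
    sensitivity = tp / n_planted
    fdr = fp / len(called) if len(called) else 0.0
    return {"sensitivity": sensitivity, "fdr": fdr,
            "n_called": int(len(called)), "n_planted": n_planted}


# ---------------------------------------------------------------------
# Survival cut-off recovery
# ---------------------------------------------------------------------

def cutoff_recovery(n_seeds: int = 100, hr: float = 2.5,
                    cohort_size: int = 800,
                    true_percentile: float = 60.0,
                    tol_percentile: float = 5.0,
                    base_seed: int = 30_000) -> dict:
    """Fraction of seeds recovering the planted marker threshold within
    +-tol_percentile percentile points."""
    from scipy.stats import norm

    cutoff = float(np.exp(norm.ppf(true_percentile / 100)))
    hits = 0
    for s in range(n_seeds):
        cfg = SimConfig(seed=base_seed + s, cohort_size=cohort_size)
        cohort = simulate_survival_cohort(cfg, (cutoff, hr))
        opt = optimize_cutoff(cohort)
        pct = float((cohort["marker"] <= opt["cutoff"]).mean() * 100)
        if abs(pct - true_percentile) <= tol_percentile:
            hits += 1
    return {"recovery_rate": hits / n_seeds, "n_seeds": n_seeds,
            "cohort_size": cohort_size, "hr": hr}
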