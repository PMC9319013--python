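"""End-to-end orchestration: simulate -> peaks -> consensus/partition ->
CNV -> SV -> concordance -> annotation/DE -> survival, with a JSON
report aggregating every stage's headline numbers.

Every stage is a pure function of its declared inputs and the master
seed; rerunning with the same config reproduces every output file
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import annotation, cnv, concordance, expression, intervals, peaks, sv
from .genome import GenomeSpec, build_genome
from .simulate import (ARM_BOUNDARY, LINES, STUB_SIZE, SimConfig,
                       TruthSet, default_genome, make_truth,
                       simulate_coverage, simulate_expression,
                       simulate_survival_cohort, substream)
from .survival import optimize_cutoff
from .tracks import CoverageTrack

log = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 42,
    "n_genes": 300,
    "mean_gene_span": 15_000,
    "n_replicates": 4,
    "background_rate": 5.0,
    "hotspot_fold": 8.0,
    "nb_dispersion": 0.1,
    "cohort_size": 800,
    "censoring_rate": 0.4,
    "q_max": 0.05,
    "min_width_bins": 2,
    "merge_gap": 500,
    "consensus_min_width": 50,
    "cnv_t_threshold": 5.0,
    "cnv_min_seg_bins": 5,
    "promoter_bp": 2000,
    "downstream_bp": 2000,
    "de_fc_min": 3.5,
    "de_alpha": 0.05,
    "nearest_max_distance": 5000,
    "n_perm": 1000,
    "survival_hr": 2.5,
}


def load_config(path=None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    _validate_config(cfg)
    return cfg


def _validate_config(cfg: dict) -> None:
    if cfg["n_replicates"] < 1:
        raise ValueError("n_replicates must be >= 1")
    for key in ("background_rate", "hotspot_fold", "q_max", "de_alpha"):
        if cfg[key] <= 0:
            raise ValueError(f"{key} must be positive")
    if cfg["q_max"] > 1 or cfg["de_alpha"] > 1:
        raise ValueError("q_max and de_alpha must be <= 1")


def _sim_config(cfg: dict) -> SimConfig:
    return SimConfig(
        seed=cfg["seed"], n_replicates=cfg["n_replicates"],
        background_rate=cfg["background_rate"],
        hotspot_fold=cfg["hotspot_fold"],
        nb_dispersion=cfg["nb_dispersion"],
        cohort_size=cfg["cohort_size"],
        censoring_rate=cfg["censoring_rate"],
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def aggregate_cnv_bins(track: CoverageTrack, genome: GenomeSpec
                       ) -> dict[str, np.ndarray]:
    """Sum fine coverage bins into the coarse CNV binning."""
    factor = genome.bin_size_cnv // genome.bin_size_cov
    out = {}
    for chrom in track.chroms:
        counts = track.counts[chrom]
        widths = (track.ends[chrom] - track.starts[chrom]).astype(float)
        n_coarse = -(-len(counts) // factor)
        padded = np.zeros(n_coarse * factor)
        padded[:len(counts)] = counts
        pad_w = np.zeros(n_coarse * factor)
        pad_w[:len(counts)] = widths
        totals = padded.reshape(n_coarse, factor).sum(axis=1)
        covered = pad_w.reshape(n_coarse, factor).sum(axis=1)
        # terminal partial bin: rescale to full-bin width so the shorter
        # window does not read as copy loss
        out[chrom] = totals * (genome.bin_size_cnv / np.maximum(covered, 1))
    return out


def run_all(config_path=None, outdir="breakscape_out",
            config: dict | None = None) -> dict:
    """Run the full pipeline; returns the report dict (also written as
    ``report.json`` in ``outdir`` along with every stage's artifacts)."""
    cfg = config if config is not None else load_config(config_path)
    _validate_config(cfg)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = _sim_config(cfg)
    genome = default_genome()
    report: dict = {"config": cfg, "stages": {}}

    # --- simulate -----------------------------------------------------
    genes = build_genome(genome, cfg["n_genes"], seed=0,
                         mean_gene_span=cfg["mean_gene_span"],
                         rng=substream(cfg["seed"], "genes"))
    truth = make_truth(genome, genes, sim, survival_hr=cfg["survival_hr"])
    genes.to_gtf(out / "genes.gtf")
    truth.to_json(out / "truth.json")
    sv.write_bedpe([bp for bp, _ in truth.sv_truth], out / "sv_truth.bedpe")

    break_tracks = {line: [simulate_coverage(genome, truth, sim, line, r)
                           for r in range(sim.n_replicates)]
                    for line in LINES}
    dna_tracks = {line: simulate_coverage(genome, truth, sim, line, 0,
                                          assay="dnaseq")
                  for line in LINES}
    for line in LINES:
        for r, tr in enumerate(break_tracks[line]):
            tr.to_bedgraph(out / f"breakseq_{line}_rep{r + 1}.bedGraph")
        dna_tracks[line].to_bedgraph(out / f"dnaseq_{line}.bedGraph")
    counts = simulate_expression(genes, truth.de_truth, sim)
    counts.to_csv(out / "rna_counts.tsv", sep="\t")
    cohort = simulate_survival_cohort(sim, truth.survival_truth)
    cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)
    report["stages"]["simulate"] = {
        "n_genes": len(genes),
        "n_hotspots": len(truth.hotspots),
        "n_sv": len(truth.sv_truth),
        "outputs": {p.name: _sha256(p) for p in sorted(out.glob("*"))
                    if p.is_file()},
    }

    # --- peaks --------------------------------------------------------
    peak_sets: dict[str, list[list]] = {}
    for line in LINES:
        reps = []
        for r, tr in enumerate(break_tracks[line]):
            norm = peaks.normalize_by_copy_number(tr, dna_tracks[line])
            calls = peaks.call_peaks(
                norm, q_max=cfg["q_max"],
                min_width_bins=cfg["min_width_bins"],
                merge_gap=cfg["merge_gap"])
            peaks.peaks_to_bed(calls, out / f"peaks_{line}_rep{r + 1}.bed")
            reps.append([(p.chrom, p.start, p.end) for p in calls])
        peak_sets[line] = reps
    report["stages"]["peaks"] = {
        line: {"per_replicate": [len(s) for s in peak_sets[line]]}
        for line in LINES
    }

    # --- consensus / partition / density ------------------------------
    cons = {line: intervals.consensus(peak_sets[line],
                                      min_width=cfg["consensus_min_width"],
                                      line_label=line)
            for line in LINES}
    part = intervals.partition(cons["A"], cons["B"])
    for line in LINES:
        intervals.write_bed(cons[line].consensus_peaks,
                            out / f"consensus_{line}.bed")
    b_specific = part.b_specific
    density = intervals.density_per_chromosome(b_specific, genome)
    density.to_csv(out / "density_B_specific.tsv", sep="\t", index=False)
    report["stages"]["consensus"] = {
        "consensus_A": len(cons["A"]), "consensus_B": len(cons["B"]),
        "partition": part.counts,
        "density_B_specific": density.to_dict("records"),
    }

    # --- CNV ----------------------------------------------------------
    cnv_boundaries_by_line = {}
    for line in LINES:
        coarse = aggregate_cnv_bins(dna_tracks[line], genome)
        all_counts = np.concatenate(list(coarse.values()))
        med = float(np.median(all_counts))
        segs = []
        for chrom in dna_tracks[line].chroms:
            ratios = cnv.bin_and_log2(coarse[chrom], median=med)
            segs.extend(cnv.segment(
                ratios, chrom=chrom, bin_size=genome.bin_size_cnv,
                t_threshold=cfg["cnv_t_threshold"],
                min_seg_bins=cfg["cnv_min_seg_bins"],
                chrom_length=genome.length_of(chrom)))
        segs = cnv.call_segments(segs)
        cnv.segments_to_table(segs, sample=line).to_csv(
            out / f"cnv_segments_{line}.tsv", sep="\t", index=False)
        cnv_boundaries_by_line[line] = cnv.boundaries(segs)
        report["stages"].setdefault("cnv", {})[line] = {
            "n_segments": len(segs),
            "n_loss": sum(1 for s in segs if s.call == "loss"),
            "n_gain": sum(1 for s in segs if s.call == "gain"),
            "boundaries": cnv_boundaries_by_line[line],
        }

    # --- SV -----------------------------------------------------------
    loaded, excl = sv.load_bedpe(out / "sv_truth.bedpe")
    tally, matrix = sv.classify_and_tally(loaded)
    tally.to_csv(out / "sv_tally.tsv", sep="\t", index=False)
    matrix.to_csv(out / "sv_pair_matrix.tsv", sep="\t")
    report["stages"]["sv"] = {
        "exclusion": {k: v for k, v in excl.items() if k != "malformed_lines"},
        "n_intra": int(tally["intra"].sum()),
        "n_inter_events": int(tally["inter"].sum()) // 2,
    }

    # --- concordance (line-B consensus DSBs vs line-B rearrangements) -
    dsbs_b = cons["B"].consensus_peaks
    hits = concordance.dsb_sv_overlap(dsbs_b, loaded)
    stub = ("chr16A", ARM_BOUNDARY, ARM_BOUNDARY + STUB_SIZE)
    region = concordance.region_report(hits, stub, loaded)
    cnv_hits = concordance.dsb_cnv_overlap(
        dsbs_b, cnv_boundaries_by_line["B"],
        window=genome.bin_size_cnv)
    perm = concordance.permutation_null(
        dsbs_b, loaded, genome, n_perm=cfg["n_perm"], seed=cfg["seed"])
    report["stages"]["concordance"] = {
        "n_sv_hits": len(hits),
        "region_report": region,
        "n_cnv_boundary_hits": len(cnv_hits),
        "permutation": perm,
    }

    # --- annotation / enrichment --------------------------------------
    dist_b = annotation.feature_distribution(
        cons["B"].consensus_peaks, genes,
        promoter_bp=cfg["promoter_bp"], downstream_bp=cfg["downstream_bp"])
    dist_a = annotation.feature_distribution(
        cons["A"].consensus_peaks, genes,
        promoter_bp=cfg["promoter_bp"], downstream_bp=cfg["downstream_bp"])
    dist_b.to_csv(out / "feature_distribution_B.tsv", sep="\t", index=False)
    intronic_b = int(dist_b.set_index("feature").loc["intron", "count"])
    intronic_a = int(dist_a.set_index("feature").loc["intron", "count"])
    tot_b, tot_a = len(cons["B"]), len(cons["A"])
    fisher_p = annotation.fisher_exact_2x2(
        intronic_b, tot_b - intronic_b, intronic_a, tot_a - intronic_a) \
        if tot_a and tot_b else None
    nearest = annotation.nearest_gene(
        b_specific, genes, max_distance=cfg["nearest_max_distance"])
    nearest.to_csv(out / "nearest_gene_B_specific.tsv", sep="\t", index=False)
    report["stages"]["annotation"] = {
        "feature_distribution_B": dist_b.to_dict("records"),
        "intronic_fisher": {
            "table": [[intronic_b, tot_b - intronic_b],
                      [intronic_a, tot_a - intronic_a]],
            "p": fisher_p,
        },
    }

    # --- differential expression --------------------------------------
    norm = expression.normalize_counts(counts)
    de = expression.anova_de(norm, expression.groups_from_columns(counts.columns),
                             alpha=cfg["de_alpha"], fc_min=cfg["de_fc_min"])
    de.to_csv(out / "de_results.tsv", sep="\t")
    linked = expression.link_de_to_dsb(de, nearest)
    linked.to_csv(out / "de_near_dsb.tsv", sep="\t", index=False)
    report["stages"]["expression"] = {
        "n_up": int((de["direction"] == "up").sum()),
        "n_down": int((de["direction"] == "down").sum()),
        "n_de_near_dsb": int(linked["gene_id"].nunique()),
    }

    # --- survival -----------------------------------------------------
    opt = optimize_cutoff(cohort, seed=cfg["seed"])
    res = opt["result"]
    report["stages"]["survival"] = {
        "cutoff": res.cutoff,
        "true_cutoff": truth.survival_truth[0],
        "p": res.p,
        "chi_square": res.chi_square,
        "hazard_ratio": res.hazard_ratio,
        "group_sizes": [res.n1, res.n2],
    }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=_jsonable)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
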