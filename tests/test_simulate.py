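import numpy as np
import pandas as pd
import pytest

from breakscape.genome import GenomeSpec, build_genome
from breakscape.simulate import (SimConfig, TruthSet, default_genome,
                                 make_truth, simulate_coverage,
                                 simulate_expression,
                                 simulate_survival_cohort, substream)
from breakscape.survival import logrank


def _flat_truth(genome, cn_b=None):
    truth = TruthSet()
    truth.cnv_truth["A"] = [(c, 0, genome.length_of(c), 2.0)
                            for c in genome.names]
    truth.cnv_truth["B"] = cn_b or truth.cnv_truth["A"]
    return truth


def test_unknown_line_label_rejected(small_genome, sim_config):
    truth = _flat_truth(small_genome)
    with pytest.raises(ValueError, match="line label"):
        simulate_coverage(small_genome, truth, sim_config, "C", 0)


def test_null_model_mean(small_genome):
    """With no hotspots and uniform diploid copy number the empirical
    bin mean matches the background rate to within 3 SE."""
    cfg = SimConfig(seed=11, background_rate=5.0, hotspot_fold=1.0)
    truth = _flat_truth(small_genome)
    track = simulate_coverage(small_genome, truth, cfg, "A", 0)
    counts = track.all_counts()[:-1]  # drop terminal partial bin
    se = np.sqrt(5.0 / len(counts))
    assert abs(counts.mean() - 5.0) < 3 * se


def test_deletion_halves_coverage(small_genome):
    """Bins inside a single-copy deletion average background/2."""
    cfg = SimConfig(seed=13, background_rate=5.0)
    deletion = ("chr1", 100_000, 600_000)
    truth = _flat_truth(small_genome, cn_b=[
        ("chr1", 0, 100_000, 2.0), deletion[:2] + (600_000, 1.0),
        ("chr1", 600_000, 1_000_000, 2.0),
        ("chr2", 0, 500_000, 2.0)])
    track = simulate_coverage(small_genome, truth, cfg, "B", 0,
                              assay="dnaseq")
    sel = (track.starts["chr1"] >= 100_000) & (track.ends["chr1"] <= 600_000)
    counts = track.counts["chr1"][sel]
    se = np.sqrt(2.5 / len(counts))
    assert abs(counts.mean() - 2.5) < 3 * se


def test_hotspot_fold_enrichment(small_genome):
    """Hotspot bins average fold x background over >= 1000 bins."""
    cfg = SimConfig(seed=17, background_rate=5.0, hotspot_fold=8.0)
    truth = _flat_truth(small_genome)
    truth.hotspots = [("chr1", 0, 150_000, "shared", 8.0)]
    track = simulate_coverage(small_genome, truth, cfg, "A", 0)
    counts = track.counts["chr1"][:1500]
    assert len(counts) >= 1000
    se = np.sqrt(40.0 / len(counts))
    assert abs(counts.mean() - 40.0) < 3 * se


def test_dnaseq_ignores_hotspots(small_genome):
    cfg = SimConfig(seed=19, background_rate=5.0, hotspot_fold=8.0)
    truth = _flat_truth(small_genome)
    truth.hotspots = [("chr1", 0, 200_000, "shared", 8.0)]
    track = simulate_coverage(small_genome, truth, cfg, "A", 0,
                              assay="dnaseq")
    counts = track.counts["chr1"][:2000]
    se = np.sqrt(5.0 / len(counts))
    assert abs(counts.mean() - 5.0) < 3 * se


def test_coverage_byte_determinism(small_genome, sim_config, tmp_path):
    truth = _flat_truth(small_genome)
    truth.hotspots = [("chr1", 5000, 5400, "A", 8.0)]
    p1, p2 = tmp_path / "a.bedGraph", tmp_path / "b.bedGraph"
    simulate_coverage(small_genome, truth, sim_config, "A", 0).to_bedgraph(p1)
    simulate_coverage(small_genome, truth, sim_config, "A", 0).to_bedgraph(p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_substreams_are_independent():
    a = substream(3, "coverage", "A", 0).integers(0, 2**31, 10)
    b = substream(3, "coverage", "A", 1).integers(0, 2**31, 10)
    c = substream(3, "expression").integers(0, 2**31, 10)
    assert not np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_truth_round_trip(tmp_path):
    genome = default_genome()
    cfg = SimConfig(seed=23)
    genes = build_genome(genome, 60, seed=0, mean_gene_span=15_000,
                         rng=substream(cfg.seed, "genes"))
    truth = make_truth(genome, genes, cfg)
    path = tmp_path / "truth.json"
    truth.to_json(path)
    back = TruthSet.from_json(path)
    assert back.hotspots == truth.hotspots
    assert back.cnv_truth == truth.cnv_truth
    assert back.de_truth == truth.de_truth
    assert back.sv_truth == truth.sv_truth
    assert tuple(back.survival_truth) == tuple(truth.survival_truth)


# -- expression -------------------------------------------------------

def _expression_genome():
    genome = GenomeSpec(chromosomes=(("chr1", 12_000_000),))
    genes = build_genome(genome, 400, seed=0, mean_gene_span=3_000,
                         rng=substream(101, "genes"))
    return genes


def test_expression_unknown_gene_rejected():
    genes = _expression_genome()
    with pytest.raises(ValueError, match="unknown gene"):
        simulate_expression(genes, [("NOPE", 2.0)], SimConfig(seed=1))


def test_expression_determinism():
    genes = _expression_genome()
    cfg = SimConfig(seed=29)
    m1 = simulate_expression(genes, [], cfg)
    m2 = simulate_expression(genes, [], cfg)
    pd.testing.assert_frame_equal(m1, m2)


def test_planted_fold_change_recovered():
    """A 4-log2FC gene at mean count 500 recovers its fold change within
    +-0.5 from n=4 per group (difference of group mean log2 counts)."""
    genes = _expression_genome()
    cfg = SimConfig(seed=31)
    planted = [(genes.genes[i].gene_id, 4.0) for i in range(0, 20, 2)]
    planted += [(genes.genes[i].gene_id, -4.0) for i in range(1, 20, 2)]
    mat = simulate_expression(genes, planted, cfg, baseline_mean=500.0)
    log2 = np.log2(mat + 1.0)
    fc = log2.iloc[:, 4:].mean(axis=1) - log2.iloc[:, :4].mean(axis=1)
    for gid, f in planted:
        assert abs(fc[gid] - f) < 0.5, (gid, fc[gid], f)
    # null genes: delta-method oracle for the median |log2FC|,
    # 0.6745 * sqrt(2/n) * log2(e) * sqrt(1/mu + dispersion) at the
    # median baseline mean mu = 500 * exp(-0.5)
    null = fc.drop([g for g, _ in planted])
    mu = 500.0 * np.exp(-0.5)
    expected = 0.6745 * np.sqrt(2 / 4) * np.log2(np.e) * np.sqrt(
        1 / mu + cfg.nb_dispersion)
    assert abs(null.abs().median() - expected) < 0.05


# -- survival ---------------------------------------------------------

def test_zero_censoring_gives_all_events():
    cfg = SimConfig(seed=37, censoring_rate=0.0, cohort_size=300)
    cohort = simulate_survival_cohort(cfg, (1.0, 2.0))
    assert (cohort["event"] == 1).all()


def test_censoring_rate_roughly_matched():
    cfg = SimConfig(seed=41, censoring_rate=0.4, cohort_size=2000)
    cohort = simulate_survival_cohort(cfg, (np.inf, 1.0))
    frac = 1 - cohort["event"].mean()
    assert abs(frac - 0.4) < 3 * np.sqrt(0.4 * 0.6 / 2000)


def test_logrank_type_i_error_at_true_cutoff():
    """Null cohorts (HR=1) reject at roughly the nominal level when the
    log-rank test is applied at the fixed, pre-specified cut-off."""
    rejections = 0
    n_sim = 200
    for s in range(n_sim):
        cfg = SimConfig(seed=1000 + s, cohort_size=200)
        cohort = simulate_survival_cohort(cfg, (1.0, 1.0))
        if logrank(cohort, 1.0).p <= 0.05:
            rejections += 1
    rate = rejections / n_sim
    assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_sim) + 0.01


def test_logrank_power_under_planted_hazard():
    """HR=2.5 at n=800 is detected at p < 0.001 in >= 95% of seeds."""
    hits = 0
    n_sim = 100
    for s in range(n_sim):
        cfg = SimConfig(seed=2000 + s, cohort_size=800)
        cohort = simulate_survival_cohort(cfg, (1.0, 2.5))
        if logrank(cohort, 1.0).p < 0.001:
            hits += 1
    assert hits >= 95
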