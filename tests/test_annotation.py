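import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from breakscape.annotation import (classify_peak, feature_distribution,
                                   nearest_gene)
from breakscape.genome import Gene, GeneModelSet
from breakscape.stats import bh_fdr, fisher_exact_2x2
from conftest import fisher_enumeration_oracle


@pytest.fixture
def genes():
    return GeneModelSet([
        # + strand gene with two exons
        Gene("GA", "chr1", 10_000, 20_000, "+",
             exons=((10_000, 12_000), (18_000, 20_000))),
        # - strand gene overlapping GA's downstream region
        Gene("GB", "chr1", 30_000, 40_000, "-",
             exons=((30_000, 31_000), (39_000, 40_000))),
    ])


def test_exon_beats_intron_priority(genes):
    # peak inside GA exon 1; also "inside" nothing else
    assert classify_peak(("chr1", 10_100, 10_200), genes) == "exon"
    # straddling exon/intron boundary still classifies exon
    assert classify_peak(("chr1", 11_900, 12_100), genes) == "exon"


def test_intron_promoter_downstream_intergenic(genes):
    assert classify_peak(("chr1", 13_000, 14_000), genes) == "intron"
    # promoter: 2 kb upstream of + strand TSS
    assert classify_peak(("chr1", 8_500, 9_000), genes) == "promoter"
    # downstream: past + strand TES
    assert classify_peak(("chr1", 20_500, 21_000), genes) == "downstream"
    # - strand promoter sits past the right end
    assert classify_peak(("chr1", 40_500, 41_000), genes) == "promoter"
    assert classify_peak(("chr1", 500_000, 500_100), genes) == "intergenic"
    assert classify_peak(("chr2", 10_100, 10_200), genes) == "intergenic"


def test_classification_single_valued_and_fractions_sum(genes):
    rng = np.random.default_rng(22)
    peaks = [("chr1", int(s), int(s) + 200)
             for s in rng.integers(0, 60_000, size=40)]
    dist = feature_distribution(peaks, genes)
    assert dist["count"].sum() == 40
    assert dist["fraction"].sum() == pytest.approx(1.0)


def test_distribution_all_intergenic_and_empty(genes):
    dist = feature_distribution([("chr2", 0, 100)], genes).set_index("feature")
    assert dist.loc["intergenic", "fraction"] == 1.0
    empty = feature_distribution([], genes)
    assert empty["count"].sum() == 0 and empty["fraction"].sum() == 0.0


def test_hand_built_tally(genes):
    peaks = [("chr1", 10_100, 10_200),   # exon
             ("chr1", 13_000, 13_100),   # intron
             ("chr1", 8_500, 8_600),     # promoter
             ("chr1", 99_000, 99_100)]   # intergenic
    dist = feature_distribution(peaks, genes).set_index("feature")
    assert dist.loc["exon", "count"] == 1
    assert dist.loc["intron", "count"] == 1
    assert dist.loc["promoter", "count"] == 1
    assert dist.loc["intergenic", "count"] == 1


# -- Fisher exact -----------------------------------------------------

def test_fisher_printed_table_value():
    # intronic DSBs: 142 of 472 vs 20 of 271
    p = fisher_exact_2x2(142, 330, 20, 251)
    assert p == pytest.approx(2.42e-14, rel=0.01)
    # the one-sided upper tail reproduces the published 1.8e-14
    assert fisher_exact_2x2(142, 330, 20, 251, alternative="greater") == \
        pytest.approx(1.8e-14, rel=0.02)


def test_fisher_degenerate_margin_and_small_table():
    assert fisher_exact_2x2(0, 10, 0, 10) == 1.0
    assert fisher_exact_2x2(3, 1, 1, 3) == pytest.approx(34 / 70, abs=1e-12)
    with pytest.raises(ValueError):
        fisher_exact_2x2(-1, 2, 3, 4)


@settings(max_examples=300, derandomize=True, deadline=None)
@given(st.tuples(st.integers(0, 12), st.integers(0, 12),
                 st.integers(0, 12), st.integers(0, 12)))
def test_fisher_matches_enumeration_on_small_tables(cells):
    a, b, c, d = cells
    got = fisher_exact_2x2(a, b, c, d)
    want = fisher_enumeration_oracle(a, b, c, d)
    assert got == pytest.approx(min(want, 1.0), abs=1e-12)


def test_fisher_transposition_invariance_and_scipy_agreement():
    from scipy.stats import fisher_exact as scipy_fisher
    rng = np.random.default_rng(24)
    for _ in range(30):
        a, b, c, d = (int(x) for x in rng.integers(0, 200, 4))
        p = fisher_exact_2x2(a, b, c, d)
        assert p == pytest.approx(fisher_exact_2x2(a, c, b, d), rel=1e-9)
        assert p == pytest.approx(
            scipy_fisher([[a, b], [c, d]]).pvalue, rel=1e-6)
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            assert p == 1.0


# -- BH FDR -----------------------------------------------------------

def test_bh_hand_examples():
    assert bh_fdr([0.02])[0] == pytest.approx(0.02)
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])
    np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)
    assert bh_fdr([]).size == 0


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests
    rng = np.random.default_rng(26)
    p = rng.uniform(size=200) ** 2
    got = bh_fdr(p)
    want = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(got, want, atol=1e-12)


def test_bh_rejects_bad_input():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


# -- nearest gene -----------------------------------------------------

def test_nearest_gene_cases(genes):
    table = nearest_gene([
        ("chr1", 11_000, 11_500),    # inside GA -> distance 0
        ("chr1", 22_000, 23_000),    # 2000 bp right of GA, 7000 left of GB
        ("chr1", 25_001, 26_000),    # 5001 bp past GA, 4000 before GB
        ("chr1", 900_000, 900_100),  # nothing within 5 kb
    ], genes, max_distance=5000)
    assert table.loc[0, "gene_id"] == "GA" and table.loc[0, "distance"] == 0
    assert table.loc[1, "gene_id"] == "GA" and table.loc[1, "distance"] == -2000
    assert table.loc[2, "gene_id"] == "GB" and table.loc[2, "distance"] == 4000
    assert table.loc[3, "gene_id"] is None


def test_nearest_gene_strict_threshold():
    g = GeneModelSet([Gene("G1", "chr1", 0, 1000, "+", exons=((0, 1000),))])
    t = nearest_gene([("chr1", 6001, 6100)], g, max_distance=5000)
    assert t.loc[0, "gene_id"] is None
    t2 = nearest_gene([("chr1", 6000, 6100)], g, max_distance=5000)
    assert t2.loc[0, "gene_id"] == "G1" and t2.loc[0, "distance"] == -5000


def test_nearest_gene_matches_brute_force():
    rng = np.random.default_rng(28)
    gs = []
    pos = 0
    for i in range(30):
        pos += int(rng.integers(2000, 8000))
        end = pos + int(rng.integers(500, 3000))
        gs.append(Gene(f"G{i:02d}", "chr1", pos, end, "+",
                       exons=((pos, end),)))
        pos = end
    gset = GeneModelSet(gs)
    peaks = [("chr1", int(s), int(s) + 300)
             for s in rng.integers(0, pos, size=40)]
    table = nearest_gene(peaks, gset, max_distance=5000)
    for row, (c, s, e) in zip(table.itertuples(index=False), peaks):
        # brute force over all genes
        best = None
        for g in gs:
            if min(e, g.end) > max(s, g.start):
                d = 0
            elif g.end <= s:
                d = s - g.end
            else:
                d = g.start - e
            if d <= 5000 and (best is None or (d, g.gene_id) < best):
                best = (d, g.gene_id)
        assert row.gene_id == (best[1] if best else None)
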