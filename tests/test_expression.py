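import numpy as np
import pandas as pd
import pytest

from breakscape.expression import (anova_de, groups_from_columns,
                                   link_de_to_dsb, normalize_counts)


@pytest.fixture
def matrix():
    return pd.DataFrame(
        {"A_1": [100, 10, 50], "A_2": [110, 12, 48],
         "B_1": [100, 160, 52], "B_2": [90, 170, 49]},
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"))


def test_cpm_proportional_for_equal_libraries():
    m = pd.DataFrame({"s1": [10, 30], "s2": [30, 10]})
    norm = normalize_counts(m)
    # equal library sizes (40): CPM = count * 25_000
    np.testing.assert_allclose(norm["s1"], np.log2([10 * 25_000 + 1,
                                                    30 * 25_000 + 1]))


def test_cpm_scale_invariance():
    m = pd.DataFrame({"s1": [10, 30], "s2": [30, 10]})
    doubled = m.copy()
    doubled["s1"] = m["s1"] * 2
    pd.testing.assert_series_equal(normalize_counts(m)["s1"],
                                   normalize_counts(doubled)["s1"])


def test_cpm_hand_computed_three_genes():
    m = pd.DataFrame({"s": [5, 15, 80]})
    norm = normalize_counts(m)
    want = np.log2(np.array([5, 15, 80]) / 100 * 1e6 + 1)
    np.testing.assert_allclose(norm["s"], want)


def test_zero_library_rejected():
    with pytest.raises(ValueError):
        normalize_counts(pd.DataFrame({"s1": [0, 0]}))


def test_anova_constant_gene_f_zero_p_one():
    m = pd.DataFrame({"A_1": [7.0], "A_2": [7.0], "B_1": [7.0], "B_2": [7.0]},
                     index=["g"])
    res = anova_de(m, ["A", "A", "B", "B"])
    assert res.loc["g", "F_statistic"] == 0.0
    assert res.loc["g", "p"] == 1.0
    assert res.loc["g", "direction"] == "ns"


def test_anova_matches_closed_form():
    """(1,1) vs (3,3) + tiny jitter: F equals the hand-computed
    between/within ratio."""
    eps = 1e-3
    vals = np.array([1.0, 1.0 + eps, 3.0, 3.0 - eps])
    m = pd.DataFrame([vals], columns=["A_1", "A_2", "B_1", "B_2"],
                     index=["g"])
    res = anova_de(m, ["A", "A", "B", "B"])
    ma, mb = vals[:2].mean(), vals[2:].mean()
    grand = vals.mean()
    ss_b = 2 * (ma - grand) ** 2 + 2 * (mb - grand) ** 2
    ss_w = ((vals[:2] - ma) ** 2).sum() + ((vals[2:] - mb) ** 2).sum()
    assert res.loc["g", "F_statistic"] == pytest.approx(ss_b / (ss_w / 2))
    # two-group ANOVA == squared two-sample t
    from scipy.stats import ttest_ind
    t = ttest_ind(vals[2:], vals[:2]).statistic
    assert res.loc["g", "F_statistic"] == pytest.approx(t ** 2)


def test_anova_agrees_with_scipy_f_oneway():
    from scipy.stats import f_oneway
    rng = np.random.default_rng(30)
    m = pd.DataFrame(rng.normal(5, 1, size=(50, 8)),
                     columns=[f"A_{i}" for i in range(4)]
                     + [f"B_{i}" for i in range(4)])
    res = anova_de(m, ["A"] * 4 + ["B"] * 4)
    want = f_oneway(m.iloc[:, :4], m.iloc[:, 4:], axis=1)
    np.testing.assert_allclose(res["F_statistic"], want.statistic, rtol=1e-9)
    np.testing.assert_allclose(res["p"], want.pvalue, rtol=1e-9)


def test_log2fc_antisymmetry(matrix):
    norm = normalize_counts(matrix)
    res = anova_de(norm, groups_from_columns(matrix.columns))
    sw = norm[["B_1", "B_2", "A_1", "A_2"]]
    sw.columns = ["A_1", "A_2", "B_1", "B_2"]
    res_swapped = anova_de(sw, ["A", "A", "B", "B"])
    np.testing.assert_allclose(res["log2_fc"], -res_swapped["log2_fc"],
                               atol=1e-12)


def test_direction_monotone_in_fc_min(matrix):
    norm = normalize_counts(matrix)
    groups = groups_from_columns(matrix.columns)
    calls = []
    for fc_min in (0.5, 1.0, 2.0, 4.0):
        res = anova_de(norm, groups, fc_min=fc_min)
        calls.append(int((res["direction"] != "ns").sum()))
    assert calls == sorted(calls, reverse=True)


def test_anova_input_validation(matrix):
    norm = normalize_counts(matrix)
    with pytest.raises(ValueError, match="two groups"):
        anova_de(norm, ["A", "A", "A", "A"])
    with pytest.raises(ValueError, match=">= 2 samples"):
        anova_de(norm, ["A", "B", "B", "B"])
    with pytest.raises(ValueError, match="per column"):
        anova_de(norm, ["A", "B"])


def test_link_de_to_dsb_join():
    de = pd.DataFrame({
        "log2_fc": [5.0, -5.0, 0.1],
        "q": [0.001, 0.002, 0.9],
        "direction": ["up", "down", "ns"],
    }, index=pd.Index(["g1", "g2", "g3"], name="gene_id"))
    nearest = pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr1"],
        "start": [0, 100, 200], "end": [50, 150, 250],
        "gene_id": ["g1", "g3", None],
        "distance": [0, 10, None],
    })
    out = link_de_to_dsb(de, nearest)
    assert list(out["gene_id"]) == ["g1"]   # g3 is ns, None dropped
    assert out.loc[0, "direction"] == "up"


def test_link_empty_and_disjoint():
    de = pd.DataFrame({"log2_fc": [], "q": [], "direction": []},
                      index=pd.Index([], name="gene_id"))
    nearest = pd.DataFrame({"chrom": [], "start": [], "end": [],
                            "gene_id": [], "distance": []})
    assert len(link_de_to_dsb(de, nearest)) == 0
    de2 = pd.DataFrame({"log2_fc": [5.0], "q": [0.01],
                        "direction": ["up"]},
                       index=pd.Index(["gX"], name="gene_id"))
    nearest2 = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10],
                             "gene_id": ["gY"], "distance": [0]})
    assert len(link_de_to_dsb(de2, nearest2)) == 0


def test_planted_six_genes_near_hotspots_recovered():
    """A truth-driven fixture: 2 up + 4 down planted genes near
    line-specific DSBs are exactly the genes returned."""
    rng = np.random.default_rng(23)
    gene_ids = [f"g{i:03d}" for i in range(200)]
    planted_up = gene_ids[:2]
    planted_down = gene_ids[2:6]
    mu = np.full((200, 8), 500.0)
    for g in planted_up:
        mu[gene_ids.index(g), 4:] *= 2 ** 4.5
    for g in planted_down:
        mu[gene_ids.index(g), 4:] /= 2 ** 4.5
    r = 10.0
    counts = rng.negative_binomial(r, r / (r + mu))
    m = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                     columns=[f"A_{i}" for i in range(4)]
                     + [f"B_{i}" for i in range(4)])
    res = anova_de(normalize_counts(m), ["A"] * 4 + ["B"] * 4, fc_min=3.5)
    nearest = pd.DataFrame({
        "chrom": ["chr1"] * 6, "start": range(6), "end": range(1, 7),
        "gene_id": planted_up + planted_down, "distance": [0] * 6,
    })
    out = link_de_to_dsb(res, nearest)
    assert sorted(out["gene_id"]) == sorted(planted_up + planted_down)
    assert (out.set_index("gene_id").loc[planted_up, "direction"] == "up").all()
    assert (out.set_index("gene_id").loc[planted_down, "direction"] == "down").all()
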