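"""Differential expression between two cell lines from a gene count
matrix, and the linkage of DE genes to DSB proximity.

The test is the one actually specified for the study design: per-gene
one-way ANOVA on log2 counts-per-million across the two groups (for two
groups this equals the equal-variance two-sample t-test, F = t^2), with
Benjamini-Hochberg FDR and tiered absolute log2 fold-change thresholds
(1, 3.5 or 4 depending on the analysis stage).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import bh_fdr

FC_TIERS = (1.0, 3.5, 4.0)


def normalize_counts(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2 counts-per-million with a +1 pseudo-count.

    ``log2(count / library_size * 1e6 + 1)`` per sample; invariant to
    scaling a library's every count by a constant.
    """
    libsize = matrix.sum(axis=0).astype(float)
    if (libsize <= 0).any():
        raise ValueError("every sample needs a positive library size")
    cpm = matrix.div(libsize, axis=1) * 1e6
    return np.log2(cpm + 1.0)


def anova_de(normalized: pd.DataFrame, groups: list[str],
             alpha: float = 0.05, fc_min: float = 4.0) -> pd.DataFrame:
    """Per-gene one-way ANOVA between two groups of samples.

    ``groups`` labels each column; exactly two distinct labels with
    >= 2 samples each are required. log2FC is the difference of group
    means of log2(CPM+1), second group over first (B over A with sorted
    labels). Direction: up iff q <= alpha and log2FC > fc_min; down iff
    q <= alpha and log2FC < -fc_min; else ns.
    """
    groups = list(groups)
    if len(groups) != normalized.shape[1]:
        raise ValueError("one group label per column required")
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    ga, gb = labels
    idx_a = [i for i, g in enumerate(groups) if g == ga]
    idx_b = [i for i, g in enumerate(groups) if g == gb]
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("each group needs >= 2 samples")

    xa = normalized.iloc[:, idx_a].to_numpy()
    xb = normalized.iloc[:, idx_b].to_numpy()
    na, nb = xa.shape[1], xb.shape[1]
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    grand = (xa.sum(axis=1) + xb.sum(axis=1)) / (na + nb)
    ss_between = na * (ma - grand) ** 2 + nb * (mb - grand) ** 2
    ss_within = ((xa - ma[:, None]) ** 2).sum(axis=1) + \
                ((xb - mb[:, None]) ** 2).sum(axis=1)
    df_b, df_w = 1, na + nb - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df_b) / (ss_within / df_w)
    # zero within- and between-variance: no evidence of difference
    F = np.where(ss_within == 0, np.where(ss_between == 0, 0.0, np.inf), F)
    from scipy.stats import f as f_dist
    p = np.where(np.isinf(F), 0.0, f_dist.sf(np.where(np.isinf(F), 1.0, F),
                                             df_b, df_w))
    p = np.where(F == 0, 1.0, p)
    q = bh_fdr(p)
    log2_fc = mb - ma

    direction = np.where(
        (q <= alpha) & (log2_fc > fc_min), "up",
        np.where((q <= alpha) & (log2_fc < -fc_min), "down", "ns"))
    return pd.DataFrame({
        "gene_id": normalized.index,
        f"mean_log2_cpm_{ga}": ma,
        f"mean_log2_cpm_{gb}": mb,
        "log2_fc": log2_fc,
        "F_statistic": F,
        "p": p,
        "q": q,
        "direction": direction,
    }).set_index("gene_id")


def groups_from_columns(columns) -> list[str]:
    """Group labels from ``LINE_replicate`` column names (e.g. ``A_1``)."""
    return [str(c).split("_")[0] for c in columns]


def link_de_to_dsb(de_results: pd.DataFrame,
                   nearest: pd.DataFrame) -> pd.DataFrame:
    """Genes both differentially expressed and within range of a DSB.

    Inner join of significant (non-ns) DE genes with the nearest-gene
    table on gene_id; returns one row per (gene, DSB) pair with the
    direction carried over.
    """
    hits = nearest.dropna(subset=["gene_id"]).copy()
    hits["gene_id"] = hits["gene_id"].astype(str)
    sig = de_results[de_results["direction"] != "ns"]
    right = sig.reset_index()[["gene_id", "log2_fc", "q", "direction"]].copy()
    right["gene_id"] = right["gene_id"].astype(str)
    merged = hits.merge(right, on="gene_id")
    return merged.sort_values(["gene_id", "chrom", "start"]).reset_index(drop=True)
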