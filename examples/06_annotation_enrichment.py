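"""Feature classification and the intronic-enrichment exact test.

Classifies peaks against gene models by priority (exon > UTRs >
promoter > downstream > intron > intergenic) and reruns the published
2x2 intronic-DSB contingency test.
"""

from breakscape import (SimConfig, build_genome, default_genome,
                        feature_distribution, fisher_exact_2x2, make_truth,
                        nearest_gene)
from breakscape.simulate import substream

genome = default_genome()
cfg = SimConfig(seed=42)
genes = build_genome(genome, 300, seed=0, mean_gene_span=15_000,
                     rng=substream(cfg.seed, "genes"))
truth = make_truth(genome, genes, cfg)

dsbs = [(c, s, e) for c, s, e, label, _ in truth.hotspots
        if label in ("B", "shared")]
print(feature_distribution(dsbs, genes).to_string(index=False))
near = nearest_gene(dsbs, genes, max_distance=5000)
print(f"{near['gene_id'].notna().sum()} of {len(near)} DSBs lie within "
      f"5 kb of a gene")

# Published contingency table: 142 intronic of 472 consensus breaks in
# the cancer line vs 20 of 271 in the control.
p2 = fisher_exact_2x2(142, 330, 20, 251)
p1 = fisher_exact_2x2(142, 330, 20, 251, alternative="greater")
print(f"intronic enrichment: two-sided p = {p2:.2e}, "
      f"one-sided p = {p1:.2e}")
# The one-sided tail reproduces the published 1.8e-14; the two-sided
# minimum-likelihood definition gives 2.4e-14.
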