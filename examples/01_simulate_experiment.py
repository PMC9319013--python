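"""Generate the synthetic two-cell-line experiment and inspect its truth.

Builds the toy genome (a background chromosome plus a rearranged-arm
analog), plants DSB hotspots, a one-arm deletion with an intact 300 kb
pericentromeric stub, SV junctions, expression fold changes and a
survival threshold, then prints what was planted.
"""

from breakscape import SimConfig, build_genome, default_genome, make_truth
from breakscape.simulate import substream

genome = default_genome()
cfg = SimConfig(seed=42)
genes = build_genome(genome, 300, seed=0, mean_gene_span=15_000,
                     rng=substream(cfg.seed, "genes"))
truth = make_truth(genome, genes, cfg)

by_label = {}
for _, _, _, label, _ in truth.hotspots:
    by_label[label] = by_label.get(label, 0) + 1
print(f"genome: {genome.names} ({[l for _, l in genome.chromosomes]} bp)")
print(f"genes placed: {len(genes)}")
print(f"hotspots by label: {by_label}")
print(f"line-B copy-number truth: {truth.cnv_truth['B']}")
n_co = sum(1 for _, co in truth.sv_truth if co)
print(f"SV junctions: {len(truth.sv_truth)} ({n_co} co-located with hotspots)")
print(f"planted DE genes: {len(truth.de_truth)}")
print(f"survival truth (cut-off, HR): {truth.survival_truth}")
# The hotspot labels define which line carries each break; the cnv truth
# shows the single-copy mid-arm deletion (copy number 1.0) flanked by
# intact diploid segments - the 16q-loss analog every later stage probes.
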