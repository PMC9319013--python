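"""Call DSB peaks from a simulated Break-seq track.

Simulates one Break-seq replicate and the matched DNA-seq control,
normalizes out copy-number dosage, and calls peaks against the Poisson
local background.
"""

from breakscape import (SimConfig, build_genome, call_peaks, default_genome,
                        make_truth, normalize_by_copy_number,
                        simulate_coverage)
from breakscape.simulate import substream

genome = default_genome()
cfg = SimConfig(seed=42)
genes = build_genome(genome, 300, seed=0, mean_gene_span=15_000,
                     rng=substream(cfg.seed, "genes"))
truth = make_truth(genome, genes, cfg)

breakseq = simulate_coverage(genome, truth, cfg, "B", replicate_index=0)
dnaseq = simulate_coverage(genome, truth, cfg, "B", 0, assay="dnaseq")
normalized = normalize_by_copy_number(breakseq, dnaseq)
peaks = call_peaks(normalized, q_max=0.05)

n_truth = len(truth.hotspots_for_line("B"))
print(f"called {len(peaks)} peaks (truth: {n_truth} line-B hotspots)")
for pk in peaks[:5]:
    print(f"  {pk.chrom}:{pk.start}-{pk.end}  q={pk.qvalue:.2e}  "
          f"signal={pk.normalized_signal_mean:.1f}")
# Each peak is a run of bins whose counts exceed the local Poisson
# background at FDR 5%; q is the BH-corrected tail probability and
# signal the mean normalized count inside the peak.
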