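# Methods

This note records the statistical models behind each pipeline stage,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the design was
genuinely open. No empirical claim is made here that the test suite or
`scripts/acceptance.py` does not itself compute.

## The synthetic experiment

The generator emulates a two-cell-line breakage study: a control line
("A") and a rearranged cancer-like line ("B") profiled by a
DSB-labeling coverage assay (4 replicates per line), one whole-genome
sequencing control per line, RNA counts (4 samples per line), and an
independent patient cohort for biomarker survival analysis.

**Genome.** Two chromosomes: a 5 Mb background chromosome and a 4 Mb
"rearranged arm" analog (`chr16A`) with an arm boundary at 1.5 Mb, an
intact 300 kb pericentromeric stub, a single-copy mid-arm deletion in
line B from 1.80 to 2.91 Mb, and an intact distal arm. The deletion
edges fall on both binning grids (100 bp coverage bins, 15 kb
copy-number bins) so boundary-recovery accuracy is measurable in bin
units. The 300 kb stub width mirrors the scale of a pericentromeric
block left intact by a partial arm loss; it is configurable.

**Coverage.** Bin counts are Poisson with mean
`background_rate x (copy_number / 2) x hotspot_fold x width_fraction`,
where `hotspot_fold` applies only inside hotspots assigned to the
simulated line (or shared) and only for the Break-seq assay; DNA-seq
tracks carry copy-number dosage but no hotspot signal. Defaults:
background 5 reads per 100 bp bin, fold 8, hotspot width 400 bp
(≈ 4 bins, matching the ~400 bp scale of a discrete DSB peak). The
terminal partial bin of each chromosome is kept, with its mean scaled
by its width fraction. Per-replicate depth jitter exists as a config
knob (`libsize_jitter_sd`, lognormal, default 0 = matched depths)
because per-replicate depth variability in real libraries is real but
its magnitude is study-specific.

**Truth layout.** 24 shared hotspots, 8 A-specific, 30 B-specific; of
these, 3 shared + 6 B-specific sit in the stub. Line B carries 25
paired SV junctions: 5 intra- and 6 inter-chromosomal junctions with
one end in the stub (4 and 5 of them respectively placed inside
hotspots — the planted concordance), plus 14 background junctions
placed uniformly. These counts reproduce the qualitative structure the
analysis is designed to detect: breakage in both lines at the
pericentromere, cancer-specific breakage elsewhere on the arm, and
rearrangement junctions concentrated where the cancer-specific breaks
are.

**Expression.** Counts are NB2 (`var = mu + alpha mu^2`, dispersion
`alpha = 0.1`) with per-gene lognormal baselines. Planted fold changes
are applied to line B's means: a 3-gene overexpressed cluster
immediately downstream of the stub, 2 up + 4 down genes within 5 kb of
B-specific hotspots, and ~20 scattered DE genes (≈ 10% of the 300-gene
transcriptome, a realistic DE fraction). Because the toy transcriptome
is small, strong asymmetric DE shifts library composition: CPM
normalization then attenuates measured up-regulation by roughly
1–1.3 log2 units. Planted up-effects are therefore specified larger on
the raw-count scale than the intended measured magnitude; this is a
property of CPM normalization itself (any count-composition change
does this), not of the test statistic, and is invisible in genome-scale
transcriptomes where DE is a small mass fraction.

**Survival.** Marker values are standard lognormal; event times are
exponential with hazard `h0 = 0.1` multiplied by the planted hazard
ratio (default 2.5) when the marker exceeds the planted threshold (the
60th percentile); censoring is an independent exponential whose rate is
chosen so the expected censored fraction in the baseline group equals
`censoring_rate` (default 0.4). Cohort size defaults to 800.

**Reproducibility.** All randomness flows from one master seed through
named substreams (`substream(seed, "coverage", assay, line, rep)`,
`"expression"`, `"survival"`, ...), so any stage can be regenerated
independently and every output file is byte-identical under a fixed
seed.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: read-level artifacts (mappability,
GC bias in Break-seq, PCR duplicates), fragment-level strand structure,
overdispersion of coverage beyond Poisson, correlated replicate noise,
gene-length effects in RNA counts, and non-proportional hazards. The
pipeline's recovery rates quantify algorithmic correctness under the
stated generative model, not end-to-end assay performance.

## Peak calling

The caller is a transparent Poisson local-background test in the
MACS2 family: per-bin `p = P(X >= c)` at
`lambda = max(genome mean, mean over 5 kb flank, mean over 10 kb
flank)`, each local window centered on the bin and excluding it. With
non-integral (normalized) counts the tail is evaluated at `ceil(c)`.
BH is applied genome-wide (one experiment-wide error rate rather than
per-chromosome). Significant bins merge across gaps ≤ 500 bp; peaks
need ≥ 2 bins (≈ 200 bp, consistent with a ~400 bp DSB peak at 100 bp
bins); the summit is the maximum-count bin. Discreteness of the Poisson
tail makes null p-values super-uniform, so the realized false-positive
bin fraction sits below the nominal level — the calibration benchmark
measures this rather than assuming exact uniformity.

Copy-number normalization divides Break-seq counts by
`max(cn_ratio, 0.25)` where `cn_ratio` is the 51-bin running median of
the DNA-seq track over its genome-wide median. The floor prevents
division blow-ups in near-zero-coverage bins; the 51-bin (~5 kb) window
is wide enough to average out Poisson noise at background depth yet
much narrower than any plausible CNV segment. Totals are deliberately
not conserved — the point is to remove dosage, not to renormalize
depth. The paired benchmark in the test suite shows the concrete
benefit: hotspots inside a heterozygous deletion are missed more often
on the raw track than after normalization.

## Consensus and partitioning

"Present in every replicate" is operationalized as the per-base
intersection of replicate indicator functions, merged and filtered at
min width 50 bp. This rule is order-independent, has no seed-peak
asymmetry, and is checkable against a brute-force per-base oracle —
which the acceptance battery does on random 100-interval fixtures.
Cross-line commonality uses ≥ 1 bp overlap (the simplest defensible
default, config-exposed). With these definitions the counting identity
|common| + |specific| = |consensus| holds exactly; published Venn
counts from interval-merging pipelines often do not satisfy such
arithmetic, which is precisely why the rule here is pinned down.

## Copy-number segmentation

Log2 ratios use a pseudo-count of 0.5 against the genome-wide median
bin count. GC correction (when per-bin GC is supplied) divides out a
running-median count-vs-GC trend. Segmentation is recursive binary
splitting: at each level the split maximizing the pooled-variance
two-sample t between left and right means is accepted iff |t| ≥ 5 and
both sides keep ≥ 5 bins; ties break to the leftmost maximizer, making
the procedure fully deterministic. Adjacent segments closer than 0.1
in mean are re-merged. Loss/gain thresholds are ∓0.3 — between 0 and
log2(0.75) ≈ −0.415, the expected ratio of a one-copy loss in a
diploid bulk — and config-exposed. Boundaries are reported between
adjacent segments differing in call or by ≥ 0.3 in mean. This
replaces circular-binary-segmentation-style tooling with a simpler
deterministic equivalent; bit-compatibility with any external
segmenter is a non-goal. Chromosomes are processed whatever their
name; non-autosomes are flagged in the output rather than dropped.

## Structural variants and concordance

Breakpoint ends use the BEDPE interval start as the coordinate (tight
per-end caller output; starts are stable). Records touching chrY,
chrM, or unassigned contigs (name containing `_` or prefixed `Un`)
are dropped and counted; every filtering stage's count is reported
explicitly, since totals under different filters are not comparable.
Intra events count once on their chromosome; inter events count once
on *each* chromosome and once in the symmetric pair matrix, so per-
chromosome inter counts sum to twice the number of inter events.

Concordance counts junction *ends*, not events: a DSB overlapping both
ends of one junction contributes two hits. Windows default to 0 bp for
SV ends (direct overlap) and one 15 kb bin for CNV boundaries (their
position is only bin-resolved). The permutation null redraws DSB start
positions uniformly within their own chromosome, preserving lengths
and non-overlap by rejection sampling, and reports the add-one
estimate `p = (1 + #{null >= obs}) / (n_perm + 1)`, which is never
zero and is conservative in the presence of ties.

## Annotation and enrichment

Classification is single-valued by priority (exon > 5′UTR > 3′UTR >
promoter > downstream > intron > intergenic; first class with ≥ 1 bp
overlap wins). Promoter and downstream spans default to 2 kb,
strand-aware; both are config-exposed since no universal convention
exists. The synthetic gene models carry no UTR records, so those two
classes are structurally present but empty in simulated runs.

Fisher's exact test is implemented in log space over the full
hypergeometric support with the minimum-likelihood two-sided
definition (sum of all tables no more probable than the observed one,
with a 1e-7 relative tolerance against floating-point ties — the
convention of standard statistical software). On the published
intronic-DSB table (142 of 472 vs 20 of 271) this two-sided definition
gives p = 2.4e-14, while the one-sided upper tail gives 1.8e-14 — the
value the source analysis reported. Both are exposed
(`alternative="greater"`), and the implementation is verified to 12
digits against exhaustive rational enumeration on all small tables.

## Differential expression

The test is the study design's own: per-gene one-way ANOVA on
log2(CPM + 1) across the two lines — algebraically the squared
equal-variance two-sample t — with BH FDR and tiered fold-change
thresholds (|log2FC| > 1, 3.5, or 4 as a single config parameter;
different stages of a breakage analysis use different tiers).
Negative-binomial GLMs are deliberately out of scope. log2FC is the
difference of group means of log2(CPM + 1), so antisymmetry under
group swap is exact. Genes with zero variance everywhere get F = 0,
p = 1; zero within-group variance with distinct means gets p = 0.

## Survival

Kaplan–Meier and the two-group log-rank statistic are in-repo
(verified against an independent survival library in the test suite):
`chi2 = (O1 - E1)^2 / V` with hypergeometric variance accumulated over
distinct event times, p from chi-square with 1 df, and
HR = (O1/E1)/(O2/E2) — the log-rank-consistent estimate; Cox
regression is a non-goal. Cut-off optimization scans every distinct
marker value whose split keeps both groups within the [0.10, 0.90]
quantile band and returns the minimum-p cutoff, ties breaking toward
the median. Because a minimum over a scan is optimistic, an optional
permutation correction re-optimizes on marker-shuffled cohorts and
reports the empirical p of the observed minimum; it is off by default
to match how data-driven grouping is commonly practiced, and the test
suite demonstrates the selection effect it corrects.

## Numerical and engineering choices

- Coordinates are 0-based half-open everywhere in memory; GTF output
  is 1-based inclusive per convention.
- BH q-values use stable sorting and reverse cumulative minima; ties
  are handled exactly.
- The Poisson tail for non-integral normalized counts is evaluated at
  the ceiling, the conservative choice.
- Degenerate inputs fail loudly: empty replicate lists, all-zero DNA
  tracks, binning mismatches, constant markers, one-sided splits, and
  unknown config keys all raise informative errors; empty tracks and
  short chromosomes degrade with a warning instead where a result is
  still well-defined.
- Problem sizes in the validation battery (100-seed CNV and cut-off
  recovery, 200-seed permutation calibration, 2000-gene DE fixture)
  were chosen to give stable rate estimates in minutes on one core.

## Known limitations

- The Poisson coverage model understates real Break-seq overdispersion;
  recall/precision benchmarks are upper bounds on real-assay behavior.
- CPM-based fold changes are composition-sensitive in small
  transcriptomes (see above); a median-of-ratios normalization would
  remove this but would depart from the pinned log2-CPM contract.
- The permutation null preserves interval lengths and chromosome
  assignment but not local covariates (GC, gene density), so its p
  answers "is the overlap more than random placement" rather than
  "more than matched-covariate placement".
- The minimum-p cut-off without correction does not control type-I
  error; the corrected variant exists for that purpose.
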