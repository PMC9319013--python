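"""Synthetic two-cell-line experiment with known ground truth.

Emulates the statistical structure of a Break-seq / DNA-seq / RNA-seq /
survival study comparing a rearranged cancer-like line ("B") with a
control line ("A"):

* shared and line-specific DSB hotspots as Poisson coverage enrichments,
* a one-arm partial deletion on one chromosome (the 16q-loss analog)
  with an intact ~300 kb pericentromeric stub,
* paired SV breakpoints, a subset co-located with hotspots in the stub,
* negative-binomial gene expression with planted fold changes in genes
  immediately downstream of the stub,
* a survival cohort whose hazard depends on a planted expression
  threshold.

All randomness flows from one master seed through named substreams so
each stage can be regenerated independently.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeSpec, GeneModelSet
from .tracks import CoverageTrack
from .sv import PairedBreakpoint, make_breakpoint

REFERENCE_PLOIDY = 2
LINES = ("A", "B")


@dataclass(frozen=True)
class SimConfig:
    """Study-level simulation parameters.

    Defaults are the study conditions: 4 Break-seq replicates per line,
    background 5 reads per 100 bp bin, 8-fold hotspot enrichment,
    negative-binomial dispersion 0.1 for RNA counts, an 800-patient
    cohort with 40% censoring.
    """

    seed: int = 0
    n_replicates: int = 4
    background_rate: float = 5.0
    hotspot_fold: float = 8.0
    nb_dispersion: float = 0.1
    cohort_size: int = 800
    censoring_rate: float = 0.4
    libsize_jitter_sd: float = 0.0  # lognormal sd of per-replicate depth

    def __post_init__(self) -> None:
        for name in ("background_rate", "hotspot_fold", "nb_dispersion",
                     "censoring_rate", "libsize_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")


@dataclass
class TruthSet:
    """Planted ground truth for every downstream stage.

    ``hotspots``: (chrom, start, end, line_label in {A, B, shared}, fold).
    ``cnv_truth``: per line, list of (chrom, start, end, copy_number).
    ``sv_truth``: list of (PairedBreakpoint, co_located_with_hotspot).
    ``de_truth``: list of (gene_id, planted log2 fold change, B over A).
    ``survival_truth``: (expression cut-off, hazard ratio above cut-off).
    """

    hotspots: list[tuple[str, int, int, str, float]] = field(default_factory=list)
    cnv_truth: dict[str, list[tuple[str, int, int, float]]] = field(default_factory=dict)
    sv_truth: list[tuple[PairedBreakpoint, bool]] = field(default_factory=list)
    de_truth: list[tuple[str, float]] = field(default_factory=list)
    survival_truth: tuple[float, float] = (1.0, 1.0)

    def validate(self) -> None:
        for _, s, e, label, fold in self.hotspots:
            if e <= s or fold <= 0 or label not in ("A", "B", "shared"):
                raise ValueError("malformed hotspot")
        for line, segs in self.cnv_truth.items():
            for _, s, e, cn in segs:
                if cn <= 0:
                    raise ValueError("planted copy numbers must be > 0")
        for bp, co_located in self.sv_truth:
            if co_located and not any(
                e.chrom == c and s <= e.pos < en
                for e in bp.ends for c, s, en, _, _ in self.hotspots
            ):
                raise ValueError(
                    f"co_located breakpoint {bp.source_id} outside all hotspots")

    def hotspots_for_line(self, line_label: str
                          ) -> list[tuple[str, int, int, float]]:
        return [(c, s, e, f) for c, s, e, label, f in self.hotspots
                if label in (line_label, "shared")]

    # -- JSON manifest round-trip --------------------------------------

    def to_json(self, path) -> None:
        obj = {
            "hotspots": [list(h) for h in self.hotspots],
            "cnv_truth": {k: [list(s) for s in v]
                          for k, v in self.cnv_truth.items()},
            "sv_truth": [
                [bp.end1.chrom, bp.end1.pos, bp.end1.strand,
                 bp.end2.chrom, bp.end2.pos, bp.end2.strand,
                 bp.source_id, bool(co)]
                for bp, co in self.sv_truth
            ],
            "de_truth": [list(d) for d in self.de_truth],
            "survival_truth": list(self.survival_truth),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            hotspots=[(c, s, e, l, f) for c, s, e, l, f in obj["hotspots"]],
            cnv_truth={k: [(c, s, e, cn) for c, s, e, cn in v]
                       for k, v in obj["cnv_truth"].items()},
            sv_truth=[
                (make_breakpoint(c1, p1, c2, p2, s1, s2, sid), bool(co))
                for c1, p1, s1, c2, p2, s2, sid, co in obj["sv_truth"]
            ],
            de_truth=[(g, f) for g, f in obj["de_truth"]],
            survival_truth=tuple(obj["survival_truth"]),
        )


def substream(seed: int, *keys) -> np.random.Generator:
    """Named child RNG stream of the master seed.

    String keys are hashed with crc32 so coverage/expression/survival
    streams are independent and individually reproducible.
    """
    ints = [int(seed)]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode()))
        else:
            ints.append(int(k))
    return np.random.default_rng(np.random.SeedSequence(ints))


# ---------------------------------------------------------------------
# Default experiment layout
# ---------------------------------------------------------------------

def default_genome() -> GenomeSpec:
    """Two-chromosome toy genome: a background chromosome and a
    rearranged-arm analog carrying the planted deletion."""
    return GenomeSpec(chromosomes=(("chr1", 5_000_000), ("chr16A", 4_000_000)))


# 16q-analog layout on chr16A: arm boundary at 1.5 Mb, intact 300 kb
# pericentromeric stub, mid-arm deletion, intact distal arm.
ARM_BOUNDARY = 1_500_000
STUB_SIZE = 300_000
DELETION = (ARM_BOUNDARY + STUB_SIZE, 2_910_000)


def make_truth(genome: GenomeSpec, genes: GeneModelSet, cfg: SimConfig,
               n_shared: int = 24, n_a_specific: int = 8,
               n_b_specific: int = 30, hotspot_width: int = 400,
               survival_hr: float = 2.5) -> TruthSet:
    """Plant the full ground truth for the default experiment.

    Line B (the cancer analog) gets more specific hotspots than line A,
    a copy-number-1 mid-arm deletion on chr16A with an intact stub, SV
    junction ends clustered in the stub (5 intra / 6 inter, of which
    4 and 5 are co-located with hotspots), planted 4-log2FC
    overexpression in the genes immediately downstream of the stub, and
    a survival cut-off at the marker's 60th percentile.
    """
    rng = substream(cfg.seed, "truth")
    truth = TruthSet()

    stub = (ARM_BOUNDARY, ARM_BOUNDARY + STUB_SIZE)

    # --- hotspots: stub cluster first (shared + B-specific, mirroring
    # pericentromeric breakage in both lines with extra cancer breaks)
    stub_shared = _place_intervals(rng, "chr16A", stub, 3, hotspot_width)
    stub_b = _place_intervals(rng, "chr16A", stub, 6, hotspot_width,
                              avoid=stub_shared)
    for s, e in stub_shared:
        truth.hotspots.append(("chr16A", s, e, "shared", cfg.hotspot_fold))
    for s, e in stub_b:
        truth.hotspots.append(("chr16A", s, e, "B", cfg.hotspot_fold))

    # --- genome-wide hotspots away from the stub
    taken = list(stub_shared) + list(stub_b)
    spans = {"chr1": (0, genome.length_of("chr1")),
             "chr16A": (0, genome.length_of("chr16A"))}
    for label, n in (("shared", n_shared - len(stub_shared)),
                     ("A", n_a_specific),
                     ("B", n_b_specific - len(stub_b))):
        for _ in range(n):
            chrom = "chr1" if rng.random() < 0.6 else "chr16A"
            avoid = [iv for c, s, e, *_ in truth.hotspots if c == chrom
                     for iv in [(s, e)]]
            if chrom == "chr16A":
                avoid = avoid + [stub]
            (s, e), = _place_intervals(rng, chrom, spans[chrom], 1,
                                       hotspot_width, avoid=avoid)
            truth.hotspots.append((chrom, s, e, label, cfg.hotspot_fold))
    truth.hotspots.sort(key=lambda h: (h[0], h[1]))

    # --- copy number: line A diploid everywhere; line B loses one copy
    # of the mid-arm of chr16A (stub and distal arm intact)
    truth.cnv_truth["A"] = [(c, 0, genome.length_of(c), 2.0)
                            for c in genome.names]
    truth.cnv_truth["B"] = [
        ("chr1", 0, genome.length_of("chr1"), 2.0),
        ("chr16A", 0, DELETION[0], 2.0),
        ("chr16A", DELETION[0], DELETION[1], 1.0),
        ("chr16A", DELETION[1], genome.length_of("chr16A"), 2.0),
    ]

    # --- SV breakpoints for line B: 5 intra and 6 inter junction ends in
    # the stub; 4 intra and 5 inter co-located with hotspots there
    stub_hot = [(s, e) for c, s, e, l, _ in truth.hotspots
                if c == "chr16A" and l in ("B", "shared")
                and stub[0] <= s and e <= stub[1]]
    bid = 0

    def hot_pos(i):
        s, e = stub_hot[i % len(stub_hot)]
        return int(rng.integers(s, e))

    def cold_pos():
        # stub position outside every hotspot
        while True:
            p = int(rng.integers(stub[0], stub[1]))
            if not any(s <= p < e for s, e in stub_hot):
                return p

    for i in range(5):  # intra-chromosomal junctions with one end in stub
        co = i < 4
        p1 = hot_pos(i) if co else cold_pos()
        p2 = int(rng.integers(3_000_000, 3_900_000))  # distal partner
        truth.sv_truth.append(
            (make_breakpoint("chr16A", p1, "chr16A", p2, "+", "-",
                             f"sv_intra_stub_{bid}"), co))
        bid += 1
    for i in range(6):  # inter-chromosomal (translocation) junctions
        co = i < 5
        p1 = hot_pos(i + 5) if co else cold_pos()
        p2 = int(rng.integers(0, genome.length_of("chr1")))
        truth.sv_truth.append(
            (make_breakpoint("chr16A", p1, "chr1", p2, "+", "+",
                             f"sv_inter_stub_{bid}"), co))
        bid += 1
    # background rearrangements elsewhere, not tied to hotspots
    for i in range(14):
        c1 = "chr1" if rng.random() < 0.5 else "chr16A"
        c2 = "chr1" if rng.random() < 0.8 else "chr16A"
        truth.sv_truth.append(
            (make_breakpoint(c1, int(rng.integers(0, spans[c1][1])),
                             c2, int(rng.integers(0, spans[c2][1])),
                             "+", "-", f"sv_bg_{bid}"), False))
        bid += 1

    # --- differential expression: genes downstream of the stub planted
    # at +4 log2FC (the overexpressed-cluster analog), plus scattered
    # up/down genes near B-specific hotspots and at random
    downstream = [g for g in genes
                  if g.chrom == "chr16A" and stub[1] <= g.start
                  and g.start < stub[1] + 400_000]
    planted: dict[str, float] = {}
    for g in downstream[:3]:
        planted[g.gene_id] = 5.0
    b_specific = [(c, s, e) for c, s, e, l, _ in truth.hotspots if l == "B"]
    near_hot = [g for g in genes if g.gene_id not in planted and any(
        g.chrom == c and g.start - 5000 <= e and s <= g.end + 5000
        for c, s, e in b_specific)]
    # raw-count fold changes; CPM composition shift in the small
    # transcriptome attenuates measured up-regulation, so up effects are
    # planted larger than the intended measured magnitude
    for g in near_hot[:2]:
        planted[g.gene_id] = 6.0
    for g in near_hot[2:6]:
        planted[g.gene_id] = -4.5
    others = [g.gene_id for g in genes if g.gene_id not in planted]
    rng.shuffle(others)
    n_extra = max(0, min(len(others), 20))
    for gid in others[:n_extra // 2]:
        planted[gid] = float(rng.uniform(4.0, 6.0))
    for gid in others[n_extra // 2:n_extra]:
        planted[gid] = float(-rng.uniform(4.0, 6.0))
    truth.de_truth = sorted(planted.items())

    # --- survival: cut-off at the 60th percentile of the lognormal marker
    from scipy.stats import norm
    cutoff = float(np.exp(norm.ppf(0.60)))
    truth.survival_truth = (cutoff, survival_hr)

    truth.validate()
    return truth


def _place_intervals(rng, chrom, span, n, width, avoid=()):
    """Place n non-overlapping width-bp intervals uniformly in span,
    rejection-sampling collisions against each other and ``avoid``."""
    placed: list[tuple[int, int]] = []
    lo, hi = span
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > 10000 * max(n, 1):
            raise RuntimeError("could not place intervals without overlap")
        s = int(rng.integers(lo, hi - width))
        e = s + width
        if any(s < be and bs < e for bs, be in list(placed) + list(avoid)):
            continue
        placed.append((s, e))
    return placed


# ---------------------------------------------------------------------
# Coverage simulation
# ---------------------------------------------------------------------

def simulate_coverage(spec: GenomeSpec, truth: TruthSet, cfg: SimConfig,
                      line_label: str, replicate_index: int,
                      assay: str = "breakseq") -> CoverageTrack:
    """Draw one binned coverage track.

    Per-bin counts are Poisson with mean
    ``background_rate * cn_scale * hotspot_scale * depth_factor`` where
    ``cn_scale`` is the planted copy number over the reference ploidy
    and ``hotspot_scale`` is the hotspot fold inside hotspots assigned
    to this line (or shared), 1 elsewhere. DNA-seq tracks carry no
    hotspot signal (``hotspot_scale == 1``).
    """
    if line_label not in LINES:
        raise ValueError(f"unknown line label {line_label!r}")
    if assay not in ("breakseq", "dnaseq"):
        raise ValueError(f"unknown assay {assay!r}")
    if assay == "breakseq" and not 0 <= replicate_index < cfg.n_replicates:
        raise ValueError("replicate_index out of range")

    rng = substream(cfg.seed, "coverage", assay, line_label, replicate_index)
    depth_factor = 1.0
    if cfg.libsize_jitter_sd > 0:
        depth_factor = float(rng.lognormal(
            -0.5 * cfg.libsize_jitter_sd ** 2, cfg.libsize_jitter_sd))

    track = CoverageTrack(bin_size=spec.bin_size_cov)
    hotspots = truth.hotspots_for_line(line_label) if assay == "breakseq" else []
    cnv = truth.cnv_truth.get(line_label, [])
    for chrom in spec.names:
        starts, ends = spec.bin_edges(chrom, spec.bin_size_cov)
        lam = np.full(starts.shape, cfg.background_rate, dtype=float)
        # copy-number scaling at bin midpoints
        mids = (starts + ends) // 2
        for c, s, e, cn in cnv:
            if c == chrom:
                mask = (mids >= s) & (mids < e)
                lam[mask] *= cn / REFERENCE_PLOIDY
        for c, s, e, fold in hotspots:
            if c == chrom:
                mask = (mids >= s) & (mids < e)
                lam[mask] *= fold
        # terminal partial bin: mean scales with bin width
        widths = (ends - starts) / spec.bin_size_cov
        counts = rng.poisson(lam * widths * depth_factor)
        track.add_chrom(chrom, starts, ends, counts)
    return track


# ---------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------

def simulate_expression(gene_models: GeneModelSet,
                        de_truth: list[tuple[str, float]],
                        cfg: SimConfig,
                        n_per_group: int | None = None,
                        baseline_mean: float = 200.0) -> pd.DataFrame:
    """Negative-binomial gene x sample count matrix for the two lines.

    Per-gene baseline means are lognormal around ``baseline_mean``; the
    planted fold change multiplies line B means. Columns are labelled
    ``A_1..A_n, B_1..B_n``. Counts use the NB2 parameterisation
    (variance = mu + dispersion * mu^2).
    """
    known = {g.gene_id for g in gene_models}
    for gid, _ in de_truth:
        if gid not in known:
            raise ValueError(f"de_truth references unknown gene {gid!r}")
    n = n_per_group if n_per_group is not None else cfg.n_replicates
    rng = substream(cfg.seed, "expression")
    gene_ids = [g.gene_id for g in gene_models]
    fc = dict(de_truth)
    base = baseline_mean * rng.lognormal(-0.5, 1.0, size=len(gene_ids))
    base = np.maximum(base, 1.0)
    r = 1.0 / cfg.nb_dispersion  # NB size parameter

    cols = {}
    for line in LINES:
        mult = np.array([2.0 ** fc.get(g, 0.0) if line == "B" else 1.0
                         for g in gene_ids])
        mu = base * mult
        for j in range(n):
            p = r / (r + mu)
            cols[f"{line}_{j + 1}"] = rng.negative_binomial(r, p)
    mat = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    return mat


# ---------------------------------------------------------------------
# Survival simulation
# ---------------------------------------------------------------------

def simulate_survival_cohort(cfg: SimConfig,
                             survival_truth: tuple[float, float],
                             baseline_hazard: float = 0.1) -> pd.DataFrame:
    """Cohort with marker-dependent hazard.

    Marker values are standard lognormal; event times are exponential
    with hazard multiplied by the truth hazard ratio when the marker
    exceeds the planted cut-off; censoring is an independent exponential
    whose rate is set so the expected censored fraction matches
    ``cfg.censoring_rate`` in the baseline group.
    """
    cutoff, hr = survival_truth
    rng = substream(cfg.seed, "survival")
    n = cfg.cohort_size
    marker = rng.lognormal(0.0, 1.0, size=n)
    hazard = baseline_hazard * np.where(marker > cutoff, hr, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    if cfg.censoring_rate > 0:
        c_rate = baseline_hazard * cfg.censoring_rate / (1 - cfg.censoring_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({
        "patient_id": [f"P{i:04d}" for i in range(n)],
        "time": np.maximum(time, 1e-9),
        "event": event,
        "marker": marker,
    })
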