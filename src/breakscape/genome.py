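"""Genome and gene-model containers for the synthetic two-cell-line experiment.

Coordinates are 0-based half-open throughout, matching BED conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome names/lengths plus the two binning resolutions.

    ``bin_size_cov`` is the fine binning used for Break-seq / DNA-seq
    coverage tracks; ``bin_size_cnv`` is the coarse binning used for copy
    number profiling (15 kb by default, the standard shallow-WGS segment
    size).
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_size_cov: int = 100
    bin_size_cnv: int = 15_000

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome must contain at least one chromosome")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        if self.bin_size_cov <= 0 or self.bin_size_cnv <= 0:
            raise ValueError("bin sizes must be positive")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    def length_of(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    def n_bins(self, chrom: str, bin_size: int) -> int:
        # terminal partial bins are kept (flagged by their short width)
        return -(-self.length_of(chrom) // bin_size)

    def bin_edges(self, chrom: str, bin_size: int) -> tuple[np.ndarray, np.ndarray]:
        """Start/end arrays of the bins tiling ``chrom``."""
        length = self.length_of(chrom)
        starts = np.arange(0, length, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, length)
        return starts, ends


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass
class GeneModelSet:
    """Sorted, non-overlapping gene models over a :class:`GenomeSpec`."""

    genes: list[Gene] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def by_chrom(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        for genes in out.values():
            genes.sort(key=lambda g: (g.start, g.end))
        return out

    def get(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def to_gtf(self, path) -> None:
        """Write a minimal GTF-like file (1-based inclusive on disk)."""
        with open(path, "w") as fh:
            for g in sorted(self.genes, key=lambda g: (g.chrom, g.start)):
                attrs = f'gene_id "{g.gene_id}";'
                fh.write(
                    f"{g.chrom}\tbreakscape\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )
                for (es, ee) in g.exons:
                    fh.write(
                        f"{g.chrom}\tbreakscape\texon\t{es + 1}\t{ee}\t.\t"
                        f"{g.strand}\t.\t{attrs}\n"
                    )

    @classmethod
    def from_gtf(cls, path) -> "GeneModelSet":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "source", "feature", "start", "end", "score",
                   "strand", "frame", "attrs"],
            dtype={"chrom": str},
        )
        genes: dict[str, dict] = {}
        order: list[str] = []
        for row in df.itertuples(index=False):
            gid = row.attrs.split('"')[1]
            if row.feature == "gene":
                genes[gid] = dict(chrom=row.chrom, start=row.start - 1,
                                  end=row.end, strand=row.strand, exons=[])
                order.append(gid)
            elif row.feature == "exon":
                genes[gid]["exons"].append((row.start - 1, row.end))
        return cls([
            Gene(gene_id=gid, chrom=d["chrom"], start=d["start"], end=d["end"],
                 strand=d["strand"], exons=tuple(sorted(d["exons"])))
            for gid, d in ((g, genes[g]) for g in order)
        ])


def build_genome(spec: GenomeSpec, n_genes: int, seed: int,
                 mean_gene_span: int = 30_000, rng: np.random.Generator | None = None
                 ) -> GeneModelSet:
    """Place ``n_genes`` non-overlapping genes on the genome.

    Gene spans are drawn around ``mean_gene_span``; each gene receives
    1-10 non-overlapping exons. Deterministic for a fixed seed. Raises
    ``ValueError`` when the sampled gene spans cannot fit in the genome.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_genes == 0:
        return GeneModelSet([])

    total_len = sum(length for _, length in spec.chromosomes)
    # spans: gamma around the mean, floored at 1 kb
    spans = np.maximum(
        rng.gamma(shape=4.0, scale=mean_gene_span / 4.0, size=n_genes), 1000
    ).astype(np.int64)
    # require spans plus 1 kb inter-gene gaps to fit
    if spans.sum() + 1000 * n_genes > total_len:
        raise ValueError(
            f"genome too small: {n_genes} genes with total span {spans.sum()} "
            f"(+ gaps) exceed genome length {total_len}"
        )

    # allot genes to chromosomes proportionally to length, then lay out
    # left-to-right with random gaps
    genes: list[Gene] = []
    chrom_weights = np.array([l for _, l in spec.chromosomes], dtype=float)
    chrom_idx = rng.choice(len(spec.chromosomes), size=n_genes,
                           p=chrom_weights / chrom_weights.sum())
    gid = 0
    for ci, (chrom, length) in enumerate(spec.chromosomes):
        my_spans = spans[chrom_idx == ci]
        if my_spans.size == 0:
            continue
        slack = length - my_spans.sum()
        if slack < 1000 * my_spans.size:
            raise ValueError(
                f"chromosome {chrom} too small for its allotted genes"
            )
        # random gap layout: split the slack into n+1 pieces
        cuts = np.sort(rng.integers(0, slack - 1000 * my_spans.size + 1,
                                    size=my_spans.size))
        pos = 0
        prev_cut = 0
        for j, span in enumerate(my_spans):
            gap = int(cuts[j] - prev_cut) + 1000
            prev_cut = cuts[j]
            start = pos + gap
            end = start + int(span)
            pos = end
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(
                gene_id=f"G{gid:05d}", chrom=chrom, start=int(start),
                end=int(end), strand=strand,
                exons=_sample_exons(rng, int(start), int(end)),
            ))
            gid += 1
    genes.sort(key=lambda g: (g.chrom, g.start))
    return GeneModelSet(genes)


def _sample_exons(rng: np.random.Generator, start: int, end: int
                  ) -> tuple[tuple[int, int], ...]:
    span = end - start
    n_exons = int(rng.integers(1, 11))
    if n_exons == 1:
        return ((start, end),)
    # cut the gene body into 2*n-1 alternating exon/intron blocks
    n_blocks = 2 * n_exons - 1
    w = rng.dirichlet(np.ones(n_blocks)) * span
    w = np.maximum(w, 1.0)
    bounds = start + np.round(np.cumsum(w) * (span / w.sum())).astype(np.int64)
    bounds = np.clip(bounds, start + 1, end)
    edges = np.concatenate([[start], bounds])
    exons = []
    for i in range(0, n_blocks, 2):
        es, ee = int(edges[i]), int(edges[i + 1])
        if ee > es:
            exons.append((es, ee))
    if not exons:
        exons = [(start, end)]
    # last exon ends at gene end
    exons[-1] = (exons[-1][0], end)
    return tuple(exons)
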