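"""Binned coverage tracks and bedGraph I/O."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CoverageTrack:
    """Chromosome-ordered binned coverage.

    For each chromosome: sorted, non-overlapping, constant-width bins
    (the terminal bin may be shorter). Counts are non-negative but not
    necessarily integral (copy-number normalization rescales them).
    """

    bin_size: int
    chroms: list[str] = field(default_factory=list)
    starts: dict[str, np.ndarray] = field(default_factory=dict)
    ends: dict[str, np.ndarray] = field(default_factory=dict)
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    def add_chrom(self, chrom: str, starts: np.ndarray, ends: np.ndarray,
                  counts: np.ndarray) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        counts = np.asarray(counts, dtype=float)
        if not (len(starts) == len(ends) == len(counts)):
            raise ValueError("start/end/count arrays differ in length")
        if np.any(counts < 0):
            raise ValueError("negative counts")
        if len(starts) > 1 and np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"overlapping bins on {chrom}")
        self.chroms.append(chrom)
        self.starts[chrom] = starts
        self.ends[chrom] = ends
        self.counts[chrom] = counts

    @property
    def total_count(self) -> float:
        return float(sum(c.sum() for c in self.counts.values()))

    def all_counts(self) -> np.ndarray:
        if not self.chroms:
            return np.array([])
        return np.concatenate([self.counts[c] for c in self.chroms])

    def same_binning(self, other: "CoverageTrack") -> bool:
        if self.chroms != other.chroms:
            return False
        return all(
            np.array_equal(self.starts[c], other.starts[c])
            and np.array_equal(self.ends[c], other.ends[c])
            for c in self.chroms
        )

    def copy_with_counts(self, new_counts: dict[str, np.ndarray]
                         ) -> "CoverageTrack":
        out = CoverageTrack(bin_size=self.bin_size)
        for c in self.chroms:
            out.add_chrom(c, self.starts[c], self.ends[c], new_counts[c])
        return out

    # -- bedGraph I/O --------------------------------------------------

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for c in self.chroms:
                for s, e, v in zip(self.starts[c], self.ends[c], self.counts[c]):
                    fh.write(f"{c}\t{s}\t{e}\t{v:g}\n")

    @classmethod
    def from_bedgraph(cls, path, bin_size: int | None = None) -> "CoverageTrack":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "count"],
                         dtype={"chrom": str})
        if bin_size is None:
            if len(df):
                bin_size = int((df["end"] - df["start"]).max())
            else:
                bin_size = 1
        track = cls(bin_size=bin_size)
        for chrom, grp in df.groupby("chrom", sort=False):
            grp = grp.sort_values("start")
            track.add_chrom(chrom, grp["start"].to_numpy(),
                            grp["end"].to_numpy(), grp["count"].to_numpy())
        return track
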