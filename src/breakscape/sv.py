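"""Paired structural-variant breakpoints: BEDPE ingestion, filtering,
intra/inter classification, per-chromosome tallies, and between-sample
deltas.

Split-read SV *detection* is out of scope; breakpoints arrive as BEDPE
from an external caller. The breakpoint coordinate of each end is the
BEDPE interval start (tight per-end intervals; starts are stable).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

DEFAULT_EXCLUDED = frozenset({"chrY", "chrM"})
UNASSIGNED_PATTERN = re.compile(r"_|^chrUn|^Un")


@dataclass(frozen=True)
class BreakpointEnd:
    chrom: str
    pos: int
    strand: str = "."


@dataclass(frozen=True)
class PairedBreakpoint:
    """A two-ended rearrangement junction.

    ``svclass`` is ``intra`` iff both ends are on the same chromosome.
    Canonical ordering (end1 <= end2 by chromosome then position) is
    enforced on construction via :func:`make_breakpoint`.
    """

    end1: BreakpointEnd
    end2: BreakpointEnd
    source_id: str = "."

    @property
    def svclass(self) -> str:
        return "intra" if self.end1.chrom == self.end2.chrom else "inter"

    @property
    def ends(self) -> tuple[BreakpointEnd, BreakpointEnd]:
        return (self.end1, self.end2)


def make_breakpoint(chrom1: str, pos1: int, chrom2: str, pos2: int,
                    strand1: str = ".", strand2: str = ".",
                    source_id: str = ".") -> PairedBreakpoint:
    e1 = BreakpointEnd(chrom1, int(pos1), strand1)
    e2 = BreakpointEnd(chrom2, int(pos2), strand2)
    if (e1.chrom, e1.pos) > (e2.chrom, e2.pos):
        e1, e2 = e2, e1
    return PairedBreakpoint(end1=e1, end2=e2, source_id=source_id)


def is_excluded_contig(name: str,
                       excluded: frozenset[str] = DEFAULT_EXCLUDED) -> bool:
    return name in excluded or bool(UNASSIGNED_PATTERN.search(name))


def load_bedpe(path, excluded_contigs: frozenset[str] = DEFAULT_EXCLUDED
               ) -> tuple[list[PairedBreakpoint], dict]:
    """Read a BEDPE file, dropping records that touch excluded contigs.

    Y chromosome, mitochondrial sequence and unassigned contigs (names
    containing ``_`` or prefixed ``Un``) are excluded by default. Returns
    the kept breakpoints plus an exclusion report with per-stage counts
    and the line numbers of malformed records.
    """
    kept: list[PairedBreakpoint] = []
    report = {"total": 0, "excluded_contig": 0, "malformed_lines": []}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                report["malformed_lines"].append(lineno)
                continue
            try:
                c1, s1 = fields[0], int(fields[1])
                c2, s2 = fields[3], int(fields[4])
            except ValueError:
                report["malformed_lines"].append(lineno)
                continue
            report["total"] += 1
            name = fields[6] if len(fields) > 6 else f"bp{lineno}"
            st1 = fields[8] if len(fields) > 9 else "."
            st2 = fields[9] if len(fields) > 9 else "."
            if is_excluded_contig(c1, excluded_contigs) or \
                    is_excluded_contig(c2, excluded_contigs):
                report["excluded_contig"] += 1
                continue
            kept.append(make_breakpoint(c1, s1, c2, s2, st1, st2, name))
    report["kept"] = len(kept)
    return kept, report


def write_bedpe(breakpoints: list[PairedBreakpoint], path) -> None:
    with open(path, "w") as fh:
        for bp in breakpoints:
            fh.write(
                f"{bp.end1.chrom}\t{bp.end1.pos}\t{bp.end1.pos + 1}\t"
                f"{bp.end2.chrom}\t{bp.end2.pos}\t{bp.end2.pos + 1}\t"
                f"{bp.source_id}\t.\t{bp.end1.strand}\t{bp.end2.strand}\n"
            )


def classify_and_tally(breakpoints: list[PairedBreakpoint]
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-chromosome intra/inter tallies plus the inter-chromosomal pair
    matrix (Circos-table layout).

    Each intra event adds 1 to its chromosome's intra count; each inter
    event adds 1 to BOTH chromosomes' inter counts and 1 to the symmetric
    pair-matrix cell.
    """
    chroms = sorted({e.chrom for bp in breakpoints for e in bp.ends})
    intra = {c: 0 for c in chroms}
    inter = {c: 0 for c in chroms}
    matrix = pd.DataFrame(0, index=chroms, columns=chroms, dtype=int)
    for bp in breakpoints:
        if bp.svclass == "intra":
            intra[bp.end1.chrom] += 1
        else:
            inter[bp.end1.chrom] += 1
            inter[bp.end2.chrom] += 1
            matrix.loc[bp.end1.chrom, bp.end2.chrom] += 1
            matrix.loc[bp.end2.chrom, bp.end1.chrom] += 1
    tally = pd.DataFrame({
        "chrom": chroms,
        "intra": [intra[c] for c in chroms],
        "inter": [inter[c] for c in chroms],
    })
    return tally, matrix


def sv_delta(total_a: int, total_b: int) -> dict:
    """Percent change in total paired-variant count from sample A to B.

    ``percent_change = 100 * (total_b - total_a) / total_a``; reported as
    not-applicable when A has zero events.
    """
    if total_a < 0 or total_b < 0:
        raise ValueError("totals must be non-negative")
    if total_a == 0:
        return {"total_a": total_a, "total_b": total_b,
                "difference": total_b - total_a, "percent_change": None}
    return {
        "total_a": total_a,
        "total_b": total_b,
        "difference": total_b - total_a,
        "percent_change": 100.0 * (total_b - total_a) / total_a,
    }


def tally_delta(tally_a: pd.DataFrame, tally_b: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome difference report between two tallies."""
    a = tally_a.set_index("chrom")
    b = tally_b.set_index("chrom")
    idx = sorted(set(a.index) | set(b.index))
    out = pd.DataFrame(index=idx)
    for col in ("intra", "inter"):
        out[f"{col}_a"] = a[col].reindex(idx).fillna(0).astype(int)
        out[f"{col}_b"] = b[col].reindex(idx).fillna(0).astype(int)
        out[f"{col}_delta"] = out[f"{col}_b"] - out[f"{col}_a"]
    return out.reset_index(names="chrom")
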