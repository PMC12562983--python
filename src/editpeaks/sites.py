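"""Strand-aware A-to-I editing-site calling inside inosine peaks.

Inosine is read as guanosine by the sequencer, so editing shows up as A->G
mismatches on plus-strand transcripts and T->C mismatches (in
reference-forward coordinates) on minus-strand transcripts.  Sites are
called from simple per-column pileups of the enrichment library and are
reported only when all four filter clauses hold:

* the position lies inside a high-confidence inosine peak;
* the mismatch matches the peak's strand context (A->G on '+', T->C on '-');
* column depth is strictly greater than 5 reads;
* the variant rate (alt reads / column depth) is at least 10%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .peaks import Peak

MAX_PILEUP_DEPTH = 20000
BASES = ("A", "C", "G", "T")


@dataclass
class PileupColumn:
    """Base counts at one reference position, split by read strand."""

    contig: str
    pos: int
    ref_base: str
    counts: dict[str, dict[str, int]]  # strand -> base -> reads
    depth: int

    def base_count(self, base: str) -> int:
        return sum(self.counts[s].get(base, 0) for s in self.counts)


@dataclass
class EditingSite:
    contig: str
    pos: int
    strand: str
    depth: int
    alt_count: int
    rate: float
    peak_id: str = ""


def _parse_overrides(spec: str) -> list[tuple[int, str]]:
    if not spec:
        return []
    out = []
    for item in spec.split(";"):
        pos_s, _, base = item.partition(":")
        out.append((int(pos_s), base))
    return out


def pileup(
    reads: pd.DataFrame,
    genome: Mapping[str, str],
    regions: Iterable[tuple[str, int, int]],
    max_depth: int = MAX_PILEUP_DEPTH,
) -> list[PileupColumn]:
    """Per-column base counts over the given regions from mapped reads.

    A read's base at a position is its override entry if present, else the
    reference base.  Columns deeper than ``max_depth`` are truncated to the
    first ``max_depth`` covering reads in (start, read_id) order, mirroring
    the depth cap of conventional pileup engines.  Columns with zero depth
    are omitted.
    """
    columns: list[PileupColumn] = []
    for contig, r_start, r_end in regions:
        if contig not in genome:
            raise ValueError(f"region contig {contig} absent from genome")
        seq = genome[contig]
        if r_start < 0 or r_end > len(seq):
            raise ValueError(f"region {contig}:{r_start}-{r_end} outside contig")
        sub = reads[
            (reads["contig"] == contig)
            & (reads["start"] < r_end)
            & (reads["start"] + reads["length"] > r_start)
        ]
        if sub.empty:
            continue
        sub = sub.sort_values(["start", "read_id"], kind="mergesort")
        starts = sub["start"].to_numpy()
        lengths = sub["length"].to_numpy()
        strands = sub["strand"].to_numpy()
        ends = starts + lengths
        width = r_end - r_start
        # depth per strand via difference arrays
        cov = {s: np.zeros(width + 1, dtype=np.int64) for s in ("+", "-")}
        for s in ("+", "-"):
            m = strands == s
            a = np.clip(starts[m] - r_start, 0, width)
            b = np.clip(ends[m] - r_start, 0, width)
            np.add.at(cov[s], a, 1)
            np.add.at(cov[s], b, -1)
        depth_by_strand = {s: np.cumsum(cov[s][:-1]) for s in ("+", "-")}
        # override (alt-base) counts per column
        alt: dict[int, dict[str, dict[str, int]]] = {}
        for start, end, strand, spec in zip(
            starts, ends, strands, sub["overrides"].to_numpy()
        ):
            for pos, base in _parse_overrides(spec):
                if r_start <= pos < r_end and start <= pos < end:
                    d = alt.setdefault(pos, {"+": {}, "-": {}})[strand]
                    d[base] = d.get(base, 0) + 1
        total_depth = depth_by_strand["+"] + depth_by_strand["-"]
        capped = np.nonzero(total_depth > max_depth)[0]
        for off in range(width):
            depth = int(total_depth[off])
            if depth == 0:
                continue
            pos = r_start + off
            ref = seq[pos].upper()
            counts = {"+": {}, "-": {}}
            for s in ("+", "-"):
                n_alt_s = sum(alt.get(pos, {"+": {}, "-": {}})[s].values())
                ref_n = int(depth_by_strand[s][off]) - n_alt_s
                if ref_n:
                    counts[s][ref] = ref_n
                for base, n in alt.get(pos, {"+": {}, "-": {}})[s].items():
                    counts[s][base] = counts[s].get(base, 0) + n
            columns.append(PileupColumn(contig, pos, ref, counts, depth))
        # re-tally truncated columns read-by-read over the first max_depth reads
        for off in capped:
            pos = r_start + int(off)
            covering = [
                i
                for i in range(len(starts))
                if starts[i] <= pos < ends[i]
            ][:max_depth]
            counts = {"+": {}, "-": {}}
            ov_specs = sub["overrides"].to_numpy()
            for i in covering:
                base = genome[contig][pos].upper()
                for p, b in _parse_overrides(ov_specs[i]):
                    if p == pos:
                        base = b
                d = counts[strands[i]]
                d[base] = d.get(base, 0) + 1
            col = next(c for c in columns if c.contig == contig and c.pos == pos)
            col.counts = counts
            col.depth = len(covering)
    return columns


def call_editing_sites(
    columns: Iterable[PileupColumn],
    peaks: Sequence[Peak],
    min_rate: float = 0.10,
    min_depth_exclusive: int = 5,
) -> list[EditingSite]:
    """Report A->G (or T->C for minus-strand context) sites inside peaks.

    Depth must be strictly greater than ``min_depth_exclusive`` and the
    variant rate (alt reads over total column depth, both read strands
    jointly) at least ``min_rate``.  Only the A->G / T->C component of a
    multi-allelic column is evaluated.  Output is sorted by (contig, pos).
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.contig, IntervalTree()).addi(p.start, p.end, p)
    sites: list[EditingSite] = []
    seen: set[tuple[str, int, str]] = set()
    for col in columns:
        tree = trees.get(col.contig)
        if tree is None:
            continue
        for iv in sorted(tree[col.pos], key=lambda iv: iv.begin):
            peak: Peak = iv.data
            if peak.strand == "+" and col.ref_base == "A":
                alt_base = "G"
            elif peak.strand == "-" and col.ref_base == "T":
                alt_base = "C"
            else:
                continue
            if col.depth <= min_depth_exclusive:
                continue
            alt = col.base_count(alt_base)
            rate = alt / col.depth
            if rate < min_rate:
                continue
            key = (col.contig, col.pos, peak.strand)
            if key in seen:
                continue
            seen.add(key)
            sites.append(
                EditingSite(
                    contig=col.contig,
                    pos=col.pos,
                    strand=peak.strand,
                    depth=col.depth,
                    alt_count=alt,
                    rate=rate,
                    peak_id=peak.name,
                )
            )
    sites.sort(key=lambda s: (s.contig, s.pos))
    return sites


def editing_density(sites: Sequence[EditingSite], peak: Peak) -> float:
    """Editing-site density of a peak, in sites per 100 bases."""
    if peak.end <= peak.start:
        raise ValueError("peak has non-positive width")
    return 100.0 * len(sites) / (peak.end - peak.start)
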