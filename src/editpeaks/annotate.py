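"""Peak-to-gene annotation against a GTF gene model.

Feature classes are exon, intron, five_prime_utr, three_prime_utr and
lncRNA.  Introns are the exact gaps between consecutive exons of a
transcript; UTRs are derived per transcript as exon minus CDS, oriented by
strand, and take precedence over the generic exon class on the exonic
stretches they cover; all exonic intervals of a gene whose biotype is
lncRNA carry the class lncRNA.  A peak is annotated with every (gene,
class) pair whose interval overlaps it by at least one base on the same
strand; gene-level assignment is the union over transcripts.
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .io import gtf_to_text, parse_gtf_attributes
from .peaks import Peak

FEATURE_CLASSES = ("exon", "intron", "five_prime_utr", "three_prime_utr", "lncRNA")


class FeatureIndex:
    """Interval lookup from (contig, strand) to (gene_id, feature_class)."""

    def __init__(self) -> None:
        self._trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
        self._by_gene: dict[str, list[tuple[int, int, str]]] = defaultdict(list)
        self.gene_strand: dict[str, str] = {}

    def add(
        self, contig: str, strand: str, start: int, end: int, gene_id: str, cls: str
    ) -> None:
        if end <= start:
            return
        self._trees[(contig, strand)].addi(start, end, (gene_id, cls))
        self._by_gene[gene_id].append((start, end, cls))
        self.gene_strand[gene_id] = strand

    def query(
        self, contig: str, strand: str, start: int, end: int
    ) -> set[tuple[str, str]]:
        tree = self._trees.get((contig, strand))
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}

    def intervals_for_gene(self, gene_id: str) -> list[tuple[int, int, str]]:
        return sorted(self._by_gene.get(gene_id, []))

    @property
    def genes(self) -> list[str]:
        return sorted(self._by_gene)


def _load_db(annotation):
    import gffutils

    if isinstance(annotation, pd.DataFrame):
        data, from_string = gtf_to_text(annotation), True
    else:
        data, from_string = str(annotation), False
    return gffutils.create_db(
        data,
        dbfn=":memory:",
        from_string=from_string,
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )


def build_feature_index(annotation: str | Path | pd.DataFrame) -> FeatureIndex:
    """Build the interval index from a GTF file path or annotation table.

    Requires gene/transcript/exon records (CDS optional); coordinates are
    converted from GTF 1-based inclusive to 0-based half-open.  A transcript
    with overlapping exons is rejected by name.
    """
    db = _load_db(annotation)
    index = FeatureIndex()
    for gene in db.features_of_type("gene"):
        gene_id = gene.attributes.get("gene_id", [""])[0]
        biotype = gene.attributes.get("gene_biotype", ["protein_coding"])[0]
        is_lnc = biotype == "lncRNA"
        for tx in db.children(gene, featuretype="transcript"):
            tx_id = tx.attributes.get("transcript_id", [""])[0]
            exons = sorted(
                (e.start - 1, e.end) for e in db.children(tx, featuretype="exon")
            )
            if not exons:
                continue
            for (s0, e0), (s1, _e1) in zip(exons, exons[1:]):
                if s1 < e0:
                    raise ValueError(f"transcript {tx_id} has overlapping exons")
                index.add(gene.seqid, tx.strand, e0, s1, gene_id, "intron")
            cds = sorted(
                (c.start - 1, c.end) for c in db.children(tx, featuretype="CDS")
            )
            if is_lnc or not cds:
                cls = "lncRNA" if is_lnc else "exon"
                for s, e in exons:
                    index.add(gene.seqid, tx.strand, s, e, gene_id, cls)
                continue
            cds_start, cds_end = cds[0][0], cds[-1][1]
            left_cls = "five_prime_utr" if tx.strand == "+" else "three_prime_utr"
            right_cls = "three_prime_utr" if tx.strand == "+" else "five_prime_utr"
            for s, e in exons:
                if s < cds_start:
                    index.add(gene.seqid, tx.strand, s, min(e, cds_start), gene_id, left_cls)
                if e > cds_end:
                    index.add(gene.seqid, tx.strand, max(s, cds_end), e, gene_id, right_cls)
                mid_s, mid_e = max(s, cds_start), min(e, cds_end)
                index.add(gene.seqid, tx.strand, mid_s, mid_e, gene_id, "exon")
    return index


def annotate_peak(peak: Peak, index: FeatureIndex) -> set[tuple[str, str]]:
    """All (gene_id, feature_class) pairs overlapping the peak on its strand;
    an intergenic peak yields {("", "unannotated")}."""
    hits = index.query(peak.contig, peak.strand, peak.start, peak.end)
    return hits if hits else {("", "unannotated")}


def annotate_peaks(peaks: Sequence[Peak], index: FeatureIndex) -> pd.DataFrame:
    rows = []
    for p in peaks:
        for gene_id, cls in sorted(annotate_peak(p, index)):
            rows.append(
                {
                    "peak_id": p.name,
                    "contig": p.contig,
                    "start": p.start,
                    "end": p.end,
                    "strand": p.strand,
                    "fold_enrichment": p.fold_enrichment,
                    "gene_id": gene_id,
                    "feature_class": cls,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "peak_id",
            "contig",
            "start",
            "end",
            "strand",
            "fold_enrichment",
            "gene_id",
            "feature_class",
        ],
    )


def region_distribution(annotated_peaks: pd.DataFrame) -> dict[str, int]:
    """Distinct genes per feature class; a gene with peaks in several
    classes counts in each, so the class totals can exceed the number of
    distinct genes.  Unannotated rows are excluded."""
    counts = {cls: 0 for cls in FEATURE_CLASSES}
    if annotated_peaks.empty:
        return counts
    sub = annotated_peaks[annotated_peaks["feature_class"] != "unannotated"]
    for cls, grp in sub.groupby("feature_class"):
        counts[cls] = int(grp["gene_id"].nunique())
    return counts
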