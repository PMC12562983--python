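"""Readers and writers for the plain-text formats the pipeline exchanges.

Alignment records travel as a TSV table rather than BAM so that simulated
experiments, intermediate files and test fixtures stay human-readable.
Schema (one row per mapped read)::

    read_id  contig  start  strand  length  mbc_class  umi  overrides

``start`` is 0-based; ``overrides`` is a ``;``-joined list of ``pos:BASE``
entries giving reference-forward bases where the read disagrees with the
reference (editing events or sequencing errors), or the empty string.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALIGNMENT_COLUMNS = [
    "read_id",
    "contig",
    "start",
    "strand",
    "length",
    "mbc_class",
    "umi",
    "overrides",
]

GTF_COLUMNS = [
    "seqname",
    "source",
    "feature",
    "start",
    "end",
    "score",
    "strand",
    "frame",
    "attributes",
]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def write_gtf(annotation: pd.DataFrame, path: str | Path) -> None:
    """Write an annotation table (``GTF_COLUMNS``, 1-based inclusive) as GTF."""
    with open(path, "w") as fh:
        fh.write(gtf_to_text(annotation))


def gtf_to_text(annotation: pd.DataFrame) -> str:
    lines = []
    for row in annotation.itertuples(index=False):
        lines.append(
            "\t".join(
                [
                    str(row.seqname),
                    str(row.source),
                    str(row.feature),
                    str(int(row.start)),
                    str(int(row.end)),
                    str(row.score),
                    str(row.strand),
                    str(row.frame),
                    str(row.attributes),
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def read_gtf(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        str(path),
        sep="\t",
        comment="#",
        header=None,
        names=GTF_COLUMNS,
        keep_default_na=False,
        dtype={"seqname": str, "attributes": str},
    )
    return df


def parse_gtf_attributes(attributes: str) -> dict[str, str]:
    """Parse a GTF attribute string into a dict (``key "value";`` pairs)."""
    out: dict[str, str] = {}
    for field in attributes.strip().split(";"):
        field = field.strip()
        if not field:
            continue
        key, _, value = field.partition(" ")
        out[key] = value.strip().strip('"')
    return out


# ---------------------------------------------------------------------------
# Alignment table
# ---------------------------------------------------------------------------

def write_alignment_table(reads: pd.DataFrame, path: str | Path) -> None:
    reads.to_csv(str(path), sep="\t", index=False, columns=ALIGNMENT_COLUMNS)


def read_alignment_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        str(path),
        sep="\t",
        dtype={
            "read_id": str,
            "contig": str,
            "start": int,
            "strand": str,
            "length": int,
            "mbc_class": str,
            "umi": str,
            "overrides": str,
        },
        keep_default_na=False,
    )
    return df[ALIGNMENT_COLUMNS]


def reads_from_sam(path: str | Path, mbc_tag: str = "MB", umi_tag: str = "RX") -> pd.DataFrame:
    """Load mapped reads from a SAM file into the alignment-table schema.

    The modification class is taken from ``mbc_tag`` and the UMI from
    ``umi_tag``; reads missing either tag get class ``unknown`` / empty UMI.
    Mismatching bases are not reconstructed from the SAM (no MD parsing);
    ``overrides`` is left empty, so SAM input supports peak calling but
    site calling needs the TSV table.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            rows.append(
                {
                    "read_id": aln.query_name,
                    "contig": aln.reference_name,
                    "start": aln.reference_start,
                    "strand": "-" if aln.is_reverse else "+",
                    "length": aln.reference_length or aln.query_length,
                    "mbc_class": aln.get_tag(mbc_tag) if aln.has_tag(mbc_tag) else "unknown",
                    "umi": aln.get_tag(umi_tag) if aln.has_tag(umi_tag) else "",
                    "overrides": "",
                }
            )
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


# ---------------------------------------------------------------------------
# Spike-in counts
# ---------------------------------------------------------------------------

SPIKE_COLUMNS = ["spike_id", "modified", "count_enriched", "count_control"]


def write_spike_counts(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(str(path), sep="\t", index=False)


def read_spike_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t", dtype={"spike_id": str})


# ---------------------------------------------------------------------------
# BED (peaks)
# ---------------------------------------------------------------------------

def peaks_to_bed(peaks: Sequence) -> str:
    """Render peaks as BED6+3: name=mod_class, score=min(1000, round(10*q)),
    extra columns fold_enrichment, q_score, max_depth."""
    lines = []
    for p in peaks:
        q = 0.0 if p.q_score is None else p.q_score
        lines.append(
            "\t".join(
                [
                    p.contig,
                    str(p.start),
                    str(p.end),
                    p.mod_class,
                    str(min(1000, round(10 * q))),
                    p.strand,
                    f"{p.fold_enrichment:.4f}",
                    f"{q:.2f}",
                    str(p.max_depth),
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def write_peaks_bed(peaks: Sequence, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(peaks_to_bed(peaks))


def read_peaks_bed(path: str | Path):
    """Read a BED6+3 peak file back into Peak objects."""
    from .peaks import Peak

    peaks = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            peaks.append(
                Peak(
                    contig=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    strand=f[5],
                    mod_class=f[3],
                    fold_enrichment=float(f[6]),
                    q_score=float(f[7]),
                    max_depth=int(f[8]),
                    summit=int(f[1]),
                    name=f"peak_{i:05d}",
                )
            )
    return peaks


# ---------------------------------------------------------------------------
# VCF / TSV (editing sites)
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=editpeaks
##INFO=<ID=PEAK_ID,Number=1,Type=String,Description="Inosine peak containing the site">
##INFO=<ID=STRAND,Number=1,Type=String,Description="Gene strand of the edit">
##INFO=<ID=EDIT_RATE,Number=1,Type=Float,Description="Fraction of reads supporting the edited base">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE
"""


def sites_to_vcf(sites: Iterable) -> str:
    lines = [_VCF_HEADER.rstrip("\n")]
    for s in sites:
        ref, alt = ("A", "G") if s.strand == "+" else ("T", "C")
        info = f"PEAK_ID={s.peak_id};STRAND={s.strand};EDIT_RATE={s.rate:.4f}"
        sample = f"{s.depth}:{s.depth - s.alt_count},{s.alt_count}"
        lines.append(
            "\t".join(
                [s.contig, str(s.pos + 1), ".", ref, alt, ".", "PASS", info, "DP:AD", sample]
            )
        )
    return "\n".join(lines) + "\n"


def write_sites_vcf(sites: Iterable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(sites_to_vcf(sites))


def sites_to_frame(sites: Iterable) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig": s.contig,
                "pos": s.pos,
                "strand": s.strand,
                "depth": s.depth,
                "alt_count": s.alt_count,
                "rate": round(s.rate, 6),
                "peak_id": s.peak_id,
            }
            for s in sites
        ],
        columns=["contig", "pos", "strand", "depth", "alt_count", "rate", "peak_id"],
    )


def write_sites_tsv(sites: Iterable, path: str | Path) -> None:
    sites_to_frame(sites).to_csv(str(path), sep="\t", index=False)


# ---------------------------------------------------------------------------
# JSON summaries
# ---------------------------------------------------------------------------

def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
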