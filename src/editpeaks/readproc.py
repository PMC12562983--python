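"""Read preprocessing: barcode extraction, quality/length filtering, UMI dedup.

Library chemistry places two barcodes at the 5' end of every read: first a
modification barcode (MBC) identifying which modification class the captured
fragment carries (e.g. inosine vs m6A), then a unique molecular identifier
(UMI) used to collapse PCR duplicates.  The remainder of the read is the
cDNA insert.  Inserts shorter than 30 nt after 3' quality trimming are
discarded; mapped reads are deduplicated per modification class on the
(UMI, contig, strand, 5' start) key.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_MIN_LENGTH = 30
DEFAULT_MIN_QUALITY = 20
TRIM_WINDOW = 4


class BarcodeError(ValueError):
    """Raised when a read cannot yield barcodes; carries a ``reason`` code."""

    def __init__(self, reason: str, message: str | None = None):
        super().__init__(message or reason)
        self.reason = reason


@dataclass
class RawRead:
    """An unmapped read with per-base PHRED qualities."""

    read_id: str
    sequence: str
    qualities: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: sequence and quality lengths differ"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MappedRead:
    """A mapped read carrying its modification class and UMI."""

    read_id: str
    contig: str
    start: int
    strand: str
    length: int
    mbc_class: str
    umi: str
    overrides: str = ""


@dataclass
class BarcodeLayout:
    """Barcode layout: ``[MBC][UMI][insert]`` from the 5' end.

    ``mbc_table`` maps barcode sequences to modification-class labels; any
    MBC absent from the table yields class ``"unknown"``.  The true code
    table of the assay is proprietary, so both lengths and the table are
    configurable.
    """

    mbc_table: dict[str, str] = field(
        default_factory=lambda: {"CAGT": "inosine", "TGAC": "m6A"}
    )
    umi_length: int = 8

    @property
    def mbc_length(self) -> int:
        lengths = {len(k) for k in self.mbc_table}
        if len(lengths) != 1:
            raise ValueError("all MBC sequences must share one length")
        return lengths.pop()


def extract_barcodes(read: RawRead, layout: BarcodeLayout) -> tuple[str, str, RawRead]:
    """Split a raw read into (mbc_class, umi, insert).

    Raises :class:`BarcodeError` with reason ``too_short_for_barcodes`` when
    the read cannot contain both barcodes.  An unrecognized MBC maps to the
    class ``"unknown"`` rather than failing, so downstream accounting can
    quantify barcode dropout.
    """
    n_bc = layout.mbc_length + layout.umi_length
    if len(read) < n_bc:
        raise BarcodeError(
            "too_short_for_barcodes",
            f"read {read.read_id} ({len(read)} nt) shorter than barcodes ({n_bc} nt)",
        )
    mbc_seq = read.sequence[: layout.mbc_length]
    umi = read.sequence[layout.mbc_length : n_bc]
    insert = RawRead(read.read_id, read.sequence[n_bc:], list(read.qualities[n_bc:]))
    mbc_class = layout.mbc_table.get(mbc_seq, "unknown")
    return mbc_class, umi, insert


def quality_trim_3prime(
    read: RawRead, min_quality: int = DEFAULT_MIN_QUALITY, window: int = TRIM_WINDOW
) -> RawRead:
    """Trim the 3' end while the trailing window's mean quality is below cutoff.

    After the window scan, any remaining trailing bases individually below
    the cutoff are dropped too, so the read never ends on a low-quality
    base.  The window shrinks near the 5' end, so a fully low-quality read
    trims to length zero.
    """
    q = list(read.qualities)
    end = len(q)
    while end > 0:
        w = min(window, end)
        if float(np.mean(q[end - w : end])) < min_quality:
            end -= 1
        else:
            break
    while end > 0 and q[end - 1] < min_quality:
        end -= 1
    return RawRead(read.read_id, read.sequence[:end], q[:end])


def filter_reads(
    inserts: Iterable[RawRead],
    min_length: int = DEFAULT_MIN_LENGTH,
    min_quality: int = DEFAULT_MIN_QUALITY,
) -> list[RawRead]:
    """Quality-trim inserts and drop those shorter than ``min_length``."""
    kept = []
    for read in inserts:
        trimmed = quality_trim_3prime(read, min_quality)
        if len(trimmed) >= min_length:
            kept.append(trimmed)
    return kept


DEDUP_KEY = ["mbc_class", "umi", "contig", "strand", "start"]


def deduplicate(reads: pd.DataFrame) -> pd.DataFrame:
    """Collapse PCR duplicates on (mbc_class, umi, contig, strand, start).

    The survivor of each duplicate group is the read with the
    lexicographically smallest read_id, making the operation reproducible
    regardless of input order.  UMIs are matched exactly (no 1-mismatch
    merging).
    """
    if reads.empty:
        return reads.copy()
    out = reads.sort_values(DEDUP_KEY + ["read_id"], kind="mergesort")
    out = out.drop_duplicates(subset=DEDUP_KEY, keep="first")
    return out.reset_index(drop=True)


def mapped_reads_to_frame(reads: Iterable[MappedRead]) -> pd.DataFrame:
    from .io import ALIGNMENT_COLUMNS

    return pd.DataFrame(
        [
            {
                "read_id": r.read_id,
                "contig": r.contig,
                "start": r.start,
                "strand": r.strand,
                "length": r.length,
                "mbc_class": r.mbc_class,
                "umi": r.umi,
                "overrides": r.overrides,
            }
            for r in reads
        ],
        columns=ALIGNMENT_COLUMNS,
    )
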