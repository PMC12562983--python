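"""Seeded synthetic data for the modification-enrichment assay.

The generator emulates paired enrichment / solution-control sequencing
libraries of a bead-capture modification assay: a small random genome with
gene models (exons, introns, UTRs, a configurable fraction of lncRNAs),
planted inosine peaks with known fold enrichment hosted inside genes,
per-site A-to-I editing rates drawn from a Beta distribution, uniform
Poisson background coverage, spike-in controls with configured recovery
ratios, and a multi-condition knockout design (WT, p150KO, p150/p110KO)
in which each peak-bearing gene belongs to a planted dependency category
that scales its peak intensity and editing per condition.

Every read is a fixed-length single-end fragment carrying a modification
class label (MBC) and a random UMI.  All randomness flows from the config
seed through fixed-offset substreams, so identical configs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ALIGNMENT_COLUMNS, GTF_COLUMNS, parse_gtf_attributes
from .peaks import CoverageTrack

LIBRARY_TYPES = ("enrichment", "control")
_LETTERS = np.array(list("ACGT"))


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SpikeSpec:
    spike_id: str
    modified: bool
    true_enrichment: float


def default_spike_set() -> list[SpikeSpec]:
    return [
        SpikeSpec("spike_mod_1", True, 2.0),
        SpikeSpec("spike_mod_2", True, 2.0),
        SpikeSpec("spike_unmod_1", False, 1.0),
        SpikeSpec("spike_unmod_2", False, 1.0),
    ]


def default_condition_design() -> dict[str, dict[str, float]]:
    """Planted dependency categories: per-condition scaling of each
    category's peak intensity and editing."""
    return {
        "strong": {"WT": 1.0, "p150KO": 0.0, "p150_p110KO": 0.0},
        "mild": {"WT": 1.0, "p150KO": 0.4, "p150_p110KO": 0.0},
        "independent": {"WT": 1.0, "p150KO": 1.0, "p150_p110KO": 0.0},
    }


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic experiment.

    Peak widths of 150-300 nt with 21-42 editable adenosines per peak give
    a *called* editing density whose median falls in the 7-8 sites per
    100 nt range typical of enrichment peaks in lymphoblastoid cells (the
    called denominator includes fragment-length smear around the planted
    interval, and sites edited below the 10% reporting floor are lost);
    editing rates follow Beta(2, 5) (mean ~0.29, long right tail).
    """

    seed: int = 0
    n_contigs: int = 1
    contig_length: int = 50_000
    n_genes: int = 10
    n_exons_range: tuple[int, int] = (2, 4)
    exon_length_range: tuple[int, int] = (200, 600)
    intron_length_range: tuple[int, int] = (300, 800)
    utr5_length_range: tuple[int, int] = (50, 150)
    utr3_length_range: tuple[int, int] = (100, 300)
    gene_gap_range: tuple[int, int] = (300, 800)
    lncRNA_fraction: float = 0.2
    n_peaks: int = 8
    n_m6a_peaks: int = 2
    peak_width_range: tuple[int, int] = (150, 300)
    fold_enrichment_range: tuple[float, float] = (8.0, 12.0)
    editing_rate_dist: tuple[float, float] = (2.0, 5.0)
    sites_per_peak_range: tuple[int, int] = (21, 42)
    background_depth: float = 20.0
    read_length: int = 100
    mbc_table: dict[str, str] = field(
        default_factory=lambda: {"CAGT": "inosine", "TGAC": "m6A"}
    )
    umi_length: int = 8
    spike_set: list[SpikeSpec] = field(default_factory=default_spike_set)
    spike_length: int = 300
    spike_base_count: int = 2000
    conditions: tuple[str, ...] = ("WT", "p150KO", "p150_p110KO")
    n_replicates: int = 2
    condition_design: dict[str, dict[str, float]] = field(
        default_factory=default_condition_design
    )
    sequencing_error_rate: float = 0.0
    pcr_duplicate_rate: float = 0.0

    def validate(self) -> None:
        def _range_ok(r, lo_min=0):
            return r[0] <= r[1] and r[0] >= lo_min

        for name in (
            "n_exons_range",
            "exon_length_range",
            "intron_length_range",
            "utr5_length_range",
            "utr3_length_range",
            "gene_gap_range",
            "peak_width_range",
            "sites_per_peak_range",
        ):
            r = getattr(self, name)
            if not _range_ok(r, 1 if "length" in name or "width" in name else 0):
                raise SimConfigError(f"degenerate range {name}={r}")
        if not self.fold_enrichment_range[0] <= self.fold_enrichment_range[1]:
            raise SimConfigError("degenerate fold_enrichment_range")
        if self.fold_enrichment_range[0] <= 0:
            raise SimConfigError("fold enrichment must be positive")
        a, b = self.editing_rate_dist
        if a <= 0 or b < 0:
            raise SimConfigError("editing rate Beta parameters must be positive")
        if self.background_depth <= 0:
            raise SimConfigError("background_depth must be positive")
        if self.read_length <= 0 or self.contig_length <= self.read_length:
            raise SimConfigError("contig_length must exceed read_length")
        if not 0 <= self.sequencing_error_rate < 1:
            raise SimConfigError("sequencing_error_rate must be in [0,1)")
        if not 0 <= self.pcr_duplicate_rate < 1:
            raise SimConfigError("pcr_duplicate_rate must be in [0,1)")
        if not self.mbc_table:
            raise SimConfigError("mbc_table must name at least one class")
        for cat, scales in self.condition_design.items():
            for cond, x in scales.items():
                if x < 0:
                    raise SimConfigError(f"negative scale for {cat}/{cond}")

    @property
    def mod_classes(self) -> list[str]:
        return sorted(set(self.mbc_table.values()))

    def spike_factor_true(self) -> float:
        mod = [s.true_enrichment for s in self.spike_set if s.modified]
        unmod = [s.true_enrichment for s in self.spike_set if not s.modified]
        if not mod or not unmod:
            raise SimConfigError("spike_set needs modified and unmodified spikes")
        return float(np.mean(mod) / np.mean(unmod))


@dataclass
class TruthTable:
    """Ground truth of a simulated experiment.

    ``peaks``: planted intervals with gene, category, spike-scaled WT fold
    (``fold``) and the raw coverage fold actually planted (``raw_fold``).
    ``sites``: planted editing positions with per-site rates; every site
    lies inside a planted peak.  ``gene_categories``: gene -> dependency
    label, a partition of the peak-bearing genes.
    """

    peaks: pd.DataFrame
    sites: pd.DataFrame
    gene_categories: dict[str, str]


def substream(seed: int, *offsets: int) -> np.random.Generator:
    """Independent generator derived from the config seed by fixed offsets."""
    return np.random.default_rng([int(seed)] + [int(o) for o in offsets])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_LETTERS[rng.integers(0, 4, n)])


def _spliced_to_genomic(
    exons: Sequence[tuple[int, int]], strand: str, t0: int, t1: int
) -> list[tuple[int, int]]:
    """Map a half-open transcript-coordinate interval to genomic pieces.

    Transcript coordinate 0 is the 5' end of the mature transcript, i.e.
    the leftmost exon base for '+' genes and the rightmost for '-' genes.
    """
    pieces = []
    offset = 0
    ordered = list(exons) if strand == "+" else list(reversed(exons))
    for s, e in ordered:
        elen = e - s
        lo, hi = max(t0, offset), min(t1, offset + elen)
        if lo < hi:
            if strand == "+":
                pieces.append((s + (lo - offset), s + (hi - offset)))
            else:
                pieces.append((e - (hi - offset), e - (lo - offset)))
        offset += elen
    return sorted(pieces)


# ---------------------------------------------------------------------------
# Reference simulation
# ---------------------------------------------------------------------------

def simulate_reference(config: SimConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Random genome plus a GTF-style annotation table.

    Genes are placed left to right on their contig with random gaps; each
    gene has one transcript.  Protein-coding transcripts get CDS and UTR
    records (UTRs confined to the terminal exons); lncRNA genes carry
    ``gene_biotype "lncRNA"`` and no CDS.  Raises
    :class:`SimConfigError` when a contig cannot host its genes.
    """
    config.validate()
    rng = substream(config.seed, 1)
    contigs = [f"chr{i + 1}" for i in range(config.n_contigs)]
    genome = {c: _random_seq(rng, config.contig_length) for c in contigs}

    # draw gene structures first, then check contig capacity
    genes = []
    for gi in range(config.n_genes):
        n_ex = int(rng.integers(config.n_exons_range[0], config.n_exons_range[1] + 1))
        exon_lens = rng.integers(
            config.exon_length_range[0], config.exon_length_range[1] + 1, n_ex
        )
        intron_lens = rng.integers(
            config.intron_length_range[0], config.intron_length_range[1] + 1, n_ex - 1
        )
        gap = int(rng.integers(config.gene_gap_range[0], config.gene_gap_range[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = "lncRNA" if rng.random() < config.lncRNA_fraction else "protein_coding"
        u5 = int(rng.integers(config.utr5_length_range[0], config.utr5_length_range[1] + 1))
        u3 = int(rng.integers(config.utr3_length_range[0], config.utr3_length_range[1] + 1))
        genes.append(
            {
                "gene_id": f"g{gi:03d}",
                "contig": contigs[gi % config.n_contigs],
                "strand": strand,
                "biotype": biotype,
                "exon_lens": [int(x) for x in exon_lens],
                "intron_lens": [int(x) for x in intron_lens],
                "gap": gap,
                "u5": u5,
                "u3": u3,
            }
        )

    cursors = {c: 0 for c in contigs}
    rows: list[dict] = []
    for g in genes:
        contig = g["contig"]
        span = sum(g["exon_lens"]) + sum(g["intron_lens"])
        start = cursors[contig] + g["gap"]
        if start + span > config.contig_length:
            raise SimConfigError(
                f"contig {contig} too short to host requested genes"
            )
        cursors[contig] = start + span
        exons = []
        pos = start
        for i, elen in enumerate(g["exon_lens"]):
            exons.append((pos, pos + elen))
            pos += elen
            if i < len(g["intron_lens"]):
                pos += g["intron_lens"][i]
        g["exons"] = exons
        g["start"], g["end"] = start, start + span
        rows.extend(_gene_gtf_rows(g))

    annotation = pd.DataFrame(rows, columns=GTF_COLUMNS)
    return genome, annotation


def _gene_gtf_rows(g: dict) -> list[dict]:
    gene_id, tx_id = g["gene_id"], g["gene_id"] + ".t1"
    base_attr = f'gene_id "{gene_id}"; gene_biotype "{g["biotype"]}";'
    tx_attr = f'gene_id "{gene_id}"; transcript_id "{tx_id}"; gene_biotype "{g["biotype"]}";'

    def row(feature, s, e, frame="."):
        return {
            "seqname": g["contig"],
            "source": "editpeaks_sim",
            "feature": feature,
            "start": s + 1,
            "end": e,
            "score": ".",
            "strand": g["strand"],
            "frame": frame,
            "attributes": tx_attr if feature != "gene" else base_attr,
        }

    rows = [row("gene", g["start"], g["end"]), row("transcript", g["start"], g["end"])]
    exons = g["exons"]
    order = exons if g["strand"] == "+" else list(reversed(exons))
    for i, (s, e) in enumerate(order):
        r = row("exon", s, e)
        r["attributes"] += f' exon_number "{i + 1}";'
        rows.append(r)
    if g["biotype"] == "protein_coding":
        tx_len = sum(e - s for s, e in exons)
        u5, u3 = g["u5"], g["u3"]
        # keep a CDS of at least 30 nt
        excess = u5 + u3 - max(tx_len - 30, 0)
        if excess > 0:
            u5 = max(1, u5 - excess)
            u3 = max(1, min(u3, tx_len - 30 - u5))
        for s, e in _spliced_to_genomic(exons, g["strand"], 0, u5):
            rows.append(row("five_prime_utr", s, e))
        phase = 0
        cds_pieces = _spliced_to_genomic(exons, g["strand"], u5, tx_len - u3)
        ordered = cds_pieces if g["strand"] == "+" else list(reversed(cds_pieces))
        for s, e in ordered:
            rows.append(row("CDS", s, e, frame=str(phase)))
            phase = (3 - ((e - s) - phase) % 3) % 3
        for s, e in _spliced_to_genomic(exons, g["strand"], tx_len - u3, tx_len):
            rows.append(row("three_prime_utr", s, e))
    return rows


def simulate_spikes(config: SimConfig) -> dict[str, str]:
    """Synthetic spike-in contigs, separate from the genomic contigs."""
    rng = substream(config.seed, 2)
    return {s.spike_id: _random_seq(rng, config.spike_length) for s in config.spike_set}


# ---------------------------------------------------------------------------
# Experiment simulation
# ---------------------------------------------------------------------------

def _gene_table(annotation: pd.DataFrame) -> pd.DataFrame:
    genes = annotation[annotation["feature"] == "gene"].copy()
    if genes.empty:
        return pd.DataFrame(columns=["gene_id", "contig", "start", "end", "strand"])
    genes["gene_id"] = genes["attributes"].map(
        lambda a: parse_gtf_attributes(a).get("gene_id", "")
    )
    out = pd.DataFrame(
        {
            "gene_id": genes["gene_id"].to_numpy(),
            "contig": genes["seqname"].to_numpy(),
            "start": genes["start"].to_numpy() - 1,
            "end": genes["end"].to_numpy(),
            "strand": genes["strand"].to_numpy(),
        }
    )
    return out.sort_values("gene_id").reset_index(drop=True)


def _plant_peaks(
    config: SimConfig, genome: Mapping[str, str], gene_table: pd.DataFrame, rng
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Place inosine (and m6A) peaks inside genes and draw editing sites."""
    categories = list(config.condition_design)
    peak_rows, site_rows = [], []
    gene_categories: dict[str, str] = {}
    n_genes = len(gene_table)
    if (config.n_peaks or config.n_m6a_peaks) and n_genes == 0:
        raise SimConfigError("cannot plant peaks without genes")

    def place(host_rows, n_peaks, mod_class):
        per_gene: dict[int, int] = {}
        for i in range(n_peaks):
            gi = i % len(host_rows)
            per_gene[gi] = per_gene.get(gi, 0) + 1
        placed = []
        for gi, k in sorted(per_gene.items()):
            gene = host_rows.iloc[gi]
            span = gene["end"] - gene["start"]
            slot = span // k
            for j in range(k):
                lo = gene["start"] + j * slot
                w = int(
                    rng.integers(config.peak_width_range[0], config.peak_width_range[1] + 1)
                )
                w = min(w, slot - 2)
                if w < 10:
                    raise SimConfigError("gene too short for requested peaks")
                s = int(rng.integers(lo, lo + slot - w))
                placed.append((gene, s, s + w, mod_class))
        return placed

    inosine_hosts = gene_table
    for gene, s, e, cls in place(inosine_hosts, config.n_peaks, "inosine"):
        gid = gene["gene_id"]
        if gid not in gene_categories:
            gene_categories[gid] = categories[len(gene_categories) % len(categories)]
        fold = float(
            rng.uniform(config.fold_enrichment_range[0], config.fold_enrichment_range[1])
        )
        idx = len(peak_rows)
        peak_rows.append(
            {
                "peak_idx": idx,
                "contig": gene["contig"],
                "start": s,
                "end": e,
                "strand": gene["strand"],
                "mod_class": cls,
                "gene_id": gid,
                "category": gene_categories[gid],
                "fold": fold,
                "raw_fold": fold * config.spike_factor_true(),
            }
        )
        # editable positions: transcript-strand adenosines
        seq = genome[gene["contig"]][s:e]
        target = "A" if gene["strand"] == "+" else "T"
        avail = np.array([s + i for i, b in enumerate(seq) if b == target])
        k = int(
            rng.integers(config.sites_per_peak_range[0], config.sites_per_peak_range[1] + 1)
        )
        chosen = (
            np.sort(rng.choice(avail, size=min(k, len(avail)), replace=False))
            if len(avail)
            else np.array([], dtype=int)
        )
        rates = rng.beta(config.editing_rate_dist[0], config.editing_rate_dist[1], len(chosen))
        rates = np.clip(rates, 1e-3, 1.0)
        for pos, rate in zip(chosen, rates):
            site_rows.append(
                {
                    "contig": gene["contig"],
                    "pos": int(pos),
                    "strand": gene["strand"],
                    "rate": float(rate),
                    "peak_idx": idx,
                    "gene_id": gid,
                }
            )
    if config.n_m6a_peaks and "m6A" in config.mod_classes:
        hosts = gene_table.iloc[::-1].reset_index(drop=True)
        for gene, s, e, cls in place(hosts, config.n_m6a_peaks, "m6A"):
            fold = float(
                rng.uniform(config.fold_enrichment_range[0], config.fold_enrichment_range[1])
            )
            peak_rows.append(
                {
                    "peak_idx": len(peak_rows),
                    "contig": gene["contig"],
                    "start": s,
                    "end": e,
                    "strand": gene["strand"],
                    "mod_class": cls,
                    "gene_id": gene["gene_id"],
                    "category": "constant",
                    "fold": fold,
                    "raw_fold": fold * config.spike_factor_true(),
                }
            )
    peaks = pd.DataFrame(
        peak_rows,
        columns=[
            "peak_idx",
            "contig",
            "start",
            "end",
            "strand",
            "mod_class",
            "gene_id",
            "category",
            "fold",
            "raw_fold",
        ],
    )
    sites = pd.DataFrame(
        site_rows, columns=["contig", "pos", "strand", "rate", "peak_idx", "gene_id"]
    )
    return peaks, sites, gene_categories


def _condition_scale(config: SimConfig, category: str, condition: str) -> float:
    if category == "constant":
        return 1.0
    return float(config.condition_design.get(category, {}).get(condition, 0.0))


def _make_umis(rng, n: int, k: int) -> list[str]:
    if n == 0:
        return []
    mat = _LETTERS[rng.integers(0, 4, (n, k))]
    return ["".join(row) for row in mat]


def _simulate_library(
    config: SimConfig,
    genome: Mapping[str, str],
    truth_peaks: pd.DataFrame,
    truth_sites: pd.DataFrame,
    condition: str,
    libtype: str,
    rng: np.random.Generator,
    label: str,
) -> pd.DataFrame:
    rl = config.read_length
    bg = config.background_depth
    classes = config.mod_classes
    contigs, starts, strands, mbcs = [], [], [], []

    # flat Poisson background, per contig / strand / class
    for contig, seq in genome.items():
        L = len(seq)
        span = L - rl + 1
        for strand in ("+", "-"):
            for cls in classes:
                n = rng.poisson(bg * span / rl)
                if n == 0:
                    continue
                st = rng.integers(0, span, n)
                contigs.append(np.full(n, contig, dtype=object))
                starts.append(st)
                strands.append(np.full(n, strand, dtype=object))
                mbcs.append(np.full(n, cls, dtype=object))

    # planted enrichment above background (enrichment library only)
    if libtype == "enrichment":
        for p in truth_peaks.itertuples(index=False):
            scale = _condition_scale(config, p.category, condition)
            extra = bg * (p.raw_fold - 1.0) * scale
            if extra <= 0:
                continue
            L = len(genome[p.contig])
            lo = max(0, p.start - rl + 1)
            hi = min(p.end - 1, L - rl)
            span = hi - lo + 1
            n = rng.poisson(extra * span / rl)
            if n == 0:
                continue
            st = rng.integers(lo, hi + 1, n)
            contigs.append(np.full(n, p.contig, dtype=object))
            starts.append(st)
            strands.append(np.full(n, p.strand, dtype=object))
            mbcs.append(np.full(n, p.mod_class, dtype=object))

    if not contigs:
        return pd.DataFrame(columns=ALIGNMENT_COLUMNS)
    contig_arr = np.concatenate(contigs)
    start_arr = np.concatenate(starts).astype(np.int64)
    strand_arr = np.concatenate(strands)
    mbc_arr = np.concatenate(mbcs)
    n_reads = len(start_arr)
    overrides: dict[int, list[str]] = {}

    # editing: every read covering a planted site carries the alt base with
    # probability rate * condition scale (the solution control is made from
    # the same edited RNA, so both library types are edited)
    cat_by_peak = dict(zip(truth_peaks["peak_idx"], truth_peaks["category"]))
    for contig in genome:
        mask = contig_arr == contig
        if not mask.any():
            continue
        idx = np.nonzero(mask)[0]
        order = np.argsort(start_arr[idx], kind="stable")
        sorted_idx = idx[order]
        sorted_starts = start_arr[sorted_idx]
        csites = truth_sites[truth_sites["contig"] == contig]
        for site in csites.itertuples(index=False):
            scale = _condition_scale(config, cat_by_peak[site.peak_idx], condition)
            p_edit = min(site.rate * scale, 1.0)
            if p_edit <= 0:
                continue
            lo = np.searchsorted(sorted_starts, site.pos - rl + 1, side="left")
            hi = np.searchsorted(sorted_starts, site.pos, side="right")
            covering = sorted_idx[lo:hi]
            edited = covering[rng.random(len(covering)) < p_edit]
            alt = "G" if site.strand == "+" else "C"
            for i in edited:
                overrides.setdefault(int(i), []).append(f"{site.pos}:{alt}")

    # optional uniform sequencing errors
    if config.sequencing_error_rate > 0:
        n_err = rng.binomial(rl, config.sequencing_error_rate, n_reads)
        for i in np.nonzero(n_err)[0]:
            seq = genome[contig_arr[i]]
            for off in rng.integers(0, rl, n_err[i]):
                pos = int(start_arr[i] + off)
                ref = seq[pos]
                others = [b for b in "ACGT" if b != ref]
                overrides.setdefault(int(i), []).append(
                    f"{pos}:{others[int(rng.integers(0, 3))]}"
                )

    umis = _make_umis(rng, n_reads, config.umi_length)
    reads = pd.DataFrame(
        {
            "read_id": [f"{label}:{i:07d}" for i in range(n_reads)],
            "contig": contig_arr,
            "start": start_arr,
            "strand": strand_arr,
            "length": np.full(n_reads, rl, dtype=np.int64),
            "mbc_class": mbc_arr,
            "umi": umis,
            "overrides": [
                ";".join(sorted(set(overrides.get(i, [])))) for i in range(n_reads)
            ],
        }
    )

    if config.pcr_duplicate_rate > 0:
        n_dup = rng.binomial(n_reads, config.pcr_duplicate_rate)
        dup_idx = rng.choice(n_reads, size=n_dup, replace=False)
        dups = reads.iloc[np.sort(dup_idx)].copy()
        dups["read_id"] = [f"{label}:d{i:07d}" for i in range(len(dups))]
        reads = pd.concat([reads, dups], ignore_index=True)
    return reads


def simulate_experiment(
    config: SimConfig,
    genome: Mapping[str, str],
    annotation: pd.DataFrame,
) -> tuple[dict[tuple[str, int, str], pd.DataFrame], pd.DataFrame, TruthTable]:
    """Generate reads per (condition, replicate, library type), spike counts
    and the ground-truth table for a full multi-condition experiment."""
    config.validate()
    gene_table = _gene_table(annotation)
    rng_plant = substream(config.seed, 3)
    truth_peaks, truth_sites, gene_categories = _plant_peaks(
        config, genome, gene_table, rng_plant
    )
    truth = TruthTable(truth_peaks, truth_sites, gene_categories)

    reads: dict[tuple[str, int, str], pd.DataFrame] = {}
    spike_rows = []
    for ci, condition in enumerate(config.conditions):
        for rep in range(1, config.n_replicates + 1):
            for li, libtype in enumerate(LIBRARY_TYPES):
                rng = substream(config.seed, 4, ci, rep, li)
                label = f"{condition}_rep{rep}_{libtype}"
                reads[(condition, rep, libtype)] = _simulate_library(
                    config, genome, truth_peaks, truth_sites, condition, libtype, rng, label
                )
            rng_sp = substream(config.seed, 5, ci, rep)
            for spec in config.spike_set:
                base = config.spike_base_count
                spike_rows.append(
                    {
                        "condition": condition,
                        "replicate": rep,
                        "spike_id": spec.spike_id,
                        "modified": spec.modified,
                        "count_enriched": int(
                            rng_sp.poisson(base * spec.true_enrichment)
                        ),
                        "count_control": int(rng_sp.poisson(base)),
                    }
                )
    spike_counts = pd.DataFrame(
        spike_rows,
        columns=[
            "condition",
            "replicate",
            "spike_id",
            "modified",
            "count_enriched",
            "count_control",
        ],
    )
    return reads, spike_counts, truth


# ---------------------------------------------------------------------------
# Track-level simulation (direct Poisson coverage, no reads)
# ---------------------------------------------------------------------------

def simulate_track_pair(
    length: int,
    background_depth: float,
    planted: Sequence[tuple[int, int, float]] = (),
    seed: int = 0,
    contig: str = "chr1",
    strand: str = "+",
    mod_class: str = "inosine",
) -> tuple[CoverageTrack, CoverageTrack]:
    """Paired enrichment/control coverage drawn base-by-base from Poisson.

    ``planted`` lists (start, end, fold) rectangles multiplying the
    enrichment mean.  Useful for fast peak-caller benchmarks where
    read-level structure is irrelevant.
    """
    rng = np.random.default_rng([int(seed), 6])
    mean = np.full(length, float(background_depth))
    for s, e, fold in planted:
        mean[s:e] = background_depth * fold
    enrich = rng.poisson(mean)
    control = rng.poisson(np.full(length, float(background_depth)))
    return (
        CoverageTrack(contig, strand, mod_class, enrich),
        CoverageTrack(contig, strand, mod_class, control),
    )


# ---------------------------------------------------------------------------
# On-disk simulation bundle
# ---------------------------------------------------------------------------

def write_simulation(config: SimConfig, outdir: str | Path) -> None:
    """Run the full simulation and write genome, spikes, annotation, reads,
    spike counts and truth tables under ``outdir``."""
    from . import io as epio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, annotation = simulate_reference(config)
    epio.write_fasta(genome, outdir / "genome.fa")
    epio.write_fasta(simulate_spikes(config), outdir / "spikes.fa")
    epio.write_gtf(annotation, outdir / "annotation.gtf")
    reads, spike_counts, truth = simulate_experiment(config, genome, annotation)
    for (condition, rep, libtype), table in reads.items():
        epio.write_alignment_table(
            table, outdir / f"reads_{condition}_rep{rep}_{libtype}.tsv"
        )
    spike_counts.to_csv(outdir / "spike_counts.tsv", sep="\t", index=False)
    truth.peaks.to_csv(outdir / "truth_peaks.tsv", sep="\t", index=False)
    truth.sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    pd.Series(truth.gene_categories, name="category").rename_axis("gene_id").to_csv(
        outdir / "truth_gene_categories.tsv", sep="\t"
    )
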