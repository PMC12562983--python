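"""End-to-end orchestration: reads -> peaks -> sites -> annotation -> dependency.

`analyze_experiment` runs the whole analysis on in-memory inputs (the shape
produced by :mod:`editpeaks.simdata`, or assembled from files);
`run_simulated_analysis` wires the simulator to it and optionally writes
every output table, which is also how the pipeline-determinism check works.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import io as epio
from .annotate import annotate_peaks, build_feature_index, region_distribution
from .dependency import (
    WT,
    classify_genes,
    cluster_gene_scores,
    common_genes,
    condition_means,
    gene_scores,
    reduction_summary,
)
from .peaks import (
    CoverageTrack,
    Peak,
    PeakParams,
    build_coverage,
    call_peaks,
    filter_high_confidence,
    scale_peaks,
    score_confidence,
    spike_enrichment_factor,
)
from .readproc import deduplicate
from .sites import EditingSite, call_editing_sites, pileup

import numpy as np


@dataclass
class SampleResult:
    sample_id: str
    condition: str
    replicate: int
    peaks: list[Peak]
    sites: list[EditingSite]
    annotated: pd.DataFrame  # inosine peaks x (gene, feature class)

    @property
    def inosine_peaks(self) -> list[Peak]:
        return [p for p in self.peaks if p.mod_class == "inosine"]

    @property
    def gene_set(self) -> set[str]:
        if self.annotated.empty:
            return set()
        return set(self.annotated.loc[self.annotated["gene_id"] != "", "gene_id"])


@dataclass
class ExperimentResult:
    samples: dict[str, SampleResult]
    condition_map: dict[str, str]
    gene_matrix: pd.DataFrame
    condition_scores: pd.DataFrame
    dependency: pd.DataFrame
    reductions: dict[str, float]
    distribution: dict[str, int]
    common_wt_genes: set[str]
    clusters: pd.Series | None = None

    def peak_counts(self, mod_class: str = "inosine") -> dict[str, list[int]]:
        counts: dict[str, list[int]] = {}
        for s in self.samples.values():
            counts.setdefault(s.condition, []).append(
                sum(1 for p in s.peaks if p.mod_class == mod_class)
            )
        return counts


def call_sample_peaks(
    enrich_reads: pd.DataFrame,
    control_reads: pd.DataFrame,
    contig_lengths: Mapping[str, int],
    spikes: pd.DataFrame,
    params: PeakParams | None = None,
    q_min: float = 13.0,
    depth_min: int = 5,
) -> list[Peak]:
    """Deduplicate one sample's libraries and call high-confidence peaks.

    The library-size factor is the ratio of total deduplicated enrichment
    to control reads, shared by every track of the sample; fold enrichment
    is divided by the sample's spike-in factor.
    """
    de = deduplicate(enrich_reads)
    dc = deduplicate(control_reads)
    params = params or PeakParams()
    if params.size_factor is None and len(dc):
        params = PeakParams(
            smoothing_window=params.smoothing_window,
            pseudocount=params.pseudocount,
            min_prominence=params.min_prominence,
            min_width=params.min_width,
            size_factor=len(de) / len(dc),
        )
    factor = spike_enrichment_factor(spikes)
    cov_e = build_coverage(de, contig_lengths)
    cov_c = build_coverage(dc, contig_lengths)
    out: list[Peak] = []
    for key in sorted(cov_e):
        enrich = cov_e[key]
        control = cov_c.get(key)
        if control is None:
            contig, strand, cls = key
            control = CoverageTrack(
                contig, strand, cls, np.zeros(contig_lengths[contig], dtype=np.int64)
            )
        called = call_peaks(enrich, control, params)
        if not called:
            continue
        called = score_confidence(called, enrich, control, params)
        called = scale_peaks(called, factor)
        out.extend(filter_high_confidence(called, q_min=q_min, depth_min=depth_min))
    out.sort(key=lambda p: (p.contig, p.start, p.strand, p.mod_class))
    for i, p in enumerate(out):
        p.name = f"peak_{i:05d}"
    return out


def call_sample_sites(
    enrich_reads: pd.DataFrame,
    genome: Mapping[str, str],
    peaks: list[Peak],
    min_rate: float = 0.10,
    min_depth_exclusive: int = 5,
) -> list[EditingSite]:
    """Pileup the deduplicated enrichment library over inosine peaks and
    call editing sites."""
    inosine = [p for p in peaks if p.mod_class == "inosine"]
    if not inosine:
        return []
    de = deduplicate(enrich_reads)
    regions = [(p.contig, p.start, p.end) for p in inosine]
    columns = pileup(de, genome, regions)
    return call_editing_sites(
        columns, inosine, min_rate=min_rate, min_depth_exclusive=min_depth_exclusive
    )


def analyze_experiment(
    reads: Mapping[tuple[str, int, str], pd.DataFrame],
    spike_counts: pd.DataFrame,
    genome: Mapping[str, str],
    annotation: pd.DataFrame,
    params: PeakParams | None = None,
    q_min: float = 13.0,
    depth_min: int = 5,
    min_rate: float = 0.10,
    min_depth_exclusive: int = 5,
    n_clusters: int | None = None,
) -> ExperimentResult:
    """Full analysis of a multi-condition experiment.

    ``reads`` maps (condition, replicate, library_type) to alignment
    tables; ``spike_counts`` carries per-sample spike recoveries.  Genes
    are scored by their maximum spike-scaled peak fold per sample, averaged
    over replicates per condition, then classified for isoform dependency.
    """
    contig_lengths = {c: len(s) for c, s in genome.items()}
    index = build_feature_index(annotation) if len(annotation) else None
    samples: dict[str, SampleResult] = {}
    condition_map: dict[str, str] = {}
    pairs = sorted({(c, r) for (c, r, _t) in reads})
    for condition, rep in pairs:
        sample_id = f"{condition}_rep{rep}"
        enrich = reads[(condition, rep, "enrichment")]
        control = reads[(condition, rep, "control")]
        spikes = spike_counts[
            (spike_counts["condition"] == condition)
            & (spike_counts["replicate"] == rep)
        ]
        peaks = call_sample_peaks(
            enrich, control, contig_lengths, spikes, params, q_min, depth_min
        )
        sites = call_sample_sites(
            enrich, genome, peaks, min_rate, min_depth_exclusive
        )
        inosine = [p for p in peaks if p.mod_class == "inosine"]
        annotated = (
            annotate_peaks(inosine, index)
            if index is not None
            else pd.DataFrame(columns=["peak_id", "gene_id", "feature_class", "fold_enrichment"])
        )
        samples[sample_id] = SampleResult(sample_id, condition, rep, peaks, sites, annotated)
        condition_map[sample_id] = condition

    matrix = gene_scores({sid: s.annotated for sid, s in samples.items()})
    cond_scores = condition_means(matrix, condition_map) if not matrix.empty else matrix
    from .dependency import P150KO

    classifiable = (
        not cond_scores.empty and WT in cond_scores and P150KO in cond_scores
    )
    dep = classify_genes(cond_scores) if classifiable else pd.DataFrame(
        columns=["gene_id", "wt", "p150ko", "dko", "ratio", "category"]
    )

    counts = {}
    for s in samples.values():
        counts.setdefault(s.condition, []).append(len(s.inosine_peaks))
    reductions = {}
    if WT in counts and sum(counts[WT]) > 0:
        reductions = reduction_summary(counts)

    wt_samples = [s for s in samples.values() if s.condition == WT]
    if len(wt_samples) >= 2:
        common = common_genes([s.gene_set for s in wt_samples])
    elif wt_samples:
        common = wt_samples[0].gene_set
    else:
        common = set()
    wt_annot = (
        pd.concat([s.annotated for s in wt_samples], ignore_index=True)
        if wt_samples
        else pd.DataFrame(columns=["gene_id", "feature_class"])
    )
    if not wt_annot.empty:
        wt_annot = wt_annot[wt_annot["gene_id"].isin(common)]
    distribution = region_distribution(wt_annot)

    clusters = None
    if n_clusters is not None and not matrix.empty:
        wt_cols = [c for c in matrix.columns if condition_map[c] == WT]
        detected = matrix[(matrix[wt_cols] > 0).any(axis=1)] if wt_cols else matrix
        if len(detected) >= n_clusters:
            clusters = cluster_gene_scores(detected, n_clusters, condition_map)

    return ExperimentResult(
        samples=samples,
        condition_map=condition_map,
        gene_matrix=matrix,
        condition_scores=cond_scores,
        dependency=dep,
        reductions=reductions,
        distribution=distribution,
        common_wt_genes=common,
        clusters=clusters,
    )


def write_outputs(result: ExperimentResult, outdir: str | Path) -> None:
    """Write BED/VCF/TSV/JSON outputs; byte-identical across runs of the
    same seeded experiment."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sid in sorted(result.samples):
        s = result.samples[sid]
        epio.write_peaks_bed(s.peaks, outdir / f"peaks_{sid}.bed")
        epio.write_sites_vcf(s.sites, outdir / f"sites_{sid}.vcf")
        epio.write_sites_tsv(s.sites, outdir / f"sites_{sid}.tsv")
        s.annotated.to_csv(outdir / f"annotated_{sid}.tsv", sep="\t", index=False)
    result.gene_matrix.rename_axis("gene_id").to_csv(
        outdir / "gene_scores.tsv", sep="\t"
    )
    result.dependency.to_csv(outdir / "dependency.tsv", sep="\t", index=False)
    if result.clusters is not None:
        result.clusters.rename_axis("gene_id").to_csv(
            outdir / "clusters.tsv", sep="\t"
        )
    summary = {
        "inosine_peak_counts": {
            c: v for c, v in sorted(result.peak_counts("inosine").items())
        },
        "m6a_peak_counts": {c: v for c, v in sorted(result.peak_counts("m6A").items())},
        "reductions_pct": result.reductions,
        "category_counts": result.dependency["category"].value_counts().to_dict()
        if not result.dependency.empty
        else {},
        "region_distribution": result.distribution,
        "n_common_wt_genes": len(result.common_wt_genes),
    }
    epio.write_json(summary, outdir / "summary.json")


def run_simulated_analysis(
    config,
    outdir: str | Path | None = None,
    n_clusters: int | None = None,
    **kwargs,
) -> tuple[ExperimentResult, "object"]:
    """Simulate an experiment from ``config`` and analyze it end to end."""
    from .simdata import simulate_experiment, simulate_reference

    genome, annotation = simulate_reference(config)
    reads, spike_counts, truth = simulate_experiment(config, genome, annotation)
    result = analyze_experiment(
        reads, spike_counts, genome, annotation, n_clusters=n_clusters, **kwargs
    )
    if outdir is not None:
        write_outputs(result, outdir)
    return result, truth
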