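"""ADAR1-isoform dependency classification from per-gene peak scores.

ADAR1 exists as two isoforms: interferon-inducible, cytoplasmic p150 and
constitutive, nuclear p110.  Comparing inosine peak scores between
wild-type (WT), p150 knockout and p150/p110 double-knockout conditions
quantifies which isoform each gene's editing requires.  A gene's score in a
sample is the maximum spike-scaled fold enrichment over its inosine peaks;
condition scores are replicate means; the dependency ratio is
``WT / (p150KO + 1)`` and the categories are::

    dko_specific     WT = 0, p150KO = 0, dKO > 1
    p150KO_specific  WT = 0, p150KO > 1
    strong           ratio >= 4
    mild             1 < ratio < 4
    independent      ratio < 1
    unclassified     anything else (the stated partition excludes ratio == 1)

evaluated in that order.  Gene profiles can additionally be clustered
(z-score per gene across condition means, Ward linkage on Euclidean
distances).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CATEGORIES = (
    "strong",
    "mild",
    "independent",
    "p150KO_specific",
    "dko_specific",
    "unclassified",
)

WT = "WT"
P150KO = "p150KO"
DKO = "p150_p110KO"


@dataclass
class DependencyCall:
    gene_id: str
    wt_score: float
    p150ko_score: float
    dko_score: float
    ratio: float
    category: str


def gene_scores(per_sample: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Gene x sample score matrix from annotated peak tables.

    Each sample table needs ``gene_id`` and ``fold_enrichment`` columns
    (one row per peak-gene assignment).  The score is the maximum fold
    enrichment over the gene's peaks in that sample; a gene absent from a
    sample scores 0.  Unannotated rows (empty gene_id) are ignored.
    """
    series = {}
    for sample, table in per_sample.items():
        sub = table[table["gene_id"] != ""] if not table.empty else table
        if sub.empty:
            series[sample] = pd.Series(dtype=float)
        else:
            # a peak assigned to a gene several times (multiple feature
            # classes) still contributes its fold once via max
            series[sample] = sub.groupby("gene_id")["fold_enrichment"].max()
    matrix = pd.DataFrame(series).fillna(0.0)
    matrix = matrix.reindex(sorted(matrix.index))
    matrix = matrix[sorted(matrix.columns)]
    return matrix


def condition_means(
    matrix: pd.DataFrame, condition_map: Mapping[str, str]
) -> pd.DataFrame:
    """Mean score per condition across replicate samples (columns)."""
    missing = [s for s in matrix.columns if s not in condition_map]
    if missing:
        raise ValueError(f"samples without a condition: {missing}")
    return matrix.T.groupby(lambda s: condition_map[s]).mean().T


def classify_dependency(wt: float, p150ko: float, dko: float = 0.0) -> DependencyCall:
    """Classify one gene from its WT / p150KO / double-KO condition scores."""
    if wt < 0 or p150ko < 0 or dko < 0:
        raise ValueError("scores must be non-negative")
    ratio = wt / (p150ko + 1.0)
    if wt == 0 and p150ko == 0 and dko > 1:
        category = "dko_specific"
    elif wt == 0 and p150ko > 1:
        category = "p150KO_specific"
    elif ratio >= 4:
        category = "strong"
    elif 1 < ratio < 4:
        category = "mild"
    elif ratio < 1:
        category = "independent"
    else:
        category = "unclassified"
    return DependencyCall("", wt, p150ko, dko, ratio, category)


def classify_genes(cond_scores: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`classify_dependency` to every row of a condition-score
    table (columns WT, p150KO and optionally p150_p110KO)."""
    rows = []
    dko_col = cond_scores[DKO] if DKO in cond_scores else None
    for gene in cond_scores.index:
        call = classify_dependency(
            float(cond_scores.at[gene, WT]),
            float(cond_scores.at[gene, P150KO]),
            float(dko_col[gene]) if dko_col is not None else 0.0,
        )
        rows.append(
            {
                "gene_id": gene,
                "wt": call.wt_score,
                "p150ko": call.p150ko_score,
                "dko": call.dko_score,
                "ratio": call.ratio,
                "category": call.category,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "wt", "p150ko", "dko", "ratio", "category"]
    )


def common_genes(gene_sets: Sequence[Iterable[str]]) -> set[str]:
    """Genes present in every replicate's gene list."""
    if len(gene_sets) < 2:
        raise ValueError("need at least two replicate gene sets")
    out = set(gene_sets[0])
    for s in gene_sets[1:]:
        out &= set(s)
    return out


def reduction_summary(
    peak_counts: Mapping[str, Sequence[float]], wt_key: str = WT
) -> dict[str, float]:
    """Percent reduction of peak counts per KO condition relative to WT,
    reported to one decimal.

    Replicates are paired by position (KO clone #i against WT clone #i) and
    the per-pair reductions averaged; when replicate numbers differ between
    conditions the ratio of condition means is used instead.
    """
    if wt_key not in peak_counts:
        raise ValueError(f"missing reference condition {wt_key}")
    wt = np.asarray(peak_counts[wt_key], dtype=float)
    if wt.size == 0 or float(wt.mean()) == 0:
        raise ValueError("WT mean peak count is zero")
    out = {}
    for cond, counts in peak_counts.items():
        if cond == wt_key:
            continue
        k = np.asarray(counts, dtype=float)
        if k.size == wt.size and (wt > 0).all():
            reduction = float(np.mean(1.0 - k / wt))
        else:
            reduction = 1.0 - float(k.mean()) / float(wt.mean())
        out[cond] = round(100.0 * reduction, 1)
    return out


def cluster_gene_scores(
    matrix: pd.DataFrame,
    n_clusters: int,
    condition_map: Mapping[str, str] | None = None,
) -> pd.Series:
    """Ward-linkage agglomerative clustering of z-scored gene profiles.

    When ``condition_map`` is given, replicate columns are first aggregated
    to condition means; each gene row is then z-scored across columns
    (zero-variance rows get z = 0) and clustered with Euclidean affinity
    and Ward linkage.  Returns gene -> integer cluster label.
    """
    from sklearn.cluster import AgglomerativeClustering

    if condition_map is not None:
        matrix = condition_means(matrix, condition_map)
    if n_clusters > len(matrix):
        raise ValueError("more clusters requested than genes")
    values = matrix.to_numpy(dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (values - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    if n_clusters == len(matrix):
        labels = np.arange(len(matrix))
    else:
        model = AgglomerativeClustering(
            n_clusters=n_clusters, metric="euclidean", linkage="ward"
        )
        labels = model.fit_predict(z)
    return pd.Series(labels, index=matrix.index, name="cluster")
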