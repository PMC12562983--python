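"""Enrichment peak calling against a solution-control background.

The enrichment library is the signal and the non-enriched solution control
the background.  Per (contig, strand, modification class) the caller forms
a pseudocounted log2 ratio of enrichment over library-size-scaled control
depth, smooths it with a centered moving average, and takes local maxima of
sufficient prominence as peak summits (scipy ``find_peaks``).  Peak
boundaries extend from each summit to where the smoothed signal drops below
half the summit's prominence (or below zero).  Fold enrichment is
summit-based (2**max smoothed signal) and is put on an absolute scale by
dividing by the exogenous spike-in controls' enrichment factor.

Confidence is a PHRED-scaled q-score from a two-state (background/enriched)
Gaussian HMM fit on the binned smoothed signal: q = -10*log10(1 - mean
posterior of the enriched state over the peak's bins), capped at 100.  The
HMM is initialized deterministically (low/high split of the sorted binned
signal) so scoring needs no random seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks as _scipy_find_peaks

Q_CAP = 100.0
Q_EPS = 1e-10


class SpikeControlZeroError(ValueError):
    """Raised when a spike-in control denominator is zero."""


@dataclass
class CoverageTrack:
    """Per-base read depth over one contig for one strand and mod class."""

    contig: str
    strand: str
    mod_class: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if (self.depth < 0).any():
            raise ValueError("coverage depths must be non-negative")


@dataclass
class Peak:
    contig: str
    start: int
    end: int
    strand: str
    mod_class: str
    fold_enrichment: float
    max_depth: int
    summit: int
    q_score: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("peak requires start < end")
        if not self.start <= self.summit < self.end:
            raise ValueError("summit must lie in [start, end)")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class PeakParams:
    """Tunables for peak calling.

    smoothing_window -- centered moving-average width in bases; also the
        bin size for HMM scoring.
    pseudocount -- added to both depths before the log ratio; keeps
        positions with zero control depth usable.
    min_prominence -- log2 units; 1.0 demands a 2-fold local excursion.
    min_width -- candidate peaks narrower than this are dropped.
    size_factor -- enrichment/control library-size ratio; None derives it
        from the track sums, but pipelines should pass the ratio of total
        deduplicated reads so sparse tracks are not self-normalized.
    """

    smoothing_window: int = 25
    pseudocount: float = 1.0
    min_prominence: float = 1.0
    min_width: int = 30
    size_factor: float | None = None


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

def build_coverage(
    reads: pd.DataFrame, contig_lengths: Mapping[str, int]
) -> dict[tuple[str, str, str], CoverageTrack]:
    """Per-base depth per (contig, strand, mod_class) from mapped reads.

    Depth at position p counts reads whose [start, start+length) interval
    covers p.  A read extending past its contig end is an error naming the
    read.
    """
    tracks: dict[tuple[str, str, str], CoverageTrack] = {}
    if reads.empty:
        return tracks
    ends = reads["start"].to_numpy() + reads["length"].to_numpy()
    limits = reads["contig"].map(contig_lengths)
    if limits.isna().any():
        bad = reads.loc[limits.isna(), "read_id"].iloc[0]
        raise ValueError(f"read {bad} maps to unknown contig")
    over = ends > limits.to_numpy()
    if over.any():
        bad = reads.loc[over, "read_id"].iloc[0]
        raise ValueError(f"read {bad} extends beyond its contig end")
    for (contig, strand, cls), grp in reads.groupby(
        ["contig", "strand", "mbc_class"], sort=True
    ):
        length = contig_lengths[contig]
        diff = np.zeros(length + 1, dtype=np.int64)
        starts = grp["start"].to_numpy()
        np.add.at(diff, starts, 1)
        np.add.at(diff, starts + grp["length"].to_numpy(), -1)
        tracks[(contig, strand, cls)] = CoverageTrack(
            contig, strand, cls, np.cumsum(diff[:-1])
        )
    return tracks


# ---------------------------------------------------------------------------
# Spike-in scaling
# ---------------------------------------------------------------------------

def spike_enrichment_factor(spikes: pd.DataFrame) -> float:
    """Ratio-of-ratios recovery of modified vs unmodified spike-ins.

    factor = (sum enriched_mod / sum control_mod)
           / (sum enriched_unmod / sum control_unmod)
    """
    mod = spikes[spikes["modified"].astype(bool)]
    unmod = spikes[~spikes["modified"].astype(bool)]
    if mod.empty or unmod.empty:
        raise ValueError("need at least one modified and one unmodified spike")
    cm = mod["count_control"].sum()
    cu = unmod["count_control"].sum()
    eu = unmod["count_enriched"].sum()
    if cm == 0 or cu == 0 or eu == 0:
        raise SpikeControlZeroError("spike_control_zero")
    factor = (mod["count_enriched"].sum() / cm) / (eu / cu)
    if factor <= 0:
        raise SpikeControlZeroError("spike_control_zero")
    return float(factor)


# ---------------------------------------------------------------------------
# Peak calling
# ---------------------------------------------------------------------------

def smoothed_log_ratio(
    enrich: CoverageTrack, control: CoverageTrack, params: PeakParams
) -> np.ndarray:
    """Centered-moving-average-smoothed log2((E+c0)/(s*C+c0))."""
    if enrich.contig != control.contig or enrich.strand != control.strand:
        raise ValueError("enrichment and control tracks must share contig/strand")
    if len(enrich.depth) != len(control.depth):
        raise ValueError("enrichment and control tracks differ in length")
    s = params.size_factor
    if s is None:
        ctot = control.depth.sum()
        s = (enrich.depth.sum() / ctot) if ctot > 0 else 1.0
    c0 = params.pseudocount
    signal = np.log2(
        (enrich.depth + c0) / (s * control.depth.astype(float) + c0)
    )
    return uniform_filter1d(signal, size=params.smoothing_window, mode="nearest")


def call_peaks(
    enrich: CoverageTrack, control: CoverageTrack, params: PeakParams | None = None
) -> list[Peak]:
    """Call unscored candidate peaks on one (contig, strand, class) track pair.

    Summits are local maxima of the smoothed log ratio with prominence >=
    ``min_prominence``; each summit's boundaries extend outward until the
    signal falls below (summit - prominence/2) or below 0, where the
    prominence is the summit's own.  Overlapping candidates are merged;
    candidates narrower than ``min_width`` are dropped.  ``fold_enrichment``
    is the raw summit fold (2**max smoothed signal), before spike scaling.
    """
    params = params or PeakParams()
    smoothed = smoothed_log_ratio(enrich, control, params)
    # a summit must both rise min_prominence above its surroundings and
    # reach min_prominence itself: enrichment is a positive excursion, so
    # prominence gained by valleys dipping below zero does not count
    summits, props = _scipy_find_peaks(
        smoothed, prominence=params.min_prominence, height=params.min_prominence
    )
    if len(summits) == 0:
        return []
    intervals = []
    n = len(smoothed)
    for summit, prom in zip(summits, props["prominences"]):
        # descend at most half the summit height (prominence capped at the
        # summit value, again ignoring sub-zero valleys), never below 0
        stop = max(smoothed[summit] - min(prom, smoothed[summit]) / 2.0, 0.0)
        left = summit
        while left > 0 and smoothed[left - 1] >= stop:
            left -= 1
        right = summit
        while right < n - 1 and smoothed[right + 1] >= stop:
            right += 1
        intervals.append((left, right + 1))
    # merge overlapping candidate intervals
    order = np.argsort([iv[0] for iv in intervals], kind="stable")
    merged: list[list[int]] = []
    for i in order:
        s0, e0 = intervals[i]
        if merged and s0 < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e0)
        else:
            merged.append([s0, e0])
    peaks = []
    for s0, e0 in merged:
        if e0 - s0 < params.min_width:
            continue
        window = smoothed[s0:e0]
        summit = s0 + int(np.argmax(window))
        peaks.append(
            Peak(
                contig=enrich.contig,
                start=int(s0),
                end=int(e0),
                strand=enrich.strand,
                mod_class=enrich.mod_class,
                fold_enrichment=float(2.0 ** window.max()),
                max_depth=int(enrich.depth[s0:e0].max()),
                summit=int(summit),
            )
        )
    return peaks


def scale_peaks(peaks: Sequence[Peak], factor: float) -> list[Peak]:
    """Divide each peak's fold enrichment by the spike-in factor."""
    if factor <= 0:
        raise ValueError("spike factor must be positive")
    return [replace(p, fold_enrichment=p.fold_enrichment / factor) for p in peaks]


# ---------------------------------------------------------------------------
# HMM confidence scoring
# ---------------------------------------------------------------------------

def posterior_to_q(posterior: float) -> float:
    """PHRED q-score of an enriched-state posterior, capped at 100."""
    return min(Q_CAP, -10.0 * math.log10(max(Q_EPS, 1.0 - posterior)))


def _bin_signal(smoothed: np.ndarray, width: int) -> np.ndarray:
    n_bins = int(math.ceil(len(smoothed) / width))
    return np.array(
        [smoothed[i * width : (i + 1) * width].mean() for i in range(n_bins)]
    )


def _enriched_posteriors(binned: np.ndarray, min_enriched_mean: float = 0.0) -> np.ndarray:
    """Posterior of the enriched (higher-mean) state per bin, via a 2-state
    Gaussian HMM with deterministic low/high initialization.

    When the fitted enriched state's mean falls below ``min_enriched_mean``
    the two states merely split the background noise, so the track is
    declared peak-free (all posteriors 0) instead of letting upper-tail
    noise bins masquerade as enrichment.
    """
    import logging

    from hmmlearn.hmm import GaussianHMM

    # the convergence monitor logs a spurious warning when the EM delta is
    # a rounding-level negative at the tolerance floor
    logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)

    if len(binned) < 4 or float(np.ptp(binned)) < 1e-9:
        return np.zeros(len(binned))
    x = binned.reshape(-1, 1)
    srt = np.sort(binned)
    half = len(srt) // 2
    lo, hi = srt[:half], srt[half:]
    means = np.array([[lo.mean()], [hi.mean()]])
    covars = np.maximum(np.array([[lo.var()], [hi.var()]]), 1e-4)
    model = GaussianHMM(
        n_components=2,
        covariance_type="diag",
        n_iter=100,
        tol=1e-6,
        init_params="",
        params="stmc",
    )
    model.startprob_ = np.array([0.5, 0.5])
    model.transmat_ = np.array([[0.95, 0.05], [0.05, 0.95]])
    model.means_ = means
    model.covars_ = covars
    model.fit(x)
    post = model.predict_proba(x)
    enriched = int(np.argmax(model.means_.ravel()))
    if model.means_.ravel()[enriched] < min_enriched_mean:
        return np.zeros(len(binned))
    return post[:, enriched]


def score_confidence(
    peaks: Sequence[Peak],
    enrich: CoverageTrack,
    control: CoverageTrack,
    params: PeakParams | None = None,
) -> list[Peak]:
    """Attach HMM-posterior q-scores to peaks called on these tracks."""
    params = params or PeakParams()
    smoothed = smoothed_log_ratio(enrich, control, params)
    w = params.smoothing_window
    posteriors = _enriched_posteriors(
        _bin_signal(smoothed, w), min_enriched_mean=params.min_prominence
    )
    out = []
    for p in peaks:
        if p.contig != enrich.contig or p.end > len(smoothed):
            raise ValueError(f"peak {p.name or p.start} lies outside the track")
        # a bin belongs to the peak when its center lies inside the interval;
        # narrow peaks fall back to the summit's bin
        b0, b1 = p.start // w, (p.end - 1) // w + 1
        bins = [i for i in range(b0, b1) if p.start <= i * w + w // 2 < p.end]
        if not bins:
            bins = [p.summit // w]
        mean_post = float(posteriors[bins].mean())
        out.append(replace(p, q_score=posterior_to_q(mean_post)))
    return out


def filter_high_confidence(
    peaks: Iterable[Peak], q_min: float = 13.0, depth_min: int = 5
) -> list[Peak]:
    """High-confidence peaks: q >= q_min and enrichment max depth >= depth_min.

    The minimum-depth default of 5 reads in the enrichment sample follows
    the assay's high-confidence definition; q_min=13 corresponds to an
    enriched-state posterior of about 0.95.
    """
    return [
        p
        for p in peaks
        if p.q_score is not None and p.q_score >= q_min and p.max_depth >= depth_min
    ]
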