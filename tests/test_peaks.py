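"""Coverage building, spike scaling, peak calling and HMM confidence scores."""

import numpy as np
import pandas as pd
import pytest

from editpeaks import (
    CoverageTrack,
    Peak,
    PeakParams,
    build_coverage,
    call_peaks,
    filter_high_confidence,
    posterior_to_q,
    scale_peaks,
    score_confidence,
    simulate_track_pair,
    spike_enrichment_factor,
)
from editpeaks.peaks import SpikeControlZeroError

PARAMS = PeakParams(size_factor=1.0)


def _reads(rows):
    return pd.DataFrame(
        rows,
        columns=["read_id", "contig", "start", "strand", "length", "mbc_class", "umi", "overrides"],
    )


class TestBuildCoverage:
    def test_single_read_covers_its_interval(self):
        tracks = build_coverage(
            _reads([("r1", "chr1", 10, "+", 50, "inosine", "AA", "")]), {"chr1": 100}
        )
        depth = tracks[("chr1", "+", "inosine")].depth
        assert depth[9] == 0 and depth[10] == 1 and depth[59] == 1 and depth[60] == 0
        assert depth.sum() == 50

    def test_overlapping_reads_add(self):
        tracks = build_coverage(
            _reads(
                [
                    ("r1", "chr1", 10, "+", 20, "inosine", "AA", ""),
                    ("r2", "chr1", 10, "+", 20, "inosine", "CC", ""),
                ]
            ),
            {"chr1": 100},
        )
        assert (tracks[("chr1", "+", "inosine")].depth[10:30] == 2).all()

    def test_matches_per_position_counting_oracle(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(60):
            rows.append(
                (
                    f"r{i}",
                    "chr1",
                    int(rng.integers(0, 450)),
                    rng.choice(["+", "-"]),
                    int(rng.integers(20, 50)),
                    rng.choice(["inosine", "m6A"]),
                    "AA",
                    "",
                )
            )
        reads = _reads(rows)
        tracks = build_coverage(reads, {"chr1": 500})
        for (contig, strand, cls), track in tracks.items():
            expected = np.zeros(500, dtype=int)
            for row in reads.itertuples():
                if row.strand == strand and row.mbc_class == cls:
                    for p in range(row.start, row.start + row.length):
                        expected[p] += 1
            np.testing.assert_array_equal(track.depth, expected)

    def test_read_beyond_contig_end_names_the_read(self):
        with pytest.raises(ValueError, match="r_bad"):
            build_coverage(
                _reads([("r_bad", "chr1", 90, "+", 50, "inosine", "AA", "")]), {"chr1": 100}
            )


class TestSpikeFactor:
    def test_ratio_of_ratios(self):
        spikes = pd.DataFrame(
            [
                {"spike_id": "m", "modified": True, "count_enriched": 1000, "count_control": 100},
                {"spike_id": "u", "modified": False, "count_enriched": 100, "count_control": 100},
            ]
        )
        assert spike_enrichment_factor(spikes) == pytest.approx(10.0)

    def test_equal_sums_give_unity(self):
        spikes = pd.DataFrame(
            [
                {"spike_id": "m", "modified": True, "count_enriched": 500, "count_control": 500},
                {"spike_id": "u", "modified": False, "count_enriched": 500, "count_control": 500},
            ]
        )
        assert spike_enrichment_factor(spikes) == pytest.approx(1.0)

    def test_zero_control_count_raises(self):
        spikes = pd.DataFrame(
            [
                {"spike_id": "m", "modified": True, "count_enriched": 500, "count_control": 500},
                {"spike_id": "u", "modified": False, "count_enriched": 500, "count_control": 0},
            ]
        )
        with pytest.raises(SpikeControlZeroError, match="spike_control_zero"):
            spike_enrichment_factor(spikes)


def _flat_tracks(length=5000, depth=20, rect=None):
    enrich = np.full(length, depth, dtype=np.int64)
    control = np.full(length, depth, dtype=np.int64)
    if rect:
        s, e, fold = rect
        enrich[s:e] = depth * fold
    return (
        CoverageTrack("chr1", "+", "inosine", enrich),
        CoverageTrack("chr1", "+", "inosine", control),
    )


class TestCallPeaks:
    def test_identical_tracks_yield_no_peaks(self):
        enrich, control = _flat_tracks()
        assert call_peaks(enrich, control, PARAMS) == []

    def test_noiseless_rectangle_recovered_with_accurate_fold(self):
        enrich, control = _flat_tracks(rect=(1000, 1200, 10))
        peaks = call_peaks(enrich, control, PARAMS)
        assert len(peaks) == 1
        p = peaks[0]
        # closed-form fold on the plateau: (200+1)/(20+1)
        assert p.fold_enrichment == pytest.approx(201 / 21, rel=1e-6)
        assert abs(p.fold_enrichment - 10) / 10 < 0.10
        w = PARAMS.smoothing_window
        assert abs(p.start - 1000) <= w and abs(p.end - 1200) <= w
        assert 1000 <= p.summit < 1200

    def test_noisy_rectangle_recovered(self):
        enrich, control = simulate_track_pair(20_000, 20.0, [(8000, 8200, 10.0)], seed=1)
        peaks = call_peaks(enrich, control, PARAMS)
        overlapping = [p for p in peaks if p.start < 8200 and p.end > 8000]
        assert len(overlapping) == 1
        assert abs(overlapping[0].fold_enrichment - 10) / 10 < 0.2

    def test_two_separated_rectangles_give_two_ordered_peaks(self):
        enrich = np.full(5000, 20, dtype=np.int64)
        enrich[1000:1200] = 200
        enrich[2000:2200] = 200
        control = np.full(5000, 20, dtype=np.int64)
        peaks = call_peaks(
            CoverageTrack("chr1", "+", "inosine", enrich),
            CoverageTrack("chr1", "+", "inosine", control),
            PARAMS,
        )
        assert len(peaks) == 2
        assert peaks[0].start < peaks[0].end <= peaks[1].start < peaks[1].end
        assert 1000 - 25 <= peaks[0].start and peaks[1].end <= 2200 + 25

    def test_mismatched_track_lengths_raise(self):
        enrich, _ = _flat_tracks(length=100)
        _, control = _flat_tracks(length=200)
        with pytest.raises(ValueError, match="length"):
            call_peaks(enrich, control, PARAMS)

    def test_peaks_disjoint_per_track(self):
        enrich, control = simulate_track_pair(
            50_000, 20.0, [(i, i + 200, 10.0) for i in range(2000, 48_000, 3000)], seed=3
        )
        peaks = call_peaks(enrich, control, PARAMS)
        for a, b in zip(peaks, peaks[1:]):
            assert a.end <= b.start

    def test_raising_prominence_never_increases_peak_count(self):
        enrich, control = simulate_track_pair(
            30_000, 20.0, [(5000, 5200, 3.0), (15_000, 15_200, 10.0)], seed=4
        )
        counts = [
            len(call_peaks(enrich, control, PeakParams(min_prominence=prom, size_factor=1.0)))
            for prom in (0.5, 1.0, 2.0, 4.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestScalePeaks:
    def _peak(self, fold=10.0):
        return Peak("chr1", 0, 100, "+", "inosine", fold, 50, 50)

    def test_identity_and_arithmetic(self):
        assert scale_peaks([self._peak(10)], 1.0)[0].fold_enrichment == 10
        assert scale_peaks([self._peak(10)], 2.0)[0].fold_enrichment == 5

    def test_composition(self):
        once = scale_peaks(scale_peaks([self._peak(12)], 3.0), 3.0)
        squared = scale_peaks([self._peak(12)], 9.0)
        assert once[0].fold_enrichment == pytest.approx(squared[0].fold_enrichment)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            scale_peaks([self._peak()], 0.0)


class TestConfidence:
    def test_posterior_half_gives_q_3(self):
        assert posterior_to_q(0.5) == pytest.approx(3.0103, abs=1e-3)

    def test_posterior_cap(self):
        assert posterior_to_q(1.0) == 100.0
        assert posterior_to_q(1 - 1e-12) == 100.0

    def test_planted_peak_outscores_background_windows(self):
        """Across 100 seeded tracks, the planted 10x peak's q exceeds the q
        of every same-width background interval."""
        wins = 0
        for seed in range(100):
            enrich, control = simulate_track_pair(
                20_000, 20.0, [(8000, 8200, 10.0)], seed=100 + seed
            )
            called = call_peaks(enrich, control, PARAMS)
            planted = [p for p in called if p.start < 8200 and p.end > 8000]
            if not planted:
                continue
            background = [
                Peak("chr1", s, s + 200, "+", "inosine", 1.0, 20, s + 100)
                for s in range(1000, 19_000, 2000)
                if not (s < 8600 and s + 200 > 7600)
            ]
            scored = score_confidence(planted + background, enrich, control, PARAMS)
            q_planted = scored[0].q_score
            if all(q_planted > p.q_score for p in scored[1:]):
                wins += 1
        assert wins == 100

    def test_peak_outside_track_raises(self):
        enrich, control = _flat_tracks(length=100)
        peak = Peak("chr1", 50, 150, "+", "inosine", 2.0, 20, 60)
        with pytest.raises(ValueError):
            score_confidence([peak], enrich, control, PARAMS)


class TestHighConfidenceFilter:
    def _peak(self, q, depth):
        return Peak("chr1", 0, 100, "+", "inosine", 10.0, depth, 50, q_score=q)

    def test_depth_below_five_removed_regardless_of_q(self):
        assert filter_high_confidence([self._peak(100.0, 4)]) == []

    def test_depth_five_with_good_q_retained(self):
        assert len(filter_high_confidence([self._peak(20.0, 5)])) == 1

    def test_zero_thresholds_are_identity(self):
        peaks = [self._peak(0.0, 0), self._peak(50.0, 100)]
        assert filter_high_confidence(peaks, q_min=0, depth_min=0) == peaks


def test_mod_classes_called_independently(experiment):
    """Removing every inosine-class read leaves the m6A peak calls
    byte-identical: peak calling is strictly per modification class."""
    from editpeaks.io import peaks_to_bed
    from editpeaks.pipeline import call_sample_peaks

    genome = experiment["genome"]
    lengths = {c: len(s) for c, s in genome.items()}
    spikes = experiment["spike_counts"]
    spikes_wt = spikes[(spikes["condition"] == "WT") & (spikes["replicate"] == 1)]
    enrich = experiment["reads"][("WT", 1, "enrichment")]
    control = experiment["reads"][("WT", 1, "control")]
    size = len(enrich) / len(control)
    params = PeakParams(size_factor=size)

    def m6a_bed(e, c):
        peaks = call_sample_peaks(e, c, lengths, spikes_wt, params=params)
        return peaks_to_bed([p for p in peaks if p.mod_class == "m6A"])

    full = m6a_bed(enrich, control)
    stripped = m6a_bed(
        enrich[enrich["mbc_class"] != "inosine"], control[control["mbc_class"] != "inosine"]
    )
    assert full == stripped and full  # identical and non-empty


def test_planted_peak_recovery_across_seeds():
    """>=95% of planted peaks (fold >= 8, depth >= 20, width >= 100) are
    recovered with Jaccard >= 0.5 across 20 seeded simulations, with at
    most ~1 false peak per 100 kb."""
    from editpeaks import SimConfig, simulate_experiment, simulate_reference
    from editpeaks.pipeline import call_sample_peaks

    recovered = planted = false_calls = total_bases = 0
    for seed in range(20):
        cfg = SimConfig(
            seed=300 + seed,
            contig_length=25_000,
            n_genes=5,
            n_peaks=5,
            n_m6a_peaks=0,
            mbc_table={"CAGT": "inosine"},
            conditions=("WT",),
            n_replicates=1,
            background_depth=20.0,
        )
        genome, annotation = simulate_reference(cfg)
        reads, spikes, truth = simulate_experiment(cfg, genome, annotation)
        peaks = call_sample_peaks(
            reads[("WT", 1, "enrichment")],
            reads[("WT", 1, "control")],
            {c: len(s) for c, s in genome.items()},
            spikes,
        )
        total_bases += cfg.contig_length
        matched_calls = set()
        for row in truth.peaks.itertuples():
            planted += 1
            best = None
            for i, p in enumerate(peaks):
                if p.strand != row.strand:
                    continue
                inter = max(0, min(p.end, row.end) - max(p.start, row.start))
                union = (p.end - p.start) + (row.end - row.start) - inter
                if union and inter / union >= 0.5:
                    best = i
                    break
            if best is not None:
                recovered += 1
                matched_calls.add(best)
        false_calls += len(peaks) - len(matched_calls)
    assert planted == 100
    assert recovered / planted >= 0.95
    assert false_calls / total_bases <= 1 / 100_000
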