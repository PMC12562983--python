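"""Pileup counting and the four-clause editing-site filter contract."""

import numpy as np
import pandas as pd
import pytest

from editpeaks import Peak, call_editing_sites, editing_density, pileup
from editpeaks.sites import EditingSite, PileupColumn


def _reads(rows):
    return pd.DataFrame(
        rows,
        columns=["read_id", "contig", "start", "strand", "length", "mbc_class", "umi", "overrides"],
    )


def _column(ref, plus_counts, minus_counts=None, contig="chr1", pos=50):
    counts = {"+": dict(plus_counts), "-": dict(minus_counts or {})}
    depth = sum(sum(d.values()) for d in counts.values())
    return PileupColumn(contig, pos, ref, counts, depth)


def _peak(start=0, end=100, strand="+", name="peak_00000", contig="chr1"):
    return Peak(contig, start, end, strand, "inosine", 10.0, 50, (start + end) // 2, 50.0, name)


class TestPileup:
    def test_single_clean_read(self):
        genome = {"chr1": "ACGT" * 25}
        cols = pileup(
            _reads([("r1", "chr1", 10, "+", 20, "inosine", "AA", "")]), genome, [("chr1", 0, 100)]
        )
        assert len(cols) == 20
        for col in cols:
            assert col.depth == 1
            assert col.counts["+"][genome["chr1"][col.pos]] == 1

    def test_override_replaces_reference_base(self):
        genome = {"chr1": "A" * 100}
        cols = pileup(
            _reads(
                [
                    ("r1", "chr1", 10, "+", 20, "inosine", "AA", "15:G"),
                    ("r2", "chr1", 10, "+", 20, "inosine", "CC", ""),
                ]
            ),
            genome,
            [("chr1", 15, 16)],
        )
        (col,) = cols
        assert col.depth == 2
        assert col.counts["+"] == {"A": 1, "G": 1}

    def test_depth_cap_at_20000(self):
        genome = {"chr1": "A" * 60}
        rows = [(f"r{i:05d}", "chr1", 10, "+", 20, "inosine", "AA", "") for i in range(20_001)]
        cols = pileup(_reads(rows), genome, [("chr1", 15, 16)])
        assert cols[0].depth == 20_000

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(7)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 300))}
        rows = []
        for i in range(150):
            start = int(rng.integers(0, 280))
            length = 20
            strand = str(rng.choice(["+", "-"]))
            ov = ""
            if rng.random() < 0.4:
                p = int(rng.integers(start, start + length))
                ov = f"{p}:{rng.choice(list('ACGT'))}"
            rows.append((f"r{i:03d}", "chr1", start, strand, length, "inosine", "AA", ov))
        reads = _reads(rows)
        cols = {c.pos: c for c in pileup(reads, genome, [("chr1", 50, 250)])}
        for pos in range(50, 250):
            expected = {"+": {}, "-": {}}
            for row in reads.itertuples():
                if row.start <= pos < row.start + row.length:
                    base = genome["chr1"][pos]
                    for item in row.overrides.split(";"):
                        if item and int(item.split(":")[0]) == pos:
                            base = item.split(":")[1]
                    expected[row.strand][base] = expected[row.strand].get(base, 0) + 1
            depth = sum(sum(d.values()) for d in expected.values())
            if depth == 0:
                assert pos not in cols
            else:
                assert cols[pos].counts == expected
                assert cols[pos].depth == depth

    def test_region_outside_genome_raises(self):
        with pytest.raises(ValueError):
            pileup(_reads([]), {"chr1": "A" * 50}, [("chr1", 0, 100)])


class TestCallEditingSites:
    def test_rate_boundary_inside_peak_is_called(self):
        col = _column("A", {"A": 18, "G": 2})
        (site,) = call_editing_sites([col], [_peak()])
        assert site.rate == pytest.approx(0.10)
        assert site.depth == 20 and site.alt_count == 2 and site.strand == "+"

    def test_depth_five_rejected_strictly(self):
        col = _column("A", {"A": 4, "G": 1})
        assert call_editing_sites([col], [_peak()]) == []

    def test_depth_six_accepted(self):
        col = _column("A", {"A": 4, "G": 2})
        (site,) = call_editing_sites([col], [_peak()])
        assert site.depth == 6

    def test_site_outside_every_peak_rejected(self):
        col = _column("A", {"A": 50, "G": 50}, pos=500)
        assert call_editing_sites([col], [_peak(0, 100)]) == []

    def test_minus_strand_t_to_c_reported_as_edit(self):
        col = _column("T", {"T": 7, "C": 2}, {"T": 1})
        (site,) = call_editing_sites([col], [_peak(strand="-")])
        assert site.strand == "-"
        assert site.rate == pytest.approx(0.2)

    def test_rate_below_threshold_rejected(self):
        col = _column("A", {"A": 19, "G": 1})
        assert call_editing_sites([col], [_peak()]) == []

    def test_multiallelic_only_edit_component_counted(self):
        col = _column("A", {"A": 13, "G": 2, "C": 5})
        (site,) = call_editing_sites([col], [_peak()])
        assert site.alt_count == 2
        assert site.rate == pytest.approx(0.10)

    def test_wrong_ref_base_for_strand_context_skipped(self):
        col = _column("C", {"C": 10, "G": 10})
        assert call_editing_sites([col], [_peak()]) == []

    def test_output_sorted_by_position(self):
        cols = [
            _column("A", {"A": 10, "G": 5}, pos=90),
            _column("A", {"A": 10, "G": 5}, pos=10),
        ]
        sites = call_editing_sites(cols, [_peak()])
        assert [s.pos for s in sites] == [10, 90]

    def test_minus_strand_gene_end_to_end(self):
        """Constructed minus-strand gene: reference T with planted C
        overrides travels through pileup into a minus-strand site call."""
        genome = {"chr1": "T" * 200}
        rows = []
        for i in range(30):
            ov = "100:C" if i < 9 else ""
            rows.append((f"r{i:02d}", "chr1", 80, "-", 40, "inosine", f"u{i}", ov))
        cols = pileup(_reads(rows), genome, [("chr1", 90, 110)])
        sites = call_editing_sites(cols, [_peak(50, 150, strand="-")])
        assert len(sites) == 1
        assert sites[0].pos == 100 and sites[0].strand == "-"
        assert sites[0].rate == pytest.approx(0.3)

    def test_raising_thresholds_never_increases_site_count(self):
        rng = np.random.default_rng(3)
        cols = [
            _column(
                "A",
                {"A": int(rng.integers(0, 30)), "G": int(rng.integers(0, 10))},
                pos=int(p),
            )
            for p in rng.choice(100, size=40, replace=False)
        ]
        peaks = [_peak()]
        base = len(call_editing_sites(cols, peaks))
        assert len(call_editing_sites(cols, peaks, min_rate=0.2)) <= base
        assert len(call_editing_sites(cols, peaks, min_depth_exclusive=10)) <= base

    def test_all_filter_clauses_recheckable(self, experiment, experiment_result):
        genome = experiment["genome"]
        sample = experiment_result.samples["WT_rep1"]
        inosine = {p.name: p for p in sample.inosine_peaks}
        assert sample.sites
        for s in sample.sites:
            peak = inosine[s.peak_id]
            assert peak.start <= s.pos < peak.end
            assert s.depth > 5
            assert s.rate >= 0.10
            ref = genome[s.contig][s.pos]
            assert ref == ("A" if s.strand == "+" else "T")


class TestEditingDensity:
    def test_zero_sites(self):
        assert editing_density([], _peak(0, 100)) == 0.0

    @pytest.mark.parametrize("n,width,expected", [(8, 100, 8.0), (19, 950, 2.0)])
    def test_arithmetic(self, n, width, expected):
        sites = [EditingSite("chr1", i, "+", 20, 4, 0.2) for i in range(n)]
        assert editing_density(sites, _peak(0, width)) == pytest.approx(expected)


def test_rate_estimates_converge_with_depth():
    """MAE of called rates against planted rates shrinks with depth and is
    below 0.02 at depth 1000."""
    rng = np.random.default_rng(12)
    genome = {"chr1": "A" * 1200}
    site_pos = np.arange(100, 1100, 40)
    rates = rng.uniform(0.15, 0.7, len(site_pos))
    maes = []
    for depth in (50, 200, 1000):
        rows = []
        n_reads = depth * 12  # read length 100 over 1200 bases
        starts = rng.integers(0, 1100, n_reads)
        for i, start in enumerate(starts):
            ov = []
            for pos, rate in zip(site_pos, rates):
                if start <= pos < start + 100 and rng.random() < rate:
                    ov.append(f"{pos}:G")
            rows.append((f"r{i:06d}", "chr1", int(start), "+", 100, "inosine", f"u{i}", ";".join(ov)))
        peak = _peak(0, 1200)
        cols = pileup(_reads(rows), genome, [("chr1", 0, 1200)])
        called = {s.pos: s.rate for s in call_editing_sites(cols, [peak])}
        errs = [abs(called[p] - r) for p, r in zip(site_pos, rates) if p in called]
        assert len(errs) == len(site_pos)
        maes.append(float(np.mean(errs)))
    assert maes[2] < 0.02
    assert maes[2] < maes[0]
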