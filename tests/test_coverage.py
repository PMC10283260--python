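import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fusionscreen._errors import ValidationError
from fusionscreen.coverage import (
    FilterParams,
    compute_coverage,
    exon_support_stats,
    filter_alignments,
    subset_alignments,
)
from fusionscreen.io_formats import CoverageTrack, GeneModel, GenomicInterval

from conftest import make_alignment, random_alignments
from oracles import naive_coverage


# Hand-enumerated 10-record filter fixture: (identity, aligned, read_len).
# Survivors at defaults (>= 0.95 identity AND >= 0.90 aligned fraction):
# records 1, 4, 5, 8, 9 (enumerated by hand before implementation).
FILTER_FIXTURE = [
    (1, 0.950, 90, 100, True),   # both thresholds exactly -> kept
    (2, 0.940, 100, 100, False), # identity below
    (3, 1.000, 89, 100, False),  # fraction 0.89 below
    (4, 1.000, 100, 100, True),
    (5, 0.951, 95, 100, True),
    (6, 0.950, 89, 100, False),  # fraction below despite identity ok
    (7, 0.800, 50, 100, False),
    (8, 0.960, 90, 100, True),
    (9, 0.950, 100, 100, True),
    (10, 0.900, 95, 100, False), # identity below despite fraction ok
]


def _fixture_alignments():
    return [
        make_alignment(
            f"r{i}", "chr1", [(0, aligned)],
            identity=ident, aligned_length=aligned, read_length=read_len,
        )
        for i, ident, aligned, read_len, _ in FILTER_FIXTURE
    ]


class TestFilter:
    def test_boundary_inclusive(self):
        aln = make_alignment("r", "c", [(0, 90)], identity=0.95,
                             aligned_length=90, read_length=100)
        assert filter_alignments([aln]) == [aln]

    def test_identity_below_dropped(self):
        aln = make_alignment("r", "c", [(0, 100)], identity=0.94)
        assert filter_alignments([aln]) == []

    def test_hand_enumerated_fixture(self):
        kept = filter_alignments(_fixture_alignments())
        expected = [f"r{i}" for i, *_rest, keep in FILTER_FIXTURE if keep]
        assert [a.read_id for a in kept] == expected

    def test_zero_read_length_rejected(self):
        aln = make_alignment("r", "c", [(0, 10)])
        object.__setattr__(aln, "read_length", 0)
        with pytest.raises(ValidationError):
            filter_alignments([aln])

    @given(
        mi=st.floats(0.0, 1.0),
        maf=st.floats(0.0, 1.0),
        d_mi=st.floats(0.0, 0.5),
        d_maf=st.floats(0.0, 0.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_relaxing_thresholds_is_monotone(self, mi, maf, d_mi, d_maf):
        alns = _fixture_alignments()
        strict = {a.read_id for a in filter_alignments(alns, FilterParams(mi, maf))}
        relaxed = {
            a.read_id
            for a in filter_alignments(
                alns, FilterParams(max(0.0, mi - d_mi), max(0.0, maf - d_maf))
            )
        }
        assert strict <= relaxed


class TestSubset:
    def test_one_base_overlap_kept(self):
        aln = make_alignment("r", "c", [(10, 60)])
        assert subset_alignments([aln], GenomicInterval("c", 59, 100)) == [aln]

    def test_adjacent_dropped(self):
        aln = make_alignment("r", "c", [(10, 60)])
        assert subset_alignments([aln], GenomicInterval("c", 60, 100)) == []

    def test_other_sequence_dropped(self):
        aln = make_alignment("r", "c2", [(10, 60)])
        assert subset_alignments([aln], GenomicInterval("c", 10, 60)) == []

    def test_gap_only_overlap_dropped(self):
        # interval falls entirely inside the N-gap: no block overlap
        aln = make_alignment("r", "c", [(0, 10), (100, 110)])
        assert subset_alignments([aln], GenomicInterval("c", 40, 60)) == []

    def test_merged_subsets_equal_subset_of_concatenation(self):
        rng = np.random.default_rng(21)
        samples = [random_alignments(rng, 30) for _ in range(3)]
        interval = GenomicInterval("chrT", 1000, 2000)
        merged = [a for s in samples for a in subset_alignments(s, interval)]
        concat = subset_alignments([a for s in samples for a in s], interval)
        assert merged == concat


class TestComputeCoverage:
    def test_no_alignments_zero_track(self):
        track = compute_coverage([], "c", 50)
        assert np.array_equal(track.counts, np.zeros(50, dtype=int))

    def test_single_spliced_alignment(self):
        aln = make_alignment("r", "c", [(10, 60), (160, 210)])
        track = compute_coverage([aln], "c", 300)
        assert (track.counts[10:60] == 1).all()
        assert (track.counts[60:160] == 0).all()
        assert (track.counts[160:210] == 1).all()

    def test_block_beyond_length_rejected(self):
        aln = make_alignment("r", "c", [(10, 60)])
        with pytest.raises(ValidationError):
            compute_coverage([aln], "c", 50)

    def test_matches_membership_oracle(self):
        rng = np.random.default_rng(8)
        alns = random_alignments(rng, 200, seq_len=3000)
        track = compute_coverage(alns, "chrT", 3000)
        assert np.array_equal(track.counts, naive_coverage(alns, 3000))

    def test_conservation_sum_equals_total_block_length(self):
        rng = np.random.default_rng(13)
        alns = random_alignments(rng, 150, seq_len=4000)
        track = compute_coverage(alns, "chrT", 4000)
        total = sum(b.length for a in alns for b in a.blocks)
        assert int(track.counts.sum()) == total


class TestExonSupport:
    def _gene(self, start, end):
        return GeneModel("g", "c", "+", (GenomicInterval("c", start, end),))

    def test_uniform_coverage(self):
        track = CoverageTrack("c", np.full(200, 50))
        (s,) = exon_support_stats(track, self._gene(20, 120))
        assert s.mean_cov == 50
        assert s.left_taper == pytest.approx(1.0)
        assert s.right_taper == pytest.approx(1.0)
        assert s.supported_fraction == 1.0
        assert not s.low_data

    def test_zero_coverage_exon(self):
        track = CoverageTrack("c", np.zeros(200, dtype=int))
        (s,) = exon_support_stats(track, self._gene(20, 120))
        assert s.mean_cov == 0
        assert s.supported_fraction == 0
        assert s.left_taper == 0.0 and s.right_taper == 0.0
        assert s.low_data

    def test_linear_ramp_taper(self):
        # counts 100 down to 1 across a 100 bp exon; window 10:
        #   right edge mean = mean(10..1)  = 5.5
        #   left edge mean  = mean(100..91) = 95.5
        #   body (pos 10..89) = mean(90..11) = 50.5
        counts = np.zeros(200, dtype=int)
        counts[50:150] = np.arange(100, 0, -1)
        track = CoverageTrack("c", counts)
        (s,) = exon_support_stats(track, self._gene(50, 150), edge_window=10)
        assert s.right_edge_cov == pytest.approx(5.5)
        assert s.left_edge_cov == pytest.approx(95.5)
        assert s.right_taper == pytest.approx(5.5 / 50.5)
        assert 0.06 <= s.right_taper <= 0.12
        assert s.left_taper == pytest.approx(95.5 / 50.5)

    def test_short_exon_uses_whole_body(self):
        counts = np.zeros(50, dtype=int)
        counts[10:30] = 10
        track = CoverageTrack("c", counts)
        (s,) = exon_support_stats(track, self._gene(10, 30), edge_window=10)
        # exon length 20 < 3 * 10 -> body is the whole exon
        assert s.left_taper == pytest.approx(1.0)

    def test_exon_outside_track_rejected(self):
        track = CoverageTrack("c", np.zeros(50, dtype=int))
        with pytest.raises(ValidationError):
            exon_support_stats(track, self._gene(40, 80))
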