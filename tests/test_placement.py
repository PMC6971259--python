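"""The placement equations and decision tree."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from srnaquant.alignments import (
    AlignmentHit,
    ClusterIndex,
    CoverageTrack,
    ReadAlignmentGroup,
    UARCluster,
)
from srnaquant.placement import (
    CountTable,
    PlacementParams,
    PlacementResult,
    ROUTE_ANNOTATION_ONLY,
    ROUTE_DENSITY_SPLIT,
    ROUTE_SALVAGE,
    ROUTE_SINGLE_AU,
    ROUTE_UAR_ONLY,
    accumulate,
    assign_uar,
    coverage_ratio,
    locus_score,
    place_multimap,
    prox_weight,
    rank_transcripts,
    split_fractions,
)
from srnaquant.reference import GenomicInterval, TranscriptSet, extend_and_index

from conftest import make_transcript

P = PlacementParams()


class TestProxWeight:
    def test_unity_on_read_body(self):
        for p in (100, 110, 121):
            assert prox_weight(p, 100, 121, 50, 10) == 1.0

    def test_exponential_decay_left_flank(self):
        # 10 nt left of the start with n=10 -> e^-1
        assert prox_weight(90, 100, 121, 50, 10) == pytest.approx(math.exp(-1))

    def test_exponential_decay_right_flank(self):
        assert prox_weight(141, 100, 121, 50, 10) == pytest.approx(math.exp(-2))

    def test_continuity_at_boundaries(self):
        eps = 1e-9
        assert prox_weight(100, 100, 121, 50, 10) == 1.0
        assert prox_weight(99, 100, 121, 50, 10) == pytest.approx(math.exp(-0.1))

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            prox_weight(100, 100, 121, 50, 0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        x=st.integers(100, 200),
        width=st.integers(1, 40),
        d=st.integers(1, 50),
        n=st.floats(1.0, 50.0),
    )
    def test_bounds_and_strict_decay(self, x, width, d, n):
        y = x + width
        w_left = prox_weight(x - d, x, y, 50, n)
        w_right = prox_weight(y + d, x, y, 50, n)
        assert 0 < w_left <= 1 and 0 < w_right <= 1
        if d > 1:
            assert w_left < prox_weight(x - d + 1, x, y, 50, n)
            assert w_right < prox_weight(y + d - 1, x, y, 50, n)


def track(chrom="chr1", strand="+", depths={}):
    cov = CoverageTrack()
    for pos, d in depths.items():
        for _ in range(d):
            cov.add(AlignmentHit(GenomicInterval(chrom, pos, pos + 1, strand)), 1)
    return cov


class TestLocusScore:
    def test_uniform_coverage_on_body(self):
        # depth 2 on exactly the 3 positions of [10,13): score = 2*1*3
        cov = track(depths={10: 2, 11: 2, 12: 2})
        locus = GenomicInterval("chr1", 10, 13, "+")
        assert locus_score(locus, cov, P) == pytest.approx(6.0)

    def test_zero_coverage(self):
        assert locus_score(GenomicInterval("chr1", 10, 13, "+"), CoverageTrack(), P) == 0.0

    def test_single_flank_position(self):
        cov = track(depths={90: 1})  # 10 left of x=100, n=10
        locus = GenomicInterval("chr1", 100, 123, "+")
        assert locus_score(locus, cov, P) == pytest.approx(math.exp(-1))

    def test_oracle_equivalence_random_tracks(self):
        """Direct per-position summation oracle over the closed window."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            depths = {int(p): int(rng.integers(1, 5)) for p in rng.integers(0, 400, 30)}
            cov = track(depths=depths)
            s = int(rng.integers(60, 300))
            locus = GenomicInterval("chr1", s, s + 22, "+")
            x, y = s, s + 21
            expected = sum(
                depths.get(p, 0) * prox_weight(p, x, y, P.r, P.n)
                for p in range(x - P.r, y + P.r + 1)
            )
            assert locus_score(locus, cov, P) == pytest.approx(expected)


class TestSplitFractions:
    def test_normalization(self):
        assert split_fractions([6, 2]) == [0.75, 0.25]

    def test_single_locus(self):
        assert split_fractions([3.7]) == [1.0]

    def test_all_zero_falls_back_to_uniform(self):
        assert split_fractions([0, 0, 0]) == pytest.approx([1 / 3] * 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            split_fractions([])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0, 1e6), min_size=1, max_size=20))
    def test_fractions_always_sum_to_one(self, scores):
        assert sum(split_fractions(scores)) == pytest.approx(1.0, abs=1e-9)


class TestCoverageRatio:
    def test_mature_mirna_fully_covered(self):
        assert coverage_ratio(22, 22, 22) == pytest.approx(2.0)

    def test_precursor_same_read(self):
        assert coverage_ratio(22, 80, 22) == pytest.approx(1.275)

    def test_identity_for_any_full_overlap(self):
        for L in (16, 22, 30, 100):
            assert coverage_ratio(L, L, L) == pytest.approx(2.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            coverage_ratio(22, 0, 22)
        with pytest.raises(ValueError):
            coverage_ratio(0, 22, 22)


class TestRankTranscripts:
    def test_mature_outranks_precursor(self):
        mature = make_transcript("mir", "chr1", 100, 122, biotype="miRNA")
        pre = make_transcript("mir-pre", "chr1", 90, 170, biotype="pre_miRNA")
        ranked = rank_transcripts([pre, mature], 22, [22, 22])
        assert ranked[0][0].transcript_id == "mir"
        assert ranked[0][1] == pytest.approx(2.0)
        assert ranked[1][1] == pytest.approx(1.275)

    def test_equal_ratio_ties_break_lexicographically(self):
        a = make_transcript("a", "chr1", 100, 122)
        b = make_transcript("b", "chr1", 200, 222)
        ranked = rank_transcripts([b, a], 22, [22, 22])
        assert [r.transcript_id for r, _ in ranked] == ["a", "b"]


def _mk_group(loci, read_len=22):
    return ReadAlignmentGroup(
        "r", "A" * read_len,
        [AlignmentHit(GenomicInterval("chr1", s, s + read_len, "+")) for s in loci],
    )


def _uniform_cov(start, end, depth):
    return {p: depth for p in range(start, end)}


class TestPlaceMultimap:
    def _env(self, transcripts, cluster_spans, depths):
        ts = TranscriptSet(transcripts)
        idx = extend_and_index(ts, extension=50)
        cidx = ClusterIndex(
            [UARCluster(GenomicInterval("chr1", s, e, "+"), 1) for s, e in cluster_spans]
        )
        return idx, cidx, track(depths=depths)

    def test_density_split_proportions(self):
        # depth 3 under locus A body, depth 1 under locus B body -> 0.75/0.25
        t1 = make_transcript("t1", "chr1", 1000, 1022)
        t2 = make_transcript("t2", "chr1", 3000, 3022)
        depths = {**_uniform_cov(1000, 1022, 3), **_uniform_cov(3000, 3022, 1)}
        idx, cidx, cov = self._env([t1, t2], [(1000, 1022), (3000, 3022)], depths)
        res = place_multimap(_mk_group([1000, 3000]), idx, cidx, cov, P)
        assert res.route == ROUTE_DENSITY_SPLIT
        assert dict(res.assignments) == pytest.approx({"t1": 0.75, "t2": 0.25})

    def test_single_evidence_locus_takes_whole_read(self):
        t1 = make_transcript("t1", "chr1", 1000, 1022)
        idx, cidx, cov = self._env(
            [t1], [(1000, 1022), (5000, 5022), (7000, 7022)], _uniform_cov(1000, 1022, 2)
        )
        res = place_multimap(_mk_group([1000, 5000, 7000]), idx, cidx, cov, P)
        assert res.route == ROUTE_SINGLE_AU
        assert res.assignments == [("t1", 1.0)]

    def test_annotation_only_prefers_mature_mirna_by_ratio(self):
        mature = make_transcript("mir", "chr1", 1000, 1022, biotype="miRNA")
        pre = make_transcript("mir-pre", "chr1", 990, 1070, biotype="pre_miRNA")
        idx, cidx, cov = self._env([mature, pre], [], {})
        res = place_multimap(_mk_group([1000, 5000]), idx, cidx, cov, P)
        assert res.route == ROUTE_ANNOTATION_ONLY
        assert res.assignments == [("mir", 1.0)]
        assert res.alternatives == ["mir-pre"]

    def test_annotation_only_without_mirna_splits_across_loci(self):
        t1 = make_transcript("t1", "chr1", 1000, 1080)
        t2 = make_transcript("t2", "chr1", 3000, 3080)
        idx, cidx, cov = self._env([t1, t2], [], {})
        res = place_multimap(_mk_group([1000, 3000]), idx, cidx, cov, P)
        assert res.route == ROUTE_ANNOTATION_ONLY
        assert dict(res.assignments) == pytest.approx({"t1": 0.5, "t2": 0.5})

    def test_uar_only_density_split_is_diagnostic(self):
        idx, cidx, cov = self._env(
            [], [(1000, 1022), (3000, 3022)],
            {**_uniform_cov(1000, 1022, 4), **_uniform_cov(3000, 3022, 1)},
        )
        res = place_multimap(_mk_group([1000, 3000]), idx, cidx, cov, P)
        assert res.route == ROUTE_UAR_ONLY
        fracs = [f for _, f in res.assignments]
        assert fracs == pytest.approx([0.8, 0.2])

    def test_no_evidence_routes_to_salvage(self):
        idx, cidx, cov = self._env([], [], {})
        res = place_multimap(_mk_group([1000, 3000]), idx, cidx, cov, P)
        assert res.route == ROUTE_SALVAGE
        assert res.assignments == []

    def test_non_multi_group_rejected(self):
        idx, cidx, cov = self._env([], [], {})
        with pytest.raises(ValueError):
            place_multimap(_mk_group([1000]), idx, cidx, cov, P)

    def test_density_dominance_monotonicity(self):
        """Raising coverage under one locus strictly raises its fraction."""
        t1 = make_transcript("t1", "chr1", 1000, 1022)
        t2 = make_transcript("t2", "chr1", 3000, 3022)
        prev = 0.0
        for depth in (1, 2, 5, 9):
            depths = {**_uniform_cov(1000, 1022, depth), **_uniform_cov(3000, 3022, 1)}
            idx, cidx, cov = self._env([t1, t2], [(1000, 1022), (3000, 3022)], depths)
            res = place_multimap(_mk_group([1000, 3000]), idx, cidx, cov, P)
            frac = dict(res.assignments)["t1"]
            assert frac > prev
            prev = frac


class TestAccumulate:
    def test_unique_read_bookkeeping(self):
        table = accumulate([], [("T", [], 1)])
        assert table.counts["T"] == 1.0
        assert table.unique_reads["T"] == 1

    def test_fractional_split_has_no_unique_reads(self):
        res = PlacementResult("r", [("a", 0.75), ("b", 0.25)], [], ROUTE_DENSITY_SPLIT)
        table = accumulate([(res, 1)], [])
        assert table.counts == pytest.approx({"a": 0.75, "b": 0.25})
        assert table.unique_reads == {}

    def test_copies_multiply_contributions(self):
        res = PlacementResult("r", [("a", 0.5), ("b", 0.5)], [], ROUTE_DENSITY_SPLIT)
        table = accumulate([(res, 4)], [("a", [], 3)])
        assert table.counts["a"] == pytest.approx(5.0)
        assert table.counts["b"] == pytest.approx(2.0)

    def test_fraction_sum_enforced(self):
        with pytest.raises(ValueError):
            PlacementResult("r", [("a", 0.6), ("b", 0.2)], [], ROUTE_DENSITY_SPLIT)


class TestAssignUar:
    def test_mature_wins_over_precursor(self):
        mature = make_transcript("mir", "chr1", 100, 122, biotype="miRNA")
        pre = make_transcript("mir-pre", "chr1", 90, 170, biotype="pre_miRNA")
        idx = extend_and_index(TranscriptSet([mature, pre]), extension=50)
        tid, alts = assign_uar(GenomicInterval("chr1", 100, 122, "+"), 22, idx)
        assert tid == "mir"
        assert alts == ["mir-pre"]

    def test_unannotated_returns_none(self):
        idx = extend_and_index(TranscriptSet([make_transcript("t", "chr1", 5000, 5080)]), 50)
        assert assign_uar(GenomicInterval("chr1", 100, 122, "+"), 22, idx) is None
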