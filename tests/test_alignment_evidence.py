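"""Depth-profile and split-link extraction against naive oracles."""

import numpy as np
import pytest

from nanocirc.alignment_evidence import (
    AlignedSegment,
    SIDE_LEFT,
    SIDE_RIGHT,
    compute_depth_profile,
    extract_split_links,
    parse_sa_tag,
    qc_bin_counts,
    read_alignments,
)
from nanocirc.simulator import reference_lengths, write_sam

from helpers import pileup_depth


def seg(read_id, contig, start, end, strand="+", mapq=60, qs=0, supp=False):
    return AlignedSegment(read_id=read_id, contig=contig, start=start, end=end,
                          strand=strand, mapq=mapq, query_start=qs,
                          is_supplementary=supp)


class TestDepthProfile:
    def test_single_segment_pileup(self):
        prof = compute_depth_profile([seg("r0", "c1", 10, 20)])
        assert prof.depth_at("c1", 9) == 0
        assert prof.depth_at("c1", 10) == 1
        assert prof.depth_at("c1", 19) == 1
        assert prof.depth_at("c1", 20) == 0

    def test_overlap_arithmetic(self):
        prof = compute_depth_profile(
            [seg("r0", "c1", 10, 20), seg("r1", "c1", 15, 25)]
        )
        for pos, want in [(12, 1), (17, 2), (22, 1), (25, 0)]:
            assert prof.depth_at("c1", pos) == want

    def test_matches_per_base_pileup_oracle(self, rng):
        for _ in range(10):
            segments = sorted(
                (seg(f"r{i}", "c1", int(a), int(a) + int(l))
                 for i, (a, l) in enumerate(zip(
                     rng.integers(0, 9_000, 200), rng.integers(1, 1_000, 200)))),
                key=lambda s: s.start,
            )
            prof = compute_depth_profile(segments)
            oracle = pileup_depth(segments, "c1", 10_000)
            got = np.array([prof.depth_at("c1", p) for p in range(10_000)])
            np.testing.assert_array_equal(got, oracle)

    def test_profile_closes_at_zero(self, rng):
        segments = sorted(
            (seg(f"r{i}", "c1", int(a), int(a) + int(l))
             for i, (a, l) in enumerate(zip(
                 rng.integers(0, 5_000, 100), rng.integers(1, 500, 100)))),
            key=lambda s: s.start,
        )
        positions, depths = compute_depth_profile(segments).steps("c1")
        assert depths[-1] == 0

    def test_mapq_filter_pointwise_monotone(self, rng):
        segments = sorted(
            (seg(f"r{i}", "c1", int(a), int(a) + 100, mapq=int(q))
             for i, (a, q) in enumerate(zip(
                 rng.integers(0, 2_000, 100), rng.integers(0, 61, 100)))),
            key=lambda s: s.start,
        )
        profiles = [compute_depth_profile(segments, mapq_min=q) for q in (0, 20, 60)]
        for pos in range(0, 2_200, 7):
            d = [p.depth_at("c1", pos) for p in profiles]
            assert d[0] >= d[1] >= d[2]

    def test_unsorted_input_raises(self):
        with pytest.raises(ValueError, match="not sorted"):
            compute_depth_profile([seg("r0", "c1", 50, 60), seg("r1", "c1", 10, 20)])
        with pytest.raises(ValueError, match="not sorted"):
            compute_depth_profile([
                seg("r0", "c1", 0, 5), seg("r1", "c2", 0, 5), seg("r2", "c1", 9, 12),
            ])

    def test_mean_depth_examples(self):
        prof = compute_depth_profile([seg("r0", "c1", 0, 100),
                                      seg("r1", "c1", 0, 100)])
        assert prof.mean_depth("c1", 0, 100) == pytest.approx(2.0)
        prof = compute_depth_profile(
            [seg(f"r{i}", "c1", 0, 50, mapq=60) for i in range(4)]
        )
        assert prof.mean_depth("c1", 0, 100) == pytest.approx(2.0)
        assert prof.mean_depth("c1", 500, 600) == 0.0  # unprofiled = depth 0

    def test_mean_depth_matches_per_base_oracle(self, rng):
        segments = sorted(
            (seg(f"r{i}", "c1", int(a), int(a) + int(l))
             for i, (a, l) in enumerate(zip(
                 rng.integers(0, 4_000, 150), rng.integers(1, 800, 150)))),
            key=lambda s: s.start,
        )
        prof = compute_depth_profile(segments)
        oracle = pileup_depth(segments, "c1", 6_000)
        for _ in range(50):
            a = int(rng.integers(0, 5_000))
            b = a + int(rng.integers(1, 900))
            assert prof.mean_depth("c1", a, b) == pytest.approx(
                oracle[a:b].mean() if b <= 6_000 else
                oracle[a:min(b, 6_000)].sum() / (b - a)
            )


class TestSplitLinks:
    def test_two_segment_read(self):
        links = extract_split_links([
            seg("r0", "c1", 100, 600, qs=0),
            seg("r0", "c1", 5_000, 5_500, qs=500, supp=True),
        ])
        assert len(links) == 1
        assert links[0].end_a == ("c1", 600, SIDE_LEFT)
        assert links[0].end_b == ("c1", 5_000, SIDE_RIGHT)

    def test_single_alignment_no_links(self):
        assert extract_split_links([seg("r0", "c1", 100, 600)]) == []

    @pytest.mark.parametrize("k", [2, 3, 4, 5])
    def test_k_segments_give_k_minus_1_links(self, k):
        segments = [
            seg("r0", "c1", 1_000 * i + 100, 1_000 * i + 500, qs=400 * i,
                supp=i > 0)
            for i in range(k)
        ]
        assert len(extract_split_links(segments)) == k - 1

    def test_mapq_filter_drops_links(self):
        segments = [
            seg("r0", "c1", 100, 600, qs=0, mapq=10),
            seg("r0", "c1", 5_000, 5_500, qs=500, mapq=60, supp=True),
        ]
        assert len(extract_split_links(segments, mapq_min=0)) == 1
        assert len(extract_split_links(segments, mapq_min=20)) == 0

    def test_reverse_strand_link_same_unordered_endpoints(self):
        # a reverse-strand read across the same junction reports the same
        # physical junction with swapped endpoint order
        fwd = extract_split_links([
            seg("rf", "c1", 3_000, 5_000, qs=0),
            seg("rf", "c1", 2_000, 2_500, qs=2_000, supp=True),
        ])[0]
        rev = extract_split_links([
            seg("rr", "c1", 2_000, 2_500, "-", qs=0),
            seg("rr", "c1", 3_000, 5_000, "-", qs=500, supp=True),
        ])[0]
        assert fwd.endpoints == rev.endpoints

    def test_simulated_circle_junction(self, simple_fixture):
        sim, _cfg = simple_fixture
        links = extract_split_links(sim.segments)
        assert links, "junction-crossing reads must yield split links"
        for lk in links:
            assert lk.endpoints == frozenset(
                {("c1", 5_000, SIDE_LEFT), ("c1", 2_000, SIDE_RIGHT)}
            )

    def test_sa_tag_parsing(self):
        entries = parse_sa_tag("c1,1001,+,500M,60,3;c2,50,-,100S400M,13,0;")
        assert entries == (
            ("c1", 1001, "+", "500M", 60), ("c2", 50, "-", "100S400M", 13)
        )
        with pytest.raises(ValueError):
            parse_sa_tag("c1,notanumber,+,500M,60,0;")


class TestSamRoundTrip:
    def test_depth_and_links_survive_sam(self, chimeric_fixture, tmp_path):
        sim, _cfg = chimeric_fixture
        path = tmp_path / "reads.sam"
        write_sam(sim, reference_lengths({"c1": 60_000, "c2": 60_000}), str(path))
        back = list(read_alignments(str(path)))
        assert len(back) == len(sim.segments)
        prof_a = compute_depth_profile(
            sorted(sim.segments, key=lambda s: (s.contig, s.start, s.read_id)))
        prof_b = compute_depth_profile(back)
        for contig in ("c1", "c2"):
            np.testing.assert_array_equal(*(p.steps(contig)[0] for p in (prof_a, prof_b)))
            np.testing.assert_array_equal(*(p.steps(contig)[1] for p in (prof_a, prof_b)))
        links_a = {(lk.read_id, lk.endpoints)
                   for lk in extract_split_links(sim.segments)}
        links_b = {(lk.read_id, lk.endpoints) for lk in extract_split_links(back)}
        assert links_a == links_b


class TestQcBins:
    def _detect_candidate(self, sim):
        from nanocirc import detect_circles

        res = detect_circles(sim.segments)
        assert len(res.candidates) == 1
        return res

    def test_perfect_junction_reads_have_no_split_read_in(self, simple_fixture):
        sim, _cfg = simple_fixture
        res = self._detect_candidate(sim)
        table = qc_bin_counts(sim.segments, res.links, res.candidates[0],
                              window=3, n_bins=20)
        assert table["split_read_in"].sum() == 0
        assert table["split_at_breakpoints"].sum() > 0
        assert table["split_read_out"].sum() == 0

    def test_window_zero_with_jitter_shifts_categories(self, simple_circle):
        from conftest import make_fixture
        from nanocirc import detect_circles

        sim, _cfg = make_fixture([simple_circle], seed=9, jitter=2)
        res = detect_circles(sim.segments)
        assert len(res.candidates) == 1
        wide = qc_bin_counts(sim.segments, res.links, res.candidates[0],
                             window=4, n_bins=20)
        tight = qc_bin_counts(sim.segments, res.links, res.candidates[0],
                              window=0, n_bins=20)
        assert tight["split_read_in"].sum() > wide["split_read_in"].sum()
        assert tight["split_at_breakpoints"].sum() < \
            wide["split_at_breakpoints"].sum()

    def test_category_totals_match_direct_enumeration(self, simple_fixture):
        sim, _cfg = simple_fixture
        res = self._detect_candidate(sim)
        cand = res.candidates[0]
        window = 3
        table = qc_bin_counts(sim.segments, res.links, cand,
                              window=window, n_bins=10)
        # direct: every split read of this fixture crosses the junction at
        # the two breakpoints, so its bases all land in the at-breakpoints
        # category; total bases = sum of overlaps with the circle segments
        split_reads = {lk.read_id for lk in res.links}
        expected = 0
        for s in sim.segments:
            if s.read_id in split_reads:
                for c, a, b in cand.segments:
                    if s.contig == c:
                        expected += max(0, min(s.end, b) - max(s.start, a))
        assert table["split_at_breakpoints"].sum() == pytest.approx(expected)
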