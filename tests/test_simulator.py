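"""Generator determinism/realism properties and the recall/precision math."""

import numpy as np
import pytest

from nanocirc.alignment_evidence import compute_depth_profile, extract_split_links
from nanocirc.simulator import (
    SIMPLE, CHIMERIC, WITH_DELETION,
    SimConfig, TrueCircle, circles_match, evaluate, read_truth,
    reference_lengths, simulate_alignments, simulate_reference, simulate_truth,
    subsample_reads, write_fasta, write_truth,
)

from conftest import make_fixture


class TestReference:
    def test_seeded_runs_identical(self, tmp_path):
        a = simulate_reference(2, 50_000, seed=9)
        b = simulate_reference(2, 50_000, seed=9)
        assert a == b
        pa, pb = tmp_path / "a.fa", tmp_path / "b.fa"
        write_fasta(a, str(pa))
        write_fasta(b, str(pb))
        assert pa.read_bytes() == pb.read_bytes()

    def test_different_seeds_differ(self):
        assert simulate_reference(1, 10_000, seed=1) != \
            simulate_reference(1, 10_000, seed=2)

    def test_gc_content_concentrates(self):
        seqs = simulate_reference(1, 1_000_000, gc=0.5, seed=3)
        seq = seqs["contig_0"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(0.5, abs=0.01)


class TestTruth:
    def test_one_circle_per_topology(self):
        ref = {"contig_0": 2_000_000}
        found = set()
        cfg = SimConfig(seed=4, n_circles=9, size_range=(20_000, 40_000))
        for tc in simulate_truth(ref, cfg):
            found.add(tc.topology)
            if tc.topology == SIMPLE:
                assert len(tc.segments) == 1
                assert tc.junction_kinds == ["split"]
            elif tc.topology == CHIMERIC:
                assert len(tc.segments) == 2
                assert tc.junction_kinds == ["split", "split"]
            elif tc.topology == WITH_DELETION:
                assert len(tc.segments) == 2
                assert tc.junction_kinds == ["deletion", "split"]
                (c1, _s1, e1, _), (c2, s2, _e2, _) = tc.segments
                assert c1 == c2 and s2 > e1  # the gap between the halves
        assert found == {SIMPLE, CHIMERIC, WITH_DELETION}

    def test_zero_circles_empty_truth(self):
        assert simulate_truth({"c": 100_000}, SimConfig(n_circles=0)) == []

    def test_invariants_over_random_configs(self):
        rng = np.random.default_rng(0)
        ref = {"contig_0": 3_000_000, "contig_1": 2_000_000}
        for trial in range(30):
            cfg = SimConfig(
                seed=int(rng.integers(1_000_000)),
                n_circles=int(rng.integers(1, 10)),
                size_range=(int(rng.integers(2_000, 10_000)),
                            int(rng.integers(20_000, 60_000))),
            )
            truth = simulate_truth(ref, cfg)
            assert len(truth) == cfg.n_circles
            spans = {}
            for tc in truth:
                assert tc.length <= cfg.max_circle_length
                for contig, s, e, strand in tc.segments:
                    assert 0 <= s < e <= ref[contig]
                    spans.setdefault(contig, []).append((s, e, tc.circle_id))
            # non-overlap with margin between distinct circles
            for contig, ivs in spans.items():
                ivs.sort()
                for (s1, e1, c1), (s2, e2, c2) in zip(ivs, ivs[1:]):
                    if c1 != c2:
                        assert s2 - e1 >= cfg.placement_margin

    def test_impossible_placement_raises(self):
        cfg = SimConfig(seed=0, n_circles=50, size_range=(40_000, 50_000))
        with pytest.raises(RuntimeError, match="cannot place"):
            simulate_truth({"c": 200_000}, cfg)

    def test_truth_tsv_round_trip(self, tmp_path, deletion_circle):
        path = tmp_path / "truth.tsv"
        write_truth([deletion_circle], str(path))
        [back] = read_truth(str(path))
        assert back.segments == deletion_circle.segments
        assert back.junction_kinds == deletion_circle.junction_kinds
        assert back.topology == deletion_circle.topology


class TestAlignments:
    def test_deterministic_per_seed(self, simple_circle):
        a, _ = make_fixture([simple_circle], seed=8)
        b, _ = make_fixture([simple_circle], seed=8)
        assert [(s.read_id, s.contig, s.start, s.end, s.strand, s.query_start)
                for s in a.segments] == \
               [(s.read_id, s.contig, s.start, s.end, s.strand, s.query_start)
                for s in b.segments]

    def test_realized_coverage_within_15_percent(self, simple_circle):
        sim, cfg = make_fixture([simple_circle], seed=8, coverage=25.0)
        segments = sorted(sim.segments, key=lambda s: (s.contig, s.start))
        prof = compute_depth_profile(segments)
        mean = prof.mean_depth("c1", 2_000, 5_000)
        assert mean == pytest.approx(25.0, rel=0.15)

    def test_zero_jitter_links_exactly_at_junction(self, simple_fixture):
        sim, _cfg = simple_fixture
        links = extract_split_links(sim.segments)
        assert links
        assert all(lk.endpoints == frozenset({("c1", 5_000, "L"),
                                              ("c1", 2_000, "R")})
                   for lk in links)

    def test_zero_circle_coverage_only_background(self, simple_circle):
        cfg = SimConfig(seed=1, circle_coverage=0.0, background_coverage=1.0)
        sim = simulate_alignments({"c1": 100_000}, [simple_circle], cfg)
        assert all(org == "background" for org in sim.origins.values())
        assert extract_split_links(sim.segments) == []

    def test_deleted_interval_has_zero_reads(self, deletion_fixture,
                                             deletion_circle):
        sim, _cfg = deletion_fixture
        (_c, _s, d1, _), (_c2, d2, _e, _) = deletion_circle.segments
        assert not any(
            s.start < d2 and s.end > d1 for s in sim.segments if s.contig == "c1"
        )

    def test_subsampling_keeps_background_thins_circles(self, simple_circle):
        sim, cfg = make_fixture([simple_circle], seed=8, background=1.0)
        half = subsample_reads(sim, 0.5, seed=1)
        n_bg = sum(1 for o in sim.origins.values() if o == "background")
        n_bg_half = sum(1 for o in half.origins.values() if o == "background")
        assert n_bg == n_bg_half
        n_circ = len(sim.origins) - n_bg
        n_circ_half = len(half.origins) - n_bg_half
        assert 0 < n_circ_half < n_circ
        none = subsample_reads(sim, 0.0, seed=1)
        assert all(o == "background" for o in none.origins.values())


class TestEvaluate:
    def test_perfect_calls(self, simple_circle, chimeric_circle):
        truth = [simple_circle, chimeric_circle]
        calls = [tc.plain_segments() for tc in truth]
        recall, precision, pairs = evaluate(calls, truth)
        assert (recall, precision) == (1.0, 1.0)
        assert len(pairs) == 2

    def test_partial_overlap_formulas(self):
        truth = [TrueCircle(f"t{i}", [("c", i * 10_000, i * 10_000 + 1_000, "+")],
                            SIMPLE) for i in range(4)]
        calls = [truth[0].plain_segments(), truth[1].plain_segments(),
                 [("c", 90_000, 91_000)]]
        recall, precision, _ = evaluate(calls, truth)
        assert recall == pytest.approx(2 / 4)
        assert precision == pytest.approx(2 / 3)

    def test_empty_sets_report_one(self):
        assert evaluate([], [])[:2] == (1.0, 1.0)
        truth = [TrueCircle("t", [("c", 0, 100, "+")], SIMPLE)]
        recall, precision, _ = evaluate([], truth)
        assert (recall, precision) == (0.0, 1.0)

    def test_tolerance_boundary(self):
        truth = [TrueCircle("t", [("c", 10_000, 20_000, "+")], SIMPLE)]
        near = [[("c", 10_050, 19_950)]]
        far = [[("c", 10_051, 19_950)]]
        assert evaluate(near, truth, match_tol=50)[0] == 1.0
        assert evaluate(far, truth, match_tol=50)[0] == 0.0

    def test_segment_count_must_match(self, deletion_circle):
        merged = [[("c1", 20_000, 30_000)]]
        assert evaluate(merged, [deletion_circle])[0] == 0.0

    def test_matching_agrees_with_bruteforce_assignment(self, rng):
        from itertools import permutations

        for _ in range(30):
            nt, nc = int(rng.integers(0, 5)), int(rng.integers(0, 5))
            truth = [
                TrueCircle(f"t{i}", [("c", int(p), int(p) + 1_000, "+")], SIMPLE)
                for i, p in enumerate(rng.choice(50, nt, replace=False) * 3_000)
            ]
            calls = []
            for _j in range(nc):
                if truth and rng.random() < 0.6:
                    base = truth[int(rng.integers(nt))].plain_segments()
                    jit = int(rng.integers(-80, 81))
                    calls.append([(c, s + jit, e + jit) for c, s, e in base])
                else:
                    a = 1_000_000 + int(rng.integers(100)) * 5_000
                    calls.append([("c", a, a + 777)])
            recall, precision, pairs = evaluate(calls, truth, match_tol=50)
            # brute force maximum matching over all injections
            call_segs = [sorted(c) for c in calls]
            truth_segs = [sorted(t.plain_segments()) for t in truth]
            best = 0
            k = min(nt, nc)
            for size in range(k, -1, -1):
                if best:
                    break
                for t_idx in permutations(range(nt), size):
                    for c_idx in permutations(range(nc), size):
                        m = sum(
                            circles_match(call_segs[ci], truth_segs[ti], 50)
                            for ci, ti in zip(c_idx, t_idx)
                        )
                        best = max(best, m)
            assert len(pairs) == best
            assert recall == (best / nt if nt else 1.0)
            assert precision == (best / nc if nc else 1.0)
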