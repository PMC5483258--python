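"""Anchoring, chaining, refinement and reciprocal-best tiling."""

import numpy as np
import pytest

from hyperhet.align import global_align
from hyperhet.io import revcomp
from hyperhet.pairing import (Anchor, PairedSegment, build_anchor_map,
                              chain_anchors, pair_assembly,
                              reciprocal_best_tiling, refine_segments,
                              summarize_pairing, summary_from_totals)

from conftest import mutate, random_seq


def brute_force_anchors(seq_x, seq_y, k):
    """All shared k-mer positions between two sequences, both strands."""
    hits = set()
    for i in range(len(seq_x) - k + 1):
        km = seq_x[i:i + k]
        for j in range(len(seq_y) - k + 1):
            other = seq_y[j:j + k]
            if km == other:
                hits.add((i, j, "forward"))
            if km == revcomp(other):
                hits.add((i, j, "reverse"))
    return hits


class TestAnchors:
    def test_identical_scaffolds_fill_the_diagonal(self):
        rng = np.random.default_rng(0)
        seq = random_seq(rng, 1000)
        anchors = build_anchor_map({"s1": seq, "s2": seq}, k=15,
                                   max_seed_multiplicity=10)
        diag = [a for a in anchors if a.orientation == "forward"
                and a.scaffold_a == "s1" and a.scaffold_b == "s2"
                and a.pos_a == a.pos_b]
        assert len(diag) >= 986  # 1000 - 15 + 1 positions

    def test_matches_brute_force_on_small_pair(self):
        rng = np.random.default_rng(3)
        x = random_seq(rng, 120)
        y = x[40:100] + random_seq(rng, 60)
        anchors = build_anchor_map({"x": x, "y": y}, k=15,
                                   max_seed_multiplicity=50)
        got = {(a.pos_a, a.pos_b, a.orientation) for a in anchors
               if a.scaffold_a == "x" and a.scaffold_b == "y"}
        assert got == brute_force_anchors(x, y, 15)

    def test_reverse_complement_yields_reverse_anchors(self):
        rng = np.random.default_rng(1)
        seq = random_seq(rng, 500)
        anchors = build_anchor_map({"fwd": seq, "rev": revcomp(seq)}, k=15)
        rev = [a for a in anchors if a.orientation == "reverse"]
        assert len(rev) >= 480
        # anti-diagonal: pos_a + pos_b constant at len - k
        assert all(a.pos_a + a.pos_b == 500 - 15 for a in rev)

    def test_random_scaffolds_share_almost_no_seeds(self):
        rng = np.random.default_rng(2)
        anchors = build_anchor_map({"a": random_seq(rng, 1000),
                                    "b": random_seq(rng, 1000)}, k=15)
        assert len(anchors) <= 2  # expected count ~ 1e6/4^15 << 1

    def test_n_positions_never_seed(self):
        seq = "ACGTACGTACGTACGTACGT"
        withn = seq[:10] + "N" + seq[10:]
        anchors = build_anchor_map({"a": seq + seq, "b": withn + withn}, k=15)
        for a in anchors:
            sa = (seq + seq) if a.scaffold_a == "a" else (withn + withn)
            assert "N" not in sa[a.pos_a:a.pos_a + a.length]

    def test_small_k_rejected_and_empty_input(self):
        with pytest.raises(ValueError):
            build_anchor_map({"a": "ACGT" * 10}, k=9)
        assert build_anchor_map({}) == []


def _mk_anchors(pairs, orient="forward", k=15):
    return [Anchor("a", "b", pa, pb, k, orient) for pa, pb in pairs]


class TestChaining:
    def test_perfect_diagonal_single_chain(self):
        anchors = _mk_anchors([(i * 20, i * 20) for i in range(10)])
        chains = chain_anchors(anchors, max_gap=500, min_chain_anchors=3)
        assert len(chains) == 1
        assert len(chains[0]) == 10

    def test_large_gap_splits_chain(self):
        anchors = _mk_anchors([(i * 20, i * 20) for i in range(5)]
                              + [(2000 + i * 20, 2000 + i * 20) for i in range(5)])
        chains = chain_anchors(anchors, max_gap=500, min_chain_anchors=3)
        assert len(chains) == 2

    def test_reverse_chain_is_antidiagonal(self):
        anchors = _mk_anchors([(i * 20, 1000 - i * 20) for i in range(10)],
                              orient="reverse")
        chains = chain_anchors(anchors, max_gap=500, min_chain_anchors=3)
        assert len(chains) == 1
        assert chains[0].orientation == "reverse"

    def test_planted_inversion_gets_its_own_reverse_chain(self):
        rng = np.random.default_rng(5)
        a = random_seq(rng, 6000)
        b = a[:2000] + revcomp(a[2000:4000]) + a[4000:]
        anchors = build_anchor_map({"a": a, "b": b})
        chains = chain_anchors(anchors)
        orients = {(c.orientation, c.scaffold_a) for c in chains}
        rev = [c for c in chains if c.orientation == "reverse"]
        assert len(rev) == 1
        assert 1900 < rev[0].pos_a.min() < 2100
        assert 3900 < rev[0].pos_a.max() + 15 < 4100


class TestRefinement:
    def test_identical_pair_single_clean_segment(self):
        rng = np.random.default_rng(6)
        seq = random_seq(rng, 10_000)
        segments = pair_assembly({"a": seq, "b": seq})
        assert len(segments) == 1
        seg = segments[0]
        assert seg.n_mismatch == 0
        assert seg.n_indel_events == 0
        assert seg.end_a - seg.start_a == 10_000

    def test_planted_substitutions_counted_exactly(self):
        rng = np.random.default_rng(7)
        a = random_seq(rng, 8000)
        positions = rng.choice(np.arange(100, 7900), size=57, replace=False)
        b = list(a)
        for p in positions:
            b[p] = "ACGT"[("ACGT".index(b[p]) + 1) % 4]
        segments = pair_assembly({"a": a, "b": "".join(b)})
        assert sum(s.n_mismatch for s in segments) == 57
        assert sum(s.n_indel_events for s in segments) == 0

    def test_planted_deletion_recovered(self):
        rng = np.random.default_rng(8)
        a = random_seq(rng, 4000)
        b = a[:2000] + a[2005:]  # 5 bp deletion
        segments = pair_assembly({"a": a, "b": b})
        events = [e for s in segments for e in s.indel_events]
        assert events == [(2000 - segments[0].start_a, "deletion", 5)]

    def test_segment_edit_distance_equals_unbanded_global(self):
        # anchored + banded pipeline vs one-shot optimal alignment
        rng = np.random.default_rng(9)
        for _ in range(12):
            n = int(rng.integers(800, 2000))
            a = random_seq(rng, n)
            b = mutate(rng, a, sub_rate=0.05, indel_rate=0.005,
                       protect_ends=60)
            segments = pair_assembly({"a": a, "b": b}, min_segment_length=100)
            assert len(segments) == 1
            full = global_align(a, b)
            assert segments[0].edit_distance == full.edit_distance
            assert segments[0].n_mismatch == full.n_mismatch


def _segment(sa, a0, a1, sb, b0, b1, ops, density):
    seg = PairedSegment(sa, a0, a1, sb, b0, b1, "forward", ops, score=0,
                        tiling_density=density)
    seg.validate()
    return seg


def brute_force_tiling(segments, scaffolds):
    """Per-base assignment oracle: every base goes to its best segment by
    (density, length, ids); a segment keeps the columns winning both sides."""
    order = sorted(
        range(len(segments)),
        key=lambda i: (-segments[i].tiling_density,
                       -(segments[i].end_a - segments[i].start_a),
                       segments[i].scaffold_a, segments[i].scaffold_b,
                       segments[i].start_a, segments[i].start_b))
    rank = {i: r for r, i in enumerate(order)}
    owner = {name: {} for name in scaffolds}
    for i, seg in enumerate(segments):
        for pos in range(seg.start_a, seg.end_a):
            cur = owner[seg.scaffold_a].get(("A", pos))
            if cur is None or rank[i] < cur:
                owner[seg.scaffold_a][("A", pos)] = rank[i]
        for pos in range(seg.start_b, seg.end_b):
            cur = owner[seg.scaffold_b].get(("B", pos))
            if cur is None or rank[i] < cur:
                owner[seg.scaffold_b][("B", pos)] = rank[i]
    kept = {}
    for i, seg in enumerate(segments):
        a_pos, b_pos, _ = seg.a_positions()
        cols = set()
        for pa, pb in zip(a_pos, b_pos):
            if owner[seg.scaffold_a][("A", int(pa))] == rank[i] and \
               owner[seg.scaffold_b][("B", int(pb))] == rank[i]:
                cols.add(int(pa))
        kept[i] = cols
    return kept


class TestTiling:
    def test_non_overlapping_segments_retained_unchanged(self):
        scaffolds = {"a": "A" * 300, "b": "C" * 300}
        s1 = _segment("a", 0, 100, "b", 0, 100, [("match", 100)], 0.9)
        s2 = _segment("a", 150, 280, "b", 150, 280, [("match", 130)], 0.8)
        out = reciprocal_best_tiling([s1, s2], scaffolds, min_segment_length=50)
        assert out == [s1, s2]

    def test_overlap_resolved_by_density(self):
        scaffolds = {"a": "A" * 300, "b": "C" * 300, "c": "G" * 300}
        s1 = _segment("a", 0, 100, "b", 0, 100, [("match", 100)], 0.9)
        s2 = _segment("a", 50, 150, "c", 0, 100, [("match", 100)], 0.5)
        out = reciprocal_best_tiling([s1, s2], scaffolds, min_segment_length=10)
        assert out[0] == s1
        trimmed = [s for s in out if s.scaffold_b == "c"]
        assert len(trimmed) == 1
        assert (trimmed[0].start_a, trimmed[0].end_a) == (100, 150)

    def test_dominated_segment_dropped(self):
        scaffolds = {"a": "A" * 200, "b": "C" * 200}
        big = _segment("a", 0, 150, "b", 0, 150, [("match", 150)], 0.9)
        inner = _segment("a", 40, 80, "b", 40, 80, [("match", 40)], 0.5)
        out = reciprocal_best_tiling([big, inner], scaffolds,
                                     min_segment_length=10)
        assert out == [big]

    def test_matches_brute_force_on_random_conflicts(self):
        rng = np.random.default_rng(10)
        scaffolds = {"a": "A" * 400, "b": "C" * 400, "c": "G" * 400}
        for _ in range(15):
            segments = []
            for i in range(int(rng.integers(2, 10))):
                length = int(rng.integers(30, 150))
                a0 = int(rng.integers(0, 400 - length))
                sb = ["b", "c"][int(rng.integers(0, 2))]
                b0 = int(rng.integers(0, 400 - length))
                density = float(rng.choice([0.3, 0.5, 0.7, 0.9]))
                segments.append(_segment("a", a0, a0 + length, sb, b0,
                                         b0 + length,
                                         [("match", length)], density))
            oracle = brute_force_tiling(segments, scaffolds)
            out = reciprocal_best_tiling(segments, scaffolds,
                                         min_segment_length=1)
            got_cols = {}
            for seg in out:
                src = next(i for i, s in enumerate(segments)
                           if s.scaffold_a == seg.scaffold_a
                           and s.scaffold_b == seg.scaffold_b
                           and s.start_a <= seg.start_a
                           and seg.end_a <= s.end_a
                           and s.tiling_density == seg.tiling_density)
                got_cols.setdefault(src, set()).update(
                    range(seg.start_a, seg.end_a))
            for i in range(len(segments)):
                assert got_cols.get(i, set()) == oracle[i], i

    def test_idempotent_on_simulation(self, clean_segments, clean_truth):
        scaffolds = {**clean_truth.haplotype_a, **clean_truth.haplotype_b}
        again = reciprocal_best_tiling(clean_segments, scaffolds)
        assert [(s.scaffold_a, s.start_a, s.end_a, s.scaffold_b, s.start_b,
                 s.end_b) for s in again] == \
               [(s.scaffold_a, s.start_a, s.end_a, s.scaffold_b, s.start_b,
                 s.end_b) for s in clean_segments]

    def test_coverage_monotone_under_unrelated_scaffolds(self, clean_truth,
                                                         clean_segments):
        rng = np.random.default_rng(11)
        scaffolds = {**clean_truth.haplotype_a, **clean_truth.haplotype_b}
        base = summarize_pairing(clean_segments, scaffolds)
        bigger = dict(scaffolds)
        bigger["orphan"] = random_seq(rng, 20_000)
        segments2 = pair_assembly(bigger)
        after = summarize_pairing(segments2, bigger)
        assert after.coverage_fraction < base.coverage_fraction


class TestSummary:
    def test_published_assembly_totals(self):
        s = summary_from_totals(genome_length=170_470_384,
                                paired_length=152_151_424,
                                total_mismatches=8_685_973,
                                total_indel_events=997_343)
        assert round(100 * s.coverage_fraction, 1) == 89.3
        assert round(s.heterozygosity_pct, 1) == 5.7
        assert round(s.indel_pct, 2) == 0.66

    def test_empty_segments_flagged(self):
        s = summarize_pairing([], {"a": "ACGT" * 100})
        assert s.undefined
        assert s.coverage_fraction == 0.0
        assert s.heterozygosity_pct == 0.0

    def test_zero_genome_length_rejected(self):
        with pytest.raises(ValueError):
            summary_from_totals(0, 0, 0, 0)

    def test_simulation_summary_consistency(self, clean_segments, clean_truth):
        scaffolds = {**clean_truth.haplotype_a, **clean_truth.haplotype_b}
        s = summarize_pairing(clean_segments, scaffolds)
        assert s.total_mismatches == 2 * s.mismatch_columns
        assert 0 < s.coverage_fraction <= 1
        assert s.heterozygosity_pct == pytest.approx(
            100 * s.total_mismatches / s.paired_length)
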