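"""Variant totals, class densities, window tracks and structural calls."""

import math

import numpy as np
import pandas as pd
import pytest

from hyperhet.hetstats import (ClassDensity, StructuralCall, build_class_array,
                               class_densities, structural_events,
                               variant_rates, variant_totals, window_tracks)
from hyperhet.io import GeneModel
from hyperhet.pairing import PairedSegment, pair_assembly
from hyperhet.simulate import generate_truth
from hyperhet.config import SimulationConfig


def _segment(sa, a0, ops, sb="b", b0=0, orientation="forward"):
    la = sum(l for op, l in ops if op in ("match", "mismatch", "deletion"))
    lb = sum(l for op, l in ops if op in ("match", "mismatch", "insertion"))
    seg = PairedSegment(sa, a0, a0 + la, sb, b0, b0 + lb, orientation,
                        ops, score=0)
    seg.validate()
    return seg


def match_ledger_events(planted, detected, slack=20):
    """Greedy 1:1 matching of indel events by type+length within a small
    positional slack (optimal alignments may slide a gap within repeats)."""
    unmatched_planted = []
    pool = list(detected)
    for scf, pos, etype, length in planted:
        hit = None
        for cand in pool:
            if cand[0] == scf and cand[2] == etype and cand[3] == length \
                    and abs(cand[1] - pos) <= slack + length:
                hit = cand
                break
        if hit is None:
            unmatched_planted.append((scf, pos, etype, length))
        else:
            pool.remove(hit)
    return unmatched_planted, pool


class TestVariantTotals:
    def test_published_totals_reproduce_rates(self):
        t = variant_rates(8_685_973, 997_343, 152_151_424)
        assert round(t.snv_pct, 1) == 5.7
        assert round(t.indel_pct, 2) == 0.66

    def test_zero_divergence_gives_zeros(self):
        seg = _segment("a", 0, [("match", 500)])
        t = variant_totals([seg])
        assert (t.snv_count, t.indel_event_count, t.snv_pct, t.indel_pct) == \
            (0, 0, 0.0, 0.0)

    def test_empty_input_flagged(self):
        t = variant_totals([])
        assert t.undefined

    def test_ledger_oracle_on_clean_simulation(self, clean_truth,
                                               clean_segments):
        led = clean_truth.variant_ledger
        cov = {scf: np.zeros(len(seq), bool)
               for scf, seq in clean_truth.haplotype_a.items()}
        det_mm = {scf: set() for scf in cov}
        detected_events = []
        for s in clean_segments:
            cov[s.scaffold_a][s.start_a:s.end_a] = True
            a_pos, _, mm = s.a_positions()
            det_mm[s.scaffold_a].update(a_pos[mm].tolist())
            for off, etype, length in s.indel_events:
                detected_events.append(
                    (s.scaffold_a, s.start_a + off, etype, length))
        # SNVs: positions must agree exactly within covered regions
        planted_snvs = {
            (r.scaffold, r.position)
            for r in led[led["type"] == "SNV"].itertuples(index=False)
            if cov[r.scaffold][r.position]
        }
        detected_snvs = {(scf, p) for scf, ps in det_mm.items() for p in ps}
        assert detected_snvs == planted_snvs
        # indels: 1:1 event matching; only events whose full context is
        # interior to one segment are required to be found
        interior = []
        for r in led[led["type"] != "SNV"].itertuples(index=False):
            lo, hi = r.position - 8, r.position + r.length + 8
            if any(s.scaffold_a == r.scaffold and s.start_a <= lo
                   and hi <= s.end_a for s in clean_segments):
                etype = "insertion" if r.type == "INS" else "deletion"
                interior.append((r.scaffold, r.position, etype, r.length))
        missed, spurious = match_ledger_events(interior, detected_events)
        assert missed == []
        # every detected event corresponds to some planted event
        all_planted = [
            (r.scaffold, r.position,
             "insertion" if r.type == "INS" else "deletion", r.length)
            for r in led[led["type"] != "SNV"].itertuples(index=False)
        ]
        missed2, spurious2 = match_ledger_events(all_planted, detected_events)
        assert spurious2 == []


class TestClassDensities:
    def test_partition_covers_every_aligned_base(self, clean_truth,
                                                 clean_segments):
        lengths = {s: len(q) for s, q in clean_truth.haplotype_a.items()}
        densities, _ = class_densities(clean_segments,
                                       clean_truth.genes_on("A"), lengths)
        aligned_total = sum(s.aligned_columns for s in clean_segments)
        assert sum(d.aligned_bases for d in densities) == aligned_total

    def test_recovers_configured_rates_without_indels(self):
        cfg = SimulationConfig(seed=31, ancestral_length=150_000,
                               n_scaffolds=2, n_genes=30,
                               indel_event_rate=0.0,
                               n_inversions=0, n_translocations=0)
        truth = generate_truth(cfg)
        scaffolds = {**truth.haplotype_a, **truth.haplotype_b}
        segments = pair_assembly(scaffolds)
        lengths = {s: len(q) for s, q in truth.haplotype_a.items()}
        densities, _ = class_densities(segments, truth.genes_on("A"), lengths)
        expected = {"CDS": 0.037, "intron": 0.071, "intergenic": 0.056}
        for d in densities:
            p = expected[d.annotation_class]
            sd = math.sqrt(p * (1 - p) / d.aligned_bases)
            assert abs(d.density_pct / 100 - p) <= 3 * sd, d.annotation_class

    def test_detected_density_equals_ledger_density(self, clean_truth,
                                                    clean_segments):
        lengths = {s: len(q) for s, q in clean_truth.haplotype_a.items()}
        densities, _ = class_densities(clean_segments,
                                       clean_truth.genes_on("A"), lengths)
        led = clean_truth.variant_ledger
        cov = {scf: np.zeros(n, bool) for scf, n in lengths.items()}
        for s in clean_segments:
            a_pos, _, _ = s.a_positions()
            cov[s.scaffold_a][a_pos] = True
        for d in densities:
            planted = sum(
                1 for r in led[(led["type"] == "SNV")
                               & (led["annotation_class"]
                                  == d.annotation_class)].itertuples(index=False)
                if cov[r.scaffold][r.position]
            )
            assert d.snvs == planted, d.annotation_class

    def test_gene_free_annotation_is_all_intergenic(self):
        seg = _segment("a", 0, [("match", 400), ("mismatch", 2),
                                ("match", 98)])
        densities, per_gene = class_densities([seg], [], {"a": 600})
        by_class = {d.annotation_class: d for d in densities}
        assert by_class["intergenic"].aligned_bases == 500
        assert by_class["intergenic"].snvs == 2
        assert by_class["CDS"].aligned_bases == 0
        assert per_gene.empty

    def test_per_gene_density_arithmetic(self):
        gene = GeneModel("g1", "a", "+", exons=[(100, 400)],
                         cds_intervals=[(100, 400)])
        ops = [("match", 100)]
        for _ in range(12):
            ops += [("mismatch", 1), ("match", 24)]
        seg = _segment("a", 0, ops)  # 12 mismatches inside [100, 400)
        densities, per_gene = class_densities([seg], [gene],
                                              {"a": seg.end_a})
        cds_rows = per_gene[per_gene["annotation_class"] == "CDS"]
        assert cds_rows.iloc[0]["aligned_bases"] == 300
        assert cds_rows.iloc[0]["snvs"] == 12
        assert cds_rows.iloc[0]["density_pct"] == pytest.approx(4.0)


class TestWindowTracks:
    def test_mismatch_window_placement(self):
        seg = _segment("a", 0, [("match", 5), ("mismatch", 1), ("match", 144),
                                ("mismatch", 1), ("match", 49)])
        tracks, indels = window_tracks([seg], {"a": 200})
        assert tracks["a"].tolist() == [1, 1]
        assert indels.empty

    def test_window_sums_conserve_mismatches(self, clean_segments,
                                             clean_truth):
        lengths = {s: len(q) for s, q in clean_truth.haplotype_a.items()}
        tracks, _ = window_tracks(clean_segments, lengths)
        per_scaffold = {scf: 0 for scf in lengths}
        for s in clean_segments:
            per_scaffold[s.scaffold_a] += s.n_mismatch
        for scf, total in per_scaffold.items():
            assert tracks[scf].sum() == total

    def test_deletion_reported_before_gap_with_negative_length(self):
        seg = _segment("a", 0, [("match", 250), ("deletion", 5),
                                ("match", 100)])
        _, indels = window_tracks([seg], {"a": 400})
        assert indels.iloc[0].tolist() == ["a", 249, -5]

    def test_insertion_reported_positive(self):
        seg = _segment("a", 0, [("match", 100), ("insertion", 3),
                                ("match", 100)])
        _, indels = window_tracks([seg], {"a": 300})
        assert indels.iloc[0].tolist() == ["a", 99, 3]


class TestStructuralEvents:
    def test_no_events_no_calls(self, clean_segments):
        assert structural_events(clean_segments) == []

    def test_planted_events_called_exactly(self, default_truth,
                                           default_segments):
        calls = structural_events(default_segments)
        inversions = [c for c in calls if c.type == "inversion"]
        translocations = [c for c in calls if c.type == "translocation"]
        assert len(inversions) == 1
        assert len(translocations) == 1
        ledger = default_truth.structural_ledger
        inv = ledger[ledger["type"] == "inversion"].iloc[0]
        # the inversion call's partner interval overlaps the planted one
        c = inversions[0]
        assert c.partner == inv["scaffold"]
        assert c.partner_start < inv["end"] and inv["start"] < c.partner_end
        tr = ledger[ledger["type"] == "translocation"].iloc[0]
        assert translocations[0].partner == tr["dest_scaffold"]

    def test_sensitivity_across_seeds(self):
        for seed in (41, 42, 43):
            cfg = SimulationConfig(seed=seed, ancestral_length=150_000,
                                   n_scaffolds=2, n_genes=30,
                                   n_inversions=1, n_translocations=1)
            truth = generate_truth(cfg)
            segments = pair_assembly(
                {**truth.haplotype_a, **truth.haplotype_b})
            calls = structural_events(segments)
            assert sum(c.type == "inversion" for c in calls) == 1
            assert sum(c.type == "translocation" for c in calls) == 1


def test_class_array_precedence():
    gene = GeneModel("g", "s", "+", exons=[(10, 40), (60, 90)],
                     cds_intervals=[(10, 40), (60, 90)])
    arr = build_class_array([gene], "s", 100)
    assert (arr[:10] == 0).all()        # upstream intergenic
    assert (arr[10:40] == 2).all()      # CDS
    assert (arr[40:60] == 1).all()      # intron
    assert (arr[90:] == 0).all()
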