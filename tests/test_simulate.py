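"""Generator contracts: identities, determinism, ledgers, emissions."""

import math

import numpy as np
import pandas as pd
import pytest

from hyperhet.config import SimulationConfig, stage_rng
from hyperhet.io import read_fasta, read_gff_genes, revcomp
from hyperhet.simulate import (apply_ledgers, emit_assembly, generate_truth,
                               simulate_est_tags, simulate_expression,
                               simulate_reads)


def zero_rate_config(**kw):
    base = dict(seed=1, ancestral_length=30_000, n_scaffolds=2,
                snv_rate_cds=0.0, snv_rate_intron=0.0, snv_rate_intergenic=0.0,
                indel_event_rate=0.0, n_inversions=0, n_translocations=0,
                n_genes=6)
    base.update(kw)
    return SimulationConfig(**base)


class TestGenerateTruth:
    def test_zero_rates_give_identical_haplotypes(self):
        truth = generate_truth(zero_rate_config())
        for scf_a, scf_b in truth.scaffold_correspondence.items():
            assert truth.haplotype_a[scf_a] == truth.haplotype_b[scf_b]
        assert len(truth.variant_ledger) == 0
        assert len(truth.structural_ledger) == 0

    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=5, ancestral_length=60_000, n_scaffolds=2,
                               n_genes=8, n_inversions=1, n_translocations=1)
        t1, t2 = generate_truth(cfg), generate_truth(cfg)
        assert t1.haplotype_a == t2.haplotype_a
        assert t1.haplotype_b == t2.haplotype_b
        assert t1.variant_ledger.equals(t2.variant_ledger)
        assert t1.structural_ledger.equals(t2.structural_ledger)
        assert t1.expression_truth.equals(t2.expression_truth)

    def test_different_seeds_differ(self):
        a = generate_truth(SimulationConfig(seed=1, ancestral_length=10_000,
                                            n_scaffolds=1, n_genes=2,
                                            n_inversions=0, n_translocations=0))
        b = generate_truth(SimulationConfig(seed=2, ancestral_length=10_000,
                                            n_scaffolds=1, n_genes=2,
                                            n_inversions=0, n_translocations=0))
        assert a.haplotype_a != b.haplotype_a

    def test_ledger_replay_reproduces_haplotype_b(self, default_truth):
        assert apply_ledgers(default_truth) == default_truth.haplotype_b

    def test_uniform_substitution_rate_concentration(self, snv_only_truth):
        truth = snv_only_truth
        n = sum(len(s) for s in truth.haplotype_a.values())
        realized = (truth.variant_ledger["type"] == "SNV").sum() / n
        p = 0.057
        assert abs(realized - p) <= 3 * math.sqrt(p * (1 - p) / n)

    def test_class_specific_rates_concentrate(self, default_truth):
        truth = default_truth
        rates = {"CDS": truth.config.snv_rate_cds,
                 "intron": truth.config.snv_rate_intron,
                 "intergenic": truth.config.snv_rate_intergenic}
        led = truth.variant_ledger
        class_codes = {"intergenic": 0, "intron": 1, "CDS": 2}
        for cls, rate in rates.items():
            n_class = sum(
                int((arr == class_codes[cls]).sum())
                for arr in truth.class_arrays.values()
            )
            snvs = int(((led["type"] == "SNV")
                        & (led["annotation_class"] == cls)).sum())
            sd = math.sqrt(rate * (1 - rate) / n_class)
            assert abs(snvs / n_class - rate) <= 3 * sd, cls

    def test_structural_event_too_large_is_rejected(self):
        cfg = SimulationConfig(seed=1, ancestral_length=40_000, n_scaffolds=2,
                               n_genes=0, n_inversions=1, n_translocations=0,
                               inversion_size_range=(30_000, 35_000))
        with pytest.raises(ValueError):
            generate_truth(cfg)

    def test_gene_models_paired_and_valid(self, default_truth):
        genes_a = default_truth.genes_on("A")
        genes_b = {g.gene_id: g for g in default_truth.genes_on("B")}
        assert len(genes_a) == len(genes_b) == default_truth.config.n_genes
        for g in genes_a:
            partner = genes_b[g.allelic_partner]
            assert partner.allelic_partner == g.gene_id
            assert partner.cds_length % 3 == 0


class TestEmitAssembly:
    def test_fasta_record_count_and_roundtrip(self, tmp_path, clean_truth):
        fasta, gff = tmp_path / "a.fasta", tmp_path / "a.gff3"
        emit_assembly(clean_truth, fasta, gff)
        seqs = read_fasta(fasta)
        assert len(seqs) == 4  # 2 A-scaffolds + 2 B-scaffolds
        assert seqs == {**clean_truth.haplotype_a, **clean_truth.haplotype_b}

    def test_gff_roundtrip_preserves_gene_models(self, tmp_path, clean_truth):
        fasta, gff = tmp_path / "a.fasta", tmp_path / "a.gff3"
        emit_assembly(clean_truth, fasta, gff)
        by_id = {g.gene_id: g for g in read_gff_genes(gff)}
        assert len(by_id) == len(clean_truth.genes)
        for g in clean_truth.genes:
            r = by_id[g.gene_id]
            assert r.exons == g.exons
            assert r.cds_intervals == g.cds_intervals
            assert r.strand == g.strand
            assert r.allelic_partner == g.allelic_partner

    def test_fragmentation_splices_back(self, tmp_path, clean_truth):
        scf = next(iter(clean_truth.haplotype_a))
        fasta, gff = tmp_path / "f.fasta", tmp_path / "f.gff3"
        emit_assembly(clean_truth, fasta, gff, fragmentation=[(scf, 10_000)])
        seqs = read_fasta(fasta)
        assert len(seqs) == 5  # one scaffold split into two parts
        rebuilt = seqs[f"{scf}_part0"] + seqs[f"{scf}_part1"]
        assert rebuilt == clean_truth.haplotype_a[scf]


class TestExpression:
    def test_no_deviants_no_noise_gives_equal_counts(self):
        cfg = zero_rate_config(deviant_pair_fraction=0.0,
                               expression_poisson=False)
        truth = generate_truth(cfg)
        table, total = simulate_expression(truth)
        by_gene = table.set_index("gene_id")["fragment_count"]
        for ga, gb in truth.gene_pairs():
            assert by_gene[ga] == by_gene[gb]
        assert total == table["fragment_count"].sum()

    def test_deviant_pair_has_configured_fold(self):
        cfg = zero_rate_config(deviant_pair_fraction=1.0,
                               deviant_fold_range=(10.0, 10.0),
                               expression_poisson=False)
        truth = generate_truth(cfg)
        for row in truth.expression_truth.itertuples(index=False):
            assert row.deviant
            hi, lo = max(row.expected_a, row.expected_b), min(row.expected_a,
                                                              row.expected_b)
            assert hi / lo == pytest.approx(10.0)

    def test_deviant_count_binomial_bound(self):
        cfg = SimulationConfig(seed=21, ancestral_length=1_200_000,
                               n_scaffolds=2, n_genes=600,
                               snv_rate_cds=0, snv_rate_intron=0,
                               snv_rate_intergenic=0, indel_event_rate=0,
                               n_inversions=0, n_translocations=0,
                               deviant_pair_fraction=0.05)
        truth = generate_truth(cfg)
        flagged = int(truth.expression_truth["deviant"].sum())
        n, p = 600, 0.05
        assert abs(flagged - n * p) <= 3 * math.sqrt(n * p * (1 - p))


class TestReads:
    def test_read_count_arithmetic(self):
        cfg = zero_rate_config(ancestral_length=10_000, n_scaffolds=1,
                               n_genes=0, coverage_per_haplotype=1.0,
                               read_length=100, read_error_rate=0.0)
        truth = generate_truth(cfg)
        reads = simulate_reads(truth)
        assert len(reads) == 200  # 100 per haplotype copy

    def test_error_free_reads_are_exact_substrings(self):
        cfg = zero_rate_config(ancestral_length=20_000, n_scaffolds=1,
                               n_genes=0, coverage_per_haplotype=2.0,
                               read_error_rate=0.0)
        truth = generate_truth(cfg)
        genome = "#".join(truth.haplotype_a.values()) + "#" + \
                 "#".join(truth.haplotype_b.values())
        both = genome + "#" + revcomp(genome)
        for _, seq in simulate_reads(truth):
            assert seq in both

    def test_error_rate_realized(self):
        # with per-base error e the exact-substring fraction is (1-e)^L
        cfg = zero_rate_config(ancestral_length=30_000, n_scaffolds=1,
                               n_genes=0, coverage_per_haplotype=5.0,
                               read_error_rate=0.01)
        truth = generate_truth(cfg)
        genome = "#".join(truth.haplotype_a.values())
        both = genome + "#" + revcomp(genome)
        reads = simulate_reads(truth)
        exact = sum(seq in both for rid, seq in reads if rid.startswith("rA"))
        n = sum(1 for rid, _ in reads if rid.startswith("rA"))
        p = 0.99 ** cfg.read_length
        assert abs(exact / n - p) <= 4 * math.sqrt(p * (1 - p) / n)

    def test_short_scaffold_skipped_with_warning(self):
        cfg = zero_rate_config(ancestral_length=50, n_scaffolds=1, n_genes=0,
                               read_length=100)
        truth = generate_truth(cfg)
        with pytest.warns(UserWarning, match="shorter than read length"):
            assert simulate_reads(truth) == []


class TestEstTags:
    def test_family_counts(self):
        cfg = zero_rate_config(est_families=5, est_family_size_range=(4, 4),
                               est_error_rate=0.0)
        truth = generate_truth(cfg)
        tags, table = simulate_est_tags(truth)
        assert len(tags) == 20
        assert table["family_id"].nunique() == 5
        assert truth.est_truth is table

    def test_error_free_members_share_their_source(self):
        from hyperhet.estclust import trim_polya

        cfg = zero_rate_config(est_families=3, est_family_size_range=(3, 3),
                               est_error_rate=0.0)
        truth = generate_truth(cfg)
        tags, table = simulate_est_tags(truth)
        for fam, sub in table.groupby("family_id"):
            seqs = [trim_polya(tags[t]) for t in sub["tag_id"]]
            longest = max(seqs, key=len)
            for s in seqs:
                assert longest.endswith(s)  # members differ only by 5' jitter

    def test_within_family_identity_matches_error_rate(self):
        from hyperhet.estclust import local_identity, trim_polya

        cfg = zero_rate_config(est_families=4, est_family_size_range=(4, 4),
                               est_error_rate=0.05, est_tag_length=300)
        truth = generate_truth(cfg)
        tags, table = simulate_est_tags(truth)
        idents = []
        for fam, sub in table.groupby("family_id"):
            ids = list(sub["tag_id"])
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    ident, cols = local_identity(trim_polya(tags[ids[i]]),
                                                 trim_polya(tags[ids[j]]))
                    if cols >= 100:
                        idents.append(ident)
        # independent errors compose: expected identity ~ (1 - e)^2
        expected = 0.95 ** 2
        assert abs(np.mean(idents) - expected) < 0.03


def test_stage_rngs_are_independent_streams():
    a = stage_rng(1, "genome").random(5)
    b = stage_rng(1, "expression").random(5)
    assert not np.allclose(a, b)
    assert np.allclose(a, stage_rng(1, "genome").random(5))
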