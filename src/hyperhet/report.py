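"""Pipeline orchestration and consolidated reporting.

Runs the stages in dependency order over one simulated (or supplied)
assembly and collects every stage's headline numbers into a single
versioned JSON report plus a human-readable text summary laid out like
the classic assembly-statistics and gene-count tables.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import allexpr, divergence, estclust, hetstats, kmerspec, orthoclass, pairing
from .config import SimulationConfig
from .io import write_fasta, write_fastq, write_tsv
from .simulate import (DiploidTruth, emit_assembly, generate_truth,
                       simulate_est_tags, simulate_expression, simulate_reads)

REPORT_SCHEMA_VERSION = 1

STAGES = ("simulate", "pair", "stats", "classify", "expr",
          "divergence", "estclust", "kmers")

_STAGE_DEPS = {
    "pair": ("simulate",),
    "stats": ("simulate", "pair"),
    "classify": ("simulate",),
    "expr": ("simulate", "classify"),
    "divergence": ("simulate", "classify"),
    "estclust": ("simulate",),
    "kmers": ("simulate",),
}


class MissingStageError(RuntimeError):
    pass


def _check_deps(selected: set[str]) -> None:
    for stage in selected:
        for dep in _STAGE_DEPS.get(stage, ()):
            if dep not in selected:
                raise MissingStageError(
                    f"stage {stage!r} requires stage {dep!r}"
                )


def run_pipeline(config: SimulationConfig, outdir,
                 stages: tuple[str, ...] = STAGES) -> dict:
    """Run the selected stages end to end; returns the report dict.

    All outputs land under ``outdir``; the report JSON mirrors the stage
    outputs exactly (copies, never recomputations).
    """
    selected = set(stages)
    unknown = selected - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    _check_deps(selected)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "stages": sorted(selected),
    }

    truth = segments = None
    classifications = None
    pair_map: list[tuple[str, str]] = []

    if "simulate" in selected:
        truth = generate_truth(config)
        emit_assembly(truth, outdir / "assembly.fasta", outdir / "annotation.gff3")
        truth.variant_ledger.to_csv(outdir / "variant_ledger.tsv", sep="\t", index=False)
        truth.structural_ledger.to_csv(
            outdir / "structural_ledger.tsv", sep="\t", index=False
        )
        report["simulate"] = {
            "genome_length": truth.genome_length,
            "n_scaffolds": len(truth.haplotype_a) + len(truth.haplotype_b),
            "n_genes": len(truth.genes),
            "n_snvs": int((truth.variant_ledger["type"] == "SNV").sum()),
            "n_indel_events": int((truth.variant_ledger["type"] != "SNV").sum()),
            "n_structural_events": len(truth.structural_ledger),
        }

    scaffolds = {**truth.haplotype_a, **truth.haplotype_b} if truth else {}

    if "pair" in selected:
        segments = pairing.pair_assembly(scaffolds)
        pairing.write_segments_tsv(segments, outdir / "segments.tsv")
        pairing.write_segments_bed12(segments, outdir / "segments.bed")
        summary = pairing.summarize_pairing(segments, scaffolds)
        summary.to_json(outdir / "pairing_summary.json")
        report["pairing"] = dataclasses.asdict(summary)

    if "stats" in selected:
        totals = hetstats.variant_totals(segments)
        lengths = {name: len(seq) for name, seq in truth.haplotype_a.items()}
        densities, per_gene = hetstats.class_densities(
            segments, truth.genes_on("A"), lengths
        )
        write_tsv(per_gene, outdir / "per_gene_densities.tsv")
        tracks, indels = hetstats.window_tracks(segments, lengths)
        hetstats.write_wiggle(tracks, outdir / "mismatch_windows.wig")
        hetstats.write_indel_bed(indels, outdir / "indels.bed")
        calls = hetstats.structural_events(segments)
        hetstats.write_structural_tsv(calls, outdir / "structural_calls.tsv")
        report["hetstats"] = {
            "variant_totals": dataclasses.asdict(totals),
            "class_densities": {
                d.annotation_class: {
                    "aligned_bases": d.aligned_bases,
                    "snvs": d.snvs,
                    "density_pct": d.density_pct,
                } for d in densities
            },
            "n_structural_calls": len(calls),
            "n_inversion_calls": sum(1 for c in calls if c.type == "inversion"),
            "n_translocation_calls": sum(
                1 for c in calls if c.type == "translocation"
            ),
        }

    if "classify" in selected:
        # the simulated ortholog table: every allelic pair is one 2:1 group
        groups = [
            orthoclass.OrthologGroup(f"grp_{i:05d}", [ga, gb], [f"ref_{i:05d}"])
            for i, (ga, gb) in enumerate(truth.gene_pairs())
        ]
        classifications = orthoclass.classify_groups(groups)
        orthoclass.write_classification_tsv(
            classifications, outdir / "ortholog_classification.tsv"
        )
        summary = orthoclass.summarize_categories(classifications)
        estimate = orthoclass.estimate_gene_number(summary)
        with open(outdir / "classification_summary.json", "w") as fh:
            json.dump(orthoclass.summary_to_dict(summary, estimate), fh, indent=2)
        report["classification"] = orthoclass.summary_to_dict(summary, estimate)
        pair_map = orthoclass.allelic_pairs(classifications)

    if "expr" in selected:
        counts, total = simulate_expression(truth, config)
        write_tsv(counts, outdir / "fragment_counts.tsv")
        records = allexpr.build_records(counts, pair_map, total)
        comparable = allexpr.select_comparable_pairs(records)
        comparison, scatter = allexpr.compare_pairs(comparable)
        write_tsv(scatter, outdir / "expression_scatter.tsv")
        with open(outdir / "expression_summary.json", "w") as fh:
            json.dump(comparison.to_dict(), fh, indent=2)
        report["expression"] = comparison.to_dict()

    if "divergence" in selected:
        cds = _cds_sequences(truth)
        pairs = {
            f"{ga}|{gb}": (cds[ga], cds[gb]) for ga, gb in pair_map
        }
        table = divergence.divergence_table(pairs)
        write_tsv(table, outdir / "divergence.tsv")
        with np.errstate(invalid="ignore"):
            report["divergence"] = {
                "n_pairs": len(table),
                "median_identity_overall_pct": _median(table["identity_overall_pct"]),
                "median_identity_pos3_pct": _median(table["identity_pos3_pct"]),
                "median_identity_fourfold_pct": _median(table["identity_fourfold_pct"]),
                "median_dnds": _median(table["dnds_ratio"]),
                "n_significant": int((table["p_value"] < 0.05).sum()),
            }

    if "estclust" in selected:
        tags, est_truth = simulate_est_tags(truth, config)
        write_fasta(tags, outdir / "est_tags.fasta")
        write_tsv(est_truth, outdir / "est_truth.tsv")
        clusters = estclust.greedy_cluster(tags)
        estclust.write_cluster_tsv(clusters, outdir / "est_clusters.tsv")
        metrics = estclust.cluster_metrics(clusters, est_truth)
        report["estclust"] = {
            "n_tags": metrics.n_tags,
            "n_clusters": metrics.n_clusters,
            "n_families_true": int(est_truth["family_id"].nunique()),
            "adjusted_rand": metrics.adjusted_rand,
        }

    if "kmers" in selected:
        reads = simulate_reads(truth, config)
        write_fastq(reads, outdir / "reads.fastq")
        spectrum = kmerspec.count_kmers(reads)
        spectrum.write_tsv(outdir / "kmer_histogram.tsv")
        fit = kmerspec.fit_spectrum(spectrum)
        fit.to_json(outdir / "spectrum_fit.json")
        report["kmer_spectrum"] = json.loads(fit.to_json())

    return report


def _cds_sequences(truth: DiploidTruth) -> dict[str, str]:
    from .io import revcomp

    seqs = {}
    source = {**truth.haplotype_a, **truth.haplotype_b}
    for g in truth.genes:
        parts = [source[g.scaffold][s:e] for s, e in g.cds_intervals]
        cds = "".join(parts)
        seqs[g.gene_id] = revcomp(cds) if g.strand == "-" else cds
    return seqs


def _median(series) -> float | None:
    vals = pd.to_numeric(series, errors="coerce").dropna()
    return float(vals.median()) if len(vals) else None


# ---------------------------------------------------------------- output --

def write_report(report: dict, json_path, text_path=None) -> None:
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if text_path is not None:
        with open(text_path, "w") as fh:
            fh.write(format_report(report))


def format_report(report: dict) -> str:
    lines = ["Paired-genome analysis report",
             "=" * 29, ""]
    pairing_section = report.get("pairing")
    if pairing_section:
        lines += [
            "Assembly pairing",
            f"  genome length        {pairing_section['genome_length']:>15,}",
            f"  paired length        {pairing_section['paired_length']:>15,}",
            f"  coverage             {100 * pairing_section['coverage_fraction']:>14.1f}%",
            f"  SNVs                 {pairing_section['total_mismatches']:>15,}",
            f"  In/Del events        {pairing_section['total_indel_events']:>15,}",
            f"  heterozygosity       {pairing_section['heterozygosity_pct']:>14.1f}%",
            f"  In/Del rate          {pairing_section['indel_pct']:>14.2f}%",
            "",
        ]
    cls = report.get("classification")
    if cls:
        lines += ["Gene classification"]
        for cat, n in cls["category_gene_counts"].items():
            lines.append(f"  {cat:<6} {n:>10,} genes")
        lines += [
            f"  allelic pairs        {cls['pairs_total']:>12,}",
            f"  singletons           {cls['singletons_total']:>12,}",
            f"  gene-family genes    {cls['group_genes_total']:>12,}",
            f"  total genes          {cls['total_genes']:>12,}",
            f"  diploid gene number  {cls.get('diploid_gene_number_estimate', 0):>12,}",
            "",
        ]
    expr = report.get("expression")
    if expr:
        lines += [
            "Allelic expression",
            f"  pairs compared       {expr['n_pairs']:>12,}",
            f"  >1.5-fold            {expr['bin_counts']['>1.5']:>12,}",
            f"  >2-fold              {expr['bin_counts']['>2']:>12,}",
            f"  >5-fold              {expr['bin_counts']['>5']:>12,}",
            f"  Pearson r            {expr['pearson_r'] if expr['pearson_r'] is not None else 'n/a':>12}",
            "",
        ]
    spec = report.get("kmer_spectrum")
    if spec:
        lines += [
            "k-mer spectrum",
            f"  single-copy depth    {spec['mu_het']:>12.1f}",
            f"  two-copy depth       {spec['mu_hom']:>12.1f}",
            f"  genome size          {spec['genome_size_estimate']:>12,.0f} bp",
            "",
        ]
    missing = [s for s in ("pairing", "classification", "expression",
                           "kmer_spectrum") if s not in report]
    if missing:
        lines.append("Sections absent: " + ", ".join(missing))
        lines.append("")
    return "\n".join(lines)
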