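"""Heterozygosity accounting: totals, class densities, tracks, structure.

Compares detected SNV/indel counts to the planted ledger, breaks SNV
density down by annotation class, writes browser tracks, and calls the
planted inversion and translocation from segment geometry.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

from common import outdir, study_config

from hyperhet.hetstats import (class_densities, structural_events,
                               variant_totals, window_tracks,
                               write_indel_bed, write_structural_tsv,
                               write_wiggle)
from hyperhet.io import write_tsv
from hyperhet.pairing import pair_assembly
from hyperhet.simulate import generate_truth


def main():
    out = outdir("03_hetstats")
    truth = generate_truth(study_config())
    scaffolds = {**truth.haplotype_a, **truth.haplotype_b}
    segments = pair_assembly(scaffolds)

    totals = variant_totals(segments)
    led = truth.variant_ledger
    print(f"detected {totals.mismatch_columns:,} SNVs "
          f"(ledger: {(led['type'] == 'SNV').sum():,}) and "
          f"{totals.indel_event_columns:,} indel events "
          f"(ledger: {(led['type'] != 'SNV').sum():,})")
    print(f"rates over paired sequence: SNV {totals.snv_pct:.2f}%, "
          f"indel {totals.indel_pct:.2f}%")

    lengths = {s: len(q) for s, q in truth.haplotype_a.items()}
    densities, per_gene = class_densities(segments, truth.genes_on("A"),
                                          lengths)
    write_tsv(per_gene, out / "per_gene_densities.tsv")
    for d in densities:
        print(f"  {d.annotation_class:<10} {d.aligned_bases:>9,} bp aligned, "
              f"SNV density {d.density_pct:.2f}%")

    tracks, indels = window_tracks(segments, lengths)
    write_wiggle(tracks, out / "mismatch_windows.wig")
    write_indel_bed(indels, out / "indels.bed")

    calls = structural_events(segments)
    write_structural_tsv(calls, out / "structural_calls.tsv")
    for c in calls:
        print(f"  {c.type}: {c.scaffold_a}:{c.start_a}-{c.end_a} "
              f"paired with {c.partner}:{c.partner_start}-{c.partner_end}")
    print(f"structural ledger:\n{truth.structural_ledger.to_string()}")
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
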