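"""Ortholog-group classification and the diploid gene-number estimate.

Applies the doubleton/singleton/family classification both to the
simulated ortholog table (every allelic pair is a 2:1 group) and to the
published category counts, reproducing the collapsed diploid gene number.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

from common import outdir, study_config

from hyperhet.orthoclass import (OrthologGroup, classify_groups,
                                 estimate_gene_number, summarize_categories,
                                 summary_to_dict, write_classification_tsv)
from hyperhet.simulate import generate_truth

PUBLISHED = [
    (2, 1, 8046), (2, 2, 374), (1, 1, 210), (2, 0, 2925),
    (6, 1, 419), (5, 1, 140), (4, 0, 170), (3, 0, 21),
]


def main():
    out = outdir("04_orthoclass")
    truth = generate_truth(study_config())
    groups = [
        OrthologGroup(f"grp_{i:05d}", [ga, gb], [f"ref_{i:05d}"])
        for i, (ga, gb) in enumerate(truth.gene_pairs())
    ]
    classifications = classify_groups(groups)
    write_classification_tsv(classifications, out / "classification.tsv")
    summary = summarize_categories(classifications)
    estimate = estimate_gene_number(summary)
    print(f"simulated table: {summary.total_genes} genes -> "
          f"{summary.pairs_total} allelic pairs, estimate {estimate} "
          f"(truth: {len(truth.gene_pairs())} pairs)")

    pub_groups, i = [], 0
    for n_a, n_b, count in PUBLISHED:
        for _ in range(count):
            pub_groups.append(OrthologGroup(
                f"g{i}", [f"a{i}_{j}" for j in range(n_a)],
                [f"b{i}_{j}" for j in range(n_b)]))
            i += 1
    singles = [f"s{j}" for j in range(7564)]
    pub_summary = summarize_categories(classify_groups(pub_groups, singles))
    pub_estimate = estimate_gene_number(pub_summary)
    with open(out / "published_summary.json", "w") as fh:
        json.dump(summary_to_dict(pub_summary, pub_estimate), fh, indent=2)
    print(f"published counts: {pub_summary.total_genes:,} genes = "
          f"{pub_summary.pairs_total:,} pairs + "
          f"{pub_summary.singletons_total:,} singletons + "
          f"{pub_summary.group_genes_total:,} family genes "
          f"-> diploid gene number {pub_estimate:,}")
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
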