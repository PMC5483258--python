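"""Ortholog-group classification and the diploid gene-number estimate.

In an unphased hyper-heterozygous assembly most genes are present twice
(once per haplotype), so ortholog groups against a reference species fall
into characteristic categories: a doubleton matched to a single reference
gene (2:1) is the signature of an allelic pair.  Ortholog inference itself
(e.g. InParanoid output) is consumed as a neutral table, not recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

CATEGORIES = ("2:1", "2:2+", "3+:N", "1:1+", "2:0", "3+:0", "1:0")


@dataclass
class OrthologGroup:
    group_id: str
    members_a: list[str]  # focal-species genes
    members_b: list[str]  # reference-species genes


@dataclass
class OrthologClassification:
    group_id: str
    category: str
    n_a: int
    n_b: int
    allelic_pair: tuple[str, str] | None = None


@dataclass
class ClassificationSummary:
    category_gene_counts: dict[str, int]
    category_group_counts: dict[str, int]
    pairs_total: int
    singletons_total: int
    group_genes_total: int
    total_genes: int


def categorize(n_a: int, n_b: int) -> str:
    """Category from focal/reference member counts (total function)."""
    if n_a < 0 or n_b < 0 or (n_a == 0 and n_b == 0):
        raise ValueError(f"invalid member counts ({n_a}, {n_b})")
    if n_a == 2:
        return "2:1" if n_b == 1 else ("2:2+" if n_b >= 2 else "2:0")
    if n_a >= 3:
        return "3+:N" if n_b >= 1 else "3+:0"
    if n_a == 1:
        return "1:1+" if n_b >= 1 else "1:0"
    raise ValueError(f"group with no focal members is not classified ({n_a}, {n_b})")


def classify_groups(groups: list[OrthologGroup],
                    singles: list[str] | None = None,
                    ) -> list[OrthologClassification]:
    """Classify groups; ``singles`` are focal genes in no group (1:0).

    A focal gene appearing in more than one group (or both in a group and
    in ``singles``) raises an error naming the gene.
    """
    seen: set[str] = set()
    out: list[OrthologClassification] = []
    for g in groups:
        for gene in g.members_a:
            if gene in seen:
                raise ValueError(f"gene {gene} assigned to more than one group")
            seen.add(gene)
        n_a, n_b = len(g.members_a), len(g.members_b)
        if n_a == 0:
            continue  # reference-only group: no focal genes to classify
        pair = tuple(sorted(g.members_a)) if n_a == 2 else None
        out.append(OrthologClassification(g.group_id, categorize(n_a, n_b),
                                          n_a, n_b, pair))
    for gene in singles or []:
        if gene in seen:
            raise ValueError(f"gene {gene} assigned to more than one group")
        seen.add(gene)
        out.append(OrthologClassification(f"single:{gene}", "1:0", 1, 0, None))
    return out


def summarize_categories(classifications: list[OrthologClassification],
                         ) -> ClassificationSummary:
    gene_counts = {c: 0 for c in CATEGORIES}
    group_counts = {c: 0 for c in CATEGORIES}
    for cl in classifications:
        gene_counts[cl.category] += cl.n_a
        group_counts[cl.category] += 1
    pairs_total = sum(group_counts[c] for c in ("2:1", "2:2+", "2:0"))
    singletons_total = gene_counts["1:1+"] + gene_counts["1:0"]
    group_genes_total = gene_counts["3+:N"] + gene_counts["3+:0"]
    return ClassificationSummary(
        category_gene_counts=gene_counts,
        category_group_counts=group_counts,
        pairs_total=pairs_total,
        singletons_total=singletons_total,
        group_genes_total=group_genes_total,
        total_genes=sum(gene_counts.values()),
    )


def estimate_gene_number(summary: ClassificationSummary) -> int:
    """Gene number of the conventional (collapsed) diploid genome:
    pairs + singletons + half the gene-family genes, halves rounded up."""
    half = (summary.group_genes_total + 1) // 2
    return summary.pairs_total + summary.singletons_total + half


def allelic_pairs(classifications: list[OrthologClassification],
                  category: str = "2:1") -> list[tuple[str, str]]:
    """The allelic gene pairs implied by doubleton groups."""
    return [cl.allelic_pair for cl in classifications
            if cl.category == category and cl.allelic_pair]


# ------------------------------------------------------------------ I/O --

def read_group_table(path) -> tuple[list[OrthologGroup], list[str]]:
    """TSV with columns (group_id, species in {A, B}, gene_id); rows with
    group_id '-' (or empty) are unassigned focal singletons."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"group_id", "species", "gene_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"group table needs columns {sorted(required)}")
    singles = df[df["group_id"].isin(["-", ""]) | df["group_id"].isna()]
    if (singles["species"] != "A").any():
        raise ValueError("unassigned singletons must be focal (species A) genes")
    groups = []
    grouped = df[~df.index.isin(singles.index)]
    for gid, sub in grouped.groupby("group_id", sort=True):
        groups.append(OrthologGroup(
            group_id=str(gid),
            members_a=sorted(sub.loc[sub["species"] == "A", "gene_id"]),
            members_b=sorted(sub.loc[sub["species"] == "B", "gene_id"]),
        ))
    return groups, sorted(singles["gene_id"])


def write_classification_tsv(classifications: list[OrthologClassification],
                             path) -> None:
    rows = [
        (cl.group_id, cl.category, cl.n_a, cl.n_b,
         ",".join(cl.allelic_pair) if cl.allelic_pair else "")
        for cl in classifications
    ]
    pd.DataFrame(rows, columns=["group_id", "category", "n_a", "n_b",
                                "allelic_pair"]).to_csv(path, sep="\t", index=False)


def summary_to_dict(summary: ClassificationSummary,
                    gene_estimate: int | None = None) -> dict:
    out = {
        "category_gene_counts": summary.category_gene_counts,
        "category_group_counts": summary.category_group_counts,
        "pairs_total": summary.pairs_total,
        "singletons_total": summary.singletons_total,
        "group_genes_total": summary.group_genes_total,
        "total_genes": summary.total_genes,
    }
    if gene_estimate is not None:
        out["diploid_gene_number_estimate"] = gene_estimate
    return out
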