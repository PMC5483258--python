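"""Greedy incremental clustering of 3'-end EST tags by alignment identity.

Tags are processed in input order; each tag is locally aligned against the
existing clusters (in creation order) and joins the first cluster reaching
the identity threshold over a minimum overlap, otherwise it founds a new
cluster.  This reproduces the classic one-pass EST classification of cDNA
libraries by their 3' ends.

The local alignment itself (match +1, mismatch -1, affine gaps -2/-1) is
delegated to scikit-bio's ``pair_align``; a shared-k-mer prescreen skips
hopeless comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DNA
from skbio.alignment import pair_align


@dataclass
class TagCluster:
    cluster_id: int
    representative: str
    members: list[str] = field(default_factory=list)


def trim_polya(seq: str, min_run: int = 8) -> str:
    """Remove a terminal poly-A run (>= min_run A's) from a 3' tag."""
    n = len(seq)
    i = n
    while i > 0 and seq[i - 1] == "A":
        i -= 1
    return seq[:i] if n - i >= min_run else seq


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def local_identity(seq_a: str, seq_b: str) -> tuple[float, int]:
    """(identity, aligned columns) of the best local alignment.

    Identity is matches over all aligned columns, gap columns included.
    """
    res = pair_align(DNA(seq_a), DNA(seq_b), mode="local",
                     sub_score=(1.0, -1.0), gap_cost=(2.0, 1.0))
    if not res.paths:
        return 0.0, 0
    path = res.paths[0]
    pos_a, pos_b = int(path.starts[0]), int(path.starts[1])
    matches = columns = 0
    for length, state in zip(path.lengths, path.states[0]):
        columns += int(length)
        if state == 0:
            for t in range(length):
                matches += seq_a[pos_a + t] == seq_b[pos_b + t]
            pos_a += length
            pos_b += length
        elif state == 1:  # gap in seq_a
            pos_b += length
        else:  # gap in seq_b
            pos_a += length
    return (matches / columns if columns else 0.0), columns


def greedy_cluster(tags: dict[str, str] | list[tuple[str, str]],
                   identity_threshold: float = 0.90,
                   min_overlap: int = 50,
                   compare_mode: str = "all_members",
                   join: str = "first",
                   polya_trim: bool = True,
                   prescreen_k: int | None = 11) -> list[TagCluster]:
    """One-pass greedy clustering of tags in input order.

    compare_mode ``all_members`` aligns against every member of a cluster
    (single-linkage flavour, the faithful reading of comparing each clone
    with all previous ones); ``representative`` aligns only against the
    founding member (faster, order-sensitive in different ways).
    ``join`` is ``first`` (first qualifying cluster wins) or ``best``
    (highest identity among qualifying clusters).  ``prescreen_k`` skips
    alignments against clusters sharing no k-mer with the tag — a speed
    heuristic that is safe for realistic tags, where a qualifying overlap
    virtually always contains an exact 11-mer (set None to disable).
    """
    if compare_mode not in ("representative", "all_members"):
        raise ValueError(f"unknown compare_mode {compare_mode!r}")
    if join not in ("first", "best"):
        raise ValueError(f"unknown join policy {join!r}")
    items = list(tags.items()) if isinstance(tags, dict) else list(tags)
    clusters: list[TagCluster] = []
    cluster_seqs: list[list[str]] = []
    cluster_kmers: list[set[str]] = []
    for tag_id, raw_seq in items:
        seq = trim_polya(raw_seq.upper()) if polya_trim else raw_seq.upper()
        if not seq:
            warnings.warn(f"tag {tag_id} empty after trimming; skipped")
            continue
        kmers = _kmer_set(seq, prescreen_k) if prescreen_k else None
        best_cluster, best_identity = None, -1.0
        for ci, cluster in enumerate(clusters):
            if kmers is not None and not (kmers & cluster_kmers[ci]):
                continue
            candidates = (cluster_seqs[ci] if compare_mode == "all_members"
                          else cluster_seqs[ci][:1])
            hit = -1.0
            for other in candidates:
                identity, columns = local_identity(seq, other)
                if columns >= min_overlap and identity >= identity_threshold:
                    hit = max(hit, identity)
                    if join == "first":
                        break
            if hit >= 0:
                if join == "first":
                    best_cluster = ci
                    break
                if hit > best_identity:
                    best_cluster, best_identity = ci, hit
        if best_cluster is None:
            clusters.append(TagCluster(len(clusters), tag_id, [tag_id]))
            cluster_seqs.append([seq])
            cluster_kmers.append(set(kmers) if kmers is not None else set())
        else:
            clusters[best_cluster].members.append(tag_id)
            if compare_mode == "all_members":
                cluster_seqs[best_cluster].append(seq)
            if kmers is not None:
                cluster_kmers[best_cluster] |= kmers
    return clusters


@dataclass
class ClusterMetrics:
    n_clusters: int
    n_tags: int
    adjusted_rand: float
    per_family_purity: pd.DataFrame


def cluster_metrics(clusters: list[TagCluster], truth: pd.DataFrame,
                    ) -> ClusterMetrics:
    """Pair-counting agreement (adjusted Rand) and per-family purity
    against a truth table with columns (tag_id, family_id)."""
    from sklearn.metrics import adjusted_rand_score

    family_of = dict(zip(truth["tag_id"], truth["family_id"]))
    labels_true, labels_pred = [], []
    assignment: dict[str, int] = {}
    for cluster in clusters:
        for tag in cluster.members:
            if tag not in family_of:
                raise ValueError(f"tag {tag} missing from truth table")
            assignment[tag] = cluster.cluster_id
            labels_true.append(family_of[tag])
            labels_pred.append(cluster.cluster_id)
    ari = float(adjusted_rand_score(labels_true, labels_pred))
    rows = []
    fam_tags: dict[str, list[str]] = {}
    for tag, fam in family_of.items():
        if tag in assignment:
            fam_tags.setdefault(fam, []).append(tag)
    for fam, tags_in_fam in sorted(fam_tags.items()):
        counts: dict[int, int] = {}
        for tag in tags_in_fam:
            counts[assignment[tag]] = counts.get(assignment[tag], 0) + 1
        purity = max(counts.values()) / len(tags_in_fam)
        rows.append((fam, len(tags_in_fam), purity))
    per_family = pd.DataFrame(rows, columns=["family_id", "n_tags", "purity"])
    return ClusterMetrics(
        n_clusters=len(clusters),
        n_tags=len(labels_true),
        adjusted_rand=ari,
        per_family_purity=per_family,
    )


def write_cluster_tsv(clusters: list[TagCluster], path) -> None:
    rows = [(tag, c.cluster_id) for c in clusters for tag in c.members]
    pd.DataFrame(rows, columns=["tag_id", "cluster_id"]).to_csv(
        path, sep="\t", index=False
    )
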