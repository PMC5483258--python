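"""Detection of paired (allelic) scaffold structure by self-alignment.

The assembly of a hyper-heterozygous diploid contains both haplotypes as
separate scaffolds.  This module finds the pairing without external
aligners: exact k-mer anchors (canonical, repeat-suppressed), colinear
chaining by longest-increasing-subsequence, banded refinement of the
inter-anchor intervals into edit operations, and a reciprocal-best
one-to-one tiling so that every base participates in at most one retained
segment on each side.

Coordinates are 0-based half-open.  ``orientation == "reverse"`` means the
B interval is given on the forward strand with a reversed column mapping
(column i of the alignment pairs A base ``start_a + i`` with B base
``end_b - 1 - i`` counted over B-consuming columns).
"""

from __future__ import annotations

import bisect
import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

from .align import (DELETION, INSERTION, MATCH, MISMATCH, adaptive_align,
                    merge_ops)
from .io import encode_seq

FORWARD, REVERSE = "forward", "reverse"


class Anchor(NamedTuple):
    scaffold_a: str
    scaffold_b: str
    pos_a: int
    pos_b: int
    length: int
    orientation: str


@dataclass
class Chain:
    scaffold_a: str
    scaffold_b: str
    orientation: str
    pos_a: np.ndarray
    pos_b: np.ndarray  # forward-strand B start positions
    k: int

    def __len__(self) -> int:
        return self.pos_a.size


@dataclass
class PairedSegment:
    """One reciprocal-best alignment segment between two scaffolds."""

    scaffold_a: str
    start_a: int
    end_a: int
    scaffold_b: str
    start_b: int
    end_b: int
    orientation: str
    edit_ops: list[tuple[str, int]]
    score: int = 0
    tiling_density: float | None = None

    def __post_init__(self):
        if self.tiling_density is None:
            cols = self.aligned_columns_total
            self.tiling_density = self.score / cols if cols else 0.0

    @property
    def n_match(self) -> int:
        return sum(l for op, l in self.edit_ops if op == MATCH)

    @property
    def n_mismatch(self) -> int:
        return sum(l for op, l in self.edit_ops if op == MISMATCH)

    @property
    def n_indel_events(self) -> int:
        return sum(1 for op, _ in self.edit_ops if op in (INSERTION, DELETION))

    @property
    def edit_distance(self) -> int:
        """Mismatched columns plus gapped bases."""
        return sum(l for op, l in self.edit_ops if op != MATCH)

    @property
    def aligned_columns(self) -> int:
        """Match + mismatch columns (bases aligned base-to-base)."""
        return sum(l for op, l in self.edit_ops if op in (MATCH, MISMATCH))

    @property
    def aligned_columns_total(self) -> int:
        return sum(l for _, l in self.edit_ops)

    @property
    def indel_events(self) -> list[tuple[int, str, int]]:
        """(A-offset from start_a, type, length) per gap event."""
        events, a_off = [], 0
        for op, length in self.edit_ops:
            if op in (INSERTION, DELETION):
                events.append((a_off, op, length))
            if op in (MATCH, MISMATCH, DELETION):
                a_off += length
        return events

    def a_positions(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Arrays over aligned columns: A position, B position, mismatch flag."""
        ops = np.array([0 if op == MATCH else 1 if op == MISMATCH else
                        2 if op == INSERTION else 3 for op, _ in self.edit_ops])
        lens = np.array([l for _, l in self.edit_ops], dtype=np.int64)
        op_per_col = np.repeat(ops, lens)
        consumes_a = np.isin(op_per_col, (0, 1, 3))
        consumes_b = np.isin(op_per_col, (0, 1, 2))
        a_off = np.cumsum(consumes_a) - 1
        b_off = np.cumsum(consumes_b) - 1
        aligned = op_per_col <= 1
        a_pos = self.start_a + a_off[aligned]
        if self.orientation == FORWARD:
            b_pos = self.start_b + b_off[aligned]
        else:
            b_pos = self.end_b - 1 - b_off[aligned]
        return a_pos, b_pos, (op_per_col[aligned] == 1)

    def validate(self) -> None:
        la = sum(l for op, l in self.edit_ops if op in (MATCH, MISMATCH, DELETION))
        lb = sum(l for op, l in self.edit_ops if op in (MATCH, MISMATCH, INSERTION))
        if la != self.end_a - self.start_a or lb != self.end_b - self.start_b:
            raise ValueError("edit operations inconsistent with segment span")


# ---------------------------------------------------------------- anchors --

def _kmer_codes(codes: np.ndarray, k: int):
    if codes.size < k:
        return (np.empty(0, dtype=np.int64),) * 2 + (np.empty(0, dtype=bool),)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win <= 3).all(axis=1)
    fwd = np.zeros(win.shape[0], dtype=np.int64)
    rev = np.zeros(win.shape[0], dtype=np.int64)
    safe = np.where(win > 3, 0, win)
    for t in range(k):
        fwd = fwd * 4 + safe[:, t]
        rev = rev * 4 + (3 - safe[:, k - 1 - t])
    return fwd, rev, valid


def build_anchor_map(scaffolds: dict[str, str], k: int = 15,
                     max_seed_multiplicity: int = 10) -> list[Anchor]:
    """Exact shared canonical k-mers between scaffold positions.

    Positions whose window contains N are never seeded; k-mers occurring
    more than ``max_seed_multiplicity`` times in the whole assembly are
    skipped (repeat suppression).  Trivial self-hits (same scaffold, same
    position) are excluded, and anchors are oriented so that
    ``scaffold_a <= scaffold_b`` (with ``pos_a < pos_b`` on self-pairs).
    """
    if k < 11:
        raise ValueError("k must be >= 11")
    if not scaffolds:
        return []
    names = sorted(scaffolds)
    kmers, scafs, poss, strands = [], [], [], []
    for si, name in enumerate(names):
        codes = encode_seq(scaffolds[name].upper())
        fwd, rev, valid = _kmer_codes(codes, k)
        canon = np.minimum(fwd, rev)
        idx = np.flatnonzero(valid)
        kmers.append(canon[idx])
        scafs.append(np.full(idx.size, si, dtype=np.int32))
        poss.append(idx.astype(np.int64))
        strands.append((fwd[idx] <= rev[idx]))
    kmer = np.concatenate(kmers)
    scaf = np.concatenate(scafs)
    pos = np.concatenate(poss)
    strand = np.concatenate(strands)

    order = np.lexsort((pos, scaf, kmer))
    kmer, scaf, pos, strand = kmer[order], scaf[order], pos[order], strand[order]
    boundaries = np.flatnonzero(np.diff(kmer)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [kmer.size]])

    anchors: list[Anchor] = []
    for s, e in zip(starts, ends):
        size = e - s
        if size < 2 or size > max_seed_multiplicity:
            continue
        for i, j in itertools.combinations(range(s, e), 2):
            si, sj = scaf[i], scaf[j]
            if si == sj and pos[i] == pos[j]:
                continue
            orient = FORWARD if strand[i] == strand[j] else REVERSE
            anchors.append(Anchor(
                names[si], names[sj], int(pos[i]), int(pos[j]), k, orient
            ))
    return anchors


# --------------------------------------------------------------- chaining --

def _lis_indices(keys: list[int]) -> list[int]:
    """Indices of one longest strictly increasing subsequence."""
    tails: list[int] = []
    tails_idx: list[int] = []
    parent = [-1] * len(keys)
    for i, key in enumerate(keys):
        p = bisect.bisect_left(tails, key)
        if p == len(tails):
            tails.append(key)
            tails_idx.append(i)
        else:
            tails[p] = key
            tails_idx[p] = i
        parent[i] = tails_idx[p - 1] if p > 0 else -1
    out = []
    i = tails_idx[-1] if tails_idx else -1
    while i != -1:
        out.append(i)
        i = parent[i]
    return out[::-1]


def chain_anchors(anchors: Iterable[Anchor], max_gap: int = 500,
                  min_chain_anchors: int = 3,
                  max_chains_per_group: int = 50) -> list[Chain]:
    """Partition anchors into maximal colinear chains.

    Within each (scaffold pair, orientation) group, chains are extracted
    by repeated longest-increasing-subsequence DP (increasing in both
    coordinates for forward anchors, decreasing in B for reverse), then
    split wherever the inter-anchor gap exceeds ``max_gap`` on either
    sequence.
    """
    groups: dict[tuple[str, str, str], list[Anchor]] = {}
    for a in anchors:
        groups.setdefault((a.scaffold_a, a.scaffold_b, a.orientation), []).append(a)

    chains: list[Chain] = []
    for (sa, sb, orient), members in sorted(groups.items()):
        k = members[0].length
        pa = np.array([m.pos_a for m in members], dtype=np.int64)
        pb = np.array([m.pos_b for m in members], dtype=np.int64)
        remaining = np.arange(pa.size)
        for _ in range(max_chains_per_group):
            if remaining.size < min_chain_anchors:
                break
            rpa, rpb = pa[remaining], pb[remaining]
            if orient == FORWARD:
                order = np.lexsort((-rpb, rpa))
                keys = rpb[order].tolist()
            else:
                order = np.lexsort((rpb, rpa))
                keys = (-rpb[order]).tolist()
            lis = _lis_indices(keys)
            chosen = remaining[order[lis]]
            if chosen.size < min_chain_anchors:
                break
            cpa, cpb = pa[chosen], pb[chosen]
            gap_a = cpa[1:] - (cpa[:-1] + k)
            if orient == FORWARD:
                gap_b = cpb[1:] - (cpb[:-1] + k)
            else:
                gap_b = cpb[:-1] - (cpb[1:] + k)
            cut = np.flatnonzero((gap_a > max_gap) | (gap_b > max_gap)) + 1
            for part in np.split(np.arange(chosen.size), cut):
                if part.size >= min_chain_anchors:
                    chains.append(Chain(sa, sb, orient, cpa[part], cpb[part], k))
            mask = np.ones(remaining.size, dtype=bool)
            mask[order[lis]] = False
            remaining = remaining[mask]
    return chains


# ------------------------------------------------------------- refinement --

def _merge_anchor_runs(pa: np.ndarray, pb: np.ndarray, k: int):
    """Collapse colinear anchors into maximal exact-match runs.

    Overlapping anchors on different diagonals are clipped so that runs
    are strictly monotone in both coordinates.
    """
    runs: list[list[int]] = []  # [a_start, b_start, length]
    a_end = b_end = -1
    for a0, b0 in zip(pa, pb):
        a0, b0, length = int(a0), int(b0), k
        if runs:
            shift = max(a_end - a0, b_end - b0, 0)
            a0, b0, length = a0 + shift, b0 + shift, length - shift
            if length <= 0:
                continue
        if runs and a0 == a_end and b0 == b_end:
            runs[-1][2] += length
        else:
            runs.append([a0, b0, length])
        a_end = runs[-1][0] + runs[-1][2]
        b_end = runs[-1][1] + runs[-1][2]
    return runs


def refine_segments(chains: list[Chain], scaffolds: dict[str, str],
                    band: int = 16) -> list[PairedSegment]:
    """Align inter-anchor intervals and emit full edit-operation segments.

    Intervals between consecutive anchor runs are aligned with the banded
    affine aligner (band doubled on edge contact); equal-length intervals
    of up to 6 bp are compared column-wise directly, which is the optimal
    alignment for isolated substitution runs of that size.
    """
    codes_cache = {name: encode_seq(seq.upper()) for name, seq in scaffolds.items()}
    rc_cache: dict[str, np.ndarray] = {}
    segments: list[PairedSegment] = []
    for chain in chains:
        ca = codes_cache[chain.scaffold_a]
        if chain.orientation == FORWARD:
            cb = codes_cache[chain.scaffold_b]
            pb = chain.pos_b
        else:
            if chain.scaffold_b not in rc_cache:
                fwd_codes = codes_cache[chain.scaffold_b][::-1]
                rc = np.where(fwd_codes <= 3, 3 - fwd_codes, fwd_codes)
                rc_cache[chain.scaffold_b] = rc.astype(np.uint8)
            cb = rc_cache[chain.scaffold_b]
            pb = cb.size - chain.pos_b - chain.k
        runs = _merge_anchor_runs(chain.pos_a, pb, chain.k)

        ops: list[tuple[str, int]] = []
        for idx, (a0, b0, length) in enumerate(runs):
            if idx > 0:
                pa_prev, pb_prev, l_prev = runs[idx - 1]
                ga_s, ga_e = pa_prev + l_prev, a0
                gb_s, gb_e = pb_prev + l_prev, b0
                la, lb = ga_e - ga_s, gb_e - gb_s
                if la == lb and la <= 6:
                    seg_a, seg_b = ca[ga_s:ga_e], cb[gb_s:gb_e]
                    eq = seg_a == seg_b
                    for same in eq:
                        ops.append((MATCH if same else MISMATCH, 1))
                elif la or lb:
                    res = adaptive_align(ca[ga_s:ga_e], cb[gb_s:gb_e], band=band)
                    ops.extend(res.edit_ops)
            ops.append((MATCH, length))
        ops = merge_ops(ops)

        start_a, end_a = runs[0][0], runs[-1][0] + runs[-1][2]
        bp_s, bp_e = runs[0][1], runs[-1][1] + runs[-1][2]
        if chain.orientation == FORWARD:
            start_b, end_b = bp_s, bp_e
        else:
            start_b, end_b = cb.size - bp_e, cb.size - bp_s
        score = sum(
            l if op == MATCH else -l if op == MISMATCH else -(2 + l)
            for op, l in ops
        )
        seg = PairedSegment(
            chain.scaffold_a, int(start_a), int(end_a),
            chain.scaffold_b, int(start_b), int(end_b),
            chain.orientation, ops, score,
        )
        seg.validate()
        segments.append(seg)
    return segments


# ----------------------------------------------------------------- tiling --

def _slice_segment(seg: PairedSegment, a_lo: int, a_hi: int) -> PairedSegment:
    """Sub-segment covering A positions [a_lo, a_hi); boundary insertions
    (B-only bases outside the kept A run) are dropped."""
    new_ops: list[tuple[str, int]] = []
    a = seg.start_a
    b_off = 0
    b_lo = b_hi = None
    for op, length in seg.edit_ops:
        if op == INSERTION:
            if a_lo < a < a_hi:
                new_ops.append((op, length))
                if b_lo is None:
                    b_lo = b_off
                b_hi = b_off + length
            b_off += length
            continue
        step_b = op != DELETION
        lo = max(a, a_lo)
        hi = min(a + length, a_hi)
        if lo < hi:
            new_ops.append((op, hi - lo))
            if step_b:
                if b_lo is None:
                    b_lo = b_off + (lo - a)
                b_hi = b_off + (hi - a)
        a += length
        if step_b:
            b_off += length
    if b_lo is None:
        b_lo = b_hi = 0
    if seg.orientation == FORWARD:
        start_b, end_b = seg.start_b + b_lo, seg.start_b + b_hi
    else:
        start_b, end_b = seg.end_b - b_hi, seg.end_b - b_lo
    ops = merge_ops(new_ops)
    score = sum(
        l if op == MATCH else -l if op == MISMATCH else -(2 + l) for op, l in ops
    )
    out = PairedSegment(
        seg.scaffold_a, a_lo, a_hi, seg.scaffold_b, start_b, end_b,
        seg.orientation, ops, score, tiling_density=seg.tiling_density,
    )
    out.validate()
    return out


def reciprocal_best_tiling(segments: list[PairedSegment],
                           scaffolds: dict[str, str],
                           min_segment_length: int = 200) -> list[PairedSegment]:
    """One-to-one tiling: per-base best score-density on both sides.

    Conflicts are resolved by score density, then segment length, then
    scaffold/position order (deterministic); segments are trimmed to their
    maximal consistent runs and trimmed pieces shorter than
    ``min_segment_length`` on the A side are dropped.  Idempotent: density
    is inherited by trimmed pieces, so retiling changes nothing.
    """
    # segments too short to ever be retained must not claim bases either
    segments = [
        s for s in segments if s.end_a - s.start_a >= min_segment_length
    ]
    if not segments:
        return []
    order = sorted(
        range(len(segments)),
        key=lambda i: (
            -segments[i].tiling_density,
            -(segments[i].end_a - segments[i].start_a),
            segments[i].scaffold_a, segments[i].scaffold_b,
            segments[i].start_a, segments[i].start_b,
        ),
    )
    rank = np.empty(len(segments), dtype=np.int32)
    for r, i in enumerate(order):
        rank[i] = r

    big = np.int32(len(segments) + 1)
    owner = {name: np.full(len(seq), big, dtype=np.int32)
             for name, seq in scaffolds.items()}
    for i, seg in enumerate(segments):
        oa = owner[seg.scaffold_a]
        oa[seg.start_a:seg.end_a] = np.minimum(oa[seg.start_a:seg.end_a], rank[i])
        ob = owner[seg.scaffold_b]
        ob[seg.start_b:seg.end_b] = np.minimum(ob[seg.start_b:seg.end_b], rank[i])

    retained: list[PairedSegment] = []
    for i, seg in enumerate(segments):
        a_pos, b_pos, _ = seg.a_positions()
        keep_cols = (owner[seg.scaffold_a][a_pos] == rank[i]) & \
                    (owner[seg.scaffold_b][b_pos] == rank[i])
        # expand to per-A-base keep mask (deletion bases follow their run)
        keep_a = np.zeros(seg.end_a - seg.start_a, dtype=bool)
        keep_a[a_pos[keep_cols] - seg.start_a] = True
        del_mask = np.ones(seg.end_a - seg.start_a, dtype=bool)
        del_mask[a_pos - seg.start_a] = False
        dele = np.flatnonzero(del_mask)
        if dele.size:
            aligned_idx = np.flatnonzero(~del_mask)
            left = np.searchsorted(aligned_idx, dele) - 1
            ok = (left >= 0) & (left + 1 < aligned_idx.size)
            good = dele[ok][
                keep_a[aligned_idx[left[ok]]] & keep_a[aligned_idx[left[ok] + 1]]
            ]
            keep_a[good] = True
        if keep_a.all():
            if seg.end_a - seg.start_a >= min_segment_length:
                retained.append(seg)
            continue
        padded = np.concatenate([[False], keep_a, [False]]).astype(np.int8)
        edges = np.diff(padded)
        run_starts = np.flatnonzero(edges == 1)
        run_ends = np.flatnonzero(edges == -1)
        for s, e in zip(run_starts, run_ends):
            if e - s >= min_segment_length:
                retained.append(
                    _slice_segment(seg, seg.start_a + int(s), seg.start_a + int(e))
                )
    retained.sort(key=lambda s: (s.scaffold_a, s.start_a, s.scaffold_b, s.start_b))
    return retained


# ---------------------------------------------------------------- summary --

@dataclass
class PairingSummary:
    """Assembly-level pairing statistics (both-sides convention).

    ``paired_length`` counts covered bases on both sides of every
    alignment, and ``total_mismatches``/``total_indel_events`` count each
    mismatch column / gap event on both sides, so that
    ``100 * total_mismatches / paired_length`` is the heterozygosity of
    the paired sequence.  Column-level counts are kept alongside for
    truth-ledger comparisons.
    """

    genome_length: int
    paired_length: int
    coverage_fraction: float
    total_mismatches: int
    total_indel_events: int
    heterozygosity_pct: float
    indel_pct: float
    n_segments: int
    aligned_columns: int = 0
    mismatch_columns: int = 0
    indel_event_count: int = 0
    undefined: bool = False

    def to_json(self, path=None) -> str:
        text = json.dumps(self.__dict__, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def summary_from_totals(genome_length: int, paired_length: int,
                        total_mismatches: int, total_indel_events: int,
                        n_segments: int = 0) -> PairingSummary:
    """Summary statistics from printed assembly totals."""
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    undefined = paired_length == 0
    return PairingSummary(
        genome_length=genome_length,
        paired_length=paired_length,
        coverage_fraction=paired_length / genome_length,
        total_mismatches=total_mismatches,
        total_indel_events=total_indel_events,
        heterozygosity_pct=(
            0.0 if undefined else 100.0 * total_mismatches / paired_length
        ),
        indel_pct=0.0 if undefined else 100.0 * total_indel_events / paired_length,
        n_segments=n_segments,
        undefined=undefined,
    )


def summarize_pairing(segments: list[PairedSegment],
                      scaffolds: dict[str, str]) -> PairingSummary:
    genome_length = sum(len(s) for s in scaffolds.values())
    paired_length = sum(
        (s.end_a - s.start_a) + (s.end_b - s.start_b) for s in segments
    )
    mismatch_columns = sum(s.n_mismatch for s in segments)
    indel_events = sum(s.n_indel_events for s in segments)
    aligned_columns = sum(s.aligned_columns for s in segments)
    summary = summary_from_totals(
        genome_length, paired_length,
        2 * mismatch_columns, 2 * indel_events, n_segments=len(segments),
    )
    summary.aligned_columns = aligned_columns
    summary.mismatch_columns = mismatch_columns
    summary.indel_event_count = indel_events
    return summary


# ------------------------------------------------------------ convenience --

def pair_assembly(scaffolds: dict[str, str], k: int = 15,
                  max_seed_multiplicity: int = 10, max_gap: int = 500,
                  min_chain_anchors: int = 3, band: int = 16,
                  min_segment_length: int = 200) -> list[PairedSegment]:
    """Full pairing pipeline: anchors -> chains -> segments -> tiling."""
    anchors = build_anchor_map(scaffolds, k=k,
                               max_seed_multiplicity=max_seed_multiplicity)
    chains = chain_anchors(anchors, max_gap=max_gap,
                           min_chain_anchors=min_chain_anchors)
    segments = refine_segments(chains, scaffolds, band=band)
    return reciprocal_best_tiling(segments, scaffolds,
                                  min_segment_length=min_segment_length)


def write_segments_tsv(segments: list[PairedSegment], path) -> None:
    with open(path, "w") as fh:
        fh.write("scaffold_a\tstart_a\tend_a\tscaffold_b\tstart_b\tend_b\t"
                 "strand\tmatches\tmismatches\tindel_events\tscore\n")
        for s in segments:
            strand = "+" if s.orientation == FORWARD else "-"
            fh.write(
                f"{s.scaffold_a}\t{s.start_a}\t{s.end_a}\t{s.scaffold_b}\t"
                f"{s.start_b}\t{s.end_b}\t{strand}\t{s.n_match}\t"
                f"{s.n_mismatch}\t{s.n_indel_events}\t{s.score}\n"
            )


def write_segments_bed12(segments: list[PairedSegment], path) -> None:
    """Each retained pairing as two BED12 lines (A-side and B-side)."""
    with open(path, "w") as fh:
        for i, s in enumerate(segments):
            strand = "+" if s.orientation == FORWARD else "-"
            for scf, lo, hi in ((s.scaffold_a, s.start_a, s.end_a),
                                (s.scaffold_b, s.start_b, s.end_b)):
                fh.write(
                    f"{scf}\t{lo}\t{hi}\tpair_{i:06d}\t0\t{strand}\t{lo}\t{hi}\t"
                    f"0,0,0\t1\t{hi - lo}\t0\n"
                )
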