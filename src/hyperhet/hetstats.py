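"""Heterozygosity statistics over reciprocal-best paired segments.

Turns tiled segments plus a gene annotation into the assembly-level
variant totals, class-specific SNV densities (CDS / intron / intergenic),
100-bp window tracks for browser display, and inversion / translocation
calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneModel
from .pairing import FORWARD, PairedSegment

CLASS_NAMES = ("intergenic", "intron", "CDS")


# ---------------------------------------------------------------- totals --

@dataclass
class VariantTotals:
    """SNV and indel totals (both-sides convention, as in assembly tables).

    ``snv_count`` / ``indel_event_count`` count every mismatch column and
    gap event on both sides of each alignment; ``mismatch_columns`` /
    ``indel_event_columns`` are the per-column counts used when comparing
    against a planted-variant ledger.
    """

    snv_count: int
    indel_event_count: int
    snv_pct: float
    indel_pct: float
    paired_length: int
    mismatch_columns: int = 0
    indel_event_columns: int = 0
    undefined: bool = False


def variant_rates(snv_count: int, indel_event_count: int,
                  paired_length: int) -> VariantTotals:
    """Rates from printed totals: each indel event counts once regardless
    of length, percentages are per paired base."""
    if paired_length <= 0:
        return VariantTotals(0, 0, 0.0, 0.0, 0, undefined=True)
    return VariantTotals(
        snv_count=snv_count,
        indel_event_count=indel_event_count,
        snv_pct=100.0 * snv_count / paired_length,
        indel_pct=100.0 * indel_event_count / paired_length,
        paired_length=paired_length,
    )


def variant_totals(segments: list[PairedSegment]) -> VariantTotals:
    mismatch_columns = sum(s.n_mismatch for s in segments)
    indel_columns = sum(s.n_indel_events for s in segments)
    paired_length = sum(
        (s.end_a - s.start_a) + (s.end_b - s.start_b) for s in segments
    )
    totals = variant_rates(2 * mismatch_columns, 2 * indel_columns, paired_length)
    totals.mismatch_columns = mismatch_columns
    totals.indel_event_columns = indel_columns
    return totals


# ------------------------------------------------------------ annotation --

def build_class_array(genes: list[GeneModel], scaffold: str,
                      length: int) -> np.ndarray:
    """Per-base class codes (0 intergenic, 1 intron, 2 CDS) for one
    scaffold, precedence CDS > intron > intergenic."""
    intron = np.zeros(length, dtype=bool)
    for g in genes:
        if g.scaffold != scaffold:
            continue
        own = np.zeros(length, dtype=bool)
        s, e = g.span
        own[s:e] = True
        # exonic non-coding bases are not introns; they fall back to
        # intergenic unless covered by CDS below
        for xs, xe in g.exons:
            own[xs:xe] = False
        intron |= own
    arr = intron.astype(np.uint8)
    for g in genes:
        if g.scaffold != scaffold:
            continue
        for cs, ce in g.cds_intervals:
            arr[cs:ce] = 2
    return arr


@dataclass
class ClassDensity:
    annotation_class: str
    aligned_bases: int
    snvs: int

    @property
    def density_pct(self) -> float:
        return 100.0 * self.snvs / self.aligned_bases if self.aligned_bases else 0.0


def class_densities(segments: list[PairedSegment], genes: list[GeneModel],
                    scaffold_lengths: dict[str, int],
                    ) -> tuple[list[ClassDensity], pd.DataFrame]:
    """Class-specific SNV densities on the A side of the pairing.

    Every aligned A base (match or mismatch column) is assigned to exactly
    one class; per-gene CDS and intron records are returned for scatter
    output.  Annotation on scaffolds absent from ``scaffold_lengths`` is
    skipped with a warning.
    """
    import warnings

    known = set(scaffold_lengths)
    genes_by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        if g.scaffold not in known:
            warnings.warn(f"annotation scaffold {g.scaffold} absent from assembly")
            continue
        genes_by_scaffold.setdefault(g.scaffold, []).append(g)

    aligned_by_scaffold: dict[str, np.ndarray] = {}
    mismatch_by_scaffold: dict[str, np.ndarray] = {}
    for seg in segments:
        scf = seg.scaffold_a
        if scf not in aligned_by_scaffold:
            aligned_by_scaffold[scf] = np.zeros(scaffold_lengths[scf], dtype=bool)
            mismatch_by_scaffold[scf] = np.zeros(scaffold_lengths[scf], dtype=bool)
        a_pos, _, mm = seg.a_positions()
        aligned_by_scaffold[scf][a_pos] = True
        mismatch_by_scaffold[scf][a_pos[mm]] = True

    counts = {name: [0, 0] for name in CLASS_NAMES}  # aligned, snvs
    gene_rows = []
    for scf, aligned in aligned_by_scaffold.items():
        class_arr = build_class_array(
            genes_by_scaffold.get(scf, []), scf, scaffold_lengths[scf]
        )
        mm = mismatch_by_scaffold[scf]
        for code, name in enumerate(CLASS_NAMES):
            sel = (class_arr == code) & aligned
            counts[name][0] += int(sel.sum())
            counts[name][1] += int((sel & mm).sum())
        for g in genes_by_scaffold.get(scf, []):
            cds_mask = np.zeros(scaffold_lengths[scf], dtype=bool)
            for cs, ce in g.cds_intervals:
                cds_mask[cs:ce] = True
            span_mask = np.zeros(scaffold_lengths[scf], dtype=bool)
            s, e = g.span
            span_mask[s:e] = True
            exon_mask = np.zeros(scaffold_lengths[scf], dtype=bool)
            for xs, xe in g.exons:
                exon_mask[xs:xe] = True
            intron_mask = span_mask & ~exon_mask
            for cls, mask in (("CDS", cds_mask), ("intron", intron_mask)):
                al = int((mask & aligned).sum())
                sv = int((mask & aligned & mm).sum())
                gene_rows.append((g.gene_id, cls, al, sv,
                                  100.0 * sv / al if al else np.nan))
    densities = [
        ClassDensity(name, counts[name][0], counts[name][1]) for name in CLASS_NAMES
    ]
    per_gene = pd.DataFrame(
        gene_rows, columns=["gene_id", "annotation_class", "aligned_bases",
                            "snvs", "density_pct"]
    )
    return densities, per_gene


# ---------------------------------------------------------------- tracks --

def window_tracks(segments: list[PairedSegment],
                  scaffold_lengths: dict[str, int], window: int = 100,
                  ) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Mismatch counts per fixed window plus signed indel positions.

    Windows are anchored at A-scaffold coordinate 0 (last partial window
    kept).  Each indel is one signed length — positive insertion, negative
    deletion — reported at the base before the gap.
    """
    tracks = {
        scf: np.zeros(-(-length // window), dtype=np.int64)
        for scf, length in scaffold_lengths.items()
    }
    indel_rows = []
    for seg in segments:
        a_pos, _, mm = seg.a_positions()
        mm_pos = a_pos[mm]
        if mm_pos.size:
            np.add.at(tracks[seg.scaffold_a], mm_pos // window, 1)
        for off, etype, length in seg.indel_events:
            pos = max(seg.start_a + off - 1, 0)
            signed = length if etype == "insertion" else -length
            indel_rows.append((seg.scaffold_a, pos, signed))
    indels = pd.DataFrame(indel_rows, columns=["scaffold", "position", "signed_length"])
    if len(indels):
        indels = indels.sort_values(["scaffold", "position"]).reset_index(drop=True)
    return tracks, indels


def write_wiggle(tracks: dict[str, np.ndarray], path, window: int = 100) -> None:
    with open(path, "w") as fh:
        for scf in sorted(tracks):
            fh.write(f"fixedStep chrom={scf} start=1 step={window} span={window}\n")
            fh.write("\n".join(str(int(v)) for v in tracks[scf]) + "\n")


def write_indel_bed(indels: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in indels.itertuples(index=False):
            fh.write(f"{row.scaffold}\t{row.position}\t{row.position + 1}\t"
                     f"indel\t{row.signed_length}\n")


# ------------------------------------------------------------ structural --

@dataclass
class StructuralCall:
    type: str  # inversion | translocation
    scaffold_a: str
    start_a: int
    end_a: int
    partner: str
    partner_start: int
    partner_end: int
    evidence: list[int]


def structural_events(segments: list[PairedSegment]) -> list[StructuralCall]:
    """Inversion and translocation calls from segment geometry.

    The dominant partner of an A scaffold is the partner scaffold covering
    the most aligned bases.  A segment paired with a different scaffold is
    a translocation; a segment whose orientation opposes both flanking
    same-partner segments is an inversion (both flanks required, so lone
    edge segments are never called).
    """
    by_a: dict[str, list[tuple[int, PairedSegment]]] = {}
    for i, seg in enumerate(segments):
        by_a.setdefault(seg.scaffold_a, []).append((i, seg))

    calls: list[StructuralCall] = []
    for scf in sorted(by_a):
        entries = sorted(by_a[scf], key=lambda t: t[1].start_a)
        partner_cover: dict[str, int] = {}
        for _, seg in entries:
            partner_cover[seg.scaffold_b] = (
                partner_cover.get(seg.scaffold_b, 0) + seg.end_a - seg.start_a
            )
        dominant = max(sorted(partner_cover), key=lambda p: partner_cover[p])

        for pos, (i, seg) in enumerate(entries):
            if seg.scaffold_b != dominant:
                calls.append(StructuralCall(
                    "translocation", scf, seg.start_a, seg.end_a,
                    seg.scaffold_b, seg.start_b, seg.end_b, [i],
                ))
        same = [(i, seg) for i, seg in entries if seg.scaffold_b == dominant]
        for idx in range(1, len(same) - 1):
            i, seg = same[idx]
            prev_seg, next_seg = same[idx - 1][1], same[idx + 1][1]
            if (seg.orientation != prev_seg.orientation
                    and seg.orientation != next_seg.orientation):
                calls.append(StructuralCall(
                    "inversion", scf, seg.start_a, seg.end_a,
                    seg.scaffold_b, seg.start_b, seg.end_b, [i],
                ))
    return calls


def write_structural_tsv(calls: list[StructuralCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("type\tscaffold_a\tstart_a\tend_a\tpartner\t"
                 "partner_start\tpartner_end\n")
        for c in calls:
            fh.write(f"{c.type}\t{c.scaffold_a}\t{c.start_a}\t{c.end_a}\t"
                     f"{c.partner}\t{c.partner_start}\t{c.partner_end}\n")
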