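"""Synthetic diploid genome generator with complete truth ledgers.

Emulates an unphased assembly of a hyper-heterozygous diploid: haplotype A
is drawn at random, haplotype B is derived from it by class-specific point
substitutions (CDS < intergenic < intron densities), short insertion /
deletion events, and a few large inversions and translocations.  Every
planted change is recorded, and replaying the ledgers over haplotype A
must reproduce haplotype B byte for byte — downstream detection stages are
tested against these ledgers rather than against external data.

Conventions
-----------
* All coordinates are 0-based half-open on the sequence they name.
* ``INS`` at position p inserts the ledger sequence *before* base p of
  haplotype A; ``DEL`` at p removes ``length`` bases starting at p.
* Structural ledger rows are applied sequentially to haplotype B (after
  point variants); coordinates refer to the state at application time.
* Indel events and structural events are restricted to non-CDS sequence so
  that both haplotypes carry intact, frame-preserving gene models.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig, stage_rng
from .io import GeneModel, decode_seq, encode_seq, revcomp, write_fasta, write_gff3

CLASS_NAMES = ("intergenic", "intron", "CDS")
_CLASS_INTERGENIC, _CLASS_INTRON, _CLASS_CDS = 0, 1, 2

VARIANT_COLUMNS = ["scaffold", "position", "type", "length", "annotation_class", "seq"]
STRUCTURAL_COLUMNS = ["type", "scaffold", "start", "end", "dest_scaffold", "dest_pos"]


@dataclass
class DiploidTruth:
    """Two haplotype scaffold sets plus ledgers of every planted change."""

    config: SimulationConfig
    haplotype_a: dict[str, str]
    haplotype_b: dict[str, str]
    scaffold_correspondence: dict[str, str]
    variant_ledger: pd.DataFrame
    structural_ledger: pd.DataFrame
    genes: list[GeneModel]
    class_arrays: dict[str, np.ndarray]
    snv_eligible: dict[str, np.ndarray]
    expression_truth: pd.DataFrame
    est_truth: pd.DataFrame | None = None

    @property
    def genome_length(self) -> int:
        return sum(len(s) for s in self.haplotype_a.values()) + sum(
            len(s) for s in self.haplotype_b.values()
        )

    def genes_on(self, haplotype: str) -> list[GeneModel]:
        return [g for g in self.genes if g.haplotype == haplotype]

    def gene_pairs(self) -> list[tuple[str, str]]:
        return [
            (g.gene_id, g.allelic_partner)
            for g in self.genes
            if g.haplotype == "A" and g.allelic_partner
        ]


# ------------------------------------------------------------ gene layout --

def _split_codons(n_codons: int, n_exons: int, rng) -> list[int]:
    """Split n_codons into n_exons parts, each >= 3 codons."""
    n_exons = max(1, min(n_exons, n_codons // 3))
    extra = n_codons - 3 * n_exons
    cuts = np.sort(rng.integers(0, extra + 1, size=n_exons - 1)) if n_exons > 1 else []
    parts = np.diff(np.concatenate([[0], cuts, [extra]])) + 3
    return [int(p) for p in parts]


def _place_genes(scaffold_len: int, n_genes: int, cds_per_gene: int,
                 cfg: SimulationConfig, rng) -> list[dict]:
    """Lay genes left to right with even intergenic spacers.

    Returns dicts with exon/cds interval lists in scaffold coordinates.
    """
    if n_genes == 0:
        return []
    lo, hi = cfg.exons_per_gene_range
    layouts = []
    for _ in range(n_genes):
        n_ex = int(rng.integers(lo, hi + 1))
        exon_codons = _split_codons(cds_per_gene // 3, n_ex, rng)
        introns = [int(rng.integers(50, 201)) for _ in range(len(exon_codons) - 1)]
        layouts.append((exon_codons, introns))
    total_span = sum(
        sum(c * 3 for c in ex) + sum(intr) for ex, intr in layouts
    )
    spacer = (scaffold_len - total_span) // (n_genes + 1)
    if spacer < 100:
        raise ValueError(
            f"gene models do not fit: {n_genes} genes spanning {total_span} bp "
            f"leave a {spacer} bp spacer on a {scaffold_len} bp scaffold"
        )
    genes = []
    pos = spacer
    for exon_codons, introns in layouts:
        exons = []
        p = pos
        for i, codons in enumerate(exon_codons):
            exons.append((p, p + codons * 3))
            p += codons * 3
            if i < len(introns):
                p += introns[i]
        genes.append({
            "exons": exons,
            "cds": list(exons),
            "strand": "+" if rng.random() < 0.5 else "-",
        })
        pos = p + spacer
    return genes


# --------------------------------------------------------- variant planting --

def _coordinate_mapper(variants: pd.DataFrame, scaffold: str):
    """A->B coordinate shift function for one scaffold's point variants."""
    sub = variants[(variants["scaffold"] == scaffold) & (variants["type"] != "SNV")]
    thresholds, deltas = [], []
    for row in sub.itertuples(index=False):
        if row.type == "INS":
            thresholds.append(row.position)
            deltas.append(row.length)
        else:  # DEL: full effect once q >= position + length
            thresholds.append(row.position + row.length)
            deltas.append(-row.length)
    thr = np.array(thresholds, dtype=np.int64)
    order = np.argsort(thr, kind="stable")
    thr = thr[order]
    cum = np.cumsum(np.array(deltas, dtype=np.int64)[order])

    def mapper(q: int) -> int:
        i = np.searchsorted(thr, q, side="right")
        return int(q + (cum[i - 1] if i > 0 else 0))

    return mapper


def apply_point_variants(seq: str, variants: pd.DataFrame, scaffold: str) -> str:
    """Replay SNV/INS/DEL ledger rows for one scaffold of haplotype A."""
    codes = encode_seq(seq).copy()
    sub = variants[variants["scaffold"] == scaffold]
    snvs = sub[sub["type"] == "SNV"]
    if len(snvs):
        codes[snvs["position"].to_numpy()] = [
            encode_seq(s)[0] for s in snvs["seq"]
        ]
    indels = sub[sub["type"] != "SNV"].sort_values("position")
    pieces, prev = [], 0
    for row in indels.itertuples(index=False):
        pieces.append(codes[prev:row.position])
        if row.type == "INS":
            pieces.append(encode_seq(row.seq))
            prev = row.position
        else:
            prev = row.position + row.length
    pieces.append(codes[prev:])
    return decode_seq(np.concatenate(pieces))


def apply_structural_events(haplotype_b: dict[str, str],
                            structural: pd.DataFrame) -> dict[str, str]:
    """Replay the structural ledger (sequentially) over haplotype B."""
    seqs = dict(haplotype_b)
    for row in structural.itertuples(index=False):
        if row.type == "inversion":
            s = seqs[row.scaffold]
            seqs[row.scaffold] = (
                s[: row.start] + revcomp(s[row.start:row.end]) + s[row.end:]
            )
        elif row.type == "translocation":
            src = seqs[row.scaffold]
            segment = src[row.start:row.end]
            seqs[row.scaffold] = src[: row.start] + src[row.end:]
            dst = seqs[row.dest_scaffold]
            seqs[row.dest_scaffold] = (
                dst[: row.dest_pos] + segment + dst[row.dest_pos:]
            )
        else:
            raise ValueError(f"unknown structural event type {row.type!r}")
    return seqs


def apply_ledgers(truth: DiploidTruth) -> dict[str, str]:
    """Rebuild haplotype B from haplotype A plus the two ledgers."""
    rebuilt = {}
    for scf_a, scf_b in truth.scaffold_correspondence.items():
        rebuilt[scf_b] = apply_point_variants(
            truth.haplotype_a[scf_a], truth.variant_ledger, scf_a
        )
    return apply_structural_events(rebuilt, truth.structural_ledger)


# ------------------------------------------------------------- generation --

def _plant_snvs(codes: np.ndarray, class_arr: np.ndarray, rates: np.ndarray,
                eligible: np.ndarray, rng):
    """Per-class Bernoulli substitutions on eligible positions.

    The planting probability is scaled by each class's eligible fraction
    so that the realized density over *all* positions of a class matches
    the configured rate despite the indel clearance zones.
    """
    planting = np.zeros(3)
    for code in range(3):
        in_class = class_arr == code
        n_class = int(in_class.sum())
        if n_class == 0 or rates[code] == 0:
            continue
        frac = eligible[in_class].mean()
        if frac <= 0 or rates[code] / frac > 0.5:
            raise ValueError(
                "substitution rate not realizable: eligible fraction "
                f"{frac:.3f} for class rate {rates[code]}"
            )
        planting[code] = rates[code] / frac
    u = rng.random(codes.size)
    mask = (u < planting[class_arr]) & eligible
    positions = np.flatnonzero(mask)
    alts = (codes[positions] + 1 + rng.integers(0, 3, size=positions.size)) % 4
    return positions, alts


#: SNVs are not planted within this many bases of an indel boundary, so
#: that the planted edit script is the parsimonious one and alignment-based
#: detection can recover the ledger exactly (a gap shifted by d bases can
#: absorb an SNV only with d coincidental base equalities, probability
#: ~4^-d, negligible beyond this clearance).
SNV_INDEL_CLEARANCE = 6


def _plant_indels(scaffold_len: int, class_arr: np.ndarray,
                  cds_starts: np.ndarray, cfg: SimulationConfig, rng):
    """Indel events at non-CDS positions; deletions never reach CDS bases.

    Events keep a dead time of 50 bp plus the event length between them
    (nearby opposite-type events would otherwise be indistinguishable
    from mismatch runs), and the candidate rate is compensated both for
    the dead time and for the excluded CDS bases, so that the realized
    genome-wide event rate matches the configured value.
    """
    rate = cfg.indel_event_rate
    if rate == 0:
        return []
    dead_time = 50 + 1.0 / cfg.indel_length_geom_p
    non_cds = class_arr != _CLASS_CDS
    frac_non_cds = non_cds.mean()
    if frac_non_cds == 0:
        return []
    r_nc = rate / frac_non_cds
    if r_nc * dead_time >= 0.8:
        raise ValueError("indel_event_rate too high for the event dead time")
    candidate_rate = r_nc / (1.0 - r_nc * dead_time)
    u = rng.random(scaffold_len)
    candidates = np.flatnonzero((u < candidate_rate) & non_cds)
    events = []
    blocked_until = -1
    for pos in candidates:
        if pos < blocked_until:
            continue
        length = min(int(rng.geometric(cfg.indel_length_geom_p)), cfg.indel_max_length)
        if rng.random() < 0.5:  # insertion before pos
            ins = decode_seq(rng.integers(0, 4, size=length).astype(np.uint8))
            events.append((int(pos), "INS", length, ins))
            blocked_until = int(pos) + 50 + length
        else:
            nxt = np.searchsorted(cds_starts, pos, side="left")
            limit = int(cds_starts[nxt]) if nxt < cds_starts.size else scaffold_len
            length = min(length, limit - int(pos), scaffold_len - int(pos))
            if length <= 0:
                continue
            events.append((int(pos), "DEL", length, ""))
            blocked_until = int(pos) + length + 50
    return events


def _snv_eligibility(scaffold_len: int, indel_events: list[tuple]) -> np.ndarray:
    """Positions where an SNV can be planted without creating alignment
    ambiguity: outside deletions and clear of indel boundaries."""
    eligible = np.ones(scaffold_len, dtype=bool)
    w = SNV_INDEL_CLEARANCE
    for pos, etype, length, _ in indel_events:
        if etype == "INS":
            eligible[max(0, pos - w):pos + w] = False
        else:
            eligible[max(0, pos - w):pos + length + w] = False
    return eligible


def _choose_interval(scaffold_len: int, size: int, forbidden: list[tuple[int, int]],
                     rng, what: str, margin: int = 1000) -> tuple[int, int]:
    if size + 2 * margin >= scaffold_len:
        raise ValueError(
            f"{what} of {size} bp does not fit on a {scaffold_len} bp scaffold"
        )
    for _ in range(500):
        start = int(rng.integers(margin, scaffold_len - size - margin))
        end = start + size
        if all(end <= fs or start >= fe for fs, fe in forbidden):
            return start, end
    raise ValueError(f"could not place {what} of {size} bp outside gene models")


def generate_truth(config: SimulationConfig) -> DiploidTruth:
    """Generate both haplotypes, gene models and complete truth ledgers.

    Deterministic for a fixed ``config.seed``; haplotype B is constructed
    by literally replaying the ledgers, so the replay invariant holds by
    construction and any bookkeeping bug breaks it loudly.
    """
    config.validate()
    rng = stage_rng(config.seed, "genome")

    n = config.n_scaffolds
    base_len = config.ancestral_length // n
    lengths = [base_len + (1 if i < config.ancestral_length % n else 0) for i in range(n)]
    names_a = [f"scfA_{i:02d}" for i in range(n)]
    names_b = [f"scfB_{i:02d}" for i in range(n)]

    rates = np.array(
        [config.snv_rate_intergenic, config.snv_rate_intron, config.snv_rate_cds]
    )

    haplotype_a: dict[str, str] = {}
    class_arrays: dict[str, np.ndarray] = {}
    snv_eligible: dict[str, np.ndarray] = {}
    genes: list[GeneModel] = []
    variant_rows: list[tuple] = []
    genes_b_raw: list[GeneModel] = []

    genes_per_scaffold = [
        config.n_genes // n + (1 if i < config.n_genes % n else 0) for i in range(n)
    ]
    cds_per_gene = 0
    if config.n_genes:
        cds_per_gene = max(
            30, (int(config.cds_fraction * config.ancestral_length) // config.n_genes) // 3 * 3
        )

    # reserve a gene-free tail per scaffold so that structural events have
    # somewhere to land without disrupting gene models
    total_events = config.n_inversions + config.n_translocations
    reserve = 0
    if total_events:
        max_event = max(
            config.inversion_size_range[1] if config.n_inversions else 0,
            config.translocation_size_range[1] if config.n_translocations else 0,
        )
        per_scaffold_events = -(-total_events // n)  # ceil
        reserve = (max_event + 1500) * per_scaffold_events + 1500
        if reserve > 0.5 * min(lengths):
            raise ValueError(
                "structural events do not fit: gene-free reserve of "
                f"{reserve} bp exceeds half the scaffold length"
            )

    gene_counter = 0
    for i, (scf_a, scf_b, L) in enumerate(zip(names_a, names_b, lengths)):
        codes = rng.integers(0, 4, size=L).astype(np.uint8)
        layout = _place_genes(L - reserve, genes_per_scaffold[i], cds_per_gene,
                              config, rng)

        class_arr = np.zeros(L, dtype=np.uint8)
        scaffold_genes_a = []
        for g in layout:
            span_s, span_e = g["exons"][0][0], g["exons"][-1][1]
            class_arr[span_s:span_e] = _CLASS_INTRON
            for cs, ce in g["cds"]:
                class_arr[cs:ce] = _CLASS_CDS
            gid_a, gid_b = f"gA_{gene_counter:05d}", f"gB_{gene_counter:05d}"
            gene_counter += 1
            scaffold_genes_a.append(GeneModel(
                gene_id=gid_a, scaffold=scf_a, strand=g["strand"],
                exons=g["exons"], cds_intervals=g["cds"],
                haplotype="A", allelic_partner=gid_b,
            ))

        cds_starts = np.sort(np.array(
            [cs for g in layout for cs, _ in g["cds"]], dtype=np.int64
        ))
        indel_events = _plant_indels(L, class_arr, cds_starts, config, rng)
        eligible = _snv_eligibility(L, indel_events)
        snv_pos, snv_alt = _plant_snvs(codes, class_arr, rates, eligible, rng)
        for p, a in zip(snv_pos, snv_alt):
            variant_rows.append(
                (scf_a, int(p), "SNV", 1, CLASS_NAMES[class_arr[p]], "ACGT"[a])
            )
        for pos, etype, length, seq in indel_events:
            variant_rows.append(
                (scf_a, pos, etype, length, CLASS_NAMES[class_arr[pos]], seq)
            )

        haplotype_a[scf_a] = decode_seq(codes)
        class_arrays[scf_a] = class_arr
        snv_eligible[scf_a] = eligible
        genes.extend(scaffold_genes_a)

    variant_ledger = pd.DataFrame(variant_rows, columns=VARIANT_COLUMNS)
    if len(variant_ledger):
        variant_ledger = variant_ledger.sort_values(
            ["scaffold", "position"], kind="stable"
        ).reset_index(drop=True)

    # haplotype B before structural events, plus mapped gene models
    haplotype_b = {
        scf_b: apply_point_variants(haplotype_a[scf_a], variant_ledger, scf_a)
        for scf_a, scf_b in zip(names_a, names_b)
    }
    for scf_a, scf_b in zip(names_a, names_b):
        mapper = _coordinate_mapper(variant_ledger, scf_a)
        for g in genes:
            if g.scaffold == scf_a and g.haplotype == "A":
                gb = g.shifted(mapper)
                gb.gene_id, gb.allelic_partner = g.allelic_partner, g.gene_id
                gb.scaffold, gb.haplotype = scf_b, "B"
                genes_b_raw.append(gb)
    genes.extend(genes_b_raw)

    # structural events on haplotype B, avoiding gene models
    structural_rows = []
    b_genes = {scf: [] for scf in names_b}
    for g in genes:
        if g.haplotype == "B":
            b_genes[g.scaffold].append(g)

    placed_events: dict[str, list[tuple[int, int]]] = {scf: [] for scf in names_b}

    def forbidden_for(scf: str) -> list[tuple[int, int]]:
        pad = 600  # keep events apart so each keeps alignable flanks
        return [g.span for g in b_genes[scf]] + [
            (max(0, s - pad), e + pad) for s, e in placed_events[scf]
        ]

    def shift_genes(scf: str, threshold: int, delta: int) -> None:
        for g in b_genes[scf]:
            if g.span[0] >= threshold:
                g.exons = [(s + delta, e + delta) for s, e in g.exons]
                g.cds_intervals = [(s + delta, e + delta) for s, e in g.cds_intervals]

    event_scaffold = itertools.cycle(range(n))
    for _ in range(config.n_inversions):
        size = int(rng.integers(*config.inversion_size_range))
        scf = names_b[next(event_scaffold)]
        start, end = _choose_interval(
            len(haplotype_b[scf]), size, forbidden_for(scf), rng, "inversion"
        )
        structural_rows.append(("inversion", scf, start, end, scf, start))
        placed_events[scf].append((start, end))

    for _ in range(config.n_translocations):
        size = int(rng.integers(*config.translocation_size_range))
        src = names_b[next(event_scaffold)]
        dst_choices = [s for s in names_b if s != src]
        dst = dst_choices[int(rng.integers(0, len(dst_choices)))]
        start, end = _choose_interval(
            len(haplotype_b[src]), size, forbidden_for(src), rng, "translocation"
        )
        dest_forbidden = forbidden_for(dst)
        for _ in range(500):
            p = int(rng.integers(1000, len(haplotype_b[dst]) - 1000))
            if all(not fs < p < fe for fs, fe in dest_forbidden):
                break
        else:
            raise ValueError("could not place translocation destination")
        structural_rows.append(("translocation", src, start, end, dst, p))
        placed_events[src].append((start, end))
        placed_events[dst].append((p, p + (end - start)))
        shift_genes(src, end, -(end - start))
        shift_genes(dst, p, end - start)

    structural_ledger = pd.DataFrame(structural_rows, columns=STRUCTURAL_COLUMNS)
    haplotype_b = apply_structural_events(haplotype_b, structural_ledger)

    # expression truth: paired genes share a log-normal base level
    pairs = [(g.gene_id, g.allelic_partner) for g in genes
             if g.haplotype == "A" and g.allelic_partner]
    n_pairs = len(pairs)
    base = rng.lognormal(config.expression_log_mean, config.expression_log_sd, n_pairs)
    deviant = rng.random(n_pairs) < config.deviant_pair_fraction
    folds = rng.uniform(*config.deviant_fold_range, size=n_pairs)
    boost_a = rng.random(n_pairs) < 0.5
    exp_a, exp_b = base.copy(), base.copy()
    exp_a[deviant & boost_a] *= folds[deviant & boost_a]
    exp_b[deviant & ~boost_a] *= folds[deviant & ~boost_a]
    expression_truth = pd.DataFrame({
        "gene_a": [a for a, _ in pairs],
        "gene_b": [b for _, b in pairs],
        "expected_a": exp_a,
        "expected_b": exp_b,
        "deviant": deviant,
        "fold": np.where(deviant, folds, 1.0),
    })

    for g in genes:
        g.validate()

    return DiploidTruth(
        config=config,
        haplotype_a=haplotype_a,
        haplotype_b=haplotype_b,
        scaffold_correspondence=dict(zip(names_a, names_b)),
        variant_ledger=variant_ledger,
        structural_ledger=structural_ledger,
        genes=genes,
        class_arrays=class_arrays,
        snv_eligible=snv_eligible,
        expression_truth=expression_truth,
    )


# ---------------------------------------------------------------- outputs --

def emit_assembly(truth: DiploidTruth, fasta_path, gff_path,
                  fragmentation: list[tuple[str, int]] | None = None) -> None:
    """Write the unphased assembly (both haplotypes) as FASTA + GFF3.

    ``fragmentation`` optionally splits named scaffolds at breakpoints
    (contiguity stress for the pairing stage); gene features are always
    reported on the unfragmented coordinates.
    """
    sequences: dict[str, str] = {}
    for name, seq in {**truth.haplotype_a, **truth.haplotype_b}.items():
        breaks = sorted(p for s, p in (fragmentation or []) if s == name)
        if breaks:
            bounds = [0] + breaks + [len(seq)]
            for j, (s, e) in enumerate(zip(bounds, bounds[1:])):
                part = f"{name}_part{j}"
                if part in sequences:
                    raise ValueError(f"duplicate scaffold identifier {part}")
                sequences[part] = seq[s:e]
        else:
            if name in sequences:
                raise ValueError(f"duplicate scaffold identifier {name}")
            sequences[name] = seq
    write_fasta(sequences, fasta_path)
    write_gff3(truth.genes, gff_path)


def simulate_expression(truth: DiploidTruth, config: SimulationConfig | None = None
                        ) -> tuple[pd.DataFrame, int]:
    """Per-gene fragment counts (Poisson around the truth expectation).

    Returns the count table and the total mapped fragment count.
    """
    config = config or truth.config
    rng = stage_rng(config.seed, "expression")
    cds_len = {g.gene_id: g.cds_length for g in truth.genes}
    rows = []
    for row in truth.expression_truth.itertuples(index=False):
        for gid, expected in ((row.gene_a, row.expected_a), (row.gene_b, row.expected_b)):
            count = rng.poisson(expected) if config.expression_poisson else int(round(expected))
            rows.append((gid, cds_len[gid], int(count), expected, bool(row.deviant)))
    table = pd.DataFrame(
        rows, columns=["gene_id", "cds_length", "fragment_count", "expected_count", "deviant"]
    )
    return table, int(table["fragment_count"].sum())


def simulate_reads(truth: DiploidTruth, config: SimulationConfig | None = None
                   ) -> list[tuple[str, str]]:
    """Uniform-coverage error-bearing reads from both haplotypes."""
    config = config or truth.config
    rng = stage_rng(config.seed, "reads")
    rl = config.read_length
    reads: list[tuple[str, str]] = []
    for hap_label, scaffolds in (("A", truth.haplotype_a), ("B", truth.haplotype_b)):
        usable = {}
        for name, seq in scaffolds.items():
            if len(seq) < rl:
                warnings.warn(f"scaffold {name} shorter than read length; skipped")
                continue
            usable[name] = encode_seq(seq)
        if not usable:
            continue
        names = list(usable)
        weights = np.array([usable[s].size - rl + 1 for s in names], dtype=float)
        total_len = sum(len(s) for s in scaffolds.values())
        n_reads = int(round(config.coverage_per_haplotype * total_len / rl))
        scaffold_idx = rng.choice(len(names), size=n_reads, p=weights / weights.sum())
        strands = rng.random(n_reads) < 0.5
        for j in range(n_reads):
            codes = usable[names[scaffold_idx[j]]]
            start = int(rng.integers(0, codes.size - rl + 1))
            window = codes[start:start + rl].copy()
            if config.read_error_rate > 0:
                err = rng.random(rl) < config.read_error_rate
                k = int(err.sum())
                if k:
                    window[err] = (window[err] + 1 + rng.integers(0, 3, size=k)) % 4
            seq = decode_seq(window)
            if strands[j]:
                seq = revcomp(seq)
            reads.append((f"r{hap_label}_{j:07d}", seq))
    return reads


def simulate_est_tags(truth: DiploidTruth, config: SimulationConfig | None = None
                      ) -> tuple[dict[str, str], pd.DataFrame]:
    """3'-end tag families: one source region each, error-bearing copies.

    Sources are taken from the 3' ends of haplotype-A gene spans when
    available (random sequence otherwise); members get a poly-A tail,
    per-base errors and 5' length jitter.  Returns (tags, truth table);
    the truth table is also attached to ``truth.est_truth``.
    """
    config = config or truth.config
    rng = stage_rng(config.seed, "est")
    if config.est_families < 1:
        raise ValueError("est_families must be >= 1")
    tag_len = config.est_tag_length
    genes_a = truth.genes_on("A")
    sources = []
    for i in range(config.est_families):
        if i < len(genes_a):
            g = genes_a[i]
            seq = truth.haplotype_a[g.scaffold][g.span[0]:g.span[1]]
            if g.strand == "-":
                seq = revcomp(seq)
            src = seq[-tag_len:]
            if len(src) < tag_len:
                src = src + decode_seq(
                    rng.integers(0, 4, size=tag_len - len(src)).astype(np.uint8)
                )
        else:
            src = decode_seq(rng.integers(0, 4, size=tag_len).astype(np.uint8))
        sources.append(src)

    tags: dict[str, str] = {}
    rows = []
    counter = 0
    lo, hi = config.est_family_size_range
    for fam, src in enumerate(sources):
        n_members = int(rng.integers(lo, hi + 1))
        for _ in range(n_members):
            jitter = int(rng.integers(0, min(21, tag_len // 4)))
            codes = encode_seq(src[jitter:]).copy()
            if config.est_error_rate > 0:
                err = rng.random(codes.size) < config.est_error_rate
                k = int(err.sum())
                if k:
                    codes[err] = (codes[err] + 1 + rng.integers(0, 3, size=k)) % 4
            tail = "A" * int(rng.integers(8, 21))
            tag_id = f"tag_{counter:05d}"
            counter += 1
            tags[tag_id] = decode_seq(codes) + tail
            rows.append((tag_id, f"family_{fam:04d}"))
    est_truth = pd.DataFrame(rows, columns=["tag_id", "family_id"])
    truth.est_truth = est_truth
    return tags, est_truth
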