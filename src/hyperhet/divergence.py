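"""Coding-sequence divergence between allelic gene copies.

Codon-aware global alignment, identity overall / at third codon positions
/ at 4-fold degenerate sites, and counting-method (Nei–Gojobori 1986)
dN/dS with Jukes–Cantor correction and a Fisher exact significance test
on the site counts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

#: Two-base codon prefixes whose four completions encode one amino acid.
FOURFOLD_PREFIXES = frozenset(
    p for p in {c[:2] for c in GENETIC_CODE}
    if len({GENETIC_CODE[p + b] for b in "ACGT"}) == 1
)

BASES = "ACGT"


# ------------------------------------------------------- codon alignment --

@dataclass
class CodonAlignment:
    aligned_a: str
    aligned_b: str

    @property
    def codon_columns(self) -> list[tuple[str, str]]:
        """Gapless aligned codon pairs."""
        out = []
        for i in range(0, len(self.aligned_a), 3):
            ca, cb = self.aligned_a[i:i + 3], self.aligned_b[i:i + 3]
            if "-" not in ca and "-" not in cb:
                out.append((ca, cb))
        return out

    def validate(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned sequences differ in length")
        if len(self.aligned_a) % 3:
            raise ValueError("alignment length not a multiple of 3")
        for seq in (self.aligned_a, self.aligned_b):
            for i in range(0, len(seq), 3):
                codon = seq[i:i + 3]
                if "-" in codon and codon != "---":
                    raise ValueError("gap not aligned to codon boundary")


def _codon_score(ca: str, cb: str, mismatch: int = 1) -> int:
    return sum(1 if x == y else -mismatch for x, y in zip(ca, cb))


def align_cds_pair(cds_a: str, cds_b: str, gap_open: int = 5,
                   gap_extend: int = 2) -> CodonAlignment:
    """Global alignment over codon units (each codon one symbol).

    Codon-pair score is the sum of per-base match (+1) / mismatch (-1)
    scores; gaps are whole codons with affine penalties.  Deterministic
    tie-breaking prefers substitution over gaps, then a gap in the first
    sequence.
    """
    for name, seq in (("first", cds_a), ("second", cds_b)):
        if len(seq) % 3:
            raise ValueError(f"{name} CDS length {len(seq)} not a multiple of 3")
    a = [cds_a[i:i + 3] for i in range(0, len(cds_a), 3)]
    b = [cds_b[i:i + 3] for i in range(0, len(cds_b), 3)]
    n, m = len(a), len(b)
    NEG = -(10 ** 9)
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in A (consumes B)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in B (consumes A)
    H[0][0] = 0
    for j in range(1, m + 1):
        E[0][j] = -(gap_open + gap_extend * j)
        H[0][j] = E[0][j]
    for i in range(1, n + 1):
        F[i][0] = -(gap_open + gap_extend * i)
        H[i][0] = F[i][0]
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] - gap_extend,
                          H[i][j - 1] - gap_open - gap_extend)
            F[i][j] = max(F[i - 1][j] - gap_extend,
                          H[i - 1][j] - gap_open - gap_extend)
            H[i][j] = max(H[i - 1][j - 1] + _codon_score(a[i - 1], b[j - 1]),
                          E[i][j], F[i][j])
    out_a, out_b = [], []
    i, j = n, m
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            if (i > 0 and j > 0
                    and H[i][j] == H[i - 1][j - 1] + _codon_score(a[i - 1], b[j - 1])):
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i, j = i - 1, j - 1
            elif j > 0 and H[i][j] == E[i][j]:
                state = "E"
            elif i > 0 and H[i][j] == F[i][j]:
                state = "F"
            else:  # pragma: no cover - DP bookkeeping error
                raise RuntimeError("codon alignment traceback failed")
        elif state == "E":
            out_a.append("---")
            out_b.append(b[j - 1])
            j -= 1
            if not (j > 0 and E[i][j + 1] == E[i][j] - gap_extend):
                state = "H"
        else:
            out_a.append(a[i - 1])
            out_b.append("---")
            i -= 1
            if not (i > 0 and F[i + 1][j] == F[i][j] - gap_extend):
                state = "H"
    aln = CodonAlignment("".join(reversed(out_a)), "".join(reversed(out_b)))
    aln.validate()
    return aln


# --------------------------------------------------------------- identity --

@dataclass
class IdentityStats:
    identity_overall_pct: float | None
    identity_pos3_pct: float | None
    identity_fourfold_pct: float | None
    n_columns: int
    n_fourfold_sites: int


def identity_stats(alignment: CodonAlignment) -> IdentityStats:
    """Identity over gapless codon columns: all bases, third positions,
    and third positions of shared 4-fold degenerate codon families."""
    columns = alignment.codon_columns
    base_match = base_total = 0
    pos3_match = 0
    ff_match = ff_total = 0
    for ca, cb in columns:
        base_total += 3
        base_match += sum(x == y for x, y in zip(ca, cb))
        if ca[2] == cb[2]:
            pos3_match += 1
        if ca[:2] == cb[:2] and ca[:2] in FOURFOLD_PREFIXES:
            ff_total += 1
            ff_match += ca[2] == cb[2]
    n = len(columns)
    return IdentityStats(
        identity_overall_pct=100.0 * base_match / base_total if n else None,
        identity_pos3_pct=100.0 * pos3_match / n if n else None,
        identity_fourfold_pct=100.0 * ff_match / ff_total if ff_total else None,
        n_columns=n,
        n_fourfold_sites=ff_total,
    )


# ------------------------------------------------------------------ NG86 --

def syn_site_fraction(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    Each position contributes the fraction of its three alternative bases
    that preserve the amino acid; changes to stop codons count as
    nonsynonymous.  Raises for stop codons.
    """
    aa = GENETIC_CODE[codon]
    if aa == "*":
        raise ValueError(f"stop codon {codon} has no site decomposition here")
    syn = 0.0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if GENETIC_CODE[alt] == aa:
                syn += 1 / 3
    return syn, 3.0 - syn


def count_substitutions(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) substitutions between two codons,
    averaged over all minimal mutation paths (paths through stop codons
    are excluded unless every path hits a stop)."""
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        current = codon_a
        syn = nonsyn = 0.0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if GENETIC_CODE[nxt] == "*" and nxt != codon_b:
                blocked = True
            if GENETIC_CODE[current] != "*" and GENETIC_CODE[nxt] != "*" \
                    and GENETIC_CODE[nxt] == GENETIC_CODE[current]:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        paths.append((blocked, syn, nonsyn))
    usable = [p for p in paths if not p[0]] or paths
    sd = sum(p[1] for p in usable) / len(usable)
    nd = sum(p[2] for p in usable) / len(usable)
    return sd, nd


def jukes_cantor(p: float) -> float:
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class DnDsResult:
    dn: float
    ds: float
    ratio: float | None
    p_value: float
    syn_sites: float
    nonsyn_sites: float
    syn_subs: float
    nonsyn_subs: float
    jc_undefined: bool = False


def compute_dnds(alignment: CodonAlignment, min_columns: int = 1) -> DnDsResult:
    """Nei–Gojobori counting dN/dS over the gapless codon columns.

    Site counts are averaged over the two sequences; substitution counts
    are averaged over minimal mutation paths.  The proportions are
    Jukes–Cantor corrected (left uncorrected with ``jc_undefined`` set
    when a proportion reaches the 0.75 saturation bound), and the p-value
    is a two-sided Fisher exact test on the rounded (site x substituted)
    contingency table.
    """
    columns = [
        (ca, cb) for ca, cb in alignment.codon_columns
        if GENETIC_CODE[ca] != "*" and GENETIC_CODE[cb] != "*"
    ]
    if len(columns) < min_columns:
        raise ValueError(
            f"need at least {min_columns} gapless codon columns, "
            f"got {len(columns)}"
        )
    S = N = Sd = Nd = 0.0
    for ca, cb in columns:
        sa, na = syn_site_fraction(ca)
        sb, nb = syn_site_fraction(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = count_substitutions(ca, cb)
        Sd += sd
        Nd += nd
    ps = Sd / S if S else 0.0
    pn = Nd / N if N else 0.0
    jc_undefined = ps >= 0.75 or pn >= 0.75
    ds = ps if jc_undefined else jukes_cantor(ps)
    dn = pn if jc_undefined else jukes_cantor(pn)
    ratio = dn / ds if ds > 0 else None
    table = [[round(Sd), max(round(S - Sd), 0)],
             [round(Nd), max(round(N - Nd), 0)]]
    _, p_value = stats.fisher_exact(table)
    return DnDsResult(dn, ds, ratio, float(p_value), S, N, Sd, Nd, jc_undefined)


# --------------------------------------------------------------- drivers --

def divergence_table(pairs: dict[str, tuple[str, str]],
                     min_columns_dnds: int = 10) -> pd.DataFrame:
    """Per-pair identities and dN/dS for a map pair_id -> (cds_a, cds_b)."""
    rows = []
    for pair_id, (ca, cb) in pairs.items():
        aln = align_cds_pair(ca, cb)
        ident = identity_stats(aln)
        try:
            dd = compute_dnds(aln, min_columns=min_columns_dnds)
            dn, ds, ratio, p = dd.dn, dd.ds, dd.ratio, dd.p_value
        except ValueError:
            dn = ds = ratio = p = None
        rows.append((pair_id, ident.identity_overall_pct, ident.identity_pos3_pct,
                     ident.identity_fourfold_pct, dn, ds, ratio, p))
    return pd.DataFrame(rows, columns=[
        "pair_id", "identity_overall_pct", "identity_pos3_pct",
        "identity_fourfold_pct", "dN", "dS", "dnds_ratio", "p_value",
    ])
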