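"""Affine-gap global alignment with an optional diagonal band.

This is the base-level workhorse of the pairing stage: inter-anchor
intervals are aligned with match +1, mismatch -1, gap open -2, gap
extend -1 (a gap of length L costs 2 + L).  The band is centred on the
corner-to-corner diagonal and is widened automatically when the optimal
path touches its edge.

Edit operations use the A-as-reference convention:

* ``deletion``  — bases present in A but not in B (consume A only)
* ``insertion`` — bases present in B but not in A (consume B only)

so that match + mismatch + deletion lengths sum to len(A) and
match + mismatch + insertion lengths sum to len(B).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NEG_INF = np.int32(-(10 ** 9) // 2)

MATCH, MISMATCH, INSERTION, DELETION = "match", "mismatch", "insertion", "deletion"


@dataclass
class AlignmentResult:
    score: int
    edit_ops: list[tuple[str, int]]
    touched_band: bool = False

    @property
    def n_match(self) -> int:
        return sum(l for op, l in self.edit_ops if op == MATCH)

    @property
    def n_mismatch(self) -> int:
        return sum(l for op, l in self.edit_ops if op == MISMATCH)

    @property
    def n_gap_events(self) -> int:
        return sum(1 for op, _ in self.edit_ops if op in (INSERTION, DELETION))

    @property
    def edit_distance(self) -> int:
        """Mismatched columns plus gapped bases."""
        return sum(l for op, l in self.edit_ops if op != MATCH)


def merge_ops(ops: list[tuple[str, int]]) -> list[tuple[str, int]]:
    """Coalesce adjacent runs of the same operation."""
    out: list[tuple[str, int]] = []
    for op, length in ops:
        if length == 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + length)
        else:
            out.append((op, length))
    return out


def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq.astype(np.int16)
    from .io import encode_seq

    return encode_seq(seq).astype(np.int16)


def global_align(a, b, band: int | None = None,
                 match: int = 1, mismatch: int = -1,
                 gap_open: int = 2, gap_extend: int = 1) -> AlignmentResult:
    """Optimal global alignment (Gotoh), optionally constrained to a band.

    ``band=None`` searches the full matrix.  With a band, cells with
    diagonal offset outside ``[min(0, lb-la) - band, max(0, lb-la) + band]``
    are unreachable; ``touched_band`` reports whether the traceback grazed
    the band edge (the caller should then widen and retry).
    """
    ca, cb = _as_codes(a), _as_codes(b)
    la, lb = ca.size, cb.size
    if la == 0 and lb == 0:
        return AlignmentResult(0, [])
    if la == 0:
        return AlignmentResult(-(gap_open + gap_extend * lb), [(INSERTION, lb)])
    if lb == 0:
        return AlignmentResult(-(gap_open + gap_extend * la), [(DELETION, la)])

    if band is None:
        dlo, dhi = -la, lb
        banded = False
    else:
        dlo = min(0, lb - la) - band
        dhi = max(0, lb - la) + band
        banded = True

    H = np.full((la + 1, lb + 1), NEG_INF, dtype=np.int32)
    E = np.full((la + 1, lb + 1), NEG_INF, dtype=np.int32)  # gap in A (consumes B)
    F = np.full((la + 1, lb + 1), NEG_INF, dtype=np.int32)  # gap in B (consumes A)

    j_idx = np.arange(lb + 1, dtype=np.int32)
    H[0, 1:] = -(gap_open + gap_extend * j_idx[1:])
    E[0, 1:] = H[0, 1:]
    H[0, 0] = 0
    if banded:
        off0 = j_idx - 0
        H[0, (off0 < dlo) | (off0 > dhi)] = NEG_INF
        E[0] = np.where(H[0] <= NEG_INF // 2, NEG_INF, H[0])
        E[0, 0] = NEG_INF

    ext_j = (gap_extend * j_idx).astype(np.int64)

    for i in range(1, la + 1):
        F[i] = np.maximum(F[i - 1] - gap_extend, H[i - 1] - gap_open - gap_extend)
        sub_row = np.where(cb == ca[i - 1], np.int32(match), np.int32(mismatch))
        G = np.full(lb + 1, np.int64(NEG_INF), dtype=np.int64)
        G[1:] = H[i - 1, :-1].astype(np.int64) + sub_row
        G = np.maximum(G, F[i].astype(np.int64))
        # affine horizontal pass via prefix max of G[k] + ext*k
        T = np.maximum.accumulate(G + ext_j)
        E_row = np.full(lb + 1, np.int64(NEG_INF))
        E_row[1:] = T[:-1] - gap_open - ext_j[1:]
        H_row = np.maximum(G, E_row)
        if banded:
            off = j_idx - i
            outside = (off < dlo) | (off > dhi)
            H_row[outside] = NEG_INF
            E_row[outside] = NEG_INF
            F[i, outside] = NEG_INF
        H[i] = np.clip(H_row, NEG_INF, None).astype(np.int32)
        E[i] = np.clip(E_row, NEG_INF, None).astype(np.int32)

    # traceback; tie-break prefers diagonal, then gap in A, then gap in B
    ops: list[tuple[str, int]] = []
    i, j = la, lb
    state = "H"
    touched = False
    while i > 0 or j > 0:
        if banded and (j - i == dlo or j - i == dhi):
            touched = True
        if state == "H":
            here = H[i, j]
            if i > 0 and j > 0:
                s = match if ca[i - 1] == cb[j - 1] else mismatch
                if here == H[i - 1, j - 1] + s:
                    ops.append((MATCH if s == match else MISMATCH, 1))
                    i, j = i - 1, j - 1
                    continue
            if j > 0 and here == E[i, j]:
                state = "E"
                continue
            if i > 0 and here == F[i, j]:
                state = "F"
                continue
            raise RuntimeError("traceback failed (inconsistent DP matrices)")
        elif state == "E":
            ops.append((INSERTION, 1))
            j -= 1
            if not (j > 0 and E[i, j + 1] == E[i, j] - gap_extend):
                state = "H"
        else:  # F
            ops.append((DELETION, 1))
            i -= 1
            if not (i > 0 and F[i + 1, j] == F[i, j] - gap_extend):
                state = "H"

    ops.reverse()
    return AlignmentResult(int(H[la, lb]), merge_ops(ops), touched_band=touched)


def adaptive_align(a, b, band: int = 16, **scoring) -> AlignmentResult:
    """Banded alignment with automatic band widening.

    The band is doubled until the score is stable across a doubling and
    the optimal path stays clear of the band edge; once the band covers
    the whole matrix the result is exactly the unbanded optimum, so the
    returned alignment is always score-optimal.
    """
    la = a.size if isinstance(a, np.ndarray) else len(a)
    lb = b.size if isinstance(b, np.ndarray) else len(b)
    full = max(la, lb)
    if band >= full:
        return global_align(a, b, band=None, **scoring)
    res = global_align(a, b, band=band, **scoring)
    while band < full:
        band *= 2
        if band >= full:
            return global_align(a, b, band=None, **scoring)
        res2 = global_align(a, b, band=band, **scoring)
        if res2.score == res.score and not res2.touched_band:
            return res2
        res = res2
    return res
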