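"""Affine-gap local alignment and maximum-subarray alignment trimming.

Split-read breakpoint mapping aligns a whole read both to a genomic
window and to ME consensus sequences.  Because the read crosses a
junction, each of those local alignments typically has a "junk" tail of
mismatches past the breakpoint.  The cleanup step converts alignment
columns to +1 (match) / -5 (mismatch or gap base) and keeps the
maximum-sum contiguous block of columns (Kadane's algorithm, O(n)); with
the lenient local score this recovers the clean portion of the alignment
on either side of the junction.

The aligner is a plain (non-SIMD) Smith-Waterman with affine gaps,
vectorized across the target axis with numpy; a gap of length g costs
``gap_open + (g - 1) * gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np


@dataclass(frozen=True)
class ScoringScheme:
    """Local alignment scores (defaults match the lenient SR scheme)."""

    match: int = 1
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2

    @property
    def open_cost(self) -> int:
        return -self.gap_open

    @property
    def extend_cost(self) -> int:
        return -self.gap_extend


DEFAULT_SCHEME = ScoringScheme()

# Kadane column values: +1 for a matching base, -5 for anything else
KADANE_MATCH = 1
KADANE_MISS = -5


@dataclass
class LocalAlignment:
    """A local alignment of ``query[query_begin:query_end]`` against
    ``target[target_begin:target_end]`` (0-based half-open intervals).

    ``cigar`` is query-vs-target: M consumes both, I consumes query only,
    D consumes target only.  ``strand`` records the query orientation the
    alignment was computed in.
    """

    query_begin: int
    query_end: int
    target_begin: int
    target_end: int
    score: int
    cigar: str
    strand: str = "+"
    query: str = ""
    target: str = ""

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_begin

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_begin

    def columns(self) -> List[Tuple[str, Optional[str], Optional[str]]]:
        """Expand the cigar into per-base columns (op, qbase, tbase)."""
        out: List[Tuple[str, Optional[str], Optional[str]]] = []
        qi, ti = self.query_begin, self.target_begin
        num = ""
        for ch in self.cigar:
            if ch.isdigit():
                num += ch
                continue
            n = int(num)
            num = ""
            if ch == "M":
                for _ in range(n):
                    out.append(("M", self.query[qi], self.target[ti]))
                    qi += 1
                    ti += 1
            elif ch == "I":
                for _ in range(n):
                    out.append(("I", self.query[qi], None))
                    qi += 1
            elif ch == "D":
                for _ in range(n):
                    out.append(("D", None, self.target[ti]))
                    ti += 1
            else:  # pragma: no cover - aligner only emits M/I/D
                raise ValueError(f"unexpected cigar op {ch!r}")
        return out

    def rescore(self, scheme: ScoringScheme = DEFAULT_SCHEME) -> int:
        """Recompute the affine-gap score of this alignment from its cigar."""
        score = 0
        prev_op = None
        for op, qb, tb in self.columns():
            if op == "M":
                eq = qb == tb and qb not in ("N", "n")
                score += scheme.match if eq else scheme.mismatch
            else:
                score += scheme.gap_extend if prev_op == op else scheme.gap_open
            prev_op = op
        return score


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


_N_CODE = ord("N")
_NEG = np.int32(-(10**8))


def local_align(
    query: str,
    target: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    strand: str = "+",
) -> Optional[LocalAlignment]:
    """Optimal affine-gap local alignment of ``query`` against ``target``.

    Returns None when no positive-scoring alignment exists.  Ties are
    broken deterministically toward the alignment with the smallest end
    coordinates (query, then target), which for repeated exact occurrences
    coincides with the smallest begin coordinates; within the traceback,
    diagonal moves are preferred over gaps.

    ``N`` never matches (it scores as a mismatch).
    """
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    q = _encode(query)
    t = _encode(target)
    nq, nt = q.size, t.size
    match = np.int32(scheme.match)
    mism = np.int32(scheme.mismatch)
    open_c = np.int32(scheme.open_cost)
    ext_c = np.int32(scheme.extend_cost)

    H = np.zeros((nq + 1, nt + 1), dtype=np.int32)
    F = np.full((nq + 1, nt + 1), _NEG, dtype=np.int32)
    E = np.full((nq + 1, nt + 1), _NEG, dtype=np.int32)
    H0 = np.zeros((nq + 1, nt + 1), dtype=np.int32)

    t_is_n = t == _N_CODE
    jarange = np.arange(nt, dtype=np.int32) * ext_c

    for i in range(1, nq + 1):
        qi = q[i - 1]
        sub = np.where((t == qi) & ~t_is_n & (qi != _N_CODE), match, mism)
        # vertical gap state (consumes query base)
        F[i, 1:] = np.maximum(H[i - 1, 1:] - open_c, F[i - 1, 1:] - ext_c)
        h0 = np.maximum(0, H[i - 1, :-1] + sub)
        h0 = np.maximum(h0, F[i, 1:])
        H0[i, 1:] = h0
        # horizontal gap state via prefix-scan:
        # E[j] = max_{k<j} H0[k] - open - (j-1-k)*ext
        A = h0 + jarange  # A[k] = H0[i, k+1] + k*ext  (k over target idx 0..nt-1)
        C = np.maximum.accumulate(A)
        if nt > 1:
            # E[i, j] = C[j-2] - open - (j-2)*ext  for target col j >= 2
            E[i, 2:] = C[:-1] - open_c - jarange[:-1]
        E[i, 1] = _NEG
        H[i, 1:] = np.maximum(h0, E[i, 1:])

    best = int(H.max())
    if best <= 0:
        return None
    # first row-major occurrence of the maximum = smallest (i, j) end cell
    flat = int(np.argmax(H))
    ei, ej = divmod(flat, nt + 1)

    # traceback
    ops: List[str] = []
    i, j = ei, ej
    allow_e = True
    while i > 0 and j > 0:
        h = H[i, j] if allow_e else H0[i, j]
        if h == 0:
            break
        qi = q[i - 1]
        eq = (qi == t[j - 1]) and t[j - 1] != _N_CODE and qi != _N_CODE
        sub = match if eq else mism
        if H[i - 1, j - 1] + sub == h and H0[i, j] == h:
            ops.append("M")
            i -= 1
            j -= 1
            allow_e = True
            continue
        if F[i, j] == h and H0[i, j] == h:
            # vertical gap run: consume query bases
            while True:
                ops.append("I")
                if F[i, j] == H[i - 1, j] - open_c:
                    i -= 1
                    allow_e = True
                    break
                i -= 1
            continue
        if allow_e and E[i, j] == h:
            # horizontal gap run: consume target bases
            while True:
                ops.append("D")
                if E[i, j] == H0[i, j - 1] - open_c:
                    j -= 1
                    allow_e = False
                    break
                j -= 1
            continue
        raise AssertionError("traceback failed")  # pragma: no cover

    ops.reverse()
    cigar = _rle(ops)
    return LocalAlignment(
        query_begin=i,
        query_end=ei,
        target_begin=j,
        target_end=ej,
        score=best,
        cigar=cigar,
        strand=strand,
        query=query,
        target=target,
    )


def _rle(ops: List[str]) -> str:
    if not ops:
        return ""
    parts = []
    cur, n = ops[0], 1
    for op in ops[1:]:
        if op == cur:
            n += 1
        else:
            parts.append(f"{n}{cur}")
            cur, n = op, 1
    parts.append(f"{n}{cur}")
    return "".join(parts)


def kadane_max_subarray(scores) -> Optional[Tuple[int, int, int]]:
    """Maximum-sum contiguous block of ``scores``.

    Returns ``(start, end, total)`` with a half-open interval, or None if
    every block sums <= 0.  Ties are broken toward the leftmost block,
    then the longest.
    """
    best_sum = 0
    best: Optional[Tuple[int, int, int]] = None
    cur_sum = 0
    cur_start = 0
    for i, s in enumerate(scores):
        if cur_sum < 0:
            cur_sum = s
            cur_start = i
        else:
            cur_sum += s
        if cur_sum > best_sum:
            best_sum = cur_sum
            best = (cur_start, i + 1, cur_sum)
        elif best is not None and cur_sum == best_sum and cur_sum > 0:
            if cur_start == best[0] and i + 1 > best[1]:
                best = (cur_start, i + 1, cur_sum)
    return best


def alignment_column_scores(aln: LocalAlignment) -> List[int]:
    """+1 per matching column, -5 per mismatch or gap base."""
    vals = []
    for op, qb, tb in aln.columns():
        ok = op == "M" and qb == tb and qb not in ("N", "n")
        vals.append(KADANE_MATCH if ok else KADANE_MISS)
    return vals


def kadane_trim(
    aln: LocalAlignment, scheme: ScoringScheme = DEFAULT_SCHEME
) -> Optional[LocalAlignment]:
    """Trim an alignment to its maximum-subarray column block.

    Columns are valued +1 (match) / -5 (mismatch or gap base); the
    retained block is the maximum-sum contiguous run of columns, ties
    broken leftmost-then-longest.  Returns None when no column matches
    (all-negative array), signalling the caller to discard the split.
    The returned alignment has its intervals and affine score recomputed.
    """
    cols = aln.columns()
    scores = [
        KADANE_MATCH if (op == "M" and qb == tb and qb not in ("N", "n")) else KADANE_MISS
        for op, qb, tb in cols
    ]
    block = kadane_max_subarray(scores)
    if block is None:
        return None
    start, end, _ = block
    qb, tb = aln.query_begin, aln.target_begin
    for op, _, _ in cols[:start]:
        if op in ("M", "I"):
            qb += 1
        if op in ("M", "D"):
            tb += 1
    qe, te = qb, tb
    ops = []
    for op, _, _ in cols[start:end]:
        if op in ("M", "I"):
            qe += 1
        if op in ("M", "D"):
            te += 1
        ops.append(op)
    trimmed = replace(
        aln,
        query_begin=qb,
        query_end=qe,
        target_begin=tb,
        target_end=te,
        cigar=_rle(ops),
    )
    trimmed.score = trimmed.rescore(scheme)
    return trimmed
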