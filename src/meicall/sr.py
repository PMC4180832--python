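"""Split-read breakpoint mapping against genome windows and ME consensus.

A split-read candidate (the soft-clipped or unmapped mate of an anchored
pair) is aligned *in full* twice: once against the genomic window implied
by its anchor, and once against k-mer-nominated regions of the ME
consensus library (both strands).  Both partial alignments are trimmed by
the maximum-subarray rule, and a consistent pair of parts — covering
near-complementary read intervals — yields a base-precise breakpoint from
the genome part alone: the last genome-aligned base before the inserted
sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .model import MEFamily, revcomp
from .sw import DEFAULT_SCHEME, LocalAlignment, ScoringScheme, kadane_trim, local_align

DEFAULT_WORD_SIZE = 11
DEFAULT_MIN_PART = 20
DEFAULT_OVERLAP_SLACK = 12
DIAG_BAND = 5
MAX_CANDIDATE_REGIONS = 8


@dataclass
class SplitAlignment:
    """A read split between a genomic flank and an ME consensus.

    ``breakpoint`` is the 1-based reference position of the last
    genome-aligned base before the inserted sequence.
    """

    genome_part: LocalAlignment
    me_part: LocalAlignment
    family: MEFamily
    me_id: str
    me_strand: str
    breakpoint: int
    chrom: str = ""
    read_name: str = ""
    sample_id: str = "sample0"


class MEIndex:
    """Hash index of ME consensus sequences (both strands).

    Words of size ``k`` from each consensus and its reverse complement
    map to ``(me_id, offset, strand)`` postings; candidate alignment
    regions are nominated where at least two words agree on a diagonal
    within +/- ``DIAG_BAND``.
    """

    def __init__(
        self,
        consensus: Dict[str, str],
        families: Dict[str, MEFamily],
        k: int = DEFAULT_WORD_SIZE,
        polya_tail: int = 15,
    ):
        if not consensus:
            raise ValueError("empty ME consensus library")
        self.k = k
        self.polya_tail = polya_tail
        self.families = dict(families)
        self.seqs: Dict[Tuple[str, str], str] = {}
        self.table: Dict[str, List[Tuple[str, int, str]]] = {}
        for me_id, seq in consensus.items():
            if me_id not in families:
                raise ValueError(f"no family mapping for consensus {me_id!r}")
            # Non-LTR retrotransposon insertions carry a 3' poly-A tail;
            # indexing the tailed consensus lets junction reads whose ME
            # segment is mostly tail still anchor a split alignment.
            seq = seq.upper() + "A" * polya_tail
            for strand, s in (("+", seq), ("-", revcomp(seq))):
                self.seqs[(me_id, strand)] = s
                for off in range(len(s) - k + 1):
                    word = s[off : off + k]
                    if "N" in word:
                        continue
                    self.table.setdefault(word, []).append((me_id, off, strand))

    def nominate(self, read: str) -> List[Tuple[str, str, int, int, int]]:
        """Candidate (me_id, strand, diag_min, diag_max, n_words) regions."""
        k = self.k
        hits: Dict[Tuple[str, str], List[int]] = {}
        for p in range(len(read) - k + 1):
            for me_id, off, strand in self.table.get(read[p : p + k], ()):
                hits.setdefault((me_id, strand), []).append(off - p)
        regions = []
        for (me_id, strand), diags in hits.items():
            diags.sort()
            start = 0
            for i in range(1, len(diags) + 1):
                if i == len(diags) or diags[i] - diags[i - 1] > DIAG_BAND:
                    group = diags[start:i]
                    if len(group) >= 2:
                        regions.append((me_id, strand, group[0], group[-1], len(group)))
                    start = i
        regions.sort(key=lambda r: (-r[4], r[0], r[1], r[2]))
        return regions[:MAX_CANDIDATE_REGIONS]


def _best_trimmed(
    query: str, target: str, scheme: ScoringScheme, strand: str
) -> Optional[LocalAlignment]:
    raw = local_align(query, target, scheme, strand=strand)
    if raw is None:
        return None
    return kadane_trim(raw, scheme)


def split_map(
    read_seq: str,
    genome_window: str,
    window_origin: int,
    index: MEIndex,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    min_part: int = DEFAULT_MIN_PART,
    overlap_slack: int = DEFAULT_OVERLAP_SLACK,
    chrom: str = "",
    read_name: str = "",
    sample_id: str = "sample0",
    try_reverse: bool = True,
) -> Optional[SplitAlignment]:
    """Split-map one read between a genome window and the ME library.

    Parameters
    ----------
    read_seq : str
        Full read sequence.  Both orientations are tried against the
        genome window unless ``try_reverse`` is False (mapped soft-clipped
        reads are already reference-forward).
    genome_window : str
        Local reference sequence (anchor +/- max expected fragment length).
    window_origin : int
        0-based reference coordinate of ``genome_window[0]``.

    Returns None when the read has no consistent two-part decomposition
    with both parts >= ``min_part`` bases and read-interval overlap <=
    ``overlap_slack``, or when a single genomic alignment explains nearly
    the whole read.
    """
    if index is None or not index.table:
        raise ValueError("empty ME index")
    read_seq = read_seq.upper()
    n = len(read_seq)

    orientations = [("+", read_seq)]
    if try_reverse:
        orientations.append(("-", revcomp(read_seq)))
    genome_part = None
    oriented = read_seq
    orient = "+"
    for o, seq in orientations:
        aln = _best_trimmed(seq, genome_window, scheme, strand=o)
        if aln is not None and (genome_part is None or aln.score > genome_part.score):
            genome_part = aln
            oriented = seq
            orient = o
    if genome_part is None or genome_part.query_span < min_part:
        return None
    if genome_part.query_span > n - min_part:
        return None  # effectively fully genomic

    best: Optional[Tuple[int, LocalAlignment, str, str]] = None
    for me_id, strand, dmin, dmax, _ in index.nominate(oriented):
        seq = index.seqs[(me_id, strand)]
        t0 = max(0, dmin - 2 * DIAG_BAND)
        t1 = min(len(seq), dmax + n + 2 * DIAG_BAND)
        me_aln = _best_trimmed(oriented, seq[t0:t1], scheme, strand=strand)
        if me_aln is None or me_aln.query_span < min_part:
            continue
        if not _parts_consistent(genome_part, me_aln, overlap_slack):
            continue
        # shift target coords back into full-consensus space
        me_aln.target_begin += t0
        me_aln.target_end += t0
        me_aln.target = seq
        if best is None or me_aln.score > best[0]:
            best = (me_aln.score, me_aln, me_id, strand)
    if best is None:
        return None
    _, me_part, me_id, hit_strand = best

    if me_part.query_begin >= genome_part.query_end - overlap_slack:
        # Genome part first: breakpoint is its last aligned base.  When
        # the parts overlap on the read (junction microhomology) the
        # junction is ambiguous within the overlap, so split it evenly.
        # When they leave a gap (an error near the junction made the
        # trimming rule stop one side early), first walk the ME part
        # backward through its own gap bases against the consensus —
        # if they are consensus sequence this closes the gap from the ME
        # side — then extend the genome part forward, capped there.
        o = genome_part.query_end - me_part.query_begin
        if o > 0:
            j = _resolve_overlap_junction(
                oriented, genome_window, me_part, genome_part, genome_first=True
            )
            breakpoint = window_origin + genome_part.target_end - (
                genome_part.query_end - j
            )
        else:
            me_begin, _ = _tolerant_walk(
                oriented, me_part.target, me_part.query_begin,
                me_part.target_begin, genome_part.query_end, step=-1,
                strict=True,
            )
            if hit_strand == "-":
                # minus-strand element: poly-T tail precedes the
                # consensus on the read; it belongs to the insertion
                while me_begin > genome_part.query_end and oriented[me_begin - 1] == "T":
                    me_begin -= 1
            _, end = _tolerant_walk(
                oriented, genome_window, genome_part.query_end,
                genome_part.target_end, me_begin, step=1,
            )
            full = _claim_full_gap(
                oriented, genome_window, me_part, genome_part,
                genome_part.query_end, me_begin, genome_first=True,
            )
            if full is not None:
                end = max(end, full)
            breakpoint = window_origin + end
    else:
        # ME part first: breakpoint is the base before the genome part
        o = me_part.query_end - genome_part.query_begin
        if o > 0:
            j = _resolve_overlap_junction(
                oriented, genome_window, me_part, genome_part, genome_first=False
            )
            breakpoint = window_origin + genome_part.target_begin + (
                j - genome_part.query_begin
            )
        else:
            me_end, _ = _tolerant_walk(
                oriented, me_part.target, me_part.query_end,
                me_part.target_end, genome_part.query_begin, step=1,
                strict=True,
            )
            if hit_strand == "+":
                # plus-strand element: poly-A tail follows the consensus
                while me_end < genome_part.query_begin and oriented[me_end] == "A":
                    me_end += 1
            _, begin = _tolerant_walk(
                oriented, genome_window, genome_part.query_begin,
                genome_part.target_begin, me_end, step=-1,
            )
            full = _claim_full_gap(
                oriented, genome_window, me_part, genome_part,
                me_end, genome_part.query_begin, genome_first=False,
            )
            if full is not None:
                begin = min(begin, full)
            breakpoint = window_origin + begin
    me_strand = "+" if hit_strand == orient else "-"
    return SplitAlignment(
        genome_part=genome_part,
        me_part=me_part,
        family=index.families[me_id],
        me_id=me_id,
        me_strand=me_strand,
        breakpoint=breakpoint,
        chrom=chrom,
        read_name=read_name,
        sample_id=sample_id,
    )


def _resolve_overlap_junction(
    read: str,
    window: str,
    me_part: LocalAlignment,
    genome_part: LocalAlignment,
    genome_first: bool,
) -> int:
    """Place the junction inside the read interval both parts claim.

    When the genome and ME partial alignments overlap on the read, either
    the junction has real microhomology (the bases match both targets) or
    one part's tail extended past the junction on chance matches.  For
    every candidate split position the overlap bases are scored against
    the two targets (assuming gapless tails); the split minimizing the
    total mismatch count is the junction, with ties resolved at the
    middle of the tied range (splitting true homology evenly).
    """
    if genome_first:
        a, b = me_part.query_begin, genome_part.query_end

        def gcost(i: int) -> int:  # read[i] vs genome tail ending at target_end
            t = genome_part.target_end - (b - i)
            return 1 if t < 0 or t >= len(window) or read[i] != window[t] else 0

        def mcost(i: int) -> int:  # read[i] vs ME prefix from target_begin
            t = me_part.target_begin + (i - a)
            tgt = me_part.target
            return 1 if t < 0 or t >= len(tgt) or read[i] != tgt[t] else 0

    else:
        a, b = genome_part.query_begin, me_part.query_end

        def gcost(i: int) -> int:  # read[i] vs genome head from target_begin
            t = genome_part.target_begin + (i - a)
            return 1 if t < 0 or t >= len(window) or read[i] != window[t] else 0

        def mcost(i: int) -> int:  # read[i] vs ME tail ending at target_end
            t = me_part.target_end - (b - i)
            tgt = me_part.target
            return 1 if t < 0 or t >= len(tgt) or read[i] != tgt[t] else 0

    if genome_first:
        # junction j: read[a:j] is ME-side mismatch-scored?  No: genome
        # part comes first, so read[j:b] belongs to the ME side and
        # read[a:j] to the genome side.
        costs = []
        for j in range(a, b + 1):
            c = sum(gcost(i) for i in range(a, j)) + sum(mcost(i) for i in range(j, b))
            costs.append(c)
    else:
        # ME part first: read[a:j] is ME-side, read[j:b] genome-side
        costs = []
        for j in range(a, b + 1):
            c = sum(mcost(i) for i in range(a, j)) + sum(gcost(i) for i in range(j, b))
            costs.append(c)
    best = min(costs)
    ties = [a + k for k, c in enumerate(costs) if c == best]
    return ties[len(ties) // 2]


def _claim_full_gap(
    read: str,
    window: str,
    me_part: LocalAlignment,
    genome_part: LocalAlignment,
    gap_lo: int,
    gap_hi: int,
    genome_first: bool,
) -> Optional[int]:
    """Claim an entire inter-part gap for the genome side, or not at all.

    The gap bases are scored against gapless extrapolations of both
    parts; the genome claims the gap only when it explains them strictly
    better than the consensus does (<= 3 mismatches, >= half matching).
    This recovers genome bases lost to an error just inside the junction
    while never claiming consensus, poly-A or TSD bases, whose reference
    match is coincidental.  Returns the refined genome-part boundary
    (target coordinate) or None.
    """
    total = gap_hi - gap_lo
    if total <= 0:
        return None
    m_ref = 0
    m_cons = 0
    tgt = me_part.target
    for i in range(gap_lo, gap_hi):
        if genome_first:
            tr = genome_part.target_end + (i - gap_lo)
            tc = me_part.target_begin - (gap_hi - i)
        else:
            tr = genome_part.target_begin - (gap_hi - i)
            tc = me_part.target_end + (i - gap_lo)
        if tr < 0 or tr >= len(window) or read[i] != window[tr]:
            m_ref += 1
        if tc < 0 or tc >= len(tgt) or read[i] != tgt[tc]:
            m_cons += 1
    if m_ref <= 3 and 2 * m_ref <= total and m_ref < m_cons:
        if genome_first:
            return genome_part.target_end + total
        return genome_part.target_begin - total
    return None


def _parts_consistent(a: LocalAlignment, b: LocalAlignment, slack: int) -> bool:
    """Near-complementary read intervals: overlap no more than ``slack``."""
    overlap = min(a.query_end, b.query_end) - max(a.query_begin, b.query_begin)
    return overlap <= slack


def _tolerant_walk(
    read: str, target: str, q: int, t: int, q_stop: int, step: int,
    strict: bool = False,
) -> Tuple[int, int]:
    """Extend an alignment boundary through uncovered read bases.

    Walks ``read`` against ``target`` from read/target offsets ``q``/``t``
    toward ``q_stop`` (``step`` +1 = forward, -1 = backward).  In
    ``strict`` mode only the contiguous all-match prefix is claimed
    (used for the capping walk along the ME consensus, where walking
    past a mismatch must never legitimize the bases behind it).  The
    genome-extension mode tolerates up to three mismatches, never ends
    on one, and commits only while the cumulative identity of the
    walked stretch stays >= 2/3 with at least two matched bases, so
    inserted bases the trimming left uncovered (poly-A tails,
    target-site duplications) are rarely claimed.  Returns the refined
    (read, target) boundary.
    """
    mism = 0
    budget = 0 if strict else 3
    best_q, best_t = q, t
    matches = 0
    total = 0
    last_matched = False
    while (q < q_stop if step > 0 else q > q_stop):
        ti = t if step > 0 else t - 1
        qi = q if step > 0 else q - 1
        if ti < 0 or ti >= len(target):
            break
        total += 1
        if read[qi] == target[ti]:
            matches += 1
            commit = True if strict else (matches >= 2 and 3 * matches >= 2 * total)
            if commit:
                best_q, best_t = q + step, t + step
        else:
            mism += 1
            if mism > budget:
                break
        q += step
        t += step
    return best_q, best_t
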