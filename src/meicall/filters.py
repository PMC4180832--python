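"""Candidate assembly and filtering.

RP events and SR split alignments from one region are merged into
per-locus MEI candidates (never across families), then filtered in two
stages:

* support filtering — a candidate needs at least two RP supporting
  fragments on *both* the 5' and 3' sides, or at least two SR supporting
  fragments;
* reference-ME proximity filtering — a candidate supported by RP signal
  alone is removed when an annotated reference mobile element of a
  disqualifying family lies within the maximum expected fragment length
  of its breakpoint.  RP evidence cannot distinguish a polymorphic
  insertion from the reference copy it sits next to; SR-supported events
  resolve the breakpoint exactly and are exempt.

The disqualifying sets are family-specific: Alu and HERV-K candidates
are only removed near reference Alu/HERV-K copies respectively, while L1
and SVA candidates are removed near their own family *or* Alu copies.
"""

from __future__ import annotations

import bisect
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .model import MEFamily
from .rp import RPEvent
from .sr import SplitAlignment

DEFAULT_MIN_RP = 2
DEFAULT_MIN_SR = 2
DEFAULT_SR_CLUSTER_WINDOW = 15

EVIDENCE_RP_ONLY = "RP_ONLY"
EVIDENCE_SR_ONLY = "SR_ONLY"
EVIDENCE_RP_AND_SR = "RP_AND_SR"

# family -> reference families whose proximity disqualifies an RP-only call
DISQUALIFYING_FAMILIES: Dict[MEFamily, frozenset] = {
    MEFamily.ALU: frozenset({MEFamily.ALU}),
    MEFamily.HERVK: frozenset({MEFamily.HERVK}),
    MEFamily.L1: frozenset({MEFamily.L1, MEFamily.ALU}),
    MEFamily.SVA: frozenset({MEFamily.SVA, MEFamily.ALU}),
}


@dataclass
class MEICandidate:
    """One candidate MEI locus with its merged evidence.

    ``breakpoint`` is 1-based (last reference base before the insertion);
    SR-resolved candidates have ``ci_low == ci_high == breakpoint``.
    ``fragments`` maps sample id to the distinct supporting fragment
    names (RP and SR pooled), which the genotyper consumes as the
    MEI-allele evidence.
    """

    family: MEFamily
    chrom: str
    breakpoint: int
    ci_low: int
    ci_high: int
    rp_support_5p: int = 0
    rp_support_3p: int = 0
    sr_support: int = 0
    me_strand: Optional[str] = None
    libraries: Set[str] = field(default_factory=set)
    fragments: Dict[str, Set[str]] = field(default_factory=dict)
    rp_event: Optional[RPEvent] = None
    sr_splits: List[SplitAlignment] = field(default_factory=list)

    @property
    def evidence_class(self) -> str:
        has_rp = self.rp_support_5p > 0 or self.rp_support_3p > 0
        has_sr = self.sr_support > 0
        if has_rp and has_sr:
            return EVIDENCE_RP_AND_SR
        return EVIDENCE_RP_ONLY if has_rp else EVIDENCE_SR_ONLY

    @property
    def samples(self) -> Dict[str, int]:
        """Per-sample count of distinct supporting fragments."""
        return {s: len(frags) for s, frags in sorted(self.fragments.items())}

    def _add_fragment(self, sample: str, name: str) -> None:
        self.fragments.setdefault(sample, set()).add(name)


@dataclass
class SRLocus:
    """SR splits of one family clustered to a locus."""

    family: MEFamily
    chrom: str
    breakpoint: int
    splits: List[SplitAlignment]

    @property
    def support(self) -> int:
        return len({s.read_name for s in self.splits})


def cluster_sr_splits(
    splits: Iterable[SplitAlignment],
    window: int = DEFAULT_SR_CLUSTER_WINDOW,
) -> List[SRLocus]:
    """Group split alignments into loci per chromosome and family.

    Breakpoints within ``window`` of the previous one join a locus; the
    locus breakpoint is the modal split breakpoint, ties broken toward
    the smallest coordinate (leftmost convention).
    """
    by_group: Dict[Tuple[str, MEFamily], List[SplitAlignment]] = {}
    for s in splits:
        by_group.setdefault((s.chrom, s.family), []).append(s)
    loci: List[SRLocus] = []
    for (chrom, family), group in sorted(
        by_group.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
    ):
        group.sort(key=lambda s: s.breakpoint)
        block: List[SplitAlignment] = []
        for s in group:
            if block and s.breakpoint - block[-1].breakpoint > window:
                loci.append(_make_sr_locus(chrom, family, block))
                block = []
            block.append(s)
        if block:
            loci.append(_make_sr_locus(chrom, family, block))
    return loci


def _make_sr_locus(chrom: str, family: MEFamily, block: List[SplitAlignment]) -> SRLocus:
    counts: Dict[int, int] = {}
    for s in block:
        counts[s.breakpoint] = counts.get(s.breakpoint, 0) + 1
    bp = min(sorted(counts), key=lambda b: (-counts[b], b))
    return SRLocus(family=family, chrom=chrom, breakpoint=bp, splits=block)


def merge_evidence(
    rp_events: Sequence[RPEvent],
    sr_splits: Sequence[SplitAlignment],
    merge_window: int,
    sr_cluster_window: int = DEFAULT_SR_CLUSTER_WINDOW,
) -> List[MEICandidate]:
    """Merge RP events and SR splits into per-locus candidates.

    An SR locus within ``merge_window`` of an RP event of the same family
    absorbs it: the merged candidate takes the SR breakpoint (the higher
    resolution signal) and pools the supporting fragments.  Matching is
    one-to-one, nearest first.  Unmatched items become RP-only or
    SR-only candidates; families never merge with each other.
    """
    sr_loci = cluster_sr_splits(sr_splits, window=sr_cluster_window)
    pairs = []
    for i, ev in enumerate(rp_events):
        for j, locus in enumerate(sr_loci):
            if ev.chrom != locus.chrom or ev.family != locus.family:
                continue
            dist = abs(locus.breakpoint - ev.breakpoint)
            if dist <= merge_window:
                pairs.append((dist, ev.breakpoint, i, j))
    pairs.sort()
    used_rp: Set[int] = set()
    used_sr: Set[int] = set()
    out: List[MEICandidate] = []
    for _, _, i, j in pairs:
        if i in used_rp or j in used_sr:
            continue
        used_rp.add(i)
        used_sr.add(j)
        out.append(_merged_candidate(rp_events[i], sr_loci[j]))
    for i, ev in enumerate(rp_events):
        if i not in used_rp:
            out.append(_rp_candidate(ev))
    for j, locus in enumerate(sr_loci):
        if j not in used_sr:
            out.append(_sr_candidate(locus))
    out.sort(key=lambda c: (c.chrom, c.breakpoint, c.family.value))
    return _dedup_candidates(out, merge_window)


def _dedup_candidates(cands: List[MEICandidate], window: int) -> List[MEICandidate]:
    """Absorb dangling RP-only duplicates of an already-called locus.

    RP cluster fragmentation can leave a second RP-only event near a
    candidate of the same family that already explains the locus; the
    one-to-one RP/SR merge cannot absorb it.  An RP-only candidate
    within ``window`` of a neighbor of the same family is folded into
    that neighbor (supports summed, fragments pooled).  Two SR-resolved
    candidates are always kept apart — distinct junctions are distinct
    insertions.  The pass is idempotent.
    """
    kept: List[MEICandidate] = []
    for cand in cands:
        target = None
        for prev in reversed(kept):
            if prev.chrom != cand.chrom or cand.breakpoint - prev.breakpoint > window:
                break
            if prev.family != cand.family:
                continue
            if prev.sr_support > 0 and cand.sr_support > 0:
                continue  # two SR junctions: keep both
            target = prev
            break
        if target is None:
            kept.append(cand)
            continue
        into, other = (target, cand) if target.sr_support >= cand.sr_support else (cand, target)
        into.rp_support_5p += other.rp_support_5p
        into.rp_support_3p += other.rp_support_3p
        into.sr_support += other.sr_support
        into.libraries |= other.libraries
        into.sr_splits.extend(other.sr_splits)
        for s, frags in other.fragments.items():
            into.fragments.setdefault(s, set()).update(frags)
        if into is not target:
            kept[kept.index(target)] = into
    return kept


def _rp_candidate(ev: RPEvent) -> MEICandidate:
    cand = MEICandidate(
        family=ev.family,
        chrom=ev.chrom,
        breakpoint=ev.breakpoint,
        ci_low=ev.ci_low,
        ci_high=ev.ci_high,
        rp_support_5p=ev.five_prime_support,
        rp_support_3p=ev.three_prime_support,
        rp_event=ev,
    )
    for m in ev.member_pairs:
        cand.libraries.add(m.library_id)
        cand._add_fragment(m.sample_id, m.name)
    return cand


def _sr_candidate(locus: SRLocus) -> MEICandidate:
    cand = MEICandidate(
        family=locus.family,
        chrom=locus.chrom,
        breakpoint=locus.breakpoint,
        ci_low=locus.breakpoint,
        ci_high=locus.breakpoint,
        sr_support=locus.support,
        sr_splits=list(locus.splits),
    )
    strands = {s.me_strand for s in locus.splits}
    cand.me_strand = strands.pop() if len(strands) == 1 else None
    for s in locus.splits:
        cand._add_fragment(s.sample_id, s.read_name)
    return cand


def _merged_candidate(ev: RPEvent, locus: SRLocus) -> MEICandidate:
    cand = _sr_candidate(locus)
    cand.rp_support_5p = ev.five_prime_support
    cand.rp_support_3p = ev.three_prime_support
    cand.rp_event = ev
    for m in ev.member_pairs:
        cand.libraries.add(m.library_id)
        cand._add_fragment(m.sample_id, m.name)
    return cand


def apply_support_filter(
    candidates: Iterable[MEICandidate],
    min_rp: int = DEFAULT_MIN_RP,
    min_sr: int = DEFAULT_MIN_SR,
) -> List[MEICandidate]:
    """Keep candidates with (>=min_rp RP fragments on both sides) or
    >=min_sr SR fragments."""
    return [
        c
        for c in candidates
        if (c.rp_support_5p >= min_rp and c.rp_support_3p >= min_rp)
        or c.sr_support >= min_sr
    ]


DEFAULT_NAME_PATTERNS: List[Tuple[str, MEFamily]] = [
    (r"^Alu", MEFamily.ALU),
    (r"^(L1|LINE1|LINE-1)", MEFamily.L1),
    (r"^SVA", MEFamily.SVA),
    (r"^(HERV|LTR5)", MEFamily.HERVK),
]


class ReferenceMEAnnotation:
    """RepeatMasker-style reference ME intervals, queryable by proximity.

    Intervals are 0-based half-open internally (BED convention).
    """

    def __init__(self, intervals: Iterable[Tuple[str, int, int, MEFamily]]):
        by_key: Dict[Tuple[str, MEFamily], List[Tuple[int, int]]] = {}
        for chrom, start, end, family in intervals:
            if end <= start:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            by_key.setdefault((chrom, family), []).append((start, end))
        self._starts: Dict[Tuple[str, MEFamily], List[int]] = {}
        self._ends: Dict[Tuple[str, MEFamily], List[int]] = {}
        for key, ivals in by_key.items():
            ivals.sort()
            self._starts[key] = [s for s, _ in ivals]
            self._ends[key] = [e for _, e in ivals]

    @classmethod
    def from_bed(
        cls,
        path: str,
        name_patterns: Optional[List[Tuple[str, MEFamily]]] = None,
    ) -> "ReferenceMEAnnotation":
        """Load 4+-column BED; the name column is mapped to a family via
        regex patterns (unmatched names are ignored)."""
        patterns = [
            (re.compile(p), fam) for p, fam in (name_patterns or DEFAULT_NAME_PATTERNS)
        ]
        intervals = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 4:
                    raise ValueError(f"BED line with <4 columns: {line!r}")
                fam = _match_family(parts[3], patterns)
                if fam is not None:
                    intervals.append((parts[0], int(parts[1]), int(parts[2]), fam))
        return cls(intervals)

    @classmethod
    def from_rmsk(
        cls,
        path: str,
        name_patterns: Optional[List[Tuple[str, MEFamily]]] = None,
    ) -> "ReferenceMEAnnotation":
        """Load a UCSC rmsk table dump (with or without the leading bin
        column); uses genoName/genoStart/genoEnd/repName."""
        patterns = [
            (re.compile(p), fam) for p, fam in (name_patterns or DEFAULT_NAME_PATTERNS)
        ]
        intervals = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                # with bin: genoName at 5; without: swScore first, genoName at 4
                off = 5 if len(parts) >= 17 else 4
                chrom, start, end = parts[off], int(parts[off + 1]), int(parts[off + 2])
                rep_name = parts[off + 5]
                fam = _match_family(rep_name, patterns)
                if fam is not None:
                    intervals.append((chrom, start, end, fam))
        return cls(intervals)

    def distance_to_nearest(
        self, chrom: str, pos1: int, families: Iterable[MEFamily]
    ) -> Optional[int]:
        """Distance (bp) from a 1-based position to the nearest interval
        of any given family; 0 when inside; None when no interval."""
        pos = pos1 - 1  # 0-based
        best: Optional[int] = None
        for fam in families:
            key = (chrom, fam)
            starts = self._starts.get(key)
            if not starts:
                continue
            ends = self._ends.get(key)
            i = bisect.bisect_right(starts, pos)
            cands = []
            if i > 0:
                cands.append(max(0, pos - ends[i - 1] + 1) if pos >= ends[i - 1] else 0)
            if i < len(starts):
                cands.append(max(0, starts[i] - pos))
            if cands:
                d = min(cands)
                best = d if best is None else min(best, d)
        return best


def _match_family(name: str, patterns) -> Optional[MEFamily]:
    for pat, fam in patterns:
        if pat.search(name):
            return fam
    return None


def apply_reference_me_filter(
    candidates: Iterable[MEICandidate],
    annotation: ReferenceMEAnnotation,
    fld_by_lib: Mapping,
    p: float = 0.005,
) -> List[MEICandidate]:
    """Drop RP-only candidates near a disqualifying reference ME.

    The proximity distance is the maximum expected fragment length
    (upper-tail p) of the candidate's contributing libraries, taking the
    largest when libraries disagree.  Candidates with any SR support are
    never touched.
    """
    out = []
    for c in candidates:
        if c.sr_support > 0:
            out.append(c)
            continue
        libs = c.libraries or set(fld_by_lib)
        dist_limit = max(
            fld_by_lib[l].max_expected_fragment_length(p) for l in libs
        )
        d = annotation.distance_to_nearest(
            c.chrom, c.breakpoint, DISQUALIFYING_FAMILIES[c.family]
        )
        if d is not None and d <= dist_limit:
            continue
        out.append(c)
    return out
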