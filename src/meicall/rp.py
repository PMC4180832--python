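"""Read-pair MEI event nucleation.

RP-candidate pairs (one mate anchored in the genome, the other on an ME
consensus) localize an insertion to a window.  Per ME family, anchors on
the plus strand approach the insertion from the left (5' side) and minus
strand anchors from the right (3' side); each side is clustered
separately by *fragment center* — the anchor position pushed half a
median insert toward the mate — with a single linear nearest-neighbor
pass.  A 5'/3' cluster pair within the neighborhood range becomes one
event whose breakpoint interval runs from the end of the 5' anchor
extent to the start of the 3' anchor extent; the reported breakpoint
follows the leftmost convention (smaller boundary).

All breakpoint/CI coordinates here are 1-based reference positions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

from .fragments import FragmentLengthDistribution
from .model import MEFamily, ReadPair


class ClusterSide(enum.Enum):
    FIVE_PRIME = "5p"
    THREE_PRIME = "3p"


def fragment_center(pair: ReadPair, fld: FragmentLengthDistribution) -> int:
    """Estimated fragment midpoint from the anchored mate alone.

    Plus-strand anchors: leftmost aligned base (1-based) plus half the
    library median; minus-strand anchors: rightmost aligned base minus
    half the median.
    """
    anchor = pair.anchor
    if anchor is None:
        raise ValueError("pair has no mapped anchor")
    half = round(fld.median / 2)
    if anchor.strand == "+":
        return anchor.pos + 1 + half
    return anchor.end - half


@dataclass
class RPCluster:
    family: MEFamily
    side: ClusterSide
    chrom: str
    members: List[ReadPair] = field(default_factory=list)
    centers: List[int] = field(default_factory=list)

    @property
    def center_min(self) -> int:
        return self.centers[0]

    @property
    def center_max(self) -> int:
        return self.centers[-1]

    @property
    def extent_start(self) -> int:
        """1-based leftmost anchored base across members."""
        return min(m.anchor.pos + 1 for m in self.members)

    @property
    def extent_end(self) -> int:
        """1-based rightmost anchored base across members."""
        return max(m.anchor.end for m in self.members)

    @property
    def support(self) -> int:
        return len({m.name for m in self.members})

    @property
    def libraries(self) -> List[str]:
        return sorted({m.library_id for m in self.members})


@dataclass
class RPEvent:
    family: MEFamily
    chrom: str
    breakpoint: int
    ci_low: int
    ci_high: int
    five_prime: RPCluster
    three_prime: RPCluster

    @property
    def five_prime_support(self) -> int:
        return self.five_prime.support

    @property
    def three_prime_support(self) -> int:
        return self.three_prime.support

    @property
    def member_pairs(self) -> List[ReadPair]:
        return self.five_prime.members + self.three_prime.members


def cluster_by_center(
    candidates: Sequence[ReadPair],
    fld_by_lib: Mapping[str, FragmentLengthDistribution],
    family: MEFamily,
    side: ClusterSide,
    chrom: str,
    window: Optional[int] = None,
    p: float = 0.005,
) -> List[RPCluster]:
    """Single-linkage clustering of candidate pairs by fragment center.

    ``candidates`` must already be sorted by center; consecutive centers
    within ``window`` join one cluster (one linear pass).  The default
    window is the spread the insert distribution allows a fragment
    center: max expected fragment length minus the median, maximized over
    the libraries present.
    """
    if not candidates:
        return []
    if window is None:
        libs = {c.library_id for c in candidates}
        window = max(
            fld_by_lib[l].max_expected_fragment_length(p) - fld_by_lib[l].median
            for l in libs
        )
    centers = [fragment_center(c, fld_by_lib[c.library_id]) for c in candidates]
    if any(b < a for a, b in zip(centers, centers[1:])):
        raise ValueError("candidates must be sorted by fragment center")
    clusters: List[RPCluster] = []
    cur = RPCluster(family, side, chrom, [candidates[0]], [centers[0]])
    for pair, center in zip(candidates[1:], centers[1:]):
        if center - cur.centers[-1] <= window:
            cur.members.append(pair)
            cur.centers.append(center)
        else:
            clusters.append(cur)
            cur = RPCluster(family, side, chrom, [pair], [center])
    clusters.append(cur)
    return clusters


def pair_clusters_to_events(
    clusters: Sequence[RPCluster],
    fld_by_lib: Mapping[str, FragmentLengthDistribution],
    p: float = 0.005,
) -> List[RPEvent]:
    """Pair 5' with 3' clusters of one family into breakpoint events.

    A pair forms when the gap between the 5' extent end and the 3'
    extent start is at most the maximum expected fragment length
    (largest across contributing libraries).  Each cluster joins at most
    one partner, nearest by interval distance with ties broken toward
    the smaller coordinate.  A lone cluster yields no event: support
    from both sides is required.
    """
    fives = [c for c in clusters if c.side == ClusterSide.FIVE_PRIME]
    threes = [c for c in clusters if c.side == ClusterSide.THREE_PRIME]
    candidates = []
    for i, f in enumerate(fives):
        for j, t in enumerate(threes):
            if f.chrom != t.chrom or f.family != t.family:
                continue
            libs = set(f.libraries) | set(t.libraries)
            dmax = max(fld_by_lib[l].max_expected_fragment_length(p) for l in libs)
            gap = t.extent_start - f.extent_end
            if -dmax <= gap <= dmax:
                candidates.append((abs(gap), min(f.extent_end, t.extent_start), i, j))
    candidates.sort()
    used_f: set = set()
    used_t: set = set()
    events: List[RPEvent] = []
    for _, _, i, j in candidates:
        if i in used_f or j in used_t:
            continue
        used_f.add(i)
        used_t.add(j)
        f, t = fives[i], threes[j]
        lo, hi = sorted((f.extent_end, t.extent_start))
        events.append(
            RPEvent(
                family=f.family,
                chrom=f.chrom,
                breakpoint=lo,
                ci_low=lo,
                ci_high=hi,
                five_prime=f,
                three_prime=t,
            )
        )
    events.sort(key=lambda e: (e.chrom, e.breakpoint))
    return events


def detect_rp_events(
    rp_pairs: Sequence[ReadPair],
    fld_by_lib: Mapping[str, FragmentLengthDistribution],
    p: float = 0.005,
) -> List[RPEvent]:
    """Full RP stage: split by chromosome/family/side, cluster, pair."""
    groups: Dict[tuple, List[ReadPair]] = {}
    for pair in rp_pairs:
        ann = pair.me_annotation
        anchor = pair.anchor
        if ann is None or anchor is None:
            continue
        side = ClusterSide.FIVE_PRIME if anchor.strand == "+" else ClusterSide.THREE_PRIME
        groups.setdefault((anchor.chrom, ann.family, side), []).append(pair)

    clusters_by_locus: Dict[tuple, List[RPCluster]] = {}
    for (chrom, family, side), pairs in sorted(
        groups.items(), key=lambda kv: (kv[0][0], kv[0][1].value, kv[0][2].value)
    ):
        pairs.sort(key=lambda pr: fragment_center(pr, fld_by_lib[pr.library_id]))
        clusters = cluster_by_center(pairs, fld_by_lib, family, side, chrom, p=p)
        clusters_by_locus.setdefault((chrom, family), []).extend(clusters)

    events: List[RPEvent] = []
    for key in sorted(clusters_by_locus, key=lambda k: (k[0], k[1].value)):
        events.extend(pair_clusters_to_events(clusters_by_locus[key], fld_by_lib, p=p))
    events.sort(key=lambda e: (e.chrom, e.breakpoint))
    return events
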