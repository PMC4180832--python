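"""End-to-end MEI detection: classify, model, nucleate, merge, filter,
genotype.

The pipeline consumes read pairs (in memory, or from tagged SAM/BAM via
:mod:`meicall.samio`), estimates per-library insert-size models from
normal pairs, nucleates candidate events from RP and SR signal, merges
and filters them, and genotypes every candidate in every sample.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .filters import (
    MEICandidate,
    ReferenceMEAnnotation,
    apply_reference_me_filter,
    apply_support_filter,
    merge_evidence,
)
from .fragments import (
    FragmentLengthDistribution,
    estimate_fragment_distributions,
    max_fld_distance,
)
from .genotype import FLAT_PRIOR, GenotypeCall, genotype_candidate
from .model import (
    DEFAULT_CLIP_MIN,
    DEFAULT_MAPQ_MIN,
    PairClass,
    ReadPair,
    classify_read_pair,
)
from .rp import detect_rp_events
from .sr import DEFAULT_MIN_PART, DEFAULT_OVERLAP_SLACK, MEIndex, SplitAlignment, split_map
from .sw import DEFAULT_SCHEME, ScoringScheme

logger = logging.getLogger(__name__)


@dataclass
class DetectorConfig:
    mapq_min: int = DEFAULT_MAPQ_MIN
    clip_min: int = DEFAULT_CLIP_MIN
    tail_p: float = 0.005
    min_normal_pairs: int = 1000
    min_rp_support: int = 2
    min_sr_support: int = 2
    min_part: int = DEFAULT_MIN_PART
    overlap_slack: int = DEFAULT_OVERLAP_SLACK
    scheme: ScoringScheme = field(default_factory=lambda: DEFAULT_SCHEME)
    genotype_prior: Tuple[float, float, float] = FLAT_PRIOR


@dataclass
class MEICall:
    """A filtered candidate with per-sample genotype calls."""

    candidate: MEICandidate
    genotypes: Dict[str, GenotypeCall]

    @property
    def chrom(self) -> str:
        return self.candidate.chrom

    @property
    def breakpoint(self) -> int:
        return self.candidate.breakpoint

    @property
    def family(self):
        return self.candidate.family


def select_normal_pairs(
    pairs: Sequence[ReadPair], mapq_min: int, clip_min: int
) -> List[ReadPair]:
    """Conservative pre-pass for insert-size estimation: both mates
    uniquely mapped, same chromosome, convergent, essentially unclipped,
    and with no ME mate annotation."""
    out = []
    for p in pairs:
        a, b = p.mate_a, p.mate_b
        if not (a.is_mapped and b.is_mapped):
            continue
        if a.mapq < mapq_min or b.mapq < mapq_min or a.chrom != b.chrom:
            continue
        if p.me_annotation is not None or not p.is_convergent():
            continue
        if a.max_soft_clip >= clip_min or b.max_soft_clip >= clip_min:
            continue
        out.append(p)
    return out


def classify_pairs(
    pairs: Sequence[ReadPair],
    fld_by_lib: Mapping[str, FragmentLengthDistribution],
    cfg: DetectorConfig,
) -> Dict[PairClass, List[ReadPair]]:
    buckets: Dict[PairClass, List[ReadPair]] = {c: [] for c in PairClass}
    for p in pairs:
        fld = fld_by_lib.get(p.library_id)
        if fld is None:
            fld = next(iter(fld_by_lib.values()))
        buckets[classify_read_pair(p, fld, cfg.mapq_min, cfg.clip_min)].append(p)
    return buckets


def collect_sr_splits(
    sr_pairs: Sequence[ReadPair],
    genome: str,
    chrom: str,
    index: MEIndex,
    fld_by_lib: Mapping[str, FragmentLengthDistribution],
    cfg: DetectorConfig,
) -> List[SplitAlignment]:
    """Split-map the clipped/unmapped mate of every SR-candidate pair.

    The genome window is directional: a plus-strand anchor implies the
    mate lies downstream within the maximum expected fragment length,
    and vice versa.
    """
    dmax = max_fld_distance(fld_by_lib, cfg.tail_p)
    splits: List[SplitAlignment] = []
    for pair in sr_pairs:
        anchor, other = _anchor_and_sr_read(pair, cfg)
        if anchor is None or not other.seq:
            continue
        rl = len(other.seq)
        if anchor.strand == "+":
            w0 = max(0, anchor.pos - rl)
            w1 = min(len(genome), anchor.pos + dmax + rl)
        else:
            w0 = max(0, anchor.end - dmax - rl)
            w1 = min(len(genome), anchor.end + rl)
        sa = split_map(
            other.seq,
            genome[w0:w1],
            w0,
            index,
            scheme=cfg.scheme,
            min_part=cfg.min_part,
            overlap_slack=cfg.overlap_slack,
            chrom=chrom,
            read_name=pair.name,
            sample_id=pair.sample_id,
            try_reverse=not other.is_mapped,
        )
        if sa is not None:
            splits.append(sa)
    return splits


def _anchor_and_sr_read(pair: ReadPair, cfg: DetectorConfig):
    a, b = pair.mate_a, pair.mate_b
    for anchor, other in ((a, b), (b, a)):
        if not (anchor.is_mapped and anchor.mapq >= cfg.mapq_min):
            continue
        if anchor.max_soft_clip >= cfg.clip_min:
            continue
        if not other.is_mapped or other.max_soft_clip >= cfg.clip_min:
            return anchor, other
    return None, None


class _PairIndex:
    """Pairs sorted by leftmost mapped position for regional queries."""

    def __init__(self, pairs: Sequence[ReadPair]):
        keyed = []
        for p in pairs:
            pos = [m.pos for m in (p.mate_a, p.mate_b) if m.is_mapped]
            if pos:
                keyed.append((min(pos), p))
        keyed.sort(key=lambda kv: kv[0])
        self._starts = [k for k, _ in keyed]
        self._pairs = [p for _, p in keyed]

    def overlapping(self, pos0: int, margin: int) -> List[ReadPair]:
        lo = bisect.bisect_left(self._starts, pos0 - margin)
        hi = bisect.bisect_right(self._starts, pos0 + margin)
        return self._pairs[lo:hi]


def detect(
    pairs: Sequence[ReadPair],
    genome: str,
    chrom: str,
    index: MEIndex,
    cfg: Optional[DetectorConfig] = None,
    annotation: Optional[ReferenceMEAnnotation] = None,
    fld_by_lib: Optional[Mapping[str, FragmentLengthDistribution]] = None,
) -> Tuple[List[MEICall], Dict[str, FragmentLengthDistribution]]:
    """Run the full detector over one chromosome's read pairs.

    Returns the filtered, genotyped calls plus the per-library insert
    models.  ``annotation``, when given, drives the reference-ME
    proximity filter for RP-only candidates.
    """
    cfg = cfg or DetectorConfig()
    if fld_by_lib is None:
        normal = select_normal_pairs(pairs, cfg.mapq_min, cfg.clip_min)
        fld_by_lib = estimate_fragment_distributions(normal, cfg.min_normal_pairs)
    logger.info(
        "insert models: %s",
        {k: (v.median, round(v.sd, 1)) for k, v in fld_by_lib.items()},
    )

    buckets = classify_pairs(pairs, fld_by_lib, cfg)
    logger.info("pair classes: %s", {c.value: len(v) for c, v in buckets.items()})

    rp_events = detect_rp_events(buckets[PairClass.RP_CANDIDATE], fld_by_lib, cfg.tail_p)
    sr_splits = collect_sr_splits(
        buckets[PairClass.SR_CANDIDATE], genome, chrom, index, fld_by_lib, cfg
    )
    merge_window = max_fld_distance(fld_by_lib, cfg.tail_p)
    candidates = merge_evidence(rp_events, sr_splits, merge_window)
    candidates = apply_support_filter(candidates, cfg.min_rp_support, cfg.min_sr_support)
    if annotation is not None:
        candidates = apply_reference_me_filter(candidates, annotation, fld_by_lib, cfg.tail_p)

    pair_index = _PairIndex(pairs)
    margin = merge_window + 2 * max(
        (len(p.mate_a.seq) for p in pairs[:100]), default=150
    )
    samples = sorted({p.sample_id for p in pairs})
    calls = []
    for cand in candidates:
        local = pair_index.overlapping(cand.breakpoint, margin)
        genotypes = {
            s: genotype_candidate(
                cand, local, fld_by_lib, s,
                prior=cfg.genotype_prior,
                mapq_min=cfg.mapq_min,
                clip_min=cfg.clip_min,
            )
            for s in samples
        }
        calls.append(MEICall(candidate=cand, genotypes=genotypes))
    logger.info("calls: %d", len(calls))
    return calls, dict(fld_by_lib)
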