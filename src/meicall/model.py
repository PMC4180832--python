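"""Core data model for ME-annotated paired-end alignments.

A mobile-element insertion (MEI) caller consumes paired-end alignments in
which some reads carry an annotation saying that their *mate* aligned to a
mobile-element consensus sequence rather than to the genome.  This module
defines the alignment record types, the per-read ME annotation, and the
classification of read pairs into the evidence classes the detector
consumes:

``NORMAL``
    both mates uniquely mapped to the same chromosome, convergent (FR)
    orientation, insert size consistent with the library distribution;
    these pairs parameterize the fragment-length model and supply
    reference-allele evidence during genotyping.
``RP_CANDIDATE``
    one mate uniquely mapped to the genome, the other aligned to an ME
    consensus (read-pair signal localizing an insertion to a window).
``SR_CANDIDATE``
    one mate uniquely mapped, the other unmapped or substantially
    soft-clipped (raw material for split-read breakpoint mapping).
``OTHER``
    everything else (discordant pairs without ME evidence, low-quality
    pairs, ...).

Internal coordinates are 0-based half-open; conversion to 1-based happens
only at SAM/VCF boundaries.  Breakpoints, by contrast, are carried as
1-based positions of the last reference base before the inserted sequence
throughout the package, because that is the reporting convention.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Optional

DEFAULT_MAPQ_MIN = 20
DEFAULT_CLIP_MIN = 20
FRAGMENT_PVALUE_CUTOFF = 0.005


class MEFamily(enum.Enum):
    """The four actively retrotransposing human ME families."""

    ALU = "ALU"
    L1 = "L1"
    SVA = "SVA"
    HERVK = "HERVK"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class PairClass(enum.Enum):
    NORMAL = "NORMAL"
    RP_CANDIDATE = "RP_CANDIDATE"
    SR_CANDIDATE = "SR_CANDIDATE"
    OTHER = "OTHER"


@dataclass(frozen=True)
class MEAnnotation:
    """Record of a read's mate aligning to an ME consensus.

    Carried on the *genome-anchored* read and describing its mate, in the
    same spirit as the mate-annotation tag a ME-aware mapper writes.

    Attributes
    ----------
    family : MEFamily
        Consensus family the mate aligned to.
    me_strand : str
        ``'+'`` or ``'-'``: consensus strand of the mate alignment.
    me_offset : int
        0-based offset of the mate alignment start in the consensus.
    mate_mapq : int
        Mapping quality of the mate's consensus alignment.
    mate_hit_count : int
        Number of consensus locations the mate aligned to (>= 1).
    """

    family: MEFamily
    me_strand: str = "+"
    me_offset: int = 0
    mate_mapq: int = 60
    mate_hit_count: int = 1

    def __post_init__(self) -> None:
        if self.me_strand not in "+-":
            raise ValueError(f"bad ME strand {self.me_strand!r}")
        if self.mate_mapq < 0 or self.mate_hit_count < 1 or self.me_offset < 0:
            raise ValueError("invalid ME annotation fields")

    def to_tag(self) -> str:
        return ",".join(
            [
                self.family.value,
                self.me_strand,
                str(self.me_offset),
                str(self.mate_mapq),
                str(self.mate_hit_count),
            ]
        )

    @classmethod
    def from_tag(cls, value: str) -> "MEAnnotation":
        parts = value.split(",")
        if len(parts) != 5:
            raise ValueError(f"malformed ME tag: {value!r}")
        fam, strand, off, mq, hits = parts
        return cls(
            family=MEFamily(fam),
            me_strand=strand,
            me_offset=int(off),
            mate_mapq=int(mq),
            mate_hit_count=int(hits),
        )


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

# CIGAR ops that consume reference bases
_REF_OPS = frozenset("MDN=X")
# CIGAR ops that consume query bases
_QUERY_OPS = frozenset("MIS=X")


def cigar_clips(cigar: str) -> tuple[int, int]:
    """Soft-clip base counts at the left and right end of a CIGAR string."""
    ops = _CIGAR_RE.findall(cigar)
    if not ops:
        return (0, 0)
    left = int(ops[0][0]) if ops[0][1] == "S" else 0
    right = int(ops[-1][0]) if len(ops) > 1 and ops[-1][1] == "S" else 0
    return (left, right)


def cigar_reference_span(cigar: str) -> int:
    return sum(int(n) for n, op in _CIGAR_RE.findall(cigar) if op in _REF_OPS)


def cigar_query_span(cigar: str) -> int:
    return sum(int(n) for n, op in _CIGAR_RE.findall(cigar) if op in _QUERY_OPS)


@dataclass
class AlignedRead:
    """One end of a paired-end fragment, as aligned to the genome.

    ``pos`` is the 0-based leftmost aligned reference base (None when
    unmapped).  ``seq`` is stored in reference-forward orientation for
    mapped reads (SAM convention); for unmapped reads it is the sequenced
    orientation.
    """

    name: str
    chrom: Optional[str]
    pos: Optional[int]
    cigar: str
    seq: str
    mapq: int
    strand: str
    me_annotation: Optional[MEAnnotation] = None
    library_id: str = "lib0"
    sample_id: str = "sample0"

    @property
    def is_mapped(self) -> bool:
        return self.chrom is not None and self.pos is not None

    @property
    def soft_clip_left(self) -> int:
        return cigar_clips(self.cigar)[0] if self.cigar else 0

    @property
    def soft_clip_right(self) -> int:
        return cigar_clips(self.cigar)[1] if self.cigar else 0

    @property
    def end(self) -> Optional[int]:
        """0-based exclusive end of the aligned reference span."""
        if not self.is_mapped:
            return None
        return self.pos + cigar_reference_span(self.cigar)

    @property
    def max_soft_clip(self) -> int:
        l, r = cigar_clips(self.cigar) if self.cigar else (0, 0)
        return max(l, r)


@dataclass
class ReadPair:
    """Two mates of one sequenced fragment.

    ``fragment_length`` (outermost-base span, TLEN convention) is defined
    only when both mates map to the same chromosome.
    """

    mate_a: AlignedRead
    mate_b: AlignedRead

    @property
    def name(self) -> str:
        return self.mate_a.name

    @property
    def fragment_length(self) -> Optional[int]:
        a, b = self.mate_a, self.mate_b
        if not (a.is_mapped and b.is_mapped) or a.chrom != b.chrom:
            return None
        return max(a.end, b.end) - min(a.pos, b.pos)

    @property
    def library_id(self) -> str:
        return self.mate_a.library_id

    @property
    def sample_id(self) -> str:
        return self.mate_a.sample_id

    def is_convergent(self) -> bool:
        """True for the expected forward-reverse (FR) orientation."""
        a, b = self.mate_a, self.mate_b
        if not (a.is_mapped and b.is_mapped) or a.chrom != b.chrom:
            return False
        if a.strand == b.strand:
            return False
        left, right = (a, b) if a.pos <= b.pos else (b, a)
        return left.strand == "+" and right.strand == "-"

    @property
    def anchor(self) -> Optional[AlignedRead]:
        """The uniquely genome-mapped mate when exactly one is mapped-ish.

        Returns the mapped mate when the other is unmapped; when both are
        mapped returns the one with the higher mapq.  Used by the RP/SR
        machinery after classification has established which situation
        applies.
        """
        a, b = self.mate_a, self.mate_b
        if a.is_mapped and not b.is_mapped:
            return a
        if b.is_mapped and not a.is_mapped:
            return b
        if a.is_mapped and b.is_mapped:
            return a if a.mapq >= b.mapq else b
        return None

    @property
    def me_annotation(self) -> Optional[MEAnnotation]:
        for m in (self.mate_a, self.mate_b):
            if m.me_annotation is not None:
                return m.me_annotation
        return None


def classify_read_pair(
    pair: ReadPair,
    fld,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    clip_min: int = DEFAULT_CLIP_MIN,
) -> PairClass:
    """Assign a read pair to one of the four evidence classes.

    "Uniquely aligned" is operationalized as ``mapq >= mapq_min``.
    Precedence: RP_CANDIDATE > SR_CANDIDATE > NORMAL > OTHER.  RP before
    SR is required because an ME-annotated mate may also be clipped; SR
    before NORMAL because a junction-straddling pair with a modestly
    clipped mate can satisfy every NORMAL condition while carrying the
    split-read evidence the detector exists to collect.

    Parameters
    ----------
    fld : FragmentLengthDistribution
        Insert-size model for the pair's library (used for the p <= 0.005
        consistency test).
    """
    a, b = pair.mate_a, pair.mate_b
    a_unique = a.is_mapped and a.mapq >= mapq_min
    b_unique = b.is_mapped and b.mapq >= mapq_min
    one_unique = a_unique != b_unique

    if one_unique and pair.me_annotation is not None:
        anchor = a if a_unique else b
        other = b if a_unique else a
        if anchor.me_annotation is not None:
            # discordance conditions: wrong orientation, different
            # chromosome (incl. mate off-genome), or inconsistent insert
            if not other.is_mapped or other.chrom != anchor.chrom:
                return PairClass.RP_CANDIDATE
            if not pair.is_convergent():
                return PairClass.RP_CANDIDATE
            flen = pair.fragment_length
            if flen is not None and fld.pvalue(flen) <= FRAGMENT_PVALUE_CUTOFF:
                return PairClass.RP_CANDIDATE

    # SR: an anchor is uniquely mapped and the other mate is unmapped or
    # substantially soft-clipped.  The clipped mate may itself map with
    # high quality; what matters is the clip.
    for anchor, other in ((a, b), (b, a)):
        if not (anchor.is_mapped and anchor.mapq >= mapq_min):
            continue
        if anchor.max_soft_clip >= clip_min:
            continue  # the anchor itself must be cleanly aligned
        if not other.is_mapped or other.max_soft_clip >= clip_min:
            return PairClass.SR_CANDIDATE

    if a_unique and b_unique and a.chrom == b.chrom and pair.is_convergent():
        flen = pair.fragment_length
        if flen is not None and flen > 0 and fld.pvalue(flen) > FRAGMENT_PVALUE_CUTOFF:
            return PairClass.NORMAL

    return PairClass.OTHER


def revcomp(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")
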