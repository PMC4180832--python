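"""Bayesian binomial genotyping of MEI candidates.

At a candidate locus every sequenced fragment either supports the
reference allele (a uniquely mapped, convergent pair with a consistent
insert size and a read crossing the insertion junction) or the MEI
allele (the distinct RP/SR fragments collected during detection).  The
data likelihood of genotype g is the binomial probability that
``n_ref + n_alt`` fragments fluctuate to ``n_alt`` MEI fragments given
the expected MEI allele fraction p_g: 0 for REF/REF, 0.5 for REF/MEI
and 1 for MEI/MEI.  Posteriors use a flat 1/3 prior by default and the
reported genotype is the posterior mode.

The strict allele fractions make the model decisive: any mixture of
reference and MEI fragments can only be heterozygous, so the
reference-fragment counting rule must not leak fragments from the
insertion-bearing haplotype (see the junction-crossing requirement in
:func:`count_allele_support`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

from .filters import MEICandidate
from .model import (
    DEFAULT_CLIP_MIN,
    DEFAULT_MAPQ_MIN,
    FRAGMENT_PVALUE_CUTOFF,
    ReadPair,
)

GENOTYPES = ("REF/REF", "REF/MEI", "MEI/MEI")
# A spanning pair is unambiguous reference support only when its insert
# stretched by the family's minimum element length is implausible at
# this (stricter) tail probability.
DISAMBIGUATION_PVALUE = 0.001
GT_STRINGS = {"REF/REF": "0/0", "REF/MEI": "0/1", "MEI/MEI": "1/1"}
_P_G = (0.0, 0.5, 1.0)
FLAT_PRIOR = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)


@dataclass(frozen=True)
class GenotypeEvidence:
    """Fragment counts supporting each allele at one locus."""

    n_ref: int
    n_alt: int

    def __post_init__(self) -> None:
        if self.n_ref < 0 or self.n_alt < 0:
            raise ValueError("negative allele support")


@dataclass
class GenotypeCall:
    genotype: str
    likelihoods: Tuple[float, float, float]
    log10_likelihoods: Tuple[float, float, float]
    posteriors: Tuple[float, float, float]
    prior: Tuple[float, float, float]
    evidence: Optional[GenotypeEvidence] = None

    @property
    def gt(self) -> str:
        return GT_STRINGS[self.genotype]


def _log_binom(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def genotype_likelihoods(ev: GenotypeEvidence) -> Tuple[float, float, float]:
    """Binomial data likelihoods L(D|g) for the three genotypes.

    L(g) = C(n_ref + n_alt, n_alt) * p_g^n_alt * (1 - p_g)^n_ref with the
    convention 0^0 = 1; computed in log space.  With no data all three
    likelihoods are 1.
    """
    n = ev.n_ref + ev.n_alt
    out = []
    for p in _P_G:
        if (p == 0.0 and ev.n_alt > 0) or (p == 1.0 and ev.n_ref > 0):
            out.append(float("-inf"))
            continue
        ll = _log_binom(n, ev.n_alt)
        if ev.n_alt > 0:
            ll += ev.n_alt * math.log(p)
        if ev.n_ref > 0:
            ll += ev.n_ref * math.log(1.0 - p)
        out.append(ll)
    return tuple(out)  # log-likelihoods


def call_genotype(
    log_likelihoods: Sequence[float],
    prior: Sequence[float] = FLAT_PRIOR,
    evidence: Optional[GenotypeEvidence] = None,
) -> GenotypeCall:
    """Posterior-mode genotype from log-likelihoods and a prior.

    Ties are broken in the order REF/REF, REF/MEI, MEI/MEI.  Raises if
    every genotype has zero posterior mass (cannot occur under the 0^0=1
    convention; guards numeric underflow).
    """
    if len(log_likelihoods) != 3 or len(prior) != 3:
        raise ValueError("expected three likelihoods and three priors")
    log_post = []
    for lp, pr in zip(log_likelihoods, prior):
        log_post.append(lp + math.log(pr) if pr > 0 and lp > float("-inf") else float("-inf"))
    m = max(log_post)
    if m == float("-inf"):
        raise ValueError("all genotype posteriors are zero")
    weights = [math.exp(lp - m) for lp in log_post]
    total = sum(weights)
    posteriors = tuple(w / total for w in weights)
    best = max(range(3), key=lambda i: (posteriors[i], -i))
    lik_m = max(log_likelihoods)
    likelihoods = tuple(
        math.exp(ll - lik_m) if ll > float("-inf") else 0.0 for ll in log_likelihoods
    )
    log10 = tuple(
        ll / math.log(10) if ll > float("-inf") else -9999.0 for ll in log_likelihoods
    )
    return GenotypeCall(
        genotype=GENOTYPES[best],
        likelihoods=likelihoods,
        log10_likelihoods=log10,
        posteriors=posteriors,
        prior=tuple(prior),
        evidence=evidence,
    )


def count_allele_support(
    candidate: MEICandidate,
    pairs: Iterable[ReadPair],
    fld_by_lib,
    sample_id: str = "sample0",
    mapq_min: int = DEFAULT_MAPQ_MIN,
    clip_min: int = DEFAULT_CLIP_MIN,
    min_insert_len: Optional[int] = None,
) -> GenotypeEvidence:
    """Count reference- and MEI-supporting fragments at a candidate.

    MEI support is the set of distinct fragments that contributed RP or
    SR evidence to the candidate during detection.  A pair counts as
    reference support when it is uniquely mapped and convergent with a
    consistent insert size (two-sided empirical p > 0.005) and either

    * one mate's aligned bases cross the insertion junction, or
    * the outer fragment span contains the junction and the insert is
      too long to be a fragment spanning an inserted element of this
      family: ``insert + min_insert_len`` falls beyond the plausible
      insert range.

    Plain outer-span counting is not safe on its own: a fragment
    straddling the whole insertion on the MEI haplotype maps back with
    an insert shortened by the element length, which for moderate
    elements still passes the consistency test and would force
    heterozygous calls at homozygous loci.  The junction-crossing and
    insert-length disambiguation routes are both immune to that
    failure.  Each fragment counts at most once, on one side.

    ``min_insert_len`` is the shortest plausible inserted length (element
    + tails) for the candidate's family; None disables the second route.
    """
    alt_names = candidate.fragments.get(sample_id, set())
    lo, hi = _junction_interval(candidate)
    n_ref = 0
    seen = set()
    for pair in pairs:
        if pair.sample_id != sample_id or pair.name in seen:
            continue
        if pair.name in alt_names:
            continue
        a, b = pair.mate_a, pair.mate_b
        if not (a.is_mapped and b.is_mapped):
            continue
        if a.chrom != candidate.chrom or a.mapq < mapq_min or b.mapq < mapq_min:
            continue
        if not pair.is_convergent():
            continue
        flen = pair.fragment_length
        if flen is None or flen <= 0:
            continue
        fld = fld_by_lib[pair.library_id]
        if fld.pvalue(flen) <= FRAGMENT_PVALUE_CUTOFF:
            continue
        supports = _crosses_junction(a, lo, hi, clip_min) or _crosses_junction(
            b, lo, hi, clip_min
        )
        if not supports and min_insert_len is not None:
            outer_start1 = min(a.pos, b.pos) + 1
            outer_end1 = max(a.end, b.end)
            if outer_start1 <= lo - 1 and outer_end1 >= hi + 2:
                stretched = flen + min_insert_len
                if (
                    stretched > fld.median
                    and fld.pvalue(stretched) <= DISAMBIGUATION_PVALUE
                ):
                    supports = True
        if supports:
            n_ref += 1
            seen.add(pair.name)
    return GenotypeEvidence(n_ref=n_ref, n_alt=len(alt_names))


def _junction_interval(candidate: MEICandidate) -> Tuple[int, int]:
    """Breakpoint interval a reference read must span entirely.

    Individual split reads place the junction within a few bases of each
    other (TSD and microhomology ambiguity); a read only counts as
    crossing when it spans the whole observed interval, so junction
    reads can never leak into the reference count whichever boundary
    was reported.  Falls back to the point breakpoint when the spread
    is implausibly wide or no splits exist.
    """
    if candidate.sr_splits:
        votes = [s.breakpoint for s in candidate.sr_splits]
        lo, hi = min(votes), max(votes)
        if hi - lo <= 10:
            return lo, hi
    return candidate.breakpoint, candidate.breakpoint


def _crosses_junction(read, lo: int, hi: int, clip_min: int, margin: int = 1) -> bool:
    """Aligned (non-clipped) span covers [lo - margin, hi + 1 + margin]."""
    if not read.is_mapped or read.max_soft_clip >= clip_min:
        return False
    start1 = read.pos + 1
    end1 = read.end  # inclusive 1-based
    return start1 <= lo - margin and end1 >= hi + 1 + margin


# Shortest plausible inserted length (element + poly-A + TSD) per family:
# Alu and HERV-K insert essentially full-length, L1 is frequently severely
# 5'-truncated, SVA varies.  Used to disambiguate reference-supporting
# spanning fragments from fragments spanning the insertion itself.
DEFAULT_MIN_INSERT_BY_FAMILY = {
    "ALU": 310,
    "L1": 130,
    "SVA": 700,
    "HERVK": 8000,
}


def genotype_candidate(
    candidate: MEICandidate,
    pairs: Iterable[ReadPair],
    fld_by_lib,
    sample_id: str = "sample0",
    prior: Sequence[float] = FLAT_PRIOR,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    clip_min: int = DEFAULT_CLIP_MIN,
    min_insert_by_family: Optional[dict] = None,
) -> GenotypeCall:
    """Convenience wrapper: count, compute likelihoods, call."""
    table = (
        DEFAULT_MIN_INSERT_BY_FAMILY
        if min_insert_by_family is None
        else min_insert_by_family
    )
    min_ins = table.get(candidate.family.value)
    ev = count_allele_support(
        candidate, pairs, fld_by_lib, sample_id,
        mapq_min=mapq_min, clip_min=clip_min, min_insert_len=min_ins,
    )
    return call_genotype(genotype_likelihoods(ev), prior, evidence=ev)
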