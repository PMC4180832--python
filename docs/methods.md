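# Methods

`meicall` detects mobile-element insertions (MEIs) — Alu, L1, SVA and
HERV-K retrotranspositions present in a sequenced sample but absent from
the reference genome — from paired-end alignments, using read-pair (RP)
and split-read (SR) mapping signals as co-equal, primary sources of
evidence. This note describes the model and procedure, the tunable
parameters and their defaults, the simulator that defines the test
conditions, and the numerical choices made where the design was open.

## Input model

The detector consumes coordinate-sorted paired-end alignments in which
the genome-anchored mate of a pair whose other mate aligned to an ME
consensus sequence carries an annotation describing that consensus hit.
In SAM the annotation travels in a custom optional tag (`ZM`,
string-encoded `family,strand,offset,mate_mapq,hit_count`); this is the
package's own documented dialect — ME-aware mappers record the same
information in mapper-specific formats, and the in-memory API accepts
any source that populates it. Read groups define the library and sample
of every read. Multiple input files are merged into one
coordinate-ordered stream, and regional access reads only the
alignments within the region. "Uniquely aligned" is operationalized as
mapping quality ≥ `mapq_min` (default 20).

Internally coordinates are 0-based half-open; breakpoints are 1-based
positions of the last reference base before the inserted sequence (the
leftmost convention), converted only at SAM/VCF boundaries.

## Pair classification

Each pair is assigned to exactly one evidence class:

* `RP_CANDIDATE` — exactly one mate uniquely genome-mapped, the pair
  carries an ME mate annotation, and the pair is discordant: wrong
  orientation, different chromosome (including a mate that is off the
  genome entirely), or an insert size with two-sided empirical p ≤ 0.005.
* `SR_CANDIDATE` — a cleanly aligned unique anchor whose mate is
  unmapped or soft-clipped by ≥ `clip_min` bases (default 20).
* `NORMAL` — both mates unique, same chromosome, convergent (FR)
  orientation, insert p > 0.005.
* `OTHER` — everything else.

Precedence is `RP > SR > NORMAL > OTHER`. The `SR > NORMAL` step
matters: a junction-straddling pair (clean anchor, clipped mate,
ordinary insert) satisfies every NORMAL condition, and classifying it
NORMAL would discard exactly the evidence SR detection exists to
collect. Only forward–reverse convergent libraries are supported.

## Insert-size model

Per library (never pooled), the empirical histogram of NORMAL-pair
insert lengths (outermost-base span, TLEN convention) supplies exact
quantiles with no distributional assumption. Estimation requires ≥
1,000 normal pairs per library. The two-sided tail probability of a
length x is `2·min(P(X≤x), P(X≥x))` capped at 1 — discordance is
directionless, and both short and long anomalies matter. The *maximum
expected fragment length* D(p) is the smallest L with P(X > L) ≤ p
(default p = 0.005, i.e. the 99.5th percentile); it sets every spatial
scale below.

## RP detection

Per family and chromosome, candidate pairs are split by the anchor
strand — plus-strand anchors approach the insertion from the 5′ (left)
side, minus-strand from the 3′ (right) side — and each side is
clustered by *fragment center*: anchor position pushed half the library
median toward the mate. Clustering is a single linear pass over
center-sorted candidates: consecutive centers within W join a cluster,
where W = D(0.005) − median is the spread the insert distribution
allows a center estimate (configurable; clusters freely mix libraries
and samples). A 5′ and a 3′ cluster pair into an event when the
separation between the 5′ anchor extent's end and the 3′ extent's start
is at most D(0.005) in absolute value; pairing is one-to-one, nearest
first by absolute separation with ties toward the smaller coordinate.
The breakpoint interval runs from the 5′ extent end to the 3′ extent
start (swapped into order if the clusters cross), and the reported
breakpoint is the interval's smaller bound. Minimum cluster size here
is 1; support thresholds are owned by the filtering stage.

## SR detection

The clipped or unmapped mate of each SR candidate is split-mapped in
full against two targets:

1. the genomic window implied by its anchor (anchor ± (D(0.005) +
   read length), directional by anchor strand), and
2. k-mer-nominated regions of the ME consensus library, both strands.

Alignment is affine-gap local Smith–Waterman with the lenient scheme
match +1, mismatch −3, gap open −5, gap extend −2 (a gap of length g
costs 5 + 2(g−1)); the implementation is a numpy-vectorized scalar DP
(the horizontal gap state is computed by a prefix-scan per row), exact
against the textbook three-state recurrence. Because the whole read is
aligned against each target, each partial alignment carries a junk tail
past the junction; tails are removed by the maximum-subarray rule: each
column scores +1 if the base matches, −5 otherwise (mismatches and gap
bases), and Kadane's algorithm keeps the maximum-sum contiguous block
(O(n); ties leftmost, then longest).

The consensus index hashes words of size k = 11 from each consensus
*with its 3′ poly-A tail appended* (15 bases; non-LTR consensus
sequences are A-rich at the 3′ end, and without the tail, junction
reads whose ME segment is mostly tail cannot anchor a split — about a
quarter of SR evidence at low coverage). Candidate regions need ≥ 2
words agreeing on a diagonal within ±5; at most 8 regions are aligned.

A split is accepted when both trimmed parts cover ≥ `min_part` (20)
read bases, the parts' read intervals overlap by ≤ 12 bases, and the
genome part does not already explain all but < `min_part` of the read.
The breakpoint derives from the genome part: its last aligned base when
the genome part comes first on the read, the base before its first
aligned base otherwise.

### Junction refinement

Trimming and microhomology blur the raw part boundaries by a few bases,
so the junction is refined deterministically:

* **Overlapping parts** (junction microhomology or a chance tail
  extension): every split position inside the overlap is scored by the
  mismatches of the overlap bases against gapless extrapolations of both
  targets; the minimum wins, with ties resolved at the middle of the
  tied range (splitting true homology evenly).
* **A gap between the parts** (a sequencing error just inside the
  junction makes the +1/−5 rule stop a matching run early): first a
  strict walk claims the contiguous all-match prefix of the gap along
  the consensus (plus the element's poly-A/poly-T run, which belongs to
  the insertion), capping the genome side; then the genome part extends
  through the remaining gap with a tolerant walk (≤ 3 mismatches, never
  ending on one, committed only while cumulative identity ≥ 2/3 with ≥
  2 matches); finally the whole gap is claimed at once iff it matches
  the reference extrapolation strictly better than the consensus
  extrapolation (≤ 3 mismatches, ≥ half matching). The asymmetric
  strictness keeps poly-A tails and target-site-duplication copies —
  whose reference match is coincidental — from being claimed as genome.

On reads synthesized as flank + consensus with 2% base error, this
recovers the junction within ±2 bases in ≥ 99% of trials; the residual
errors are clustered errors at the junction and genuine ≥ 3-base
microhomology, which no local evidence can resolve.

## Candidate assembly and filtering

SR splits cluster per chromosome and family within 15 bp; the locus
breakpoint is the modal split breakpoint (ties toward the smaller
coordinate — with a target-site duplication, left- and right-junction
reads can disagree by up to the TSD length, and the leftmost convention
applies). An SR locus within the merge window (default D(0.005)) of an
RP event of the same family absorbs it one-to-one, nearest first; the
merged candidate takes the SR breakpoint (the higher-resolution signal)
and pools supporting fragments. Families never merge. A dedup pass then
folds any RP-only candidate lying within the merge window of a
same-family neighbor into that neighbor — RP cluster fragmentation can
leave a second event describing the same locus, which would otherwise
surface as a false positive — while two SR-resolved candidates always
stay separate.

Support filtering retains a candidate iff it has ≥ 2 RP fragments on
*both* the 5′ and 3′ sides, or ≥ 2 SR fragments. Candidates supported
by RP alone are additionally removed when an annotated reference ME of
a disqualifying family lies within D(0.005) of the breakpoint
(largest D across contributing libraries when they disagree): Alu and
HERV-K are disqualified only by their own kind; L1 and SVA by their own
kind or Alu. RP evidence cannot distinguish a polymorphic insertion
from the reference copy it sits next to; SR-supported candidates
resolve the breakpoint exactly and are exempt. Annotations load from
4+-column BED (name column mapped to families by configurable regex
patterns) or UCSC RepeatMasker dumps.

## Genotyping

At each candidate, per sample, `N_alt` is the number of distinct
fragments that contributed RP or SR evidence during detection, and
`N_ref` counts uniquely mapped convergent pairs with a consistent
insert (p > 0.005) that demonstrably carry the reference allele by one
of two routes:

1. a mate's aligned (non-clipped) bases cross the junction — cover the
   interval spanned by the candidate's split breakpoints with one base
   of margin on each side; or
2. the outer fragment span contains the junction and the insert is too
   long to be a fragment spanning an inserted element of this family:
   insert + (family minimum element length) lands in the extreme upper
   tail (p ≤ 0.001 above the median).

Plain outer-span counting is unsafe: on the insertion-bearing
haplotype, a fragment straddling the whole element maps back with its
insert shortened by the element length, which for a ~300 bp Alu still
passes the consistency test roughly one time in ten — and under the
strict allele fractions below, a single such fragment forces a
heterozygous call at every homozygous locus. Both routes above are
immune: junction reads never cross the breakpoint interval, and a
fragment whose insert is already long cannot have been shortened by an
element. The family minimum inserted lengths (element + tails) default
to ALU 310, L1 130, SVA 700, HERV-K 8000 — Alu and HERV-K insert
essentially full-length, L1 is frequently severely 5′-truncated, SVA
varies.

The data likelihood of genotype g is binomial:
`L(g) = C(N_ref+N_alt, N_alt) · p_g^N_alt · (1−p_g)^N_ref` with p_g =
0, 0.5, 1 for REF/REF, REF/MEI, MEI/MEI and the convention 0⁰ = 1
(computed in log space). A flat 1/3 prior (configurable) gives
posteriors; the call is the posterior mode, ties broken in the order
REF/REF, REF/MEI, MEI/MEI. VCF output stores log10 likelihoods in GL
order (REF/REF, REF/MEI, MEI/MEI).

## Reporting and evaluation

Calls are emitted as VCF 4.2: POS is the 1-based breakpoint, ALT the
symbolic `<INS:ME:FAMILY>`, CIPOS only for RP-only events (SR-resolved
events report the point breakpoint), INFO carries family, support
counts and evidence class, and per-sample fields are GT and GL.

Evaluation against simulation truth matches calls to planted insertions
one-to-one, nearest first, within 500 bp on the same chromosome and
family (an exhaustive optimal matcher exists behind a flag for oracle
tests). Sensitivity decomposes by the signal that would retain a call
on its own (RP: ≥2/≥2; SR: ≥2), unmatched calls are false positives,
and breakpoint deltas are tabulated with the 0 / ≤15 / >15 bp
convention. Weighted genotype accuracy draws het and hom true positives
4:1 (400+100, scaled to availability), scores concordance, and averages
five seeded repeats. The allele frequency spectrum bins per-locus MEI
allele frequencies (alt alleles over 2× called samples) and normalizes
to sum 1.

## The simulator

The built-in generator reproduces the evaluation protocol the detector
is designed for, with one deliberate substitution: instead of wrapping
an external read simulator and mapper, reads are emitted directly as
alignments at their true coordinates (an idealized mapper). Its
defaults are the study conditions:

* full-length Alu insertions, or L1 insertions 5′-truncated to a length
  drawn from a shipped table heavily weighted to short retained lengths
  (100–6000 bp, including a <150 bp class); the table stands in for an
  unavailable empirical distribution and is user-replaceable;
* each insertion = consensus + 15 bp poly-A + a duplication of the 15
  reference bases 3′ of the site (on the minus strand the element and
  tail are reverse-complemented; the TSD stays a direct duplication —
  consistent with target-primed reverse transcription);
* insertions are excluded within 100 bp of each other and of any
  declared reference-ME interval; heterozygous insertions go to one
  random haplotype, homozygous to both;
* paired-end fragments with insert 500 ± 100 bp (median ± sd, normal,
  clipped below at one read length), read lengths 76 or 106 bp,
  coverages 5–20X, uniform base-substitution errors at 0.1%.

The idealized mapper maps each read's longest reference-provenance run
(≥ 20 bases) and soft-clips the rest; a read mostly inside the
consensus portion of an element is emitted unmapped with its anchor
ME-annotated; reads with neither are unmapped. Consequences worth
knowing: junction soft-clips are placed exactly at provenance
boundaries (split-read realignment rediscovers the junction from
sequence, so breakpoint accuracy is still earned, but mapper placement
noise, multi-mapping ambiguity and chimeric artifacts are absent), and
reads never mis-map into reference ME copies since the default genome
is random sequence. Passing results on these simulations therefore
bound what a real mapper would allow from above — which is the right
direction for validating the machinery itself — and say nothing about
mapper-induced failure modes on real genomes. The ME consensus library
shipped for simulations and tests is synthetic (deterministic random
sequences of realistic lengths: Alu 300 bp, L1 6 kb, SVA 1.3 kb,
HERV-K 9.5 kb); the method never depends on real consensus content,
only on reads matching whatever library is supplied. FASTQ export
exists for users who want to run a real mapper instead.

All randomness flows from a single integer seed; a fixed seed
reproduces haplotypes, truth and reads bit-identically.

## Problem sizes

The acceptance script reruns the protocol at 2.5 Mb / 125 insertions /
5 seeds per condition (seven conditions: Alu het+hom 10X, het 5X at
both read lengths, hom 20X; L1 het 10X and 20X, all 106 bp unless
stated); the test suite uses 1.2 Mb / 60 insertions / 2 seeds. These
sizes give stable fractions (625 and 120 loci per condition) at
interactive runtimes; the protocol itself is scale-free.

## Known limitations

* Only FR convergent libraries; no CRAM; no GC-bias or per-chromosome
  insert models.
* Insertions nested inside annotated reference MEs are out of reach by
  construction, as are novel (non-consensus) insertions.
* The strict 0/0.5/1 binomial makes heterozygote calls fragile when
  either allele's fragment count is zero, which at 5X coverage happens
  a few percent of the time; the two-route reference counting above is
  what keeps both ploidies accurate there.
* Greedy nearest-first truth matching is not globally optimal (the
  exhaustive matcher is exponential and gated to toy inputs).
* Breakpoints at junctions with ≥ 3 bp of microhomology or TSD-induced
  double matches are genuinely ambiguous; the reported position is a
  deterministic convention (leftmost / middle-of-ties), not a claim of
  certainty.
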