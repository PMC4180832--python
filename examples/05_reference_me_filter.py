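"""The family-specific reference-ME proximity filter.

A candidate supported only by read-pair signal localizes the insertion
to a window the size of a fragment length.  If the reference genome
already carries a mobile element of the same kind inside that window,
the candidate is most likely mis-mapped reads from the reference copy,
so it is removed; split-read-supported candidates resolve the exact
breakpoint and are exempt.  The disqualifying families differ: Alu and
HERV-K are removed only near their own kind, while L1 and SVA are also
removed near reference Alu copies.
"""

from meicall import MEFamily, ReferenceMEAnnotation, apply_reference_me_filter
from meicall.filters import MEICandidate
from meicall.fragments import FragmentLengthDistribution

# annotated reference MEs (0-based half-open, RepeatMasker-style)
annotation = ReferenceMEAnnotation(
    [
        ("chr1", 100_000, 100_300, MEFamily.ALU),
        ("chr1", 500_000, 506_000, MEFamily.L1),
    ]
)
# degenerate insert model: proximity distance = 400 bp
flds = {"lib0": FragmentLengthDistribution.from_lengths("lib0", [400] * 2000)}


def candidate(family, bp, sr):
    return MEICandidate(
        family, "chr1", bp, bp, bp,
        rp_support_5p=3, rp_support_3p=3, sr_support=sr, libraries={"lib0"},
    )


cases = [
    ("RP-only Alu, 200 bp from reference Alu", candidate(MEFamily.ALU, 99_800, 0)),
    ("RP-only Alu, 200 bp from reference L1", candidate(MEFamily.ALU, 499_800, 0)),
    ("SR-supported Alu inside reference Alu", candidate(MEFamily.ALU, 100_100, 4)),
    ("RP-only L1, 200 bp from reference Alu", candidate(MEFamily.L1, 99_800, 0)),
    ("RP-only SVA, 3 kb from anything", candidate(MEFamily.SVA, 503_000 + 9_000, 0)),
]

for label, cand in cases:
    kept = bool(apply_reference_me_filter([cand], annotation, flds))
    print(f"{'kept   ' if kept else 'removed'}  {label}")
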