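"""Split-map a single junction read to base-precise breakpoint.

Builds a read straddling an insertion junction — 48 genomic bases
followed by 58 bases of Alu consensus — and split-maps it against the
local genome window and the consensus index.  The two partial
alignments are trimmed by the +1/-5 maximum-subarray rule, and the
breakpoint is the last genome-aligned base before the inserted
sequence.  The same read reverse-complemented yields the same
breakpoint with the element strand flipped.
"""

import numpy as np

from meicall import MEIndex, split_map, synthetic_me_library
from meicall.model import revcomp
from meicall.simulate import _random_seq

rng = np.random.default_rng(7)
window = _random_seq(rng, 2_000)          # local reference around the anchor
window_origin = 1_250_000                  # its 0-based genomic coordinate
junction = 900                             # 0-based junction offset in the window

consensus, families = synthetic_me_library()
index = MEIndex(consensus, families)
alu = consensus["ALU_synthetic_consensus"]

read = window[junction - 48 : junction] + alu[:58]
split = split_map(read, window, window_origin, index)
print(f"read: 48 genome bases + 58 consensus bases")
print(f"genome part: read[{split.genome_part.query_begin}:"
      f"{split.genome_part.query_end}]  score {split.genome_part.score}")
print(f"ME part:     read[{split.me_part.query_begin}:"
      f"{split.me_part.query_end}]  {split.family.value} "
      f"strand {split.me_strand}  consensus offset {split.me_part.target_begin}")
print(f"breakpoint:  {split.breakpoint:,} "
      f"(expected {window_origin + junction:,} = last genome base before the insertion)")

flipped = split_map(revcomp(read), window, window_origin, index)
print(f"reverse-complemented read: breakpoint {flipped.breakpoint:,}, "
      f"strand {flipped.me_strand} (same position, flipped strand)")
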