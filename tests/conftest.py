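import random

import numpy as np
import pytest

from meicall import MEFamily, MEIndex, synthetic_me_library
from meicall.fragments import FragmentLengthDistribution
from meicall.model import AlignedRead, ReadPair


def random_seq(rng, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture(scope="session")
def me_library():
    return synthetic_me_library()


@pytest.fixture(scope="session")
def me_index(me_library):
    cons, fams = me_library
    return MEIndex(cons, fams)


@pytest.fixture(scope="session")
def small_index():
    """Small two-family index over deterministic random consensus."""
    rng = random.Random(3)
    cons = {"ALU_toy": random_seq(rng, 300), "L1_toy": random_seq(rng, 2000)}
    fams = {"ALU_toy": MEFamily.ALU, "L1_toy": MEFamily.L1}
    return MEIndex(cons, fams)


@pytest.fixture
def normal_fld():
    """Empirical insert model from a seeded N(500, 100) sample."""
    rng = np.random.default_rng(42)
    lengths = np.clip(np.rint(rng.normal(500, 100, 20_000)), 100, None).astype(int)
    return FragmentLengthDistribution.from_lengths("lib0", lengths)


def make_read(
    name="r", chrom="chr1", pos=1000, cigar="100M", seq=None, mapq=60,
    strand="+", ann=None, lib="lib0", sample="sample0",
):
    if seq is None:
        from meicall.model import cigar_query_span

        seq = "A" * (cigar_query_span(cigar) if cigar else 100)
    return AlignedRead(
        name=name, chrom=chrom, pos=pos, cigar=cigar, seq=seq, mapq=mapq,
        strand=strand, me_annotation=ann, library_id=lib, sample_id=sample,
    )


def make_pair(name="frag0", pos_a=1000, pos_b=1400, rl=100, **kw):
    """Convergent same-chromosome pair with the given leftmost positions."""
    a = make_read(name=name, pos=pos_a, cigar=f"{rl}M", strand="+", **kw)
    b = make_read(name=name, pos=pos_b, cigar=f"{rl}M", strand="-", **kw)
    return ReadPair(a, b)
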