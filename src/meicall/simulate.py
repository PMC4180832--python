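"""Diploid MEI simulation with idealized tagged alignments.

The generator emulates the evaluation protocol the detector is designed
for: mobile elements are planted into a genome — full-length Alu (with a
15 bp poly-A tail and a 15 bp target-site duplication) or 5'-truncated
L1 — separately for heterozygous and homozygous states, and paired-end
fragments (insert 500 +/- 100 bp, read lengths 76 or 106 bp, coverages
5-20X) are drawn from the resulting haplotypes.

Instead of wrapping an external read simulator and mapper, reads are
emitted directly as alignments at their true reference coordinates (an
idealized mapper): a read whose mate lies inside an inserted element is
emitted with the mate ME-annotated (RP signal); a read straddling an
insertion junction is emitted soft-clipped at the junction (SR signal);
a read mostly inside the consensus portion of an insertion is emitted
unmapped with its pair annotated.  Base errors are uniform random
substitutions.  This removes mapper noise — detector results on these
alignments bound what a real mapper would allow — and makes every stage
testable hermetically.  FASTQ export is available for users who prefer
to run a real mapper.

All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import AlignedRead, MEAnnotation, MEFamily, ReadPair, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Synthetic consensus lengths per family (bp): full-length AluY is ~300,
# L1 ~6 kb, SVA ~1.3 kb, HERV-K ~9.5 kb.
SYNTHETIC_ME_LENGTHS = {
    MEFamily.ALU: 300,
    MEFamily.L1: 6000,
    MEFamily.SVA: 1300,
    MEFamily.HERVK: 9500,
}

# Stand-in 5' truncation table for L1 insertions: retained 3' lengths and
# weights, heavily skewed to severely truncated elements (including the
# <150 bp class).  User-replaceable via SimulationConfig.
DEFAULT_L1_TRUNCATION_TABLE: Dict[int, float] = {
    100: 0.22,
    150: 0.15,
    300: 0.15,
    600: 0.13,
    1000: 0.10,
    1500: 0.09,
    2500: 0.08,
    4000: 0.05,
    6000: 0.03,
}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def synthetic_me_library(
    seed: int = 714025,
) -> Tuple[Dict[str, str], Dict[str, MEFamily]]:
    """Deterministic synthetic ME consensus library.

    Random sequences standing in for the RepBase consensus of each
    family; the detector never relies on real consensus content, only on
    reads matching whatever library it is given.
    """
    rng = np.random.default_rng(seed)
    consensus, families = {}, {}
    for fam in (MEFamily.ALU, MEFamily.L1, MEFamily.SVA, MEFamily.HERVK):
        name = f"{fam.value}_synthetic_consensus"
        consensus[name] = _random_seq(rng, SYNTHETIC_ME_LENGTHS[fam])
        families[name] = fam
    return consensus, families


def write_fasta(seqs: Dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class TruthInsertion:
    """Ground truth for one planted insertion.

    ``position`` is the 1-based last reference base before the inserted
    sequence (equal to the 0-based insertion index into the reference).
    """

    chrom: str
    position: int
    family: MEFamily
    inserted_length: int  # consensus part only
    tsd_len: int
    polya_len: int
    ploidy: str  # HET or HOM
    me_strand: str

    @property
    def total_insert_length(self) -> int:
        return self.inserted_length + self.polya_len + self.tsd_len


@dataclass
class SimulationConfig:
    genome_length: int = 2_000_000
    n_insertions: int = 100
    family: MEFamily = MEFamily.ALU
    read_length: int = 106
    coverage: float = 10.0
    fragment_median: int = 500
    fragment_sd: int = 100
    base_error_rate: float = 0.001
    ploidy: str = "HET"
    tsd_len: int = 15
    polya_len: int = 15
    min_distance: int = 100
    chrom: str = "sim1"
    sample_id: str = "sample0"
    library_id: str = "lib0"
    map_min: int = 20  # minimum reference bases for the idealized mapper
    seed: int = 1
    l1_truncation_table: Dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_L1_TRUNCATION_TABLE)
    )

    def __post_init__(self) -> None:
        if self.ploidy not in ("HET", "HOM"):
            raise ValueError("ploidy must be HET or HOM")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


def truncate_l1(full_l1: str, table: Dict[int, float], rng: np.random.Generator) -> str:
    """Retain a 3'-suffix of an L1 consensus, length drawn from ``table``.

    Lengths are capped at the full consensus length.
    """
    if not table:
        raise ValueError("empty truncation table")
    lengths = np.array(sorted(table), dtype=np.int64)
    weights = np.array([table[int(l)] for l in lengths], dtype=float)
    weights = weights / weights.sum()
    L = int(rng.choice(lengths, p=weights))
    L = min(L, len(full_l1))
    return full_l1[-L:]


@dataclass
class _Block:
    """One segment of a haplotype: reference or inserted sequence."""

    hap_start: int
    hap_end: int
    ref_start: Optional[int]  # None for inserted blocks
    truth: Optional[TruthInsertion] = None
    # consensus sub-interval of an inserted block, in hap coords
    me_span: Optional[Tuple[int, int]] = None
    me_offset: int = 0
    me_strand: str = "+"


@dataclass
class Haplotype:
    seq: str
    blocks: List[_Block]
    ins_starts: np.ndarray  # hap coords of inserted blocks, for fast hit test
    ins_ends: np.ndarray


def plant_insertions(
    genome: str,
    me_library: Tuple[Dict[str, str], Dict[str, MEFamily]],
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    forbidden: Optional[Sequence[Tuple[int, int]]] = None,
) -> Tuple[Tuple[Haplotype, Haplotype], List[TruthInsertion]]:
    """Plant insertions into a genome, returning a diploid haplotype pair.

    The inserted sequence is consensus (5'-truncated for L1) + poly-A +
    a duplication of the ``tsd_len`` reference bases 3' of the site; on
    the minus strand the element and tail are reverse-complemented while
    the TSD stays a direct reference duplication.  No two insertions sit
    within ``cfg.min_distance`` of each other or of any ``forbidden``
    interval (e.g. planted reference MEs).

    HET insertions go to one randomly chosen haplotype, HOM to both.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    consensus, families = me_library
    by_family = {fam: consensus[name] for name, fam in families.items()}
    n, L = cfg.n_insertions, len(genome)
    margin = cfg.min_distance + cfg.tsd_len + 1
    if L < 2 * margin + n * cfg.min_distance:
        raise ValueError("genome too short for requested insertions")

    positions = _draw_positions(rng, n, margin, L - margin, cfg.min_distance, forbidden)

    truths: List[TruthInsertion] = []
    inserts: List[Tuple[int, str, TruthInsertion, Tuple[int, int, str, int]]] = []
    for p in positions:
        fam = cfg.family
        cons = by_family[fam]
        if fam == MEFamily.L1:
            cons = truncate_l1(cons, cfg.l1_truncation_table, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        tsd = genome[p : p + cfg.tsd_len]
        body = cons + "A" * cfg.polya_len
        if strand == "+":
            ins_seq = body + tsd
            me_rel = (0, len(cons))  # consensus part within ins_seq
            me_off = len(by_family[fam]) - len(cons)  # 5' truncation offset
        else:
            ins_seq = revcomp(body) + tsd
            me_rel = (cfg.polya_len, cfg.polya_len + len(cons))
            me_off = 0
        truth = TruthInsertion(
            chrom=cfg.chrom,
            position=p,
            family=fam,
            inserted_length=len(cons),
            tsd_len=cfg.tsd_len,
            polya_len=cfg.polya_len,
            ploidy=cfg.ploidy,
            me_strand=strand,
        )
        truths.append(truth)
        inserts.append((p, ins_seq, truth, (me_rel[0], me_rel[1], strand, me_off)))

    hap_assign = []
    for _ in inserts:
        if cfg.ploidy == "HOM":
            hap_assign.append((True, True))
        else:
            first = rng.random() < 0.5
            hap_assign.append((first, not first))

    haplotypes = []
    for h in range(2):
        chosen = [ins for ins, take in zip(inserts, hap_assign) if take[h]]
        haplotypes.append(_build_haplotype(genome, chosen))
    return (haplotypes[0], haplotypes[1]), truths


def _draw_positions(rng, n, lo, hi, min_dist, forbidden) -> List[int]:
    forbidden = sorted(forbidden or [])
    for _ in range(200):
        pos = np.sort(rng.integers(lo, hi, size=n))
        if n > 1 and np.min(np.diff(pos)) < min_dist:
            continue
        if forbidden and any(
            s - min_dist <= p <= e + min_dist for p in pos for s, e in forbidden
        ):
            continue
        return [int(p) for p in pos]
    raise ValueError("could not place insertions under the distance constraint")


def _build_haplotype(genome: str, inserts) -> Haplotype:
    parts: List[str] = []
    blocks: List[_Block] = []
    hap_pos = 0
    ref_pos = 0
    for p, ins_seq, truth, (me_a, me_b, strand, me_off) in inserts:
        if p > ref_pos:
            seg = genome[ref_pos:p]
            blocks.append(_Block(hap_pos, hap_pos + len(seg), ref_pos))
            parts.append(seg)
            hap_pos += len(seg)
            ref_pos = p
        blocks.append(
            _Block(
                hap_pos,
                hap_pos + len(ins_seq),
                None,
                truth=truth,
                me_span=(hap_pos + me_a, hap_pos + me_b),
                me_offset=me_off,
                me_strand=strand,
            )
        )
        parts.append(ins_seq)
        hap_pos += len(ins_seq)
    seg = genome[ref_pos:]
    blocks.append(_Block(hap_pos, hap_pos + len(seg), ref_pos))
    parts.append(seg)
    ins_blocks = [b for b in blocks if b.ref_start is None]
    return Haplotype(
        seq="".join(parts),
        blocks=blocks,
        ins_starts=np.array([b.hap_start for b in ins_blocks], dtype=np.int64),
        ins_ends=np.array([b.hap_end for b in ins_blocks], dtype=np.int64),
    )


def simulate_alignments(
    haplotypes: Tuple[Haplotype, Haplotype],
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> List[ReadPair]:
    """Draw paired-end fragments and emit idealized tagged alignments.

    Mean depth over non-inserted regions lands within a few percent of
    ``cfg.coverage``; reads are reference-forward; base errors are
    injected uniformly at ``cfg.base_error_rate`` per base.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    rl = cfg.read_length
    pairs: List[ReadPair] = []
    frag_counter = 0
    for hap in haplotypes:
        hap_len = len(hap.seq)
        n_pairs = int(round(cfg.coverage / 2.0 * hap_len / (2.0 * rl)))
        if n_pairs <= 0:
            raise ValueError("coverage too low to draw any pairs")
        flens = np.rint(rng.normal(cfg.fragment_median, cfg.fragment_sd, n_pairs))
        flens = np.clip(flens, rl, None).astype(np.int64)
        starts = (rng.random(n_pairs) * (hap_len - flens)).astype(np.int64)
        # error plan: which reads carry errors at all
        err_draws = rng.random(2 * n_pairs)
        p_clean = (1.0 - cfg.base_error_rate) ** rl
        for i in range(n_pairs):
            s = int(starts[i])
            f = int(flens[i])
            name = f"frag{frag_counter:08d}"
            frag_counter += 1
            r1 = _make_read(hap, s, s + rl, "+", name, cfg)
            r2 = _make_read(hap, s + f - rl, s + f, "-", name, cfg)
            for r, draw in ((r1, err_draws[2 * i]), (r2, err_draws[2 * i + 1])):
                if draw > p_clean:
                    r.seq = _inject_errors(r.seq, cfg.base_error_rate, rng)
            _annotate_pair(r1, r2)
            pairs.append(ReadPair(r1, r2))
    return pairs


def _inject_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    n = rng.binomial(len(seq), rate)
    if n == 0:
        n = 1  # conditioned on the read being flagged as carrying errors
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    pos = rng.choice(len(seq), size=min(n, len(seq)), replace=False)
    arr[pos] = _BASES[(rng.integers(1, 4, size=len(pos)) +
                       np.searchsorted(_BASES, arr[pos])) % 4]
    return arr.tobytes().decode("ascii")


def _make_read(
    hap: Haplotype, a: int, b: int, strand: str, name: str, cfg: SimulationConfig
) -> AlignedRead:
    """Idealized mapping of the haplotype interval [a, b) to the reference."""
    seq = hap.seq[a:b]
    # fast path: no overlap with any inserted block
    i = int(np.searchsorted(hap.ins_ends, a, side="right"))
    clean = i >= len(hap.ins_starts) or hap.ins_starts[i] >= b
    if clean:
        block = _block_at(hap, a)
        ref = block.ref_start + (a - block.hap_start)
        return AlignedRead(
            name=name,
            chrom=cfg.chrom,
            pos=ref,
            cigar=f"{b - a}M",
            seq=seq,
            mapq=60,
            strand=strand,
            library_id=cfg.library_id,
            sample_id=cfg.sample_id,
        )
    return _make_junction_read(hap, a, b, strand, name, cfg, seq)


def _block_at(hap: Haplotype, pos: int) -> _Block:
    lo, hi = 0, len(hap.blocks) - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if hap.blocks[mid].hap_end <= pos:
            lo = mid + 1
        else:
            hi = mid
    return hap.blocks[lo]


def _make_junction_read(
    hap: Haplotype, a: int, b: int, strand: str, name: str, cfg, seq: str
) -> AlignedRead:
    """A read overlapping inserted sequence: soft-clip, ME-map or unmap."""
    ref_runs = []  # (read_offset, length, ref_start)
    me_hit = None  # (family, strand, offset, overlap)
    x = a
    while x < b:
        block = _block_at(hap, x)
        end = min(block.hap_end, b)
        if block.ref_start is not None:
            ref_runs.append((x - a, end - x, block.ref_start + (x - block.hap_start)))
        else:
            span = block.me_span
            if span is not None:
                ov_a, ov_b = max(x, span[0]), min(end, span[1])
                overlap = ov_b - ov_a
                if overlap > 0 and (me_hit is None or overlap > me_hit[3]):
                    off = block.me_offset + (
                        ov_a - span[0] if block.me_strand == "+" else span[1] - ov_b
                    )
                    me_hit = (block.truth.family, block.me_strand, off, overlap)
        x = end
    ref_runs.sort(key=lambda r: (-r[1], r[0]))
    if ref_runs and ref_runs[0][1] >= cfg.map_min:
        off, length, ref_start = ref_runs[0]
        cig = []
        if off:
            cig.append(f"{off}S")
        cig.append(f"{length}M")
        if b - a - off - length:
            cig.append(f"{b - a - off - length}S")
        read = AlignedRead(
            name=name,
            chrom=cfg.chrom,
            pos=ref_start,
            cigar="".join(cig),
            seq=seq,
            mapq=60,
            strand=strand,
            library_id=cfg.library_id,
            sample_id=cfg.sample_id,
        )
    else:
        read = AlignedRead(
            name=name,
            chrom=None,
            pos=None,
            cigar="",
            seq=seq,
            mapq=0,
            strand=strand,
            library_id=cfg.library_id,
            sample_id=cfg.sample_id,
        )
    if me_hit is not None and me_hit[3] >= cfg.map_min:
        read._me_self = MEAnnotation(  # type: ignore[attr-defined]
            family=me_hit[0],
            me_strand=me_hit[1],
            me_offset=int(me_hit[2]),
            mate_mapq=60,
            mate_hit_count=1,
        )
    return read


def _annotate_pair(r1: AlignedRead, r2: AlignedRead) -> None:
    """Attach the mate's ME hit to the genome-anchored read."""
    for anchor, other in ((r1, r2), (r2, r1)):
        hit = getattr(other, "_me_self", None)
        if hit is not None and anchor.is_mapped and not other.is_mapped:
            anchor.me_annotation = hit
    for r in (r1, r2):
        if hasattr(r, "_me_self"):
            delattr(r, "_me_self")


def simulate_dataset(
    cfg: SimulationConfig,
    me_library: Optional[Tuple[Dict[str, str], Dict[str, MEFamily]]] = None,
    genome: Optional[str] = None,
) -> Tuple[str, List[TruthInsertion], List[ReadPair]]:
    """One-call convenience: genome, insertions, tagged alignments.

    Returns (reference genome, truth records, read pairs).  Everything is
    reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    if me_library is None:
        me_library = synthetic_me_library()
    if genome is None:
        genome = _random_seq(rng, cfg.genome_length)
    haps, truths = plant_insertions(genome, me_library, cfg, rng)
    pairs = simulate_alignments(haps, cfg, rng)
    return genome, truths, pairs


def write_truth_tsv(truths: Sequence[TruthInsertion], path: str) -> None:
    cols = "chrom position family inserted_length tsd_len polya_len ploidy me_strand"
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(cols.split()) + "\n")
        for t in truths:
            fh.write(
                f"{t.chrom}\t{t.position}\t{t.family.value}\t{t.inserted_length}"
                f"\t{t.tsd_len}\t{t.polya_len}\t{t.ploidy}\t{t.me_strand}\n"
            )


def read_truth_tsv(path: str) -> List[TruthInsertion]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            c, pos, fam, il, tsd, pa, pl, st = line.rstrip("\n").split("\t")
            out.append(
                TruthInsertion(
                    chrom=c,
                    position=int(pos),
                    family=MEFamily(fam),
                    inserted_length=int(il),
                    tsd_len=int(tsd),
                    polya_len=int(pa),
                    ploidy=pl,
                    me_strand=st,
                )
            )
    return out


def write_fastq(pairs: Sequence[ReadPair], path1: str, path2: str) -> None:
    """Export pairs as FASTQ (read 2 in sequencing orientation)."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            q1 = "I" * len(p.mate_a.seq)
            q2 = "I" * len(p.mate_b.seq)
            f1.write(f"@{p.name}/1\n{p.mate_a.seq}\n+\n{q1}\n")
            f2.write(f"@{p.name}/2\n{revcomp(p.mate_b.seq)}\n+\n{q2}\n")
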