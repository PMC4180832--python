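"""Simulator: planting, truncation, idealized read generation, determinism."""

import numpy as np
import pytest

from meicall.model import revcomp
from meicall.simulate import (
    SimulationConfig,
    plant_insertions,
    simulate_dataset,
    synthetic_me_library,
    truncate_l1,
    read_truth_tsv,
    write_truth_tsv,
    _random_seq,
)
from meicall.model import MEFamily


@pytest.fixture(scope="module")
def library():
    return synthetic_me_library()


def _cfg(**kw):
    base = dict(genome_length=100_000, n_insertions=10, coverage=10.0,
                read_length=106, ploidy="HOM", seed=7)
    base.update(kw)
    return SimulationConfig(**base)


class TestPlanting:
    def test_placement_constraints_and_tsd(self, library):
        rng = np.random.default_rng(7)
        genome = _random_seq(rng, 100_000)
        cfg = _cfg()
        (h0, h1), truths = plant_insertions(genome, library, cfg, rng)
        assert len(truths) == 10
        positions = sorted(t.position for t in truths)
        assert all(b - a >= 100 for a, b in zip(positions, positions[1:]))
        for t in truths:
            # inserted block ends with an exact duplication of the 15
            # reference bases 3' of the site
            block = _find_block(h0, t)
            assert block is not None
            ins_seq = h0.seq[block.hap_start : block.hap_end]
            assert ins_seq[-15:] == genome[t.position : t.position + 15]
            # haplotype continues with the same reference bases (duplication)
            assert h0.seq[block.hap_end : block.hap_end + 15] == ins_seq[-15:]

    def test_no_insertions_identity(self, library):
        rng = np.random.default_rng(1)
        genome = _random_seq(rng, 50_000)
        (h0, h1), truths = plant_insertions(
            genome, library, _cfg(n_insertions=0, genome_length=50_000), rng
        )
        assert truths == []
        assert h0.seq == genome and h1.seq == genome

    def test_deterministic_under_seed(self, library):
        a = simulate_dataset(_cfg())
        b = simulate_dataset(_cfg())
        assert a[0] == b[0]
        assert a[1] == b[1]
        assert len(a[2]) == len(b[2])
        for pa, pb in zip(a[2], b[2]):
            assert pa.mate_a.seq == pb.mate_a.seq
            assert pa.mate_a.pos == pb.mate_a.pos
            assert pa.mate_b.cigar == pb.mate_b.cigar

    def test_het_uses_one_haplotype(self, library):
        rng = np.random.default_rng(3)
        genome = _random_seq(rng, 100_000)
        (h0, h1), truths = plant_insertions(genome, library, _cfg(ploidy="HET"), rng)
        n0 = sum(1 for b in h0.blocks if b.ref_start is None)
        n1 = sum(1 for b in h1.blocks if b.ref_start is None)
        assert n0 + n1 == 10
        assert 0 < n0 < 10  # split across haplotypes

    def test_minus_strand_insertion_reverse_complemented(self, library):
        rng = np.random.default_rng(5)
        genome = _random_seq(rng, 200_000)
        cons, fams = library
        alu = next(s for n, s in cons.items() if fams[n] == MEFamily.ALU)
        (h0, _), truths = plant_insertions(genome, library, _cfg(genome_length=200_000), rng)
        minus = [t for t in truths if t.me_strand == "-"]
        assert minus  # seed chosen to include both strands
        t = minus[0]
        block = _find_block(h0, t)
        ins = h0.seq[block.hap_start : block.hap_end]
        assert ins.startswith("T" * 15)  # reverse-complemented poly-A
        assert revcomp(alu) in ins


def _find_block(hap, truth):
    for b in hap.blocks:
        if b.ref_start is None and b.truth is not None and b.truth.position == truth.position:
            return b
    return None


class TestTruncation:
    def test_degenerate_table_is_identity(self):
        rng = np.random.default_rng(0)
        seq = "ACGT" * 100
        assert truncate_l1(seq, {len(seq): 1.0}, rng) == seq

    def test_fixed_length_keeps_three_prime_end(self):
        rng = np.random.default_rng(0)
        seq = "ACGT" * 100
        assert truncate_l1(seq, {150: 1.0}, rng) == seq[-150:]

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            truncate_l1("ACGT", {}, np.random.default_rng(0))

    def test_two_point_table_frequencies(self):
        rng = np.random.default_rng(42)
        seq = "A" * 6000
        draws = [len(truncate_l1(seq, {150: 0.7, 6000: 0.3}, rng)) for _ in range(10_000)]
        frac_short = sum(1 for d in draws if d == 150) / len(draws)
        assert abs(frac_short - 0.7) <= 0.02


class TestReadGeneration:
    def test_fragment_median_recovered(self, library):
        cfg = _cfg(genome_length=600_000, n_insertions=0, coverage=20)
        _, _, pairs = simulate_dataset(cfg)
        lengths = [p.fragment_length for p in pairs if p.fragment_length]
        assert len(lengths) > 50_000 * 0.5
        assert 498 <= int(np.median(lengths)) <= 502

    def test_error_free_reads_match_genome(self, library):
        cfg = _cfg(n_insertions=0, base_error_rate=0.0, coverage=5)
        genome, _, pairs = simulate_dataset(cfg)
        for p in pairs[:500]:
            for m in (p.mate_a, p.mate_b):
                assert m.seq == genome[m.pos : m.pos + len(m.seq)]

    def test_mean_depth_near_target(self, library):
        cfg = _cfg(n_insertions=0, coverage=10, genome_length=300_000)
        genome, _, pairs = simulate_dataset(cfg)
        total_bases = sum(len(p.mate_a.seq) + len(p.mate_b.seq) for p in pairs)
        depth = total_bases / len(genome)
        assert abs(depth - 10) / 10 < 0.1

    def test_hom_insertions_have_rp_support_both_sides(self, library):
        """At 20X every homozygous Alu yields >= 2 ME-annotated pairs on
        each side (checked across 20 insertions; Poisson failure odds are
        negligible at this depth)."""
        cfg = _cfg(genome_length=400_000, n_insertions=20, coverage=20)
        genome, truths, pairs = simulate_dataset(cfg)
        for t in truths:
            five = three = 0
            for p in pairs:
                ann = p.me_annotation
                anchor = p.anchor
                if ann is None or anchor is None:
                    continue
                if abs(anchor.pos - t.position) < 700:
                    if anchor.strand == "+":
                        five += 1
                    else:
                        three += 1
            assert five >= 2 and three >= 2, t

    def test_junction_reads_soft_clipped(self, library):
        cfg = _cfg(genome_length=200_000, n_insertions=5, coverage=20)
        genome, truths, pairs = simulate_dataset(cfg)
        clipped = [
            m
            for p in pairs
            for m in (p.mate_a, p.mate_b)
            if m.is_mapped and m.max_soft_clip >= 20
        ]
        assert clipped
        # every substantially clipped read sits at an insertion site
        for m in clipped:
            assert any(
                abs((m.pos if m.soft_clip_left else m.end) - t.position) <= 140
                for t in truths
            )

    def test_zero_coverage_raises(self):
        with pytest.raises(ValueError):
            SimulationConfig(coverage=0)


def test_truth_tsv_round_trip(tmp_path, library):
    _, truths, _ = simulate_dataset(_cfg())
    path = tmp_path / "truth.tsv"
    write_truth_tsv(truths, str(path))
    assert read_truth_tsv(str(path)) == list(truths)
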