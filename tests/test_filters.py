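"""Evidence merging, support filtering, reference-ME proximity filtering."""

import pytest

from meicall.filters import (
    EVIDENCE_RP_AND_SR,
    EVIDENCE_RP_ONLY,
    EVIDENCE_SR_ONLY,
    MEICandidate,
    ReferenceMEAnnotation,
    apply_reference_me_filter,
    apply_support_filter,
    cluster_sr_splits,
    merge_evidence,
)
from meicall.fragments import FragmentLengthDistribution
from meicall.model import AlignedRead, MEAnnotation, MEFamily, ReadPair
from meicall.rp import ClusterSide, RPCluster, RPEvent
from meicall.sr import SplitAlignment
from meicall.sw import LocalAlignment


def _fld(median=500):
    # degenerate model: max expected fragment length == median
    return {"lib0": FragmentLengthDistribution.from_lengths("lib0", [median] * 2000)}


def _rp_event(family=MEFamily.ALU, bp=10_240, ci=(10_240, 10_260), n5=2, n3=2):
    def cluster(side, n):
        members = []
        for i in range(n):
            anchor = AlignedRead(
                f"{side.value}m{i}", "chr1", bp - 100, "100M", "A" * 100, 60,
                "+" if side == ClusterSide.FIVE_PRIME else "-",
                me_annotation=MEAnnotation(family),
            )
            mate = AlignedRead(f"{side.value}m{i}", None, None, "", "A" * 100, 0, "-")
            members.append(ReadPair(anchor, mate))
        return RPCluster(family, side, "chr1", members, [bp] * n)

    return RPEvent(
        family=family, chrom="chr1", breakpoint=bp, ci_low=ci[0], ci_high=ci[1],
        five_prime=cluster(ClusterSide.FIVE_PRIME, n5),
        three_prime=cluster(ClusterSide.THREE_PRIME, n3),
    )


def _split(family=MEFamily.ALU, bp=10_251, name="s0"):
    part = LocalAlignment(0, 50, 0, 50, 50, "50M")
    return SplitAlignment(
        genome_part=part, me_part=part, family=family, me_id="x",
        me_strand="+", breakpoint=bp, chrom="chr1", read_name=name,
    )


class TestMergeEvidence:
    def test_rp_and_sr_merge_takes_sr_breakpoint(self):
        cands = merge_evidence(
            [_rp_event()], [_split(bp=10_251, name="s0"), _split(bp=10_251, name="s1")],
            merge_window=760,
        )
        assert len(cands) == 1
        c = cands[0]
        assert c.breakpoint == 10_251
        assert c.evidence_class == EVIDENCE_RP_AND_SR
        assert c.ci_low == c.ci_high == 10_251
        assert c.rp_support_5p == 2 and c.sr_support == 2

    def test_families_never_merge(self):
        cands = merge_evidence(
            [_rp_event(MEFamily.ALU)],
            [_split(MEFamily.L1, name="a"), _split(MEFamily.L1, name="b")],
            merge_window=760,
        )
        assert len(cands) == 2
        assert {c.evidence_class for c in cands} == {EVIDENCE_RP_ONLY, EVIDENCE_SR_ONLY}

    def test_identical_sr_breakpoints_pool_support(self):
        cands = merge_evidence(
            [], [_split(name="a"), _split(name="b")], merge_window=760
        )
        assert len(cands) == 1
        assert cands[0].sr_support == 2
        assert cands[0].evidence_class == EVIDENCE_SR_ONLY

    def test_sr_locus_breakpoint_is_mode_leftmost_on_tie(self):
        splits = [
            _split(bp=100, name="a"), _split(bp=100, name="b"),
            _split(bp=103, name="c"), _split(bp=103, name="d"),
            _split(bp=105, name="e"),
        ]
        loci = cluster_sr_splits(splits)
        assert len(loci) == 1
        assert loci[0].breakpoint == 100  # tie 2-2 resolved leftmost

    def test_merge_idempotent(self):
        ev = _rp_event()
        splits = [_split(name="a"), _split(name="b")]
        once = merge_evidence([ev], splits, merge_window=760)
        again = merge_evidence([], [], merge_window=760) + once
        # re-running the merge machinery on already-merged candidates is a no-op
        from meicall.filters import _dedup_candidates

        assert _dedup_candidates(list(once), 760) == once
        assert again == once

    def test_dangling_rp_duplicate_absorbed(self):
        ev_far = _rp_event(bp=10_600, ci=(10_600, 10_650))
        cands = merge_evidence(
            [_rp_event(), ev_far], [_split(name="a"), _split(name="b")],
            merge_window=760,
        )
        assert len(cands) == 1
        assert cands[0].evidence_class == EVIDENCE_RP_AND_SR


class TestSupportFilter:
    @pytest.mark.parametrize(
        "rp5,rp3,sr,kept",
        [
            (2, 2, 0, True),
            (3, 0, 1, False),
            (0, 0, 2, True),
            (1, 2, 0, False),
            (2, 1, 1, False),
            (5, 5, 5, True),
            (0, 0, 0, False),
        ],
    )
    def test_retention_predicate(self, rp5, rp3, sr, kept):
        c = MEICandidate(
            MEFamily.ALU, "chr1", 100, 100, 100,
            rp_support_5p=rp5, rp_support_3p=rp3, sr_support=sr,
        )
        assert bool(apply_support_filter([c])) is kept

    def test_raising_thresholds_never_adds_calls(self):
        cands = [
            MEICandidate(MEFamily.ALU, "chr1", i, i, i, rp_support_5p=i % 4,
                         rp_support_3p=(i + 1) % 4, sr_support=(i + 2) % 4)
            for i in range(1, 40)
        ]
        prev = None
        for thresh in (1, 2, 3, 4):
            kept = {c.breakpoint for c in apply_support_filter(cands, thresh, thresh)}
            if prev is not None:
                assert kept <= prev
            prev = kept


class TestReferenceMEFilter:
    def _annotation(self):
        return ReferenceMEAnnotation(
            [
                ("chr1", 10_500, 10_800, MEFamily.ALU),
                ("chr1", 50_000, 56_000, MEFamily.L1),
                ("chr1", 90_000, 99_000, MEFamily.HERVK),
            ]
        )

    def _cand(self, family, bp, sr=0, rp=3):
        return MEICandidate(
            family, "chr1", bp, bp, bp,
            rp_support_5p=rp, rp_support_3p=rp, sr_support=sr,
            libraries={"lib0"},
        )

    def test_rp_only_alu_near_reference_alu_removed(self):
        c = self._cand(MEFamily.ALU, 10_300)  # 200 bp from the Alu interval
        assert apply_reference_me_filter([c], self._annotation(), _fld(300)) == []

    def test_rp_only_alu_near_l1_only_retained(self):
        c = self._cand(MEFamily.ALU, 49_900)
        assert apply_reference_me_filter([c], self._annotation(), _fld(300)) == [c]

    def test_sr_supported_candidate_never_filtered(self):
        c = self._cand(MEFamily.ALU, 10_600, sr=2, rp=0)
        assert apply_reference_me_filter([c], self._annotation(), _fld(300)) == [c]

    def test_l1_removed_near_alu_or_l1(self):
        near_alu = self._cand(MEFamily.L1, 10_300)
        near_l1 = self._cand(MEFamily.L1, 49_900)
        out = apply_reference_me_filter(
            [near_alu, near_l1], self._annotation(), _fld(300)
        )
        assert out == []

    def test_sva_removed_near_alu(self):
        c = self._cand(MEFamily.SVA, 10_300)
        assert apply_reference_me_filter([c], self._annotation(), _fld(300)) == []

    def test_hervk_only_removed_near_hervk(self):
        near_alu = self._cand(MEFamily.HERVK, 10_300)
        near_herv = self._cand(MEFamily.HERVK, 89_900)
        out = apply_reference_me_filter(
            [near_alu, near_herv], self._annotation(), _fld(300)
        )
        assert out == [near_alu]

    def test_distance_beyond_limit_retained(self):
        c = self._cand(MEFamily.ALU, 10_100)  # 400 bp away, limit 300
        assert apply_reference_me_filter([c], self._annotation(), _fld(300)) == [c]


class TestAnnotationIO:
    def test_bed_parsing_with_name_patterns(self, tmp_path):
        bed = tmp_path / "rmsk.bed"
        bed.write_text(
            "chr1\t100\t400\tAluYb8\t0\t+\n"
            "chr1\t1000\t7000\tL1HS\t0\t-\n"
            "chr1\t9000\t9100\tMIR\t0\t+\n"  # unmatched -> ignored
        )
        ann = ReferenceMEAnnotation.from_bed(str(bed))
        assert ann.distance_to_nearest("chr1", 450, [MEFamily.ALU]) == 50
        assert ann.distance_to_nearest("chr1", 999, [MEFamily.L1]) == 2
        assert ann.distance_to_nearest("chr1", 9050, [MEFamily.SVA]) is None

    def test_rmsk_dump_parsing(self, tmp_path):
        rmsk = tmp_path / "rmsk.txt"
        cols = ["585", "1000", "10", "0", "0", "chr1", "200", "500", "-1000", "+",
                "AluSx", "SINE", "Alu", "1", "300", "0", "1"]
        rmsk.write_text("\t".join(cols) + "\n")
        ann = ReferenceMEAnnotation.from_rmsk(str(rmsk))
        assert ann.distance_to_nearest("chr1", 350, [MEFamily.ALU]) == 0

    def test_invalid_interval_raises(self):
        with pytest.raises(ValueError):
            ReferenceMEAnnotation([("chr1", 500, 400, MEFamily.ALU)])
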