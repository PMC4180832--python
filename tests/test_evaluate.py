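"""Truth matching, sensitivity decomposition, weighted accuracy, AFS."""

import numpy as np
import pytest

from meicall.evaluate import (
    allele_frequency_spectrum,
    evaluate,
    match_calls_to_truth,
    weighted_genotype_accuracy,
)
from meicall.filters import MEICandidate
from meicall.genotype import GenotypeCall
from meicall.model import MEFamily
from meicall.pipeline import MEICall
from meicall.simulate import TruthInsertion


def _truth(pos, family=MEFamily.ALU, ploidy="HET"):
    return TruthInsertion("chr1", pos, family, 300, 15, 15, ploidy, "+")


def _call(pos, family=MEFamily.ALU, rp=(3, 3), sr=3, genotype="REF/MEI"):
    cand = MEICandidate(
        family, "chr1", pos, pos, pos,
        rp_support_5p=rp[0], rp_support_3p=rp[1], sr_support=sr,
    )
    gt = GenotypeCall(
        genotype=genotype,
        likelihoods=(0, 1, 0),
        log10_likelihoods=(0, 0, 0),
        posteriors=(0, 1, 0),
        prior=(1 / 3, 1 / 3, 1 / 3),
    )
    return MEICall(candidate=cand, genotypes={"sample0": gt})


class TestMatching:
    def test_within_window_matches(self):
        m = match_calls_to_truth([_call(10_400)], [_truth(10_000)], window=500)
        assert len(m.matched) == 1

    def test_beyond_window_unmatched(self):
        m = match_calls_to_truth([_call(10_600)], [_truth(10_000)], window=500)
        assert m.matched == []
        assert len(m.false_positives) == 1
        assert len(m.false_negatives) == 1

    def test_two_calls_one_truth(self):
        m = match_calls_to_truth(
            [_call(10_010), _call(10_050)], [_truth(10_000)], window=500
        )
        assert len(m.matched) == 1
        assert m.matched[0][0].breakpoint == 10_010  # nearest first
        assert len(m.false_positives) == 1

    def test_family_mismatch_never_matches(self):
        m = match_calls_to_truth(
            [_call(10_000, family=MEFamily.L1)], [_truth(10_000)], window=500
        )
        assert m.matched == []

    def test_greedy_equals_exhaustive_on_toy_sets(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            truths = [_truth(int(p)) for p in np.sort(rng.integers(0, 5000, 4))]
            calls = [_call(int(p)) for p in np.sort(rng.integers(0, 5000, 4))]
            greedy = match_calls_to_truth(calls, truths, window=500)
            optimal = match_calls_to_truth(calls, truths, window=500, exhaustive=True)
            # same matching cardinality (greedy nearest-first is max here)
            assert len(greedy.matched) == len(optimal.matched)


class TestEvaluation:
    def test_perfect_caller(self):
        truths = [_truth(p) for p in range(10_000, 110_000, 1000)]
        calls = [_call(t.position) for t in truths]
        rep = evaluate(calls, truths)
        assert rep.sensitivity_union == 1.0
        assert rep.fdr == 0.0
        assert rep.breakpoint_exact_fraction == 1.0
        assert rep.breakpoint_deltas == {0: len(truths)}

    def test_missing_ten_of_hundred(self):
        truths = [_truth(p) for p in range(10_000, 110_000, 1000)]
        calls = [_call(t.position) for t in truths[:90]]
        rep = evaluate(calls, truths)
        assert rep.sensitivity_union == pytest.approx(0.90)

    def test_signal_decomposition_set_arithmetic(self):
        # truth {A,B,C,D}; RP finds {A,B}, SR finds {B,C}
        A, B, C, D = 10_000, 20_000, 30_000, 40_000
        truths = [_truth(p) for p in (A, B, C, D)]
        calls = [
            _call(A, rp=(3, 3), sr=0),
            _call(B, rp=(3, 3), sr=3),
            _call(C, rp=(0, 0), sr=3),
        ]
        rep = evaluate(calls, truths)
        assert rep.sensitivity_rp == pytest.approx(0.5)
        assert rep.sensitivity_sr == pytest.approx(0.5)
        assert rep.sensitivity_rp_only == pytest.approx(0.25)
        assert rep.sensitivity_sr_only == pytest.approx(0.25)
        assert rep.sensitivity_union == pytest.approx(0.75)

    def test_union_identity(self):
        rng = np.random.default_rng(4)
        truths = [_truth(int(p)) for p in np.arange(40) * 3000 + 10_000]
        calls = []
        for t in truths:
            if rng.random() < 0.8:
                rp = (3, 3) if rng.random() < 0.6 else (0, 0)
                sr = 3 if rng.random() < 0.7 else 0
                if rp == (0, 0) and sr == 0:
                    continue
                calls.append(_call(t.position, rp=rp, sr=sr))
        rep = evaluate(calls, truths)
        assert rep.sensitivity_union == pytest.approx(
            rep.sensitivity_rp + rep.sensitivity_sr_only
        )
        assert rep.sensitivity_union == pytest.approx(
            rep.sensitivity_sr + rep.sensitivity_rp_only
        )

    def test_genotype_accuracy_by_ploidy(self):
        truths = [_truth(10_000, ploidy="HET"), _truth(20_000, ploidy="HOM")]
        calls = [
            _call(10_000, genotype="REF/MEI"),
            _call(20_000, genotype="REF/MEI"),  # wrong for HOM
        ]
        rep = evaluate(calls, truths)
        assert rep.genotype_accuracy_het == 1.0
        assert rep.genotype_accuracy_hom == 0.0


class TestWeightedAccuracy:
    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(0)
        records = [("HET", bool(rng.random() < 0.95)) for _ in range(600)] + [
            ("HOM", bool(rng.random() < 0.9)) for _ in range(200)
        ]
        a, _ = weighted_genotype_accuracy(records, seed=5)
        b, _ = weighted_genotype_accuracy(records, seed=5)
        assert a == b

    def test_draw_ratio_dominated_by_het(self):
        records = [("HET", True)] * 500 + [("HOM", False)] * 500
        acc, _ = weighted_genotype_accuracy(records, n_het=400, n_hom=100, seed=1)
        assert acc == pytest.approx(0.8)

    def test_fallback_to_all_available_notes(self):
        records = [("HET", True)] * 10 + [("HOM", True)] * 3
        acc, notes = weighted_genotype_accuracy(records, seed=1)
        assert acc == 1.0
        assert notes


class TestAFS:
    def test_single_hom_locus_at_frequency_one(self):
        edges, hist, freqs = allele_frequency_spectrum([{"s0": "MEI/MEI"}])
        assert freqs == [1.0]
        assert hist[-1] == 1.0
        assert hist.sum() == pytest.approx(1.0)

    def test_het_plus_ref_gives_quarter(self):
        _, _, freqs = allele_frequency_spectrum(
            [{"s0": "REF/MEI", "s1": "REF/REF"}]
        )
        assert freqs == [0.25]

    def test_matches_direct_tabulation(self):
        rng = np.random.default_rng(6)
        labels = ["REF/REF", "REF/MEI", "MEI/MEI"]
        loci = [
            {f"s{j}": labels[rng.integers(0, 3)] for j in range(8)}
            for _ in range(200)
        ]
        edges, hist, freqs = allele_frequency_spectrum(loci, bins=10)
        assert hist.sum() == pytest.approx(1.0)
        expected = [
            sum(("MEI" in g) + (g == "MEI/MEI") for g in locus.values()) / 16
            for locus in loci
        ]
        assert sorted(freqs) == sorted(expected)

    def test_no_called_loci_raises(self):
        with pytest.raises(ValueError):
            allele_frequency_spectrum([])
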