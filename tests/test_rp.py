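"""RP nucleation: fragment centers, linear clustering, cluster pairing."""

import numpy as np
import pytest

from meicall.fragments import FragmentLengthDistribution
from meicall.model import MEAnnotation, MEFamily, ReadPair
from meicall.rp import (
    ClusterSide,
    cluster_by_center,
    fragment_center,
    pair_clusters_to_events,
)

from .conftest import make_read


def _fld(median=500, lib="lib0"):
    return FragmentLengthDistribution.from_lengths(lib, [median] * 2000)


def _anchor_pair(pos, strand, name="f", rl=100, lib="lib0"):
    """RP-candidate pair: genome anchor plus unmapped annotated mate."""
    anchor = make_read(
        name=name, pos=pos, cigar=f"{rl}M", strand=strand,
        ann=MEAnnotation(MEFamily.ALU), lib=lib,
    )
    from meicall.model import AlignedRead

    mate = AlignedRead(name, None, None, "", "A" * rl, 0, "-" if strand == "+" else "+")
    return ReadPair(anchor, mate)


class TestFragmentCenter:
    def test_plus_strand_formula(self):
        # 1-based anchor at 10,000, median 500 -> center 10,250
        pair = _anchor_pair(pos=9_999, strand="+")
        assert fragment_center(pair, _fld(500)) == 10_250

    def test_degenerate_median_zero_is_anchor(self):
        pair = _anchor_pair(pos=9_999, strand="+")
        fld = FragmentLengthDistribution.from_lengths("lib0", [1] * 10)
        assert fragment_center(pair, fld) == 10_000

    def test_minus_strand_mirrors_plus(self):
        # minus anchor ending at 10,500 (1-based), median 500 -> 10,250
        pair = _anchor_pair(pos=10_400, strand="-")
        assert fragment_center(pair, _fld(500)) == 10_250

    def test_mirror_symmetry_on_simulated_fragments(self):
        """Plus and minus anchors of the same median-length fragment give
        centers within one base of each other."""
        fld = _fld(500)
        rng = np.random.default_rng(0)
        for start in rng.integers(1000, 10_000, 50):
            start = int(start)
            plus = _anchor_pair(pos=start - 1, strand="+")  # leftmost mate
            minus = _anchor_pair(pos=start + 500 - 100, strand="-")  # rightmost
            c_plus = fragment_center(plus, fld)
            c_minus = fragment_center(minus, fld)
            assert abs(c_plus - c_minus) <= 1


def _pairs_at_centers(centers, fld, strand="+"):
    """Pairs whose fragment centers equal the given values exactly."""
    half = round(fld.median / 2)
    out = []
    for i, c in enumerate(sorted(centers)):
        out.append(_anchor_pair(pos=c - half - 1, strand=strand, name=f"f{i}"))
    return out


def single_linkage_oracle(centers, cutoff):
    """O(n^2) single-linkage partition of sorted centers."""
    centers = sorted(centers)
    clusters = [[c] for c in centers]
    merged = True
    while merged:
        merged = False
        for i in range(len(clusters) - 1):
            if any(
                abs(a - b) <= cutoff for a in clusters[i] for b in clusters[i + 1]
            ):
                clusters[i] += clusters.pop(i + 1)
                merged = True
                break
    return [sorted(c) for c in clusters]


class TestClustering:
    def test_close_centers_one_cluster(self):
        fld = _fld(500)
        pairs = _pairs_at_centers([100_000, 100_005, 100_010], fld)
        clusters = cluster_by_center(
            pairs, {"lib0": fld}, MEFamily.ALU, ClusterSide.FIVE_PRIME, "chr1",
            window=50,
        )
        assert len(clusters) == 1
        assert clusters[0].support == 3

    def test_distant_centers_split(self):
        fld = _fld(500)
        pairs = _pairs_at_centers([100_000, 105_000], fld)
        clusters = cluster_by_center(
            pairs, {"lib0": fld}, MEFamily.ALU, ClusterSide.FIVE_PRIME, "chr1",
            window=50,
        )
        assert [c.support for c in clusters] == [1, 1]

    def test_unsorted_input_raises(self):
        fld = _fld(500)
        pairs = _pairs_at_centers([100_000, 100_500], fld)[::-1]
        with pytest.raises(ValueError):
            cluster_by_center(
                pairs, {"lib0": fld}, MEFamily.ALU, ClusterSide.FIVE_PRIME, "chr1",
                window=50,
            )

    def test_matches_single_linkage_oracle(self):
        rng = np.random.default_rng(8)
        fld = _fld(500)
        centers = sorted(int(c) for c in rng.integers(0, 20_000, 200) + 10_000)
        pairs = _pairs_at_centers(centers, fld)
        clusters = cluster_by_center(
            pairs, {"lib0": fld}, MEFamily.ALU, ClusterSide.FIVE_PRIME, "chr1",
            window=75,
        )
        got = [c.centers for c in clusters]
        assert got == single_linkage_oracle(centers, 75)

    def test_partitions_nest_under_smaller_window(self):
        rng = np.random.default_rng(9)
        fld = _fld(500)
        centers = sorted(int(c) for c in rng.integers(0, 5_000, 100) + 10_000)
        pairs = _pairs_at_centers(centers, fld)

        def partition(w):
            return [
                tuple(c.centers)
                for c in cluster_by_center(
                    pairs, {"lib0": fld}, MEFamily.ALU, ClusterSide.FIVE_PRIME,
                    "chr1", window=w,
                )
            ]

        coarse = partition(100)
        fine = partition(20)
        # every fine cluster is contained in exactly one coarse cluster
        for f in fine:
            assert sum(1 for c in coarse if set(f) <= set(c)) == 1


class TestClusterPairing:
    def _cluster(self, side, pos_list, strand):
        fld = _fld(500)
        pairs = [
            _anchor_pair(pos=p, strand=strand, name=f"{side.value}{i}")
            for i, p in enumerate(pos_list)
        ]
        clusters = cluster_by_center(
            sorted(pairs, key=lambda pr: fragment_center(pr, fld)),
            {"lib0": fld}, MEFamily.ALU, side, "chr1", window=10**6,
        )
        assert len(clusters) == 1
        return clusters[0]

    def test_breakpoint_leftmost_convention(self):
        fld = _fld(500)
        five = self._cluster(ClusterSide.FIVE_PRIME, [10_040, 10_140], "+")  # ends 10,240
        three = self._cluster(ClusterSide.THREE_PRIME, [10_259, 10_359], "-")  # starts 10,260
        events = pair_clusters_to_events([five, three], {"lib0": fld})
        assert len(events) == 1
        ev = events[0]
        assert ev.breakpoint == 10_240
        assert (ev.ci_low, ev.ci_high) == (10_240, 10_260)

    def test_lone_cluster_yields_no_event(self):
        fld = _fld(500)
        five = self._cluster(ClusterSide.FIVE_PRIME, [10_040], "+")
        assert pair_clusters_to_events([five], {"lib0": fld}) == []

    def test_crossing_clusters_swapped_into_order(self):
        fld = _fld(500)
        five = self._cluster(ClusterSide.FIVE_PRIME, [10_050, 10_150], "+")  # ends 10,250
        three = self._cluster(ClusterSide.THREE_PRIME, [10_229, 10_329], "-")  # starts 10,230
        events = pair_clusters_to_events([five, three], {"lib0": fld})
        assert events[0].breakpoint == 10_230
        assert (events[0].ci_low, events[0].ci_high) == (10_230, 10_250)

    def test_each_cluster_pairs_at_most_once_nearest_first(self):
        """Exhaustive check on a toy set: 2x 5' and 2x 3' clusters pair
        nearest-first one-to-one."""
        fld = _fld(500)
        f1 = self._cluster(ClusterSide.FIVE_PRIME, [10_000], "+")  # ends 10,100
        f2 = self._cluster(ClusterSide.FIVE_PRIME, [10_300], "+")  # ends 10,400
        t1 = self._cluster(ClusterSide.THREE_PRIME, [10_109], "-")  # starts 10,110
        t2 = self._cluster(ClusterSide.THREE_PRIME, [10_409], "-")  # starts 10,410
        events = pair_clusters_to_events([f1, f2, t1, t2], {"lib0": fld})
        assert len(events) == 2
        assert {(e.ci_low, e.ci_high) for e in events} == {
            (10_100, 10_110),
            (10_400, 10_410),
        }

    def test_out_of_range_clusters_do_not_pair(self):
        fld = _fld(500)
        five = self._cluster(ClusterSide.FIVE_PRIME, [10_000], "+")
        three = self._cluster(ClusterSide.THREE_PRIME, [20_000], "-")
        assert pair_clusters_to_events([five, three], {"lib0": fld}) == []
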