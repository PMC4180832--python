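"""Per-library empirical fragment (insert) length model.

The detector's discordance tests, clustering scale and proximity filter
all derive from the library insert-size distribution, estimated from
NORMAL read pairs.  The model is fully empirical (a histogram of observed
outermost-base spans): quantiles are exact and no distributional family
is assumed.  Libraries are never pooled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping

import numpy as np

DEFAULT_MIN_PAIRS = 1000


class InsufficientPairsError(ValueError):
    pass


@dataclass
class FragmentLengthDistribution:
    """Empirical insert-size distribution for one library.

    Attributes
    ----------
    library_id : str
    lengths : np.ndarray
        Sorted unique observed lengths (bp).
    counts : np.ndarray
        Histogram counts aligned with ``lengths``.
    """

    library_id: str
    lengths: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.lengths.size == 0:
            raise ValueError("empty fragment length distribution")
        if np.any(self.lengths <= 0):
            raise ValueError("fragment lengths must be positive")
        order = np.argsort(self.lengths)
        self.lengths = self.lengths[order]
        self.counts = self.counts[order]
        self._cum = np.cumsum(self.counts)

    @classmethod
    def from_lengths(cls, library_id: str, lengths: Iterable[int]) -> "FragmentLengthDistribution":
        arr = np.asarray(list(lengths), dtype=np.int64)
        vals, counts = np.unique(arr, return_counts=True)
        return cls(library_id, vals, counts)

    @property
    def n(self) -> int:
        return int(self._cum[-1])

    def cdf(self, length: int) -> float:
        """Empirical P(X <= length)."""
        idx = np.searchsorted(self.lengths, length, side="right")
        return float(self._cum[idx - 1] / self.n) if idx > 0 else 0.0

    def quantile(self, q: float) -> int:
        """Smallest observed length with CDF >= q."""
        if not 0.0 < q <= 1.0:
            raise ValueError("quantile requires 0 < q <= 1")
        target = q * self.n
        idx = int(np.searchsorted(self._cum, target, side="left"))
        idx = min(idx, self.lengths.size - 1)
        return int(self.lengths[idx])

    @property
    def median(self) -> int:
        return self.quantile(0.5)

    @property
    def sd(self) -> float:
        mean = float(np.average(self.lengths, weights=self.counts))
        var = float(np.average((self.lengths - mean) ** 2, weights=self.counts))
        return var**0.5

    def pvalue(self, length: int) -> float:
        """Two-sided empirical tail probability of an insert length.

        2 * min(P(X <= length), P(X >= length)), capped at 1.  Values at
        the distribution's center return 1; values outside the observed
        support return 0.
        """
        if length <= 0:
            raise ValueError("fragment length must be positive")
        lower = self.cdf(length)
        upper = 1.0 - self.cdf(length - 1)
        return min(1.0, 2.0 * min(lower, upper))

    def max_expected_fragment_length(self, p: float = 0.005) -> int:
        """Smallest length L with upper-tail probability P(X > L) <= p.

        This is the scale used for the reference-ME proximity filter and
        the RP cluster neighborhood; equivalently ``quantile(1 - p)``.
        """
        if not 0.0 < p < 1.0:
            raise ValueError("p must be in (0, 1)")
        return self.quantile(1.0 - p)

    def to_tsv(self) -> str:
        lines = ["length\tcount"]
        lines += [f"{l}\t{c}" for l, c in zip(self.lengths, self.counts)]
        return "\n".join(lines) + "\n"


def estimate_fragment_distributions(
    pairs: Iterable,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> Dict[str, FragmentLengthDistribution]:
    """Estimate one insert-size distribution per library from NORMAL pairs.

    Parameters
    ----------
    pairs : iterable of ReadPair
        Pairs already vetted as NORMAL (uniquely mapped, same chromosome,
        convergent, no substantial clipping); estimation itself only needs
        their fragment lengths and library ids.
    min_pairs : int
        Minimum pairs per library; a library below this raises
        :class:`InsufficientPairsError` naming it.
    """
    by_lib: Dict[str, list] = {}
    for p in pairs:
        flen = p.fragment_length
        if flen is None or flen <= 0:
            continue
        by_lib.setdefault(p.library_id, []).append(flen)
    out: Dict[str, FragmentLengthDistribution] = {}
    for lib, lens in sorted(by_lib.items()):
        if len(lens) < min_pairs:
            raise InsufficientPairsError(
                f"library {lib!r}: {len(lens)} normal pairs < required {min_pairs}"
            )
        out[lib] = FragmentLengthDistribution.from_lengths(lib, lens)
    return out


def fragment_pvalue(fld: FragmentLengthDistribution, length: int) -> float:
    """Functional alias for :meth:`FragmentLengthDistribution.pvalue`."""
    return fld.pvalue(length)


def max_expected_fragment_length(fld: FragmentLengthDistribution, p: float = 0.005) -> int:
    """Functional alias for :meth:`FragmentLengthDistribution.max_expected_fragment_length`."""
    return fld.max_expected_fragment_length(p)


def max_fld_distance(flds: Mapping[str, FragmentLengthDistribution], p: float = 0.005) -> int:
    """Largest max-expected-fragment-length across libraries (conservative)."""
    return max(f.max_expected_fragment_length(p) for f in flds.values())
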