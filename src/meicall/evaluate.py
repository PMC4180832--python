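"""Evaluation against simulation truth: matching, sensitivity
decomposition, genotype accuracy, breakpoint resolution, AFS.

A call matches a truth locus when the two lie within a fixed window
(default 500 bp) on the same chromosome with the same family; matching
is one-to-one, nearest first.  Sensitivity is decomposed by the signal
class that would retain the call on its own: RP (>=2 fragments on both
sides), SR (>=2 split fragments), their exclusive parts, and the union.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .pipeline import MEICall
from .simulate import TruthInsertion

DEFAULT_MATCH_WINDOW = 500

PLOIDY_TO_GENOTYPE = {"HET": "REF/MEI", "HOM": "MEI/MEI"}


@dataclass
class Matching:
    matched: List[Tuple[MEICall, TruthInsertion, int]]
    false_positives: List[MEICall]
    false_negatives: List[TruthInsertion]

    @property
    def n_truth(self) -> int:
        return len(self.matched) + len(self.false_negatives)


def match_calls_to_truth(
    calls: Sequence[MEICall],
    truths: Sequence[TruthInsertion],
    window: int = DEFAULT_MATCH_WINDOW,
    exhaustive: bool = False,
) -> Matching:
    """Greedy nearest-first one-to-one matching within ``window``.

    With ``exhaustive=True`` an optimal assignment (minimum total
    distance over all one-to-one matchings of maximum size) is computed
    by brute force — intended for oracle checks on toy inputs only.
    """
    edges = []
    for i, c in enumerate(calls):
        for j, t in enumerate(truths):
            if c.chrom != t.chrom or c.family != t.family:
                continue
            d = abs(c.breakpoint - t.position)
            if d <= window:
                edges.append((d, c.breakpoint, i, j))
    if exhaustive:
        pairs = _optimal_assignment(edges, len(calls), len(truths))
    else:
        edges.sort()
        used_c: set = set()
        used_t: set = set()
        pairs = []
        for d, _, i, j in edges:
            if i in used_c or j in used_t:
                continue
            used_c.add(i)
            used_t.add(j)
            pairs.append((i, j, d))
    mi = {i for i, _, _ in pairs}
    mj = {j for _, j, _ in pairs}
    return Matching(
        matched=[(calls[i], truths[j], d) for i, j, d in pairs],
        false_positives=[c for i, c in enumerate(calls) if i not in mi],
        false_negatives=[t for j, t in enumerate(truths) if j not in mj],
    )


def _optimal_assignment(edges, n_calls, n_truth):
    best: List[Tuple[int, int, int]] = []
    best_cost = None
    edges = sorted(edges)

    def rec(k, used_c, used_t, acc):
        nonlocal best, best_cost
        if k == len(edges):
            cost = sum(d for _, _, d in acc)
            if len(acc) > len(best) or (len(acc) == len(best) and (best_cost is None or cost < best_cost)):
                best = list(acc)
                best_cost = cost
            return
        d, _, i, j = edges[k]
        rec(k + 1, used_c, used_t, acc)
        if i not in used_c and j not in used_t:
            rec(k + 1, used_c | {i}, used_t | {j}, acc + [(i, j, d)])

    rec(0, frozenset(), frozenset(), [])
    return best


def _has_rp(call: MEICall, min_support: int = 2) -> bool:
    c = call.candidate
    return c.rp_support_5p >= min_support and c.rp_support_3p >= min_support


def _has_sr(call: MEICall, min_support: int = 2) -> bool:
    return call.candidate.sr_support >= min_support


@dataclass
class EvaluationReport:
    n_truth: int
    n_calls: int
    sensitivity_rp: float
    sensitivity_sr: float
    sensitivity_rp_only: float
    sensitivity_sr_only: float
    sensitivity_union: float
    fdr: float
    genotype_accuracy_het: Optional[float]
    genotype_accuracy_hom: Optional[float]
    genotype_accuracy_weighted: Optional[float]
    breakpoint_deltas: Dict[int, int]
    breakpoint_exact_fraction: float
    breakpoint_within15_fraction: float
    notes: List[str] = field(default_factory=list)

    def to_dict(self) -> Dict:
        d = self.__dict__.copy()
        d["breakpoint_deltas"] = {str(k): v for k, v in self.breakpoint_deltas.items()}
        return d


def genotype_correct(call: MEICall, truth: TruthInsertion, sample_id: str) -> bool:
    gt = call.genotypes.get(sample_id)
    if gt is None:
        return False
    return gt.genotype == PLOIDY_TO_GENOTYPE[truth.ploidy]


def weighted_genotype_accuracy(
    tp_records: Sequence[Tuple[str, bool]],
    n_het: int = 400,
    n_hom: int = 100,
    repeats: int = 5,
    seed: int = 0,
) -> Tuple[float, List[str]]:
    """Average genotype concordance over seeded 4:1 het:hom draws.

    ``tp_records`` is (ploidy, correct) per true-positive locus.  Draws
    are without replacement; when fewer loci are available than the draw
    size, all are used (noted in the returned log).
    """
    notes: List[str] = []
    het = [ok for pl, ok in tp_records if pl == "HET"]
    hom = [ok for pl, ok in tp_records if pl == "HOM"]
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(repeats):
        take_het = het if len(het) <= n_het else list(
            np.array(het, dtype=bool)[rng.choice(len(het), n_het, replace=False)]
        )
        take_hom = hom if len(hom) <= n_hom else list(
            np.array(hom, dtype=bool)[rng.choice(len(hom), n_hom, replace=False)]
        )
        sel = list(take_het) + list(take_hom)
        if not sel:
            raise ValueError("no true-positive loci to draw from")
        accs.append(sum(sel) / len(sel))
    if len(het) < n_het or len(hom) < n_hom:
        notes.append(
            f"weighted draw fell back to all available loci "
            f"({len(het)} het, {len(hom)} hom)"
        )
    return float(np.mean(accs)), notes


def evaluate(
    calls: Sequence[MEICall],
    truths: Sequence[TruthInsertion],
    sample_id: str = "sample0",
    window: int = DEFAULT_MATCH_WINDOW,
    n_het_draw: int = 400,
    n_hom_draw: int = 100,
    repeats: int = 5,
    seed: int = 0,
) -> EvaluationReport:
    """Full evaluation of a callset against simulation truth."""
    m = match_calls_to_truth(calls, truths, window)
    n_truth = len(truths)
    notes: List[str] = []

    def frac(pred) -> float:
        if n_truth == 0:
            return 0.0
        return sum(1 for c, t, _ in m.matched if pred(c)) / n_truth

    sen_rp = frac(_has_rp)
    sen_sr = frac(_has_sr)
    sen_rp_only = frac(lambda c: _has_rp(c) and not _has_sr(c))
    sen_sr_only = frac(lambda c: _has_sr(c) and not _has_rp(c))
    sen_union = frac(lambda c: True)
    fdr = len(m.false_positives) / len(calls) if calls else 0.0

    het_ok = [genotype_correct(c, t, sample_id) for c, t, _ in m.matched if t.ploidy == "HET"]
    hom_ok = [genotype_correct(c, t, sample_id) for c, t, _ in m.matched if t.ploidy == "HOM"]
    acc_het = sum(het_ok) / len(het_ok) if het_ok else None
    acc_hom = sum(hom_ok) / len(hom_ok) if hom_ok else None
    tp_records = [(t.ploidy, genotype_correct(c, t, sample_id)) for c, t, _ in m.matched]
    if tp_records:
        acc_weighted, wnotes = weighted_genotype_accuracy(
            tp_records, n_het_draw, n_hom_draw, repeats, seed
        )
        notes.extend(wnotes)
    else:
        acc_weighted = None

    deltas: Dict[int, int] = {}
    for _, _, d in m.matched:
        deltas[d] = deltas.get(d, 0) + 1
    n_matched = len(m.matched)
    exact = deltas.get(0, 0) / n_matched if n_matched else 0.0
    within15 = (
        sum(v for k, v in deltas.items() if k <= 15) / n_matched if n_matched else 0.0
    )

    return EvaluationReport(
        n_truth=n_truth,
        n_calls=len(calls),
        sensitivity_rp=sen_rp,
        sensitivity_sr=sen_sr,
        sensitivity_rp_only=sen_rp_only,
        sensitivity_sr_only=sen_sr_only,
        sensitivity_union=sen_union,
        fdr=fdr,
        genotype_accuracy_het=acc_het,
        genotype_accuracy_hom=acc_hom,
        genotype_accuracy_weighted=acc_weighted,
        breakpoint_deltas=deltas,
        breakpoint_exact_fraction=exact,
        breakpoint_within15_fraction=within15,
        notes=notes,
    )


def allele_frequency_spectrum(
    genotypes_by_locus: Sequence[Mapping[str, str]],
    bins: int = 20,
) -> Tuple[np.ndarray, np.ndarray, List[float]]:
    """Normalized alternate-allele frequency spectrum across samples.

    Each locus is a mapping sample -> genotype label (``REF/REF``,
    ``REF/MEI`` or ``MEI/MEI``); the per-locus frequency is the MEI
    allele count over 2x the called samples.  Returns (bin_edges,
    normalized_histogram, frequencies); the histogram sums to 1.
    """
    alt_count = {"REF/REF": 0, "REF/MEI": 1, "MEI/MEI": 2}
    freqs = []
    for locus in genotypes_by_locus:
        called = [g for g in locus.values() if g in alt_count]
        if not called:
            continue
        freqs.append(sum(alt_count[g] for g in called) / (2 * len(called)))
    if not freqs:
        raise ValueError("no called loci")
    edges = np.linspace(0.0, 1.0, bins + 1)
    hist, _ = np.histogram(freqs, bins=edges)
    return edges, hist / hist.sum(), freqs
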