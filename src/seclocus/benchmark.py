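"""ROC benchmarking of gene-neighbor scores against complex/pathway truth.

Truth sets of functionally associated pairs come from shared membership:
two proteins are a true pair when they share at least one complex (or
pathway, or both). The universe is every unordered pair over the scored
proteome. A threshold sweep then classifies each pair as interacting when
its neighbor score is at least the threshold, giving a confusion matrix
and the ROC coordinates sensitivity = TP/(TP+FN) and
1 - specificity = FP/(FP+TN) at every threshold. Pairs without a reported
score default to score 0 (optionally they can be excluded from the
universe instead).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


@dataclass(frozen=True)
class TruthSets:
    pairs_complexes: frozenset[Pair]
    pairs_pathways: frozenset[Pair]
    universe: frozenset[Pair]

    @property
    def pairs_both(self) -> frozenset[Pair]:
        return self.pairs_complexes & self.pairs_pathways

    def __post_init__(self) -> None:
        for pairs in (self.pairs_complexes, self.pairs_pathways):
            if not pairs <= self.universe:
                raise ValueError("truth pairs outside the scored universe")


@dataclass(frozen=True)
class ConfusionCounts:
    threshold: float
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("negative confusion count")


@dataclass(frozen=True)
class ROCPoint:
    threshold: float
    sensitivity: float
    one_minus_specificity: float

    def __post_init__(self) -> None:
        if not (0 <= self.sensitivity <= 1 and 0 <= self.one_minus_specificity <= 1):
            raise ValueError("ROC coordinates outside [0, 1]")


def _canonical(a: str, b: str) -> Pair:
    return (a, b) if a < b else (b, a)


def build_truth_sets(
    complex_membership: Mapping[str, Iterable[str]],
    pathway_membership: Mapping[str, Iterable[str]],
    scored_proteins: Iterable[str],
) -> TruthSets:
    """Expand group memberships into unordered true pairs over the universe.

    Proteins absent from ``scored_proteins`` are dropped before pair
    expansion; groups left with fewer than two scored members contribute
    nothing (logged). Self-pairs never occur.
    """
    scored = frozenset(scored_proteins)
    universe = frozenset(
        _canonical(a, b) for a, b in itertools.combinations(sorted(scored), 2)
    )

    def expand(membership: Mapping[str, Iterable[str]]) -> frozenset[Pair]:
        pairs: set[Pair] = set()
        for gid, members in membership.items():
            usable = sorted(set(members) & scored)
            if len(usable) < 2:
                logger.info("group %s has < 2 scored members; no pairs", gid)
                continue
            pairs.update(itertools.combinations(usable, 2))
        return frozenset(pairs)

    return TruthSets(
        pairs_complexes=expand(complex_membership),
        pairs_pathways=expand(pathway_membership),
        universe=universe,
    )


def pair_scores(
    score_table: Mapping[Pair, float],
    universe: Iterable[Pair],
    group_of: Mapping[str, str] | None = None,
    exclude_unscored: bool = False,
) -> dict[Pair, float]:
    """Score every universe pair, optionally via a protein-to-group map.

    When ``group_of`` is given, scores are looked up by the proteins'
    orthologous groups, and pairs whose proteins map to the same group are
    dropped (self-association carries no neighbor-score signal). Unscored
    pairs default to 0 unless ``exclude_unscored``.
    """
    out: dict[Pair, float] = {}
    for a, b in universe:
        if group_of is not None:
            ga, gb = group_of.get(a), group_of.get(b)
            if ga is None or gb is None or ga == gb:
                continue
            key = _canonical(ga, gb)
        else:
            key = _canonical(a, b)
        if key in score_table:
            out[(a, b)] = score_table[key]
        elif not exclude_unscored:
            out[(a, b)] = 0.0
    return out


def roc_sweep(
    scores: Mapping[Pair, float],
    truth_pairs: Iterable[Pair],
    thresholds: Sequence[float] | None = None,
) -> tuple[list[ConfusionCounts], list[ROCPoint]]:
    """Sweep score thresholds over the scored universe.

    At threshold t a pair is predicted interacting iff its score >= t.
    ``thresholds`` defaults to the integers 0..905. The universe is the
    key set of ``scores``; the truth set must be non-empty and contained
    in it.
    """
    truth = frozenset(truth_pairs)
    if not truth:
        raise ValueError("empty truth set")
    universe = frozenset(scores)
    if not truth <= universe:
        raise ValueError("truth pairs outside the scored universe")
    if thresholds is None:
        thresholds = np.arange(0, 906)
    thresholds = np.asarray(thresholds, dtype=float)

    pos_scores = np.sort([scores[p] for p in truth])
    neg_scores = np.sort([scores[p] for p in universe - truth])
    n_pos, n_neg = len(pos_scores), len(neg_scores)

    confusion: list[ConfusionCounts] = []
    points: list[ROCPoint] = []
    for t in thresholds:
        tp = int(n_pos - np.searchsorted(pos_scores, t, side="left"))
        fp = int(n_neg - np.searchsorted(neg_scores, t, side="left"))
        fn, tn = n_pos - tp, n_neg - fp
        confusion.append(ConfusionCounts(float(t), tp, fp, tn, fn))
        points.append(
            ROCPoint(
                float(t),
                tp / n_pos,
                fp / n_neg if n_neg else 0.0,
            )
        )
    return confusion, points


def roc_auc(points: Sequence[ROCPoint]) -> float:
    """Trapezoidal area under the swept ROC curve (sorted by x)."""
    xs = np.array([p.one_minus_specificity for p in points])
    ys = np.array([p.sensitivity for p in points])
    order = np.argsort(xs, kind="stable")
    return float(np.trapezoid(ys[order], xs[order]))
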