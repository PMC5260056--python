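"""Benchmarking against a gold-standard edge set.

The evaluation universe is every unordered non-self gene pair over the gold
standard's gene list.  Gold standards are symmetrised: a directed reference
edge A->B marks the unordered pair {A, B} positive, because the inferred
networks carry no direction.  From a predicted edge set the four-way
confusion is

    TP  predicted and in gold      FP  predicted, not in gold
    FN  in gold, not predicted     TN  neither

with TPR = TP/(TP+FN), FPR = FP/(TN+FP), PPV = TP/(TP+FP) and
ACC = (TP+TN)/total; a zero denominator leaves the metric undefined (None).

Ranked evaluation sorts pairs by descending score, treats tied scores as a
single threshold step, and integrates both the ROC curve (FPR, TPR) and the
raw precision-recall points by the trapezoidal rule.

Two threshold-quality tools close the loop: the "true threshold" is the grid
cutoff whose network maximises accuracy against the gold standard (smallest
such cutoff on ties), and the offset score is the |true - predicted| distance
normalised by the grid range, in percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InvalidInputError, UndefinedCurveError
from .inference import InferenceConfig, infer_network
from .io import ExpressionMatrix


def _ordered(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class GoldStandard:
    """Reference edge set: positive unordered pairs over a gene universe."""

    positive_pairs: frozenset[tuple[str, str]]
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        genes = tuple(str(g) for g in self.genes)
        known = set(genes)
        pairs = frozenset(_ordered(str(a), str(b)) for a, b in self.positive_pairs)
        for a, b in pairs:
            if a == b:
                raise InvalidInputError(f"self-pair {a!r} in gold standard")
            if a not in known or b not in known:
                raise InvalidInputError(f"gold pair ({a!r}, {b!r}) references unknown gene")
        object.__setattr__(self, "positive_pairs", pairs)
        object.__setattr__(self, "genes", genes)

    def universe(self) -> list[tuple[str, str]]:
        """All unordered non-self pairs over the gene list, sorted."""
        g = sorted(self.genes)
        return [(g[i], g[j]) for i in range(len(g)) for j in range(i + 1, len(g))]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class ScoreSummary:
    """Point metrics; None marks a metric with a zero denominator."""

    TPR: float | None
    FPR: float | None
    PPV: float | None
    ACC: float | None


def confusion(predicted_pairs: Iterable[tuple[str, str]], gold: GoldStandard) -> ConfusionCounts:
    """Four-way confusion of a predicted edge set against the gold standard."""
    known = set(gold.genes)
    predicted = set()
    for a, b in predicted_pairs:
        a, b = str(a), str(b)
        if a not in known or b not in known:
            raise InvalidInputError(f"predicted pair ({a!r}, {b!r}) references unknown gene")
        predicted.add(_ordered(a, b))
    tp = fp = tn = fn = 0
    positives = gold.positive_pairs
    for pair in gold.universe():
        if pair in positives:
            if pair in predicted:
                tp += 1
            else:
                fn += 1
        elif pair in predicted:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def classification_metrics(counts: ConfusionCounts) -> ScoreSummary:
    """TPR/FPR/PPV/ACC from confusion counts; zero denominators give None."""

    def ratio(num: int, den: int) -> float | None:
        return num / den if den else None

    return ScoreSummary(
        TPR=ratio(counts.TP, counts.TP + counts.FN),
        FPR=ratio(counts.FP, counts.TN + counts.FP),
        PPV=ratio(counts.TP, counts.TP + counts.FP),
        ACC=ratio(counts.TP + counts.TN, counts.total),
    )


@dataclass(frozen=True)
class RankedCurves:
    """ROC and PR curves with their trapezoidal areas."""

    roc_points: np.ndarray  # columns (FPR, TPR)
    pr_points: np.ndarray  # columns (recall, precision)
    auroc: float
    aupr: float


def roc_pr_curves(pair_scores: Mapping[tuple[str, str], float], gold: GoldStandard) -> RankedCurves:
    """Ranked-threshold ROC and PR curves over the gold universe.

    Pairs absent from ``pair_scores`` score 0 (never evaluated means never
    ranked above an evaluated pair).  Equal scores collapse into one
    threshold step, so ties cannot be ordered favourably.
    """
    universe = gold.universe()
    normalized = {_ordered(str(a), str(b)): float(s) for (a, b), s in pair_scores.items()}
    labels = np.array([pair in gold.positive_pairs for pair in universe], dtype=bool)
    scores = np.array([normalized.get(pair, 0.0) for pair in universe])
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedCurveError("ROC/PR need at least one positive and one negative pair")

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    # indices of the last element of each tied-score block
    block_ends = np.nonzero(np.diff(sorted_scores) != 0)[0]
    block_ends = np.append(block_ends, sorted_scores.size - 1)
    cum_tp = np.cumsum(sorted_labels)[block_ends]
    cum_fp = (block_ends + 1) - cum_tp

    tpr = cum_tp / n_pos
    fpr = cum_fp / n_neg
    recall = tpr
    precision = cum_tp / (cum_tp + cum_fp)

    roc = np.column_stack((np.concatenate(([0.0], fpr)), np.concatenate(([0.0], tpr))))
    pr = np.column_stack((np.concatenate(([0.0], recall)), np.concatenate(([precision[0]], precision))))
    auroc = float(np.trapezoid(roc[:, 1], roc[:, 0]))
    aupr = float(np.trapezoid(pr[:, 1], pr[:, 0]))
    return RankedCurves(roc_points=roc, pr_points=pr, auroc=auroc, aupr=aupr)


def threshold_offset(true_threshold: float, predicted_threshold: float, grid_min: float, grid_max: float) -> float:
    """|true - predicted| normalised by the grid range, in percent."""
    if not grid_max > grid_min:
        raise InvalidInputError("grid_max must exceed grid_min")
    return abs(true_threshold - predicted_threshold) / (grid_max - grid_min) * 100.0


#: Offset (percent) bounds defining the stringent / standard / moderate
#: quality criteria for an automatically selected cutoff.
OFFSET_CRITERIA = {"stringent": 5.0, "standard": 10.0, "moderate": 20.0}


def offset_criteria_met(offset_percent: float) -> set[str]:
    """Which named offset criteria a given offset satisfies (offset < bound)."""
    return {name for name, bound in OFFSET_CRITERIA.items() if offset_percent < bound}


def true_threshold(
    expr: ExpressionMatrix,
    gold: GoldStandard,
    order: int,
    grid: Sequence[float],
    workers: int = 1,
) -> float:
    """Accuracy-maximising cutoff: run inference at the given order once per
    grid point and return the (smallest) cutoff whose network maximises ACC
    against the gold standard."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise InvalidInputError("grid must be a non-empty 1-D sequence")
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise InvalidInputError("grid must be strictly ascending")
    best_cutoff, best_acc = float(grid[0]), -np.inf
    for cutoff in grid:
        state = infer_network(
            expr,
            InferenceConfig(max_order=order, threshold_mode=float(cutoff), workers=workers),
        )
        acc = classification_metrics(confusion(state.edge_labels(), gold)).ACC
        if acc is not None and acc > best_acc:
            best_cutoff, best_acc = float(cutoff), acc
    return best_cutoff
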