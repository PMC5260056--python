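"""Order-stepping network inference by conditional-mutual-information pruning.

The reconstruction proceeds in orders.  Order 0 scores every gene pair by
mutual information and keeps pairs scoring strictly above the interaction
cutoff — a relevance network.  Each subsequent order ``k`` re-tests every
surviving edge (i, j): conditioning sets of size exactly ``k`` are drawn from
the pair's common neighbors (genes currently connected to both i and j), the
conditional mutual information is computed for every such set, and the
maximum CMI becomes the edge's new weight.  The edge survives iff that
maximum still exceeds the cutoff; an edge whose dependence is fully explained
by its neighbors (a chain or fan-out artifact) drops to near-zero CMI and is
pruned.  Edges with fewer than ``k`` common neighbors pass through unchanged.

Within an order all CMI computations use the adjacency snapshot taken at the
order's start and removals apply at the order's end.  This batch semantics
makes the result independent of edge processing order, which is what allows
pair chunks to be distributed across workers with a bit-identical result for
any worker count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from joblib import Parallel, delayed

from . import threshold as _threshold
from .errors import InvalidInputError
from .information import (
    CovarianceEstimate,
    conditional_mutual_information,
    mutual_information_matrix,
    sample_covariance,
)
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

#: Beyond this order the number of conditioning sets grows combinatorially;
#: runs are allowed but a warning is logged.
MAX_RECOMMENDED_ORDER = 3


@dataclass(frozen=True)
class NetworkState:
    """Weighted undirected network at a given pruning order.

    ``weights[i, j]`` holds the current score of pair (i, j): MI after order
    0, the maximum CMI recorded at the last order in which the edge was
    re-evaluated thereafter.  ``adjacency`` marks retained edges.  Both
    matrices are symmetric with the diagonal excluded from all edge logic.
    """

    gene_labels: tuple[str, ...]
    weights: np.ndarray
    adjacency: np.ndarray
    order_completed: int
    cutoffs_used: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        a = np.asarray(self.adjacency, dtype=bool)
        n = len(self.gene_labels)
        if w.shape != (n, n) or a.shape != (n, n):
            raise InvalidInputError("weights/adjacency shape must match gene count")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "adjacency", a)
        object.__setattr__(self, "gene_labels", tuple(self.gene_labels))
        object.__setattr__(self, "cutoffs_used", tuple(self.cutoffs_used))

    @property
    def n_genes(self) -> int:
        return len(self.gene_labels)

    def edge_count(self) -> int:
        return int(np.triu(self.adjacency, k=1).sum())

    def edges(self) -> list[tuple[int, int]]:
        """Retained edges as index pairs (i < j)."""
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(ii.tolist(), jj.tolist()))

    def edge_labels(self) -> set[tuple[str, str]]:
        """Retained edges as lexically ordered label pairs."""
        out = set()
        for i, j in self.edges():
            a, b = self.gene_labels[i], self.gene_labels[j]
            out.add((a, b) if a <= b else (b, a))
        return out

    def pair_weights(self) -> dict[tuple[str, str], float]:
        """All pair scores as a lexically ordered label-pair mapping."""
        out = {}
        n = self.n_genes
        for i in range(n):
            for j in range(i + 1, n):
                a, b = self.gene_labels[i], self.gene_labels[j]
                key = (a, b) if a <= b else (b, a)
                out[key] = float(self.weights[i, j])
        return out


@dataclass(frozen=True)
class InferenceConfig:
    """Run configuration.

    ``threshold_mode`` is ``"auto"`` (cutoff recomputed at each order from
    the current weight distribution via the decay-curve method), a single
    float (same fixed cutoff at every order), or a per-order sequence of
    floats.  ``max_order`` defaults to 1: first-order pruning removes most
    indirect edges while keeping the conditioning-set enumeration cheap.
    """

    max_order: int = 1
    threshold_mode: str | float | Sequence[float] = "auto"
    workers: int = 1
    grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.max_order < 0:
            raise InvalidInputError("max_order must be >= 0")
        if self.max_order > MAX_RECOMMENDED_ORDER:
            logger.warning(
                "max_order=%d: cost grows combinatorially beyond order %d",
                self.max_order,
                MAX_RECOMMENDED_ORDER,
            )
        if self.workers < 1:
            raise InvalidInputError("workers must be >= 1")
        if isinstance(self.threshold_mode, str):
            if self.threshold_mode != "auto":
                raise InvalidInputError(f"unknown threshold mode {self.threshold_mode!r}")
        elif isinstance(self.threshold_mode, (int, float)):
            if self.threshold_mode < 0:
                raise InvalidInputError("fixed threshold must be >= 0")
        else:
            object.__setattr__(self, "threshold_mode", tuple(float(t) for t in self.threshold_mode))
            if len(self.threshold_mode) < self.max_order + 1:
                raise InvalidInputError("per-order threshold list must cover orders 0..max_order")

    def cutoff_for_order(self, order: int, weights: np.ndarray) -> float:
        """Resolve the cutoff to apply at ``order`` given current weights."""
        mode = self.threshold_mode
        if isinstance(mode, str):  # auto
            flat = weights[np.triu_indices(weights.shape[0], k=1)]
            return float(_threshold.auto_threshold(flat, self.grid))
        if isinstance(mode, tuple):
            return float(mode[order])
        return float(mode)


def partition_pairs(n_pairs: int, n_workers: int) -> list[tuple[int, int]]:
    """Split ``0..n_pairs-1`` into ``n_workers`` contiguous ranges whose
    sizes differ by at most one, remainder assigned to the leading chunks."""
    if n_workers < 1:
        raise InvalidInputError("n_workers must be >= 1")
    if n_pairs < 0:
        raise InvalidInputError("n_pairs must be >= 0")
    base, extra = divmod(n_pairs, n_workers)
    ranges, start = [], 0
    for w in range(n_workers):
        size = base + (1 if w < extra else 0)
        ranges.append((start, start + size))
        start += size
    return ranges


def initial_network(
    expr: ExpressionMatrix,
    cutoff: float,
    _cov: CovarianceEstimate | None = None,
) -> NetworkState:
    """Order-0 relevance network: all-pairs MI thresholded at ``cutoff``."""
    if expr.n_genes < 2:
        raise InvalidInputError("need at least 2 genes")
    if expr.n_conditions < 3:
        raise InvalidInputError("need at least 3 conditions")
    cov = _cov if _cov is not None else sample_covariance(expr.values)
    weights = mutual_information_matrix(cov)
    adjacency = weights > cutoff
    np.fill_diagonal(adjacency, False)
    return NetworkState(
        gene_labels=expr.gene_ids,
        weights=weights,
        adjacency=adjacency,
        order_completed=0,
        cutoffs_used=(float(cutoff),),
    )


def common_neighbors(state: NetworkState, i: int, j: int) -> tuple[int, ...]:
    """Genes adjacent to both ``i`` and ``j`` (excluding the pair itself),
    in ascending index order."""
    if i == j:
        raise InvalidInputError("common neighbors require two distinct genes")
    mask = state.adjacency[i] & state.adjacency[j]
    mask[i] = mask[j] = False
    return tuple(int(k) for k in np.nonzero(mask)[0])


def _max_cmi(cov_matrix: np.ndarray, i: int, j: int, neighbors: tuple[int, ...], k: int) -> float:
    cov = CovarianceEstimate(matrix=cov_matrix)
    return max(
        conditional_mutual_information(i, j, z, cov)
        for z in combinations(neighbors, k)
    )

def _score_chunk(cov_matrix: np.ndarray, tasks: list[tuple[int, int, tuple[int, ...]]], k: int) -> list[float]:
    return [_max_cmi(cov_matrix, i, j, nbrs, k) for i, j, nbrs in tasks]


def prune_step(
    state: NetworkState,
    k: int,
    cutoff: float,
    expr: ExpressionMatrix | None = None,
    _cov: CovarianceEstimate | None = None,
    workers: int = 1,
) -> NetworkState:
    """One pruning order: re-score eligible edges by max CMI over size-``k``
    conditioning sets drawn from common neighbors, drop those at or below
    ``cutoff``.

    Common neighbors are read from the adjacency snapshot at entry and
    removals are applied at the end, so the outcome is independent of edge
    ordering and of the worker partition.
    """
    if k < 1:
        raise InvalidInputError("prune order k must be >= 1")
    if state.order_completed != k - 1:
        raise InvalidInputError(
            f"state completed order {state.order_completed}; expected {k - 1} before pruning at order {k}"
        )
    if _cov is None:
        if expr is None:
            raise InvalidInputError("prune_step needs the expression matrix or its covariance")
        _cov = sample_covariance(expr.values)

    tasks: list[tuple[int, int, tuple[int, ...]]] = []
    for i, j in state.edges():
        nbrs = common_neighbors(state, i, j)
        if len(nbrs) >= k:
            tasks.append((i, j, nbrs))

    if tasks:
        cov_matrix = _cov.matrix
        if workers == 1 or len(tasks) < 2:
            scores = _score_chunk(cov_matrix, tasks, k)
        else:
            ranges = partition_pairs(len(tasks), workers)
            chunks = Parallel(n_jobs=workers)(
                delayed(_score_chunk)(cov_matrix, tasks[lo:hi], k) for lo, hi in ranges if hi > lo
            )
            scores = [s for chunk in chunks for s in chunk]
    else:
        scores = []

    weights = state.weights.copy()
    adjacency = state.adjacency.copy()
    for (i, j, _), score in zip(tasks, scores):
        weights[i, j] = weights[j, i] = score
        keep = score > cutoff
        adjacency[i, j] = adjacency[j, i] = keep

    return NetworkState(
        gene_labels=state.gene_labels,
        weights=weights,
        adjacency=adjacency,
        order_completed=k,
        cutoffs_used=state.cutoffs_used + (float(cutoff),),
    )


def infer_network(expr: ExpressionMatrix, config: InferenceConfig | None = None) -> NetworkState:
    """Full reconstruction: order 0 through ``config.max_order``.

    The cutoff at each order is resolved from ``config.threshold_mode``
    before that order's pruning; in auto mode it is recomputed from the
    weight distribution as it stands at that order.  Stops early when no
    surviving edge has enough common neighbors for the next order.
    """
    config = config or InferenceConfig()
    if expr.n_genes == 0 or expr.n_conditions == 0:
        raise InvalidInputError("empty expression matrix")
    cov = sample_covariance(expr.values)

    mi = mutual_information_matrix(cov)
    cutoff0 = config.cutoff_for_order(0, mi)
    state = initial_network(expr, cutoff0, _cov=cov)
    logger.info("order 0: cutoff %.6g, %d edges", cutoff0, state.edge_count())

    for k in range(1, config.max_order + 1):
        eligible = any(len(common_neighbors(state, i, j)) >= k for i, j in state.edges())
        if not eligible:
            logger.info("no edge has >= %d common neighbors; stopping early", k)
            break
        cutoff = config.cutoff_for_order(k, state.weights)
        state = prune_step(state, k, cutoff, _cov=cov, workers=config.workers)
        logger.info("order %d: cutoff %.6g, %d edges", k, cutoff, state.edge_count())

    return state
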