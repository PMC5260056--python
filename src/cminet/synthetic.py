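"""Ground-truth networks and linear-Gaussian expression for benchmarking.

A random DAG is drawn by permuting the genes into a topological order and
including each forward pair as an edge with probability ``avg_degree /
(n_genes - 1)``, giving an expected edge count of ``n_genes * avg_degree /
2``.  Expression follows the linear structural-equation model the Gaussian
CMI estimator assumes exactly:

    root genes      ~ N(0, 1)  i.i.d. per sample
    non-root gene g = sum_parents w_pg * x_p + N(0, noise_sd^2)

Edge weights are drawn from +/-[0.5, 1.5] so no effect is vanishingly small.
Chains (X <- Z -> Y and X -> Z -> Y) arise naturally and create the indirect
marginal correlations that order-1 pruning is meant to remove; the dedicated
:func:`chain_fixture` builds the minimal such motif with hand-computable
population values (unit-variance hub Z, child noise sd 0.5, so the indirect
pair has population correlation 0.8 and zero conditional dependence given Z).

Every generator output is a pure function of (seed, config): the DAG and the
noise draw their randomness from independent seeded streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .evaluation import GoldStandard
from .io import ExpressionMatrix


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters for one synthetic benchmark dataset."""

    n_genes: int
    n_samples: int
    avg_degree: float = 2.0
    weight_range: tuple[float, float] = (0.5, 1.5)
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise InvalidInputError("n_genes must be >= 1")
        if self.n_samples < 3:
            raise InvalidInputError("n_samples must be >= 3")
        if not 0 <= self.avg_degree < self.n_genes:
            raise InvalidInputError("avg_degree must satisfy 0 <= avg_degree < n_genes")
        if not 0 < self.weight_range[0] <= self.weight_range[1]:
            raise InvalidInputError("weight_range must be a positive interval (signs are drawn separately)")
        if self.noise_sd <= 0:
            raise InvalidInputError("noise_sd must be > 0")


@dataclass(frozen=True)
class SynthNetwork:
    """A ground-truth DAG: directed weighted edges over genes G1..Gn."""

    n_genes: int
    edges: tuple[tuple[int, int, float], ...]  # (parent, child, weight)
    topo_order: tuple[int, ...]

    def __post_init__(self) -> None:
        pos = {g: r for r, g in enumerate(self.topo_order)}
        for u, v, w in self.edges:
            if pos[u] >= pos[v]:
                raise InvalidInputError("edge violates the topological order (cycle)")
            if w == 0:
                raise InvalidInputError("edge weights must be non-zero")
        object.__setattr__(self, "edges", tuple(self.edges))
        object.__setattr__(self, "topo_order", tuple(self.topo_order))

    @property
    def gene_labels(self) -> tuple[str, ...]:
        return tuple(f"G{i + 1}" for i in range(self.n_genes))

    def gold_standard(self) -> GoldStandard:
        """The symmetrised gold standard: each directed edge as an unordered
        positive pair over the full gene universe."""
        labels = self.gene_labels
        pairs = set()
        for u, v, _ in self.edges:
            a, b = labels[u], labels[v]
            pairs.add((a, b) if a <= b else (b, a))
        return GoldStandard(positive_pairs=frozenset(pairs), genes=labels)


def random_dag(config: SynthConfig) -> SynthNetwork:
    """Sample a random DAG under the configured density (seeded)."""
    rng = np.random.default_rng([int(config.seed), 0])
    n = config.n_genes
    order = tuple(int(g) for g in rng.permutation(n))
    p = config.avg_degree / (n - 1) if n > 1 else 0.0
    if p > 1.0:
        raise InvalidInputError("avg_degree too high for this gene count")
    lo, hi = config.weight_range
    edges = []
    for a in range(n):
        for b in range(a + 1, n):
            if rng.random() < p:
                w = rng.uniform(lo, hi) * (1.0 if rng.random() < 0.5 else -1.0)
                edges.append((order[a], order[b], float(w)))
    return SynthNetwork(n_genes=n, edges=tuple(edges), topo_order=order)


def simulate_expression(network: SynthNetwork, config: SynthConfig) -> ExpressionMatrix:
    """Draw expression from the linear-Gaussian model on the given DAG.

    Roots are i.i.d. standard normal; every other gene is the weighted sum
    of its parents plus N(0, noise_sd^2) noise, generated in topological
    order.  Output is genes x samples.
    """
    if network.n_genes != config.n_genes:
        raise InvalidInputError("network and config disagree on gene count")
    rng = np.random.default_rng([int(config.seed), 1])
    n, m = network.n_genes, config.n_samples
    parents: dict[int, list[tuple[int, float]]] = {g: [] for g in range(n)}
    for u, v, w in network.edges:
        parents[v].append((u, w))
    values = np.zeros((n, m))
    for g in network.topo_order:
        if parents[g]:
            noise = rng.normal(0.0, config.noise_sd, size=m)
            values[g] = sum(w * values[u] for u, w in parents[g]) + noise
        else:
            values[g] = rng.normal(0.0, 1.0, size=m)
    return ExpressionMatrix(
        gene_ids=network.gene_labels,
        condition_ids=tuple(f"S{s + 1}" for s in range(m)),
        values=values,
    )


def chain_fixture(n_samples: int, seed: int) -> tuple[SynthNetwork, ExpressionMatrix]:
    """The minimal indirect-correlation motif: hub Z with children X and Y.

    True edges are Z-X and Z-Y only (genes G1 = X, G2 = Y, G3 = Z).  With a
    unit-variance hub and child noise sd 0.5 the population covariance of
    (X, Y, Z) is [[1.25, 1, 1], [1, 1.25, 1], [1, 1, 1]]: the untrue pair
    X-Y has correlation 0.8 (MI 0.5108 nats) marginally but is conditionally
    independent given Z, so first-order pruning should delete exactly it.
    """
    if n_samples < 100:
        raise InvalidInputError("chain fixture needs n_samples >= 100")
    network = SynthNetwork(
        n_genes=3,
        edges=((2, 0, 1.0), (2, 1, 1.0)),
        topo_order=(2, 0, 1),
    )
    config = SynthConfig(n_genes=3, n_samples=n_samples, noise_sd=0.5, seed=seed)
    return network, simulate_expression(network, config)


def chain_motif_network(n_motifs: int, seed: int) -> SynthNetwork:
    """A chain-rich ground truth: ``n_motifs`` independent serial chains
    A -> B -> C, each with seeded weights from +/-[0.5, 1.5].

    Every motif contributes one indirect pair (A, C) that is marginally
    correlated but conditionally independent given B — the regime where
    first-order pruning should beat plain relevance scoring.
    """
    if n_motifs < 1:
        raise InvalidInputError("need at least one motif")
    rng = np.random.default_rng([int(seed), 2])
    n = 3 * n_motifs
    edges = []
    for m in range(n_motifs):
        a, b, c = 3 * m, 3 * m + 1, 3 * m + 2
        for u, v in ((a, b), (b, c)):
            w = rng.uniform(0.5, 1.5) * (1.0 if rng.random() < 0.5 else -1.0)
            edges.append((u, v, float(w)))
    return SynthNetwork(n_genes=n, edges=tuple(edges), topo_order=tuple(range(n)))


def chain_population_covariance() -> np.ndarray:
    """Population covariance of the chain motif's (X, Y, Z)."""
    return np.array([[1.25, 1.0, 1.0], [1.0, 1.25, 1.0], [1.0, 1.0, 1.0]])
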