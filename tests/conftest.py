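"""Shared fixtures: random positive-definite covariances and small synthetic
expression datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from cminet import CovarianceEstimate, ExpressionMatrix


def random_spd(rng: np.random.Generator, dim: int) -> np.ndarray:
    """A well-conditioned random symmetric positive-definite matrix."""
    a = rng.normal(size=(dim, dim))
    return a @ a.T + 0.1 * np.eye(dim)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


@pytest.fixture
def toy_expression(rng) -> ExpressionMatrix:
    """Three genes: A and B tightly coupled, C independent (n = 500)."""
    a = rng.normal(size=500)
    b = a + rng.normal(scale=0.1, size=500)
    c = rng.normal(size=500)
    return ExpressionMatrix(
        gene_ids=("A", "B", "C"),
        condition_ids=tuple(f"S{i}" for i in range(500)),
        values=np.vstack([a, b, c]),
    )


@pytest.fixture
def chain_cov() -> CovarianceEstimate:
    """Population covariance of the hub motif X <- Z -> Y (unit-variance hub,
    child noise sd 0.5): [[1.25, 1, 1], [1, 1.25, 1], [1, 1, 1]]."""
    return CovarianceEstimate(np.array([[1.25, 1.0, 1.0], [1.0, 1.25, 1.0], [1.0, 1.0, 1.0]]))
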