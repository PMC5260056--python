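"""Gaussian entropy, mutual information and conditional mutual information.

All quantities are estimated under the multivariate-Gaussian assumption from
covariance determinants, in nats (natural logarithm throughout).  For a
variable set of dimension ``d`` with covariance matrix ``C`` the differential
entropy is

    H = 1/2 * ln((2*pi*e)^d * |C|)

and the conditional mutual information of two genes X, Y given a conditioning
gene set Z follows from the entropy combination
H(X,Z) + H(Y,Z) - H(Z) - H(X,Y,Z), which collapses to the determinant ratio

    I(X;Y|Z) = 1/2 * ln( |C(X,Z)| * |C(Y,Z)| / (|C(Z)| * |C(X,Y,Z)|) ).

The (2*pi*e)^d factors cancel because the dimensions of the four variable
sets sum to zero: (1+k) + (1+k) - k - (2+k) = 0 for |Z| = k.  With an empty
conditioning set (|C(empty)| := 1) the ratio reduces to plain mutual
information, so order-0 scoring is the MI special case of the same estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DegenerateCovarianceError, InsufficientDataError, InvalidInputError

logger = logging.getLogger(__name__)

#: Determinants at or below this floor are treated as numerically degenerate;
#: they are replaced by the floor so a genome-scale run never aborts mid-way.
DETERMINANT_FLOOR = 1e-12

#: Estimated MI/CMI values above this magnitude of negativity indicate a
#: numerical problem rather than round-off; below it they are clamped to 0.
_NEGATIVE_CLAMP = -1e-10


@dataclass(frozen=True)
class CovarianceEstimate:
    """Sample covariance matrix over an ordered set of variables.

    Attributes
    ----------
    matrix:
        Symmetric ``dimension x dimension`` covariance matrix
        (expression units squared).
    labels:
        Gene indices (into the originating expression matrix) in row order.
    """

    matrix: np.ndarray
    labels: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise InvalidInputError("covariance matrix must be square")
        if not np.allclose(m, m.T, atol=1e-8, rtol=1e-8):
            raise InvalidInputError("covariance matrix must be symmetric")
        labels = tuple(self.labels) if self.labels else tuple(range(m.shape[0]))
        if len(labels) != m.shape[0]:
            raise InvalidInputError("label count must equal matrix dimension")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "labels", labels)

    @property
    def dimension(self) -> int:
        return self.matrix.shape[0]

    def submatrix(self, indices: Sequence[int]) -> np.ndarray:
        """Covariance sub-block for the given gene indices (label space)."""
        pos = [self.labels.index(i) for i in indices]
        return self.matrix[np.ix_(pos, pos)]


def sample_covariance(data: np.ndarray, labels: Sequence[int] | None = None) -> CovarianceEstimate:
    """Unbiased sample covariance of a variables-by-observations matrix.

    Parameters
    ----------
    data:
        Real matrix with one row per variable and one column per observation.
    labels:
        Optional gene indices naming the rows; defaults to ``0..n_vars-1``.

    Uses the n-1 denominator.  Requires at least two observations and all
    entries finite.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[1] < 2:
        raise InsufficientDataError(
            f"need >= 2 observations to estimate covariance, got {data.shape[1]}"
        )
    if data.shape[0] < 1:
        raise InvalidInputError("need at least one variable")
    if not np.all(np.isfinite(data)):
        raise InvalidInputError("expression data contains non-finite values")
    cov = np.cov(data, ddof=1)
    cov = np.atleast_2d(cov)
    # np.cov of a single row returns a 0-d array
    return CovarianceEstimate(matrix=cov, labels=tuple(labels) if labels is not None else ())


def _floored_det(matrix: np.ndarray) -> tuple[float, bool]:
    """Determinant with the numerical floor applied; flags degeneracy.

    An empty matrix (0x0) has determinant 1 by convention, which makes the
    unconditioned case fall out of the general formula.
    """
    if matrix.size == 0:
        return 1.0, False
    det = float(np.linalg.det(matrix))
    if det <= DETERMINANT_FLOOR:
        return DETERMINANT_FLOOR, True
    return det, False


def gaussian_entropy(cov: CovarianceEstimate | np.ndarray) -> float:
    """Differential entropy in nats of a Gaussian with the given covariance.

    Returns ``1/2 * ln((2*pi*e)^d * |C|)`` where ``d`` is the dimension of
    the variable set.  The empty variable set has entropy 0 (``|C| := 1``,
    ``d = 0``).  Raises :class:`DegenerateCovarianceError` when the
    determinant is at or below the floor.
    """
    matrix = cov.matrix if isinstance(cov, CovarianceEstimate) else np.atleast_2d(np.asarray(cov, float))
    if matrix.size == 0:
        return 0.0
    det, degenerate = _floored_det(matrix)
    if degenerate:
        raise DegenerateCovarianceError(
            f"covariance determinant {np.linalg.det(matrix):.3e} at or below floor {DETERMINANT_FLOOR:.0e}"
        )
    d = matrix.shape[0]
    return 0.5 * (d * np.log(2.0 * np.pi * np.e) + np.log(det))


def _clamp(value: float, degenerate: bool, what: str) -> float:
    if degenerate:
        logger.warning("%s computed with floored determinant; value is numerically degenerate", what)
    if value < _NEGATIVE_CLAMP:
        logger.warning("%s = %.3e is negative beyond round-off; clamping to 0", what, value)
    return max(value, 0.0)


def mutual_information(x: int, y: int, cov_source: CovarianceEstimate) -> float:
    """Mutual information in nats between genes ``x`` and ``y``.

    Computed as ``1/2 * ln(|C(X)| * |C(Y)| / |C(X,Y)|)`` from the covariance
    sub-blocks of ``cov_source``; equals ``-1/2 * ln(1 - rho^2)`` for the
    sample correlation ``rho``.  A zero-variance gene yields 0 with a logged
    warning rather than an exception.
    """
    if x == y:
        raise InvalidInputError("mutual information requires two distinct genes")
    vx = float(cov_source.submatrix([x])[0, 0])
    vy = float(cov_source.submatrix([y])[0, 0])
    if vx <= DETERMINANT_FLOOR or vy <= DETERMINANT_FLOOR:
        logger.warning("gene %s or %s has (near-)zero variance; MI set to 0", x, y)
        return 0.0
    det_xy, degenerate = _floored_det(cov_source.submatrix([x, y]))
    value = 0.5 * (np.log(vx) + np.log(vy) - np.log(det_xy))
    return _clamp(value, degenerate, f"MI({x},{y})")


def conditional_mutual_information(
    x: int,
    y: int,
    z: Sequence[int],
    source: CovarianceEstimate | np.ndarray,
) -> float:
    """Conditional mutual information in nats of ``x`` and ``y`` given ``z``.

    ``source`` is either a precomputed :class:`CovarianceEstimate` over (at
    least) the genes involved, or a raw genes-by-observations expression
    matrix from which the needed covariance is estimated.  With an empty
    conditioning set the value equals :func:`mutual_information` on the same
    pair.  Degenerate determinants are floored and the result clamped to be
    non-negative; the event is logged, not raised, so large screens run to
    completion.
    """
    z = tuple(z)
    if x == y:
        raise InvalidInputError("CMI requires two distinct genes")
    if x in z or y in z:
        raise InvalidInputError("conditioning set must not contain the tested pair")
    if len(set(z)) != len(z):
        raise InvalidInputError("conditioning set indices must be unique")
    cov = source if isinstance(source, CovarianceEstimate) else sample_covariance(source)

    if not z:
        return mutual_information(x, y, cov)

    # canonical (min, max) pair order so CMI(x,y|z) == CMI(y,x|z) bit-for-bit
    lo, hi = (x, y) if x < y else (y, x)
    det_xz, d1 = _floored_det(cov.submatrix([lo, *z]))
    det_yz, d2 = _floored_det(cov.submatrix([hi, *z]))
    det_z, d3 = _floored_det(cov.submatrix(list(z)))
    det_xyz, d4 = _floored_det(cov.submatrix([lo, hi, *z]))
    value = 0.5 * (np.log(det_xz) + np.log(det_yz) - np.log(det_z) - np.log(det_xyz))
    return _clamp(value, d1 or d2 or d3 or d4, f"CMI({x},{y}|{z})")


def mutual_information_matrix(cov: CovarianceEstimate) -> np.ndarray:
    """Pairwise MI in nats for every gene pair, vectorised.

    Returns a symmetric matrix with zeros on the diagonal.  Equivalent to
    calling :func:`mutual_information` on each pair; used to initialise the
    relevance network where all-pairs scoring dominates runtime.
    """
    c = cov.matrix
    v = np.diag(c).copy()
    ok = v > DETERMINANT_FLOOR
    if not np.all(ok):
        logger.warning("%d gene(s) with (near-)zero variance; their MI set to 0", int((~ok).sum()))
    det = np.outer(v, v) - c**2
    det = np.maximum(det, DETERMINANT_FLOOR)
    with np.errstate(divide="ignore", invalid="ignore"):
        mi = 0.5 * (np.log(np.outer(v, v)) - np.log(det))
    mi[~ok, :] = 0.0
    mi[:, ~ok] = 0.0
    np.fill_diagonal(mi, 0.0)
    return np.maximum(mi, 0.0)
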