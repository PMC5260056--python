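"""Automatic interaction-cutoff selection from the edge-count decay curve.

The number of pairs scoring above a cutoff falls roughly exponentially as the
cutoff rises.  The procedure scans edge counts over a cutoff grid, fits

    y = a * exp(-b * x) + c        (a > 0, b > 0, c >= 0)

by least squares, and returns the inflection point of the fitted curve as the
x-coordinate where the tangent line at the start of the grid meets the
tangent line at the end.  The additive floor ``c`` captures the plateau of
weak background correlations that genome-scale scans sit on.

When the fit is degenerate (flat scan, failed optimiser, parallel tangents)
a deterministic fallback returns the elbow of the raw scan: the grid point
farthest from the chord joining the scan's endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import DegenerateFitError, DegenerateScanError, InvalidInputError

#: Default scan grid: cutoffs 0 to 1 in steps of 0.02 (51 points).
DEFAULT_GRID_START = 0.0
DEFAULT_GRID_STOP = 1.0
DEFAULT_GRID_POINTS = 51

_OPT_TOL = 1e-8
_OPT_MAXFEV = 10_000


@dataclass(frozen=True)
class ThresholdScan:
    """Edge counts (pairs with weight strictly above each cutoff) on a grid."""

    cutoffs: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        cutoffs = np.asarray(self.cutoffs, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        if cutoffs.ndim != 1 or counts.shape != cutoffs.shape:
            raise InvalidInputError("cutoffs and counts must be 1-D and equally long")
        if np.any(np.diff(cutoffs) <= 0):
            raise InvalidInputError("cutoff grid must be strictly ascending")
        object.__setattr__(self, "cutoffs", cutoffs)
        object.__setattr__(self, "counts", counts)

    @property
    def grid_min(self) -> float:
        return float(self.cutoffs[0])

    @property
    def grid_max(self) -> float:
        return float(self.cutoffs[-1])


@dataclass(frozen=True)
class ExponentialFit:
    """Parameters of the decay model y = a*exp(-b*x) + c."""

    a: float
    b: float
    c: float
    rmse: float
    converged: bool

    def __call__(self, x):
        return self.a * np.exp(-self.b * np.asarray(x, dtype=float)) + self.c

    def slope(self, x: float) -> float:
        return -self.a * self.b * float(np.exp(-self.b * x))


def default_grid(max_weight: float | None = None) -> np.ndarray:
    """The scan grid: 0 to 1 step 0.02, rescaled to [0, max] when scores
    exceed 1 (MI in nats is unbounded above)."""
    stop = DEFAULT_GRID_STOP
    if max_weight is not None and max_weight > DEFAULT_GRID_STOP:
        stop = float(max_weight)
    return np.linspace(DEFAULT_GRID_START, stop, DEFAULT_GRID_POINTS)


def scan_counts(weights, grid=None) -> ThresholdScan:
    """Count pairs whose weight strictly exceeds each grid cutoff."""
    w = np.asarray(list(weights) if not isinstance(weights, np.ndarray) else weights, dtype=float).ravel()
    if w.size == 0:
        raise InvalidInputError("cannot scan an empty weight collection")
    grid = default_grid(float(w.max())) if grid is None else np.asarray(grid, dtype=float)
    counts = (w[None, :] > grid[:, None]).sum(axis=1)
    return ThresholdScan(cutoffs=grid, counts=counts.astype(float))


def fit_exponential(scan: ThresholdScan) -> ExponentialFit:
    """Least-squares fit of the decay model to a scan.

    Initialisation: ``c0`` = final count, ``a0`` = first count − c0, ``b0``
    from a log-linear regression of the floored excess counts.  Raises
    :class:`DegenerateScanError` when the counts carry no decay (all equal);
    optimiser failure is reported through ``converged=False`` rather than an
    exception so callers can fall back.
    """
    x, y = scan.cutoffs, scan.counts
    if x.size < 4:
        raise InvalidInputError("need at least 4 grid points to fit the decay model")
    if np.all(y == y[0]):
        raise DegenerateScanError("all scan counts equal; no decay to fit")

    c0 = float(y[-1])
    a0 = max(float(y[0]) - c0, 1e-6)
    excess = np.maximum(y - c0, 1e-9)
    slope = np.polyfit(x, np.log(excess), 1)[0]
    b0 = max(-float(slope), 1e-3)

    try:
        popt, _ = curve_fit(
            lambda t, a, b, c: a * np.exp(-b * t) + c,
            x,
            y,
            p0=(a0, b0, c0),
            bounds=((1e-12, 1e-12, 0.0), (np.inf, np.inf, np.inf)),
            xtol=_OPT_TOL,
            ftol=_OPT_TOL,
            maxfev=_OPT_MAXFEV,
        )
        a, b, c = (float(v) for v in popt)
        converged = True
    except (RuntimeError, ValueError):
        a, b, c, converged = a0, b0, c0, False

    fit = ExponentialFit(a=a, b=b, c=c, rmse=float(np.sqrt(np.mean((a * np.exp(-b * x) + c - y) ** 2))), converged=converged)
    return fit


def determine_threshold(fit: ExponentialFit, x_start: float, x_end: float) -> float:
    """Inflection cutoff: intersection of the tangents at the grid ends.

    Solves for the x-coordinate where the tangent line to the fitted curve at
    ``x_start`` crosses the tangent at ``x_end``; the result is clamped into
    ``[x_start, x_end]``.  ``x_end = inf`` uses the flat asymptote ``y = c``
    as the end tangent, giving the closed form ``x_start + 1/b``.
    """
    if not fit.converged:
        raise DegenerateFitError("cannot place tangents on a non-converged fit")
    if not x_start < x_end:
        raise InvalidInputError("x_start must be below x_end")

    s1 = fit.slope(x_start)
    if np.isinf(x_end):
        if s1 == 0.0:
            raise DegenerateFitError("flat start tangent; intersection undefined")
        return x_start + 1.0 / fit.b
    s2 = fit.slope(x_end)
    if abs(s1 - s2) < 1e-12 * max(1.0, abs(s1)):
        raise DegenerateFitError("start and end tangents are parallel")
    x = (float(fit(x_end)) - float(fit(x_start)) + s1 * x_start - s2 * x_end) / (s1 - s2)
    return float(np.clip(x, x_start, x_end))


def chord_elbow(scan: ThresholdScan) -> float:
    """Fallback cutoff: grid point farthest from the endpoint-joining chord."""
    x, y = scan.cutoffs, scan.counts
    # normalise so the two axes are commensurable before measuring distance
    xr = x[-1] - x[0]
    yr = y[0] - y[-1]
    xn = (x - x[0]) / (xr if xr else 1.0)
    yn = (y - y[-1]) / (yr if yr else 1.0)
    # distance from (xn, yn) to the line through (0, yn0) and (1, ynN)
    d = np.abs((yn[-1] - yn[0]) * xn - (xn[-1] - xn[0]) * yn + xn[-1] * yn[0] - yn[-1] * xn[0])
    return float(x[int(np.argmax(d))])


def auto_threshold(weights, grid=None) -> float:
    """Scan, fit and intersect; fall back to the raw-scan elbow when the fit
    degenerates.  Always returns a value within the grid."""
    scan = scan_counts(weights, grid)
    try:
        fit = fit_exponential(scan)
        return determine_threshold(fit, scan.grid_min, scan.grid_max)
    except (DegenerateScanError, DegenerateFitError, InvalidInputError):
        return chord_elbow(scan)
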