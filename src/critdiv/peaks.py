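"""Noisy local-maxima finder for sampled piecewise-linear signals.

A sampled divergence-rate series is piecewise linear and typically noisy:
it carries many small local maxima besides the genuine critical spikes.
The finder here ascends the piecewise-linear interpolant with a discrete
Nesterov-momentum iteration, seeded at each interior local minimum in turn,
snaps every converged trajectory to the nearest candidate maximum, and then
keeps only maxima whose z-score-normalized height exceeds a significance
threshold ``alpha``.

The ascent runs in sample-index coordinates — the step size ``eta`` is in
units of one grid step and the gradient is the forward difference between
neighboring samples — so the defaults behave identically on linear beta
grids, log beta grids, w grids, or any other strictly increasing abscissa.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass

import numpy as np

from .divergence import DivergenceSeries

__all__ = [
    "PeakConfig",
    "PeakSet",
    "find_all_local_maxima",
    "piecewise_gradient",
    "find_next_local_maximum",
    "find_significant_peaks",
]


@dataclass(frozen=True)
class PeakConfig:
    """Hyperparameters of the momentum ascent and the significance filter.

    ``eta``: step size (grid-step units); ``mu``: momentum in [0, 1);
    ``eps``: convergence threshold on successive iterates; ``alpha``:
    minimum normalized height for a peak to count as significant;
    ``max_iter``: iteration cap guaranteeing termination on signals where
    the ascent oscillates without settling.
    """

    eta: float = 0.05
    mu: float = 0.9
    eps: float = 1e-6
    alpha: float = 1.0
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if self.eta <= 0 or self.eps <= 0:
            raise ValueError("eta and eps must be positive")
        if not 0 <= self.mu < 1:
            raise ValueError("mu must lie in [0, 1)")


@dataclass(frozen=True)
class PeakSet:
    """Significant peaks: parameter locations ``x`` (strictly increasing)
    and their normalized heights.  ``fallback_used`` marks series with no
    interior minima, where the sweep degenerates to a plain
    maxima-plus-filter pass."""

    x: np.ndarray
    height: np.ndarray
    fallback_used: bool = False

    def __len__(self) -> int:
        return self.x.size


def find_all_local_maxima(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Indices of strict interior local maxima (``y[i-1] < y[i] > y[i+1]``).

    Endpoints are never returned, and plateaus do not qualify under the
    strict comparison.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    interior = (y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])
    return np.flatnonzero(interior) + 1


def _nearest_index(xs: list, x0: float) -> int:
    """Index of the point nearest to ``x0``; ties keep the earlier index."""
    i = bisect_left(xs, x0)
    if i == 0:
        return 0
    if i == len(xs):
        return len(xs) - 1
    return i - 1 if x0 - xs[i - 1] <= xs[i] - x0 else i


def piecewise_gradient(x: np.ndarray, y: np.ndarray, x0: float) -> float:
    """Slope of the segment forward of the sample nearest to ``x0``.

    At the last sample (where no forward segment exists) the preceding
    segment's slope is used instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points")
    o = _nearest_index(list(x), float(x0))
    if o == x.size - 1:
        o -= 1
    return float((y[o + 1] - y[o]) / (x[o + 1] - x[o]))


#: iterations over which lack of net progress counts as settled
_STALL_WINDOW = 50
#: trust region: largest displacement (in grid steps) per iteration
_MAX_STEP = 3.0


def _ascend(
    y: np.ndarray, max_idx: np.ndarray, start: int, config: PeakConfig
) -> tuple[int, bool]:
    """Nesterov-momentum ascent in sample-index coordinates.

    The iterate ``u`` lives on the continuous index axis; the gradient at
    ``u`` is the forward difference ``y[o+1] - y[o]`` of the sample ``o``
    nearest to ``u`` (the preceding difference at the last sample).  Index
    coordinates make the dynamics identical on linear, logarithmic or
    irregular parameter grids: ``eta`` is in units of one grid step.

    Displacements are clipped to a few grid steps per iteration (with the
    momentum reset on clipping), since the nearest-sample gradient carries
    no information beyond its own segment; without the clip, a spike with
    a large slope flings the iterate far past the peak.  Terminates when
    successive iterates differ by less than ``eps``, when the trajectory
    makes no net progress over a window (it is bouncing around a kink of
    the piecewise-linear signal, which a fixed-step momentum scheme never
    leaves), or at the iteration cap; then snaps to the candidate maximum
    nearest the highest sample visited (ties keep the earlier candidate).
    """
    m = y.size
    eta, mu, eps = config.eta, config.mu, config.eps
    u = float(start)
    phi = u
    best = int(start)
    converged = False
    history: list[float] = []

    def visit(a: float, b: float) -> None:
        # record the best sample over every index the move [a, b] crossed
        nonlocal best
        lo = max(0, int(np.floor(min(a, b))))
        hi = min(m - 1, int(np.ceil(max(a, b))))
        for k in range(lo, hi + 1):
            if y[k] > y[best]:
                best = k

    for _ in range(config.max_iter):
        u_prev = u
        o = int(round(u))
        o = 0 if o < 0 else (m - 1 if o > m - 1 else o)
        if o == m - 1:
            o -= 1
        grad = y[o + 1] - y[o]
        phi_prev = phi
        phi = u + eta * grad
        u = phi + mu * (phi - phi_prev)
        if abs(u - u_prev) > _MAX_STEP:
            u = u_prev + np.sign(u - u_prev) * _MAX_STEP
            phi = u  # drop accumulated momentum along with the clip
        visit(u_prev, u)
        if abs(u - u_prev) < eps:
            converged = True
            break
        history.append(u)
        if len(history) > _STALL_WINDOW:
            if abs(u - history[-_STALL_WINDOW]) < 0.5:
                converged = True
                break
    dist = np.abs(max_idx - best)
    return int(max_idx[int(np.argmin(dist))]), converged


def find_next_local_maximum(
    x: np.ndarray,
    y: np.ndarray,
    maxima_x: np.ndarray,
    theta0: float,
    config: PeakConfig | None = None,
) -> tuple[float, bool]:
    """Ascend from ``theta0`` by Nesterov momentum; snap to a candidate.

    Iterates ``phi_new = theta + eta * grad(theta)``,
    ``theta = phi_new + mu * (phi_new - phi_prev)`` — with the gradient
    taken per grid step at the sample nearest the iterate — until
    successive iterates differ by less than ``eps``, the trajectory stops
    making progress, or the iteration cap is hit; returns the candidate
    maximum location nearest the final iterate and a convergence flag.
    """
    config = config or PeakConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    maxima_x = np.asarray(maxima_x, dtype=float)
    if maxima_x.size == 0:
        raise ValueError("maxima_x must be non-empty")
    xs = list(x)
    start = _nearest_index(xs, float(theta0))
    max_idx = np.array([_nearest_index(xs, mx) for mx in maxima_x])
    reached, converged = _ascend(y, max_idx, start, config)
    pos = int(np.argmin(np.abs(max_idx - reached)))
    return float(maxima_x[pos]), converged


def find_significant_peaks(
    series: DivergenceSeries | tuple[np.ndarray, np.ndarray],
    config: PeakConfig | None = None,
) -> PeakSet:
    """Momentum sweep over a divergence series, then significance filter.

    Candidate maxima and minima come from the strict local-extremum scan;
    starting at the first interior minimum the ascent runs repeatedly, each
    recorded maximum advancing the start to the next minimum beyond it,
    until the minima are exhausted.  Recorded maxima with normalized height
    ``<= alpha`` are then discarded.  Accepts a :class:`DivergenceSeries`
    (using its midpoint abscissa and normalized rates) or a raw ``(x, y)``
    pair.  The ascent runs in grid-step units, so the result is invariant
    under any monotone rescaling of the abscissa.
    """
    config = config or PeakConfig()
    if isinstance(series, DivergenceSeries):
        x, y = series.t_mid, series.M_norm
    else:
        x, y = series
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")

    max_idx = find_all_local_maxima(x, y)
    if max_idx.size == 0:
        return PeakSet(x=np.empty(0), height=np.empty(0))
    # seed ascents at *weak* interior minima: a divergence series is often
    # exactly flat between spikes, where no strict minimum exists and a
    # strict-minimum sweep would never start near (hence never find) a peak
    interior = (y[1:-1] <= y[:-2]) & (y[1:-1] <= y[2:])
    min_idx = np.flatnonzero(interior) + 1

    if min_idx.size == 0:
        keep = max_idx[y[max_idx] > config.alpha]
        return PeakSet(x=x[keep], height=y[keep], fallback_used=True)

    recorded: set[int] = set()
    i = 0
    while True:
        reached, _ = _ascend(y, max_idx, int(min_idx[i]), config)
        recorded.add(reached)
        nxt = None
        for j in range(i + 1, min_idx.size):
            if min_idx[j] > reached:
                nxt = j
                break
        if nxt is None:
            break
        i = nxt

    keep = np.asarray(sorted(k for k in recorded if y[k] > config.alpha), dtype=int)
    return PeakSet(x=x[keep], height=y[keep])
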