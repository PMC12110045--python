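"""Closed-form and algebraic rate–distortion results used as oracles.

For large ``beta`` (small ``w = exp(-beta)``) the optimal output
distribution has an explicit matrix closed form,

    p = W^{-T} (q / (W^{-1} 1)),

valid while all entries stay positive.  The first critical trade-off
parameter ``beta*`` — the largest ``beta`` at which some output probability
reaches zero — is found by scanning this closed form downward from the
high-``beta`` regime and refining the first zero crossing by bracketing.

Two families admit fully explicit answers and anchor the test suite:

* the two-state family with ``q = (1/2, 1/2)`` and distortions
  ``d = [[0, 1], [a, 0]]``, whose output probabilities are rational in
  ``w`` and whose critical ``w*`` is the positive root (other than 1) of
  ``1 - 2w + w**(a+1)`` when ``a > 1``;
* Berger's three-state family with source ``((1-u)/2, u, (1-u)/2)`` and a
  banded distortion matrix, whose first critical value is
  ``w* = (1 - u - sqrt(1 - 6u + u**2)) / 2`` whenever ``u <= 3 - 2*sqrt(2)``.

A generalized Descartes rule of signs bounds the number of positive roots
of the polynomials that arise in the two-state analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .rd import RDProblem

__all__ = [
    "CriticalPoint",
    "PolynomialSignProfile",
    "NoCriticalPointError",
    "high_beta_output",
    "first_critical_beta",
    "two_state_problem",
    "two_state_outputs",
    "berger_problem",
    "berger_critical_w",
    "BERGER_U_MAX",
    "descartes_positive_root_bound",
]

#: Largest u for which Berger's three-state family has a real critical w*.
BERGER_U_MAX = 3.0 - 2.0 * np.sqrt(2.0)


class NoCriticalPointError(ValueError):
    """No output probability reaches zero in the scanned beta range."""


@dataclass(frozen=True)
class CriticalPoint:
    """A support transition: at ``beta_star`` (``w_star = exp(-beta_star)``)
    the output probability of ``vanishing_index`` reaches zero."""

    beta_star: float
    w_star: float
    vanishing_index: int


@dataclass(frozen=True)
class PolynomialSignProfile:
    """Coefficients (ascending powers) and their count of strict sign
    changes; by Descartes' rule the number of positive roots is
    ``sign_changes - 2k`` for some integer ``k >= 0``."""

    coefficients: tuple
    sign_changes: int


def high_beta_output(problem: RDProblem, beta: float) -> np.ndarray:
    """Closed-form output distribution ``W^{-T}(q / (W^{-1} 1))``.

    Exact on the RD curve while every entry is positive; past the first
    critical point entries go negative and the value is no longer a
    probability vector (callers use the sign change to locate criticality).

    Raises
    ------
    numpy.linalg.LinAlgError
        If ``W`` is singular at this beta.
    """
    W = np.exp(-beta * problem.d)
    ones = np.ones(problem.n)
    a = np.linalg.solve(W, ones)  # W^{-1} 1
    return np.linalg.solve(W.T, problem.q / a)


def first_critical_beta(
    problem: RDProblem,
    beta_hi: float = 30.0,
    beta_lo: float = 1e-3,
    tol: float = 1e-10,
    scan_points: int = 2000,
) -> CriticalPoint:
    """First critical ``beta*`` coming down from the high-beta regime.

    Scans ``min_i p_i`` of the closed-form output on a geometric grid in
    ``w`` from ``exp(-beta_hi)`` up to ``exp(-beta_lo)``, brackets the first
    sign change, and refines it by Brent's method to ``tol`` (in ``w``).

    Raises
    ------
    NoCriticalPointError
        If the minimum entry stays positive over the whole range.
    ValueError
        If some entry is already non-positive at ``beta_hi``.
    """
    if beta_hi <= beta_lo:
        raise ValueError("beta_hi must exceed beta_lo")

    def min_entry(w: float) -> float:
        return float(np.min(high_beta_output(problem, -np.log(w))))

    w_grid = np.geomspace(np.exp(-beta_hi), np.exp(-beta_lo), scan_points)
    f_prev = min_entry(w_grid[0])
    if f_prev <= 0:
        raise ValueError(
            "high_beta_output has a non-positive entry already at beta_hi; "
            "increase beta_hi"
        )
    for w_prev, w_next in zip(w_grid[:-1], w_grid[1:]):
        try:
            f_next = min_entry(w_next)
        except np.linalg.LinAlgError:
            break  # W singular (w too close to 1): end of usable range
        if f_next <= 0:
            w_star = (
                w_next
                if f_next == 0
                else brentq(min_entry, w_prev, w_next, xtol=tol)
            )
            p = high_beta_output(problem, -np.log(w_star))
            return CriticalPoint(
                beta_star=float(-np.log(w_star)),
                w_star=float(w_star),
                vanishing_index=int(np.argmin(p)),
            )
        f_prev = f_next
    raise NoCriticalPointError(
        f"no critical point in beta range [{beta_lo:g}, {beta_hi:g}]"
    )


def two_state_problem(a: float) -> RDProblem:
    """The two-state family: ``q = (1/2, 1/2)``, ``d = [[0, 1], [a, 0]]``."""
    if a <= 0:
        raise ValueError("a must be positive")
    return RDProblem(q=np.array([0.5, 0.5]), d=np.array([[0.0, 1.0], [a, 0.0]]))


def two_state_outputs(a: float, beta: float) -> tuple[float, float]:
    """Explicit output probabilities for the two-state family.

    ``p1 = (1 - 2 w**a + w**(a+1)) / (2 (1-w)(1-w**a))`` and symmetrically
    for ``p2`` with ``w`` and ``w**a`` exchanged.  Valid before the first
    critical point; the removable singularities at ``w = 1`` and
    ``w**a = 1`` (in particular the whole ``a = 1`` line) are refused
    rather than limit-evaluated, since they sit outside the ``beta > 0``
    operating range.
    """
    if a == 0:
        raise ValueError("a must be nonzero")
    if a == 1:
        raise ZeroDivisionError(
            "a = 1 is the symmetric case: the critical-point structure "
            "degenerates (no analytic critical beta exists) and the "
            "explicit formulas are refused"
        )
    w = np.exp(-beta)
    wa = w**a
    if abs(1.0 - w) < 1e-12 or abs(1.0 - wa) < 1e-12:
        raise ZeroDivisionError(
            "removable singularity: w = 1 or w**a = 1 (e.g. a = 1); "
            "the explicit two-state formulas are undefined here"
        )
    denom = 2.0 * (1.0 - w) * (1.0 - wa)
    p1 = (1.0 - 2.0 * wa + wa * w) / denom
    p2 = (1.0 - 2.0 * w + wa * w) / denom
    return float(p1), float(p2)


def berger_problem(u: float) -> RDProblem:
    """Berger's three-state family: source ``((1-u)/2, u, (1-u)/2)`` with
    the fixed banded distortion ``[[0,1,2],[1,0,1],[2,1,0]]``."""
    if not 0.0 < u < 1.0:
        raise ValueError("u must lie in (0, 1)")
    q = np.array([(1.0 - u) / 2.0, u, (1.0 - u) / 2.0])
    d = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
    return RDProblem(q=q, d=d)


def berger_critical_w(u: float) -> float | None:
    """Closed-form first critical ``w*`` of the Berger family.

    Returns ``(1 - u - sqrt(1 - 6u + u**2)) / 2`` for ``u <= 3 - 2*sqrt(2)``
    (where the discriminant is non-negative) and ``None`` otherwise —
    beyond that boundary the middle output never loses support.
    """
    if u > BERGER_U_MAX:
        return None
    disc = max(1.0 - 6.0 * u + u * u, 0.0)  # roundoff guard at the boundary
    return float((1.0 - u - np.sqrt(disc)) / 2.0)


def descartes_positive_root_bound(coefficients) -> PolynomialSignProfile:
    """Sign-change count of a real polynomial (ascending coefficients).

    Descartes' rule: the number of positive real roots equals the number of
    strict sign changes among the nonzero coefficients minus an even
    non-negative integer.  Zero coefficients are skipped.
    """
    coeffs = tuple(float(c) for c in coefficients)
    signs = [np.sign(c) for c in coeffs if c != 0.0]
    if not signs:
        raise ValueError("at least one coefficient must be nonzero")
    changes = sum(1 for s0, s1 in zip(signs[:-1], signs[1:]) if s0 != s1)
    return PolynomialSignProfile(coefficients=coeffs, sign_changes=changes)
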