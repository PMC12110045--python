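"""Blahut–Arimoto fixed-point solver for discrete rate–distortion problems.

A rate–distortion (RD) problem is a source distribution ``q`` over ``n``
states together with a non-negative distortion matrix ``d``.  For each value
of the trade-off parameter ``beta`` (equivalently ``w = exp(-beta)``), the
Blahut–Arimoto (BA) iteration finds the output distribution ``p`` and the
conditional codebook ``p(y|x)`` that achieve the minimal rate ``R`` at the
corresponding average distortion ``D``.

Index convention used throughout the package: **rows are outputs i, columns
are inputs j**, so ``d[i, j]`` is the cost of coding input ``j`` as output
``i`` and a codebook column is the conditional distribution of outputs given
one input.  All probability vectors are 1-D numpy arrays on the simplex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "RDProblem",
    "WMatrix",
    "Codebook",
    "BAConfig",
    "RDSolution",
    "BAConvergenceWarning",
    "make_w_matrix",
    "ba_update",
    "ba_solve",
    "rd_curve",
    "solve_path",
]

_SIMPLEX_TOL = 1e-12


class BAConvergenceWarning(UserWarning):
    """Raised (as a warning) when the BA iteration hits its iteration cap."""


@dataclass(frozen=True)
class RDProblem:
    """Source distribution ``q`` plus distortion matrix ``d`` (outputs x inputs).

    Parameters
    ----------
    q
        Strictly positive probability vector of length ``n``; must sum to 1.
    d
        ``n x n`` matrix of non-negative distortions, ``d[i, j]`` = cost of
        coding input ``j`` as output ``i``.
    """

    q: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        d = np.asarray(self.d, dtype=float)
        if q.ndim != 1:
            raise ValueError("q must be a 1-D probability vector")
        if d.shape != (q.size, q.size):
            raise ValueError(
                f"d must be {q.size}x{q.size} to match q, got {d.shape}"
            )
        if np.any(q <= 0):
            raise ValueError("all entries of q must be strictly positive")
        if abs(q.sum() - 1.0) > 1e-6:
            raise ValueError(f"q must sum to 1, got {q.sum():.17g}")
        if np.any(d < 0):
            raise ValueError("distortion entries must be non-negative")
        # exact renormalization so downstream simplex checks hold to 1e-12
        object.__setattr__(self, "q", q / q.sum())
        object.__setattr__(self, "d", d)

    @property
    def n(self) -> int:
        return self.q.size

    def entropy_bits(self) -> float:
        """Shannon entropy H(q) in bits — the zero-distortion rate."""
        return float(-np.sum(self.q * np.log2(self.q)))


@dataclass(frozen=True)
class WMatrix:
    """The matrix ``W[i, j] = w ** d[i, j]`` with ``w = exp(-beta)``."""

    w: float
    W: np.ndarray


@dataclass(frozen=True)
class Codebook:
    """Conditional matrix ``p_cond[i, j] = p(output i | input j)``.

    Columns of a normalized codebook sum to 1.  The sub-normalized
    deterministic-map variant (see :mod:`critdiv.divergence`) carries
    ``normalized=False``.
    """

    p_cond: np.ndarray
    normalized: bool = True

    def __post_init__(self) -> None:
        p = np.asarray(self.p_cond, dtype=float)
        if p.ndim != 2:
            raise ValueError("p_cond must be a 2-D matrix")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("codebook entries must lie in [0, 1]")
        if self.normalized:
            colsums = p.sum(axis=0)
            if np.any(np.abs(colsums - 1.0) > 1e-9):
                raise ValueError("codebook columns must each sum to 1")
        object.__setattr__(self, "p_cond", p)

    @property
    def n_out(self) -> int:
        return self.p_cond.shape[0]

    @property
    def n_in(self) -> int:
        return self.p_cond.shape[1]


def as_conditional(codebook) -> np.ndarray:
    """Return the conditional matrix of a :class:`Codebook` or ndarray."""
    return np.asarray(getattr(codebook, "p_cond", codebook), dtype=float)


@dataclass(frozen=True)
class BAConfig:
    """Numerical knobs for the BA fixed-point iteration.

    ``tol`` is the max-abs-change convergence threshold on the output
    distribution, ``support_eps`` the level below which an output
    probability counts as zero when reporting the support.
    """

    tol: float = 1e-10
    max_iter: int = 10_000
    support_eps: float = 1e-8
    zero_beta_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.tol <= 0 or self.support_eps <= 0 or self.max_iter <= 0:
            raise ValueError("tol, support_eps and max_iter must be positive")
        if self.zero_beta_tol < 0:
            raise ValueError("zero_beta_tol must be non-negative")


@dataclass(frozen=True)
class RDSolution:
    """One converged point on the RD curve.

    ``p_out`` is the output distribution, ``codebook`` the optimal
    conditional ``p(y|x)``, ``D`` the average distortion, ``R`` the rate in
    bits, ``support`` the indices of outputs with ``p_out`` above the
    support threshold.  ``converged`` is False when the iteration cap was
    reached; ``residual`` is the final max-abs change.
    """

    beta: float
    w: float
    p_out: np.ndarray
    codebook: Codebook
    D: float
    R: float
    support: np.ndarray
    converged: bool = True
    n_iter: int = 0
    residual: float = 0.0


def make_w_matrix(problem: RDProblem, beta: float) -> WMatrix:
    """Build ``W[i, j] = exp(-beta * d[i, j])`` for the given problem."""
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    return WMatrix(w=float(np.exp(-beta)), W=np.exp(-beta * problem.d))


@njit(cache=True)
def _ba_fixed_point(W, q, p0, tol, max_iter):
    """Iterate ``p <- p * W (q / (W^T p))`` until the max-abs change drops
    below ``tol``; returns (p, iterations, residual, converged)."""
    n = q.size
    p = p0.copy()
    p_new = np.empty(n)
    z = np.empty(n)
    residual = np.inf
    for it in range(1, max_iter + 1):
        for j in range(n):
            acc = 0.0
            for i in range(n):
                acc += W[i, j] * p[i]
            if acc <= 0.0:
                raise FloatingPointError(
                    "degenerate BA update: a partition value underflowed to 0"
                )
            z[j] = q[j] / acc
        total = 0.0
        for i in range(n):
            acc = 0.0
            for j in range(n):
                acc += W[i, j] * z[j]
            p_new[i] = p[i] * acc
            total += p_new[i]
        residual = 0.0
        for i in range(n):
            p_new[i] /= total
            diff = abs(p_new[i] - p[i])
            if diff > residual:
                residual = diff
            p[i] = p_new[i]
        if residual < tol:
            return p, it, residual, True
    return p, max_iter, residual, False


def ba_update(p_out: np.ndarray, problem: RDProblem, Wm: WMatrix) -> np.ndarray:
    """One BA step ``p <- p * W (q / (W^T p))``; preserves the simplex."""
    p = np.asarray(p_out, dtype=float)
    Z = Wm.W.T @ p  # Z_j = sum_i p_i W_ij
    if np.any(Z <= 0):
        raise FloatingPointError(
            "degenerate BA update: some partition value Z_j underflowed to 0"
        )
    p_new = p * (Wm.W @ (problem.q / Z))
    return p_new / p_new.sum()


def _finish(
    problem: RDProblem,
    beta: float,
    Wm: WMatrix,
    p: np.ndarray,
    config: BAConfig,
    converged: bool,
    n_iter: int,
    residual: float,
) -> RDSolution:
    Z = Wm.W.T @ p
    cond = p[:, None] * Wm.W / Z[None, :]
    cond /= cond.sum(axis=0, keepdims=True)
    D = float(np.einsum("j,ij,ij->", problem.q, cond, problem.d))
    mask = cond > 0
    ratio = np.ones_like(cond)
    np.divide(cond, p[:, None], out=ratio, where=mask & (p[:, None] > 0))
    R = float(np.einsum("j,ij->", problem.q, cond * np.log2(ratio, where=ratio > 0, out=np.zeros_like(ratio))))
    R = max(R, 0.0)
    support = np.flatnonzero(p > config.support_eps)
    return RDSolution(
        beta=float(beta),
        w=Wm.w,
        p_out=p,
        codebook=Codebook(cond),
        D=D,
        R=R,
        support=support,
        converged=converged,
        n_iter=n_iter,
        residual=residual,
    )


def ba_solve(
    problem: RDProblem,
    beta: float,
    config: BAConfig | None = None,
    p_init: np.ndarray | None = None,
) -> RDSolution:
    """Solve the RD fixed point at one ``beta`` by BA iteration.

    Starts from the uniform output distribution unless ``p_init`` is given
    (used for warm-started continuation along a grid).  On hitting the
    iteration cap, a :class:`BAConvergenceWarning` is emitted and the
    (flagged) last iterate is returned.
    """
    config = config or BAConfig()
    Wm = make_w_matrix(problem, beta)
    n = problem.n
    # When beta * max(d) is below zero_beta_tol, W is uniformly within that
    # tolerance of all-ones and every simplex point satisfies the fixed-point
    # equation to machine scale: the iteration cannot distinguish fixed
    # points.  The zero-rate limit is known analytically — a single output
    # (the row minimizing expected distortion) with R = 0 — and its D and R
    # differ from the true values at this beta by at most O(beta * max d).
    if beta * problem.d.max() < config.zero_beta_tol:
        i_star = int(np.argmin(problem.d @ problem.q))
        p = np.zeros(n)
        p[i_star] = 1.0
        cond = np.zeros((n, n))
        cond[i_star, :] = 1.0
        return RDSolution(
            beta=float(beta),
            w=Wm.w,
            p_out=p,
            codebook=Codebook(cond),
            D=float(problem.d[i_star] @ problem.q),
            R=0.0,
            support=np.array([i_star]),
            converged=True,
            n_iter=0,
            residual=0.0,
        )
    if p_init is None:
        p = np.full(n, 1.0 / n)
    else:
        p = np.asarray(p_init, dtype=float)
        p = p / p.sum()
    p, it, residual, converged = _ba_fixed_point(
        np.ascontiguousarray(Wm.W), problem.q, p, config.tol, config.max_iter
    )
    residual = float(residual)
    if not converged:
        warnings.warn(
            f"BA iteration did not converge at beta={beta:g} after "
            f"{config.max_iter} iterations (residual {residual:.3g})",
            BAConvergenceWarning,
            stacklevel=2,
        )
    return _finish(problem, beta, Wm, p, config, converged, it, residual)


# Output states that lose support cannot re-enter a purely multiplicative
# update; warm starts are floored at this fraction of uniform so support can
# re-emerge along a continuation path.
_WARM_FLOOR = 1e-6


def solve_path(
    problem: RDProblem,
    betas: np.ndarray,
    config: BAConfig | None = None,
) -> list[RDSolution]:
    """Solve a sequence of betas in the order given, warm-starting each solve
    from the previous output distribution (floored so lost support can
    reappear)."""
    config = config or BAConfig()
    out: list[RDSolution] = []
    p_prev: np.ndarray | None = None
    for beta in np.asarray(betas, dtype=float):
        if p_prev is not None:
            p_prev = np.maximum(p_prev, _WARM_FLOOR / problem.n)
        sol = ba_solve(problem, beta, config, p_init=p_prev)
        p_prev = sol.p_out
        out.append(sol)
    return out


def rd_curve(
    problem: RDProblem,
    beta_grid: np.ndarray,
    config: BAConfig | None = None,
) -> list[RDSolution]:
    """RD solutions along a strictly increasing beta grid (continuation).

    Each point is warm-started from the previous solution, which keeps the
    solver fast away from critical betas and stable through support
    transitions.
    """
    betas = np.asarray(beta_grid, dtype=float)
    if betas.size == 0:
        raise ValueError("beta_grid must be non-empty")
    if betas.size > 1 and np.any(np.diff(betas) <= 0):
        raise ValueError("beta_grid must be strictly increasing")
    return solve_path(problem, betas, config)
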