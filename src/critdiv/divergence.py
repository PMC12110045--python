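"""The divergence rate: per-step averaged KL change between codebooks.

For a family of conditional distributions ``p_t(y|x)`` indexed by a control
parameter ``t``, the divergence rate over one sampled step is

    M_t = (1/dt) * sum_x q_x * KL( p_t(.|x) || p_{t+dt}(.|x) ),

a non-negative proxy for how fast the system's behavior changes at ``t``.
For a differentiable family with full support M_t vanishes linearly as the
grid is refined, while a support loss between consecutive samples makes
the true KL infinite — numerically, such steps report a large finite
sentinel of uniform height.  Peaks of the z-score-normalized series mark
critical parameter values.

KL here uses the natural logarithm; the choice of base rescales the whole
series uniformly and cancels in the normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .rd import Codebook, as_conditional

__all__ = [
    "KLConfig",
    "DivergenceSeries",
    "kl_divergence",
    "divergence_rate",
    "divergence_series",
    "codebook_from_deterministic_map",
]


@dataclass(frozen=True)
class KLConfig:
    """Clamps for numerically infinite divergences.

    A support loss — some outcome with probability above ``floor`` under
    the first distribution and at or below ``floor`` under the second —
    makes the true KL numerically infinite; it is reported as the finite
    sentinel ``cap``, so every loss step spikes to the same height and
    stays finite under z-score normalization.  ``floor`` doubles as the
    clamp on reference probabilities inside the log; it must sit above the
    solver's stall scale (the level where converged-to-zero probabilities
    linger) and below genuinely small probabilities of interest.
    """

    floor: float = 1e-6
    cap: float = 1e6

    def __post_init__(self) -> None:
        if not 0 < self.floor < 1:
            raise ValueError("floor must lie in (0, 1)")
        if self.cap <= 0:
            raise ValueError("cap must be positive")


@dataclass(frozen=True)
class DivergenceSeries:
    """Sampled divergence rates along a control-parameter grid.

    ``t`` is the length-``m`` parameter grid; ``M_raw[k]`` is the divergence
    rate over the step ``t[k] -> t[k+1]`` and is assigned the midpoint
    abscissa ``t_mid[k]``; ``M_norm`` is the z-score of ``M_raw``.
    ``degenerate`` flags a constant raw series (zero standard deviation),
    in which case ``M_norm`` is all zeros.
    """

    t: np.ndarray
    t_mid: np.ndarray
    M_raw: np.ndarray
    M_norm: np.ndarray
    q: np.ndarray
    degenerate: bool = False


def kl_divergence(
    u: np.ndarray,
    v: np.ndarray,
    config: KLConfig | None = None,
    check: bool = True,
) -> float:
    """Floor-clamped Kullback–Leibler divergence ``sum u ln(u / v)``.

    If ``v`` loses support where ``u`` still has it — some entry of ``u``
    above ``config.floor`` facing an entry of ``v`` at or below it — the
    divergence is genuinely infinite and the sentinel ``config.cap`` is
    returned.  Otherwise entries of ``v`` below the floor are clamped up
    to it and the (finite) sum is returned, still capped at ``cap``.
    Terms with ``u[y] = 0`` contribute zero.  With ``check=False`` the
    simplex validation is skipped, which permits the sub-normalized
    deterministic-map codebooks.
    """
    config = config or KLConfig()
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    if check:
        for name, vec in (("u", u), ("v", v)):
            if abs(vec.sum() - 1.0) > 1e-6:
                raise ValueError(f"{name} must sum to 1 within 1e-6")
            if np.any(vec < 0):
                raise ValueError(f"{name} must be non-negative")
    lost = bool(np.any((u > config.floor) & (v <= config.floor)))
    mask = u > 0
    val = float(np.sum(u[mask] * np.log(u[mask] / np.maximum(v[mask], config.floor))))
    # flooring v can only increase KL, so negatives are pure roundoff
    val = max(val, 0.0)
    if lost:
        return config.cap
    return min(val, config.cap)


def _kl_parts(
    u: np.ndarray, v: np.ndarray, config: KLConfig
) -> tuple[float, bool]:
    """Floor-clamped KL value plus a flag for support loss (some entry of
    ``u`` above the floor facing an entry of ``v`` at or below it)."""
    lost = bool(np.any((u > config.floor) & (v <= config.floor)))
    mask = u > 0
    val = float(np.sum(u[mask] * np.log(u[mask] / np.maximum(v[mask], config.floor))))
    return max(val, 0.0), lost


def divergence_rate(
    cb_t: Codebook | np.ndarray,
    cb_next: Codebook | np.ndarray,
    q: np.ndarray,
    dt: float,
    config: KLConfig | None = None,
) -> float:
    """Input-averaged KL between consecutive codebooks, per unit ``dt``.

    If any input's conditional loses an output state between the two
    codebooks, the true rate is infinite; the step then reports the
    sentinel ``cap`` plus the input-averaged clamped sum — so every
    support-loss step spikes to essentially the same height (which makes
    losses uniformly significant after z-scoring), while the finite part
    still orders coincident losses for the peak finder's strict
    comparisons.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    config = config or KLConfig()
    a = as_conditional(cb_t)
    b = as_conditional(cb_next)
    if a.shape != b.shape:
        raise ValueError(f"codebook shape mismatch: {a.shape} vs {b.shape}")
    q = np.asarray(q, dtype=float)
    if q.size != a.shape[1]:
        raise ValueError("q length must equal the number of codebook columns")
    total = 0.0
    any_lost = False
    for j in range(q.size):
        val, lost = _kl_parts(a[:, j], b[:, j], config)
        any_lost = any_lost or lost
        total += q[j] * min(val, config.cap)
    if any_lost:
        total = config.cap + total
    return total / dt


def divergence_series(
    codebooks: Sequence[Codebook | np.ndarray],
    t: np.ndarray,
    q: np.ndarray,
    config: KLConfig | None = None,
) -> DivergenceSeries:
    """Divergence rates over consecutive codebook pairs, z-score normalized.

    The normalization is computed over the whole sampled series (not
    windowed).  A constant raw series is returned with ``M_norm`` all zero
    and ``degenerate=True``.
    """
    config = config or KLConfig()
    t = np.asarray(t, dtype=float)
    if len(codebooks) != t.size:
        raise ValueError("need one codebook per parameter sample")
    if t.size < 3:
        raise ValueError("need at least 3 parameter samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("t must be strictly increasing")
    q = np.asarray(q, dtype=float)
    M_raw = np.array(
        [
            divergence_rate(codebooks[k], codebooks[k + 1], q, t[k + 1] - t[k], config)
            for k in range(t.size - 1)
        ]
    )
    sd = float(M_raw.std())
    degenerate = sd == 0.0
    M_norm = np.zeros_like(M_raw) if degenerate else (M_raw - M_raw.mean()) / sd
    return DivergenceSeries(
        t=t,
        t_mid=0.5 * (t[:-1] + t[1:]),
        M_raw=M_raw,
        M_norm=M_norm,
        q=q,
        degenerate=degenerate,
    )


def codebook_from_deterministic_map(
    mapping: Callable[[int], int],
    n_in: int,
    n_out: int,
    mode: str = "one_hot",
) -> Codebook:
    """Codebook of a deterministic input->output map.

    ``one_hot`` puts probability 1 on ``mapping(x)`` in column ``x``.
    ``paper_subnorm`` instead puts ``1/(n_in + 1)`` there — the
    sub-normalized convention used when one extra output state is reserved
    for everything outside the nominal input set (columns then do not sum
    to 1; downstream KL relies on the floor clamp).
    """
    if mode not in ("one_hot", "paper_subnorm"):
        raise ValueError(f"unknown mode {mode!r}")
    value = 1.0 if mode == "one_hot" else 1.0 / (n_in + 1)
    p = np.zeros((n_out, n_in))
    for x in range(n_in):
        y = mapping(x)
        if not 0 <= y < n_out:
            raise ValueError(f"mapping({x}) = {y} out of range [0, {n_out})")
        p[y, x] = value
    return Codebook(p, normalized=(mode == "one_hot"))
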