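"""Validation and application studies for the divergence-rate measure.

These entry points reproduce, at configurable scale, the studies that
validate criticality detection on rate–distortion problems:

* random RD problems and the count of significant divergence-rate peaks
  versus the conjectured ``n - 1`` law;
* weak universality — i.i.d.-drawn distortion matrices give nearly
  coincident RD curves whose critical points nevertheless differ;
* the (u, beta) criticality manifold of the Berger three-state family;
* an 18-state clustering demo whose intermediate codebooks code for the
  cluster centers;
* the ternarized 2x2-patch coding pipeline (ON/OFF-style sensory code,
  Hamming distortion, 81 states), with a synthetic 1/f-noise image
  generator standing in for a natural-image database.

Every entry point is deterministic given its seed(s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .divergence import DivergenceSeries, KLConfig, divergence_series
from .exact import BERGER_U_MAX, berger_critical_w, berger_problem
from .peaks import PeakConfig, PeakSet, find_significant_peaks
from .rd import BAConfig, RDProblem, RDSolution, rd_curve, solve_path

__all__ = [
    "RandomRDSpec",
    "CriticalCountResult",
    "WeakUniversalityResult",
    "HeatmapResult",
    "PatchState",
    "N_PATCH_STATES",
    "default_beta_grid",
    "random_rd_problem",
    "divergence_over_betas",
    "divergence_over_w",
    "count_critical_points",
    "conjecture1_experiment",
    "weak_universality_experiment",
    "criticality_heatmap",
    "cluster_problem",
    "ternarize_patch",
    "patch_state_from_index",
    "patch_rd_problem",
    "synthetic_image_generator",
]


def default_beta_grid(
    beta_min: float = 0.05, beta_max: float = 10.0, num: int = 400
) -> np.ndarray:
    """Log-spaced beta grid dense enough to resolve support transitions of
    small worked examples."""
    return np.geomspace(beta_min, beta_max, num)


def default_scan_grid(
    beta_min: float = 0.01, beta_max: float = 60.0, num: int = 700
) -> np.ndarray:
    """Geometric beta grid for criticality scans.

    Peak counts estimate the number of support transitions *inside* the
    sampled window, so the window must cover essentially all of them: for
    problems of up to ~10 states with distortions of order [0, 4], the
    latest first-entries occur around beta 20-60 (they scale up as the
    smallest off-diagonal distortion shrinks) and the collapse to a single
    output finishes above beta 0.01.  Critical betas spread roughly
    log-uniformly, so geometric spacing resolves the low-beta cluster that
    a linear grid would merge; the scan's divergence series runs over
    ``t = -ln(beta)``, on which these grid steps are uniform.
    """
    return np.geomspace(beta_min, beta_max, num)


# ---------------------------------------------------------------------------
# random problems and the n - 1 law
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RandomRDSpec:
    """Recipe for a random RD problem: ``q`` from normalized uniform draws,
    distortions with zero diagonal and off-diagonal entries uniform on
    ``[d_low, d_high]`` (default [0, 4])."""

    n: int
    seed: int
    d_low: float = 0.0
    d_high: float = 4.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be at least 2")
        if self.d_low < 0 or self.d_high <= self.d_low:
            raise ValueError("need 0 <= d_low < d_high")


def random_rd_problem(spec: RandomRDSpec) -> RDProblem:
    """Draw the problem described by ``spec``; reproducible from its seed."""
    rng = np.random.default_rng(spec.seed)
    q = rng.uniform(0.0, 1.0, size=spec.n)
    # strictly positive q is required; a zero draw has probability zero but
    # guard against it anyway
    q = np.maximum(q, 1e-12)
    q /= q.sum()
    d = rng.uniform(spec.d_low, spec.d_high, size=(spec.n, spec.n))
    np.fill_diagonal(d, 0.0)
    return RDProblem(q=q, d=d)


def divergence_over_betas(
    problem: RDProblem,
    beta_grid: np.ndarray,
    ba_config: BAConfig | None = None,
    kl_config: KLConfig | None = None,
) -> tuple[list[RDSolution], DivergenceSeries]:
    """RD continuation along an increasing beta grid plus the divergence
    series of the resulting codebooks (abscissa t = beta)."""
    solutions = rd_curve(problem, beta_grid, ba_config)
    series = divergence_series(
        [s.codebook for s in solutions], beta_grid, problem.q, kl_config
    )
    return solutions, series


def divergence_over_w(
    problem: RDProblem,
    w_grid: np.ndarray,
    ba_config: BAConfig | None = None,
    kl_config: KLConfig | None = None,
) -> tuple[list[RDSolution], DivergenceSeries]:
    """Same pipeline on an increasing ``w = exp(-beta)`` grid (the natural
    abscissa for the two-state plots); the continuation runs from small w
    (high beta) upward."""
    w_grid = np.asarray(w_grid, dtype=float)
    if np.any(np.diff(w_grid) <= 0):
        raise ValueError("w_grid must be strictly increasing")
    if np.any((w_grid <= 0) | (w_grid >= 1)):
        raise ValueError("w values must lie in (0, 1)")
    solutions = solve_path(problem, -np.log(w_grid), ba_config)
    series = divergence_series(
        [s.codebook for s in solutions], w_grid, problem.q, kl_config
    )
    return solutions, series


@dataclass(frozen=True)
class CriticalScan:
    """A downward traversal of the RD curve: solutions from high to low
    beta, the divergence series over the traversal parameter
    ``t = -ln(beta)``, the significant peaks, and their critical betas
    (sorted increasing)."""

    solutions: list
    series: DivergenceSeries
    peaks: PeakSet
    beta_stars: np.ndarray


def critical_scan(
    problem: RDProblem,
    beta_grid: np.ndarray | None = None,
    ba_config: BAConfig | None = None,
    kl_config: KLConfig | None = None,
    peak_config: PeakConfig | None = None,
) -> CriticalScan:
    """Locate critical betas by scanning the RD curve from high to low beta.

    Traversed in this direction every support transition is a support
    *loss* for the next codebook (states drop out one by one as beta
    decreases), so each critical beta produces a sentinel-capped divergence
    spike of uniform height — whereas in the increasing direction a state's
    emergence yields only a small finite kink that the global significance
    filter would miss next to a genuine loss.  The series abscissa is
    ``t = -ln(beta)`` (increasing along the traversal, with uniform steps
    on a geometric grid); peak locations are reported as betas.
    """
    beta_grid = default_scan_grid() if beta_grid is None else np.asarray(beta_grid, dtype=float)
    if np.any(np.diff(beta_grid) <= 0):
        raise ValueError("beta_grid must be strictly increasing")
    if np.any(beta_grid <= 0):
        raise ValueError("beta values must be positive")
    descending = beta_grid[::-1]
    solutions = solve_path(problem, descending, ba_config)
    series = divergence_series(
        [s.codebook for s in solutions], -np.log(descending), problem.q, kl_config
    )
    peaks = find_significant_peaks(series, peak_config)
    return CriticalScan(
        solutions=solutions,
        series=series,
        peaks=peaks,
        beta_stars=np.sort(np.exp(-peaks.x)),
    )


def count_critical_points(
    problem: RDProblem,
    beta_grid: np.ndarray | None = None,
    ba_config: BAConfig | None = None,
    kl_config: KLConfig | None = None,
    peak_config: PeakConfig | None = None,
) -> int:
    """Number of significant divergence-rate peaks along the RD curve."""
    if problem.n == 1:
        return 0
    scan = critical_scan(problem, beta_grid, ba_config, kl_config, peak_config)
    return len(scan.peaks)


@dataclass(frozen=True)
class CriticalCountResult:
    """Mean/sd significant-peak counts per state count ``n``, with the
    coefficient of determination of the means against the fixed line
    ``n - 1`` (not a fitted line)."""

    n_values: np.ndarray
    mean_counts: np.ndarray
    sd_counts: np.ndarray
    r_squared: float


def conjecture1_experiment(
    n_values=range(2, 11),
    trials: int = 10,
    seed: int = 0,
    beta_grid: np.ndarray | None = None,
    ba_config: BAConfig | None = None,
    kl_config: KLConfig | None = None,
    peak_config: PeakConfig | None = None,
    d_low: float = 0.0,
    d_high: float = 4.0,
) -> CriticalCountResult:
    """Peak counts on random problems versus the ``n - 1`` law.

    For each ``n`` draws ``trials`` random problems (child seeds derived
    from ``seed``), counts significant peaks for each, and regresses the
    per-``n`` means onto the line ``n - 1``.
    """
    if trials < 1:
        raise ValueError("trials must be at least 1")
    n_values = np.asarray(list(n_values), dtype=int)
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=(n_values.size, trials))
    means = np.empty(n_values.size)
    sds = np.empty(n_values.size)
    for k, n in enumerate(n_values):
        counts = [
            count_critical_points(
                random_rd_problem(
                    RandomRDSpec(n=int(n), seed=int(child_seeds[k, t]), d_low=d_low, d_high=d_high)
                ),
                beta_grid,
                ba_config,
                kl_config,
                peak_config,
            )
            for t in range(trials)
        ]
        means[k] = np.mean(counts)
        sds[k] = np.std(counts)
    line = n_values - 1.0
    ss_res = float(np.sum((means - line) ** 2))
    ss_tot = float(np.sum((means - means.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    return CriticalCountResult(
        n_values=n_values, mean_counts=means, sd_counts=sds, r_squared=r2
    )


# ---------------------------------------------------------------------------
# weak universality
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WeakUniversalityResult:
    """Two RD curves from i.i.d.-drawn distortions on a uniform source, the
    sup vertical gap between them on the common distortion range, and the
    critical-point sets found on each."""

    curve1: tuple[np.ndarray, np.ndarray]  # (D, R)
    curve2: tuple[np.ndarray, np.ndarray]
    gap: float
    peaks1: PeakSet
    peaks2: PeakSet


def _uniform_q_problem(n: int, seed: int, d_high: float = 1.0) -> RDProblem:
    rng = np.random.default_rng(seed)
    d = rng.uniform(0.0, d_high, size=(n, n))
    np.fill_diagonal(d, 0.0)
    return RDProblem(q=np.full(n, 1.0 / n), d=d)


def weak_universality_experiment(
    n: int,
    seed1: int,
    seed2: int,
    beta_grid: np.ndarray | None = None,
    ba_config: BAConfig | None = None,
    kl_config: KLConfig | None = None,
    peak_config: PeakConfig | None = None,
) -> WeakUniversalityResult:
    """Compare RD curves and critical points of two random distortions.

    Both problems use the uniform source on ``n`` states and distortion
    entries uniform on [0, 1] (zero diagonal).  The gap is the sup of
    ``|R1(D) - R2(D)|`` over a common 200-point distortion grid.
    """
    beta_grid = default_beta_grid() if beta_grid is None else beta_grid
    curves = []
    peak_sets = []
    for seed in (seed1, seed2):
        problem = _uniform_q_problem(n, seed)
        sols, series = divergence_over_betas(problem, beta_grid, ba_config, kl_config)
        D = np.array([s.D for s in sols])
        R = np.array([s.R for s in sols])
        curves.append((D, R))
        peak_sets.append(find_significant_peaks(series, peak_config))

    (D1, R1), (D2, R2) = curves
    lo = max(D1.min(), D2.min())
    hi = min(D1.max(), D2.max())
    if hi <= lo:
        gap = float("inf")
    else:
        Dg = np.linspace(lo, hi, 200)
        # D decreases along increasing beta; np.interp needs ascending x
        r1 = np.interp(Dg, D1[::-1], R1[::-1])
        r2 = np.interp(Dg, D2[::-1], R2[::-1])
        gap = float(np.max(np.abs(r1 - r2)))
    return WeakUniversalityResult(
        curve1=curves[0],
        curve2=curves[1],
        gap=gap,
        peaks1=peak_sets[0],
        peaks2=peak_sets[1],
    )


# ---------------------------------------------------------------------------
# the (u, beta) criticality manifold of the Berger family
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HeatmapResult:
    """Normalized divergence rates over a (u, beta) grid for the Berger
    family, with the closed-form critical curve where it exists."""

    u: np.ndarray
    t_mid: np.ndarray
    M: np.ndarray  # shape (len(u), len(beta) - 1)
    theory_u: np.ndarray
    theory_beta: np.ndarray


def criticality_heatmap(
    u_grid: np.ndarray,
    beta_grid: np.ndarray,
    ba_config: BAConfig | None = None,
    kl_config: KLConfig | None = None,
) -> HeatmapResult:
    """Divergence-rate heatmap over source parameter ``u`` and ``beta``.

    Each row is the z-score-normalized divergence series of the Berger
    problem at that ``u``.  The theoretical overlay
    ``beta* = -ln w*(u)`` exists only for ``u <= 3 - 2*sqrt(2)``.
    """
    u_grid = np.asarray(u_grid, dtype=float)
    beta_grid = np.asarray(beta_grid, dtype=float)
    rows = []
    t_mid = None
    for u in u_grid:
        _, series = divergence_over_betas(
            berger_problem(float(u)), beta_grid, ba_config, kl_config
        )
        rows.append(series.M_norm)
        t_mid = series.t_mid
    theory_u = u_grid[u_grid <= BERGER_U_MAX]
    theory_beta = np.array(
        [-np.log(berger_critical_w(float(u))) for u in theory_u]
    )
    return HeatmapResult(
        u=u_grid,
        t_mid=t_mid,
        M=np.vstack(rows),
        theory_u=theory_u,
        theory_beta=theory_beta,
    )


# ---------------------------------------------------------------------------
# clustering demo
# ---------------------------------------------------------------------------


def cluster_problem(
    n_clusters: int = 3,
    per_cluster: int = 6,
    d_intra: float = 0.1,
    d_inter: float = 4.0,
    jitter: float = 0.05,
    seed: int = 0,
) -> RDProblem:
    """Block-structured RD problem: uniform source over
    ``n_clusters * per_cluster`` states, low within-block distortion
    ``d_intra``, high across-block distortion ``d_inter``, plus symmetric
    uniform jitter on [0, jitter] to break ties.

    The wide intra/inter separation (40x by default) opens a clear
    annealing phase in which the optimal codebook puts essentially all
    output mass on one representative state per block — the clustering
    phenomenon the demo illustrates.  With a milder separation the
    within-block merge overlaps the across-block merge and no exact
    one-per-block phase appears.
    """
    if d_intra >= d_inter:
        raise ValueError("d_intra must be smaller than d_inter")
    n = n_clusters * per_cluster
    block = np.repeat(np.arange(n_clusters), per_cluster)
    d = np.where(block[:, None] == block[None, :], d_intra, d_inter).astype(float)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        noise = rng.uniform(0.0, jitter, size=(n, n))
        noise = np.triu(noise, 1)
        d = d + noise + noise.T
    np.fill_diagonal(d, 0.0)
    return RDProblem(q=np.full(n, 1.0 / n), d=d)


# ---------------------------------------------------------------------------
# ternarized image patches
# ---------------------------------------------------------------------------

#: 3**4 ternary states of a 2x2 patch.
N_PATCH_STATES = 81

# per-pixel ternary digit -> 2-bit code: below threshold, middle, above
_DIGIT_BITS = {0: (0, 1), 1: (0, 0), 2: (1, 0)}
_POWERS = np.array([27, 9, 3, 1])


@dataclass(frozen=True)
class PatchState:
    """Ternarized 2x2 patch: four ternary digits (0 = below -0.5,
    1 = middle, 2 = above 0.5 after per-patch normalization), their 8-bit
    ON/OFF code, and the base-3 state index in [0, 80]."""

    digits: tuple
    bits: tuple
    index: int


def _state_from_digits(digits: np.ndarray) -> PatchState:
    digits = tuple(int(t) for t in digits)
    bits = tuple(b for t in digits for b in _DIGIT_BITS[t])
    return PatchState(digits=digits, bits=bits, index=int(np.dot(digits, _POWERS)))


def patch_state_from_index(index: int) -> PatchState:
    """Inverse of the digits -> index bijection."""
    if not 0 <= index < N_PATCH_STATES:
        raise ValueError(f"index must lie in [0, {N_PATCH_STATES})")
    digits = [(index // p) % 3 for p in _POWERS]
    return _state_from_digits(np.array(digits))


def ternarize_patch(patch: np.ndarray) -> PatchState:
    """Ternarize one 2x2 patch.

    The four values are mean-centered and scaled to unit variance, then
    each normalized value ``v`` maps to a 2-bit code: ``v < -0.5`` ->
    (0, 1), ``-0.5 <= v <= 0.5`` -> (0, 0), ``v > 0.5`` -> (1, 0).
    Constant patches (zero variance) map to the all-middle state by
    convention.
    """
    vals = np.asarray(patch, dtype=float).reshape(-1)
    if vals.size != 4:
        raise ValueError("patch must contain exactly 4 values")
    sd = vals.std()
    if sd == 0:
        return _state_from_digits(np.ones(4, dtype=int))
    v = (vals - vals.mean()) / sd
    digits = np.where(v < -0.5, 0, np.where(v > 0.5, 2, 1))
    return _state_from_digits(digits)


def _ternarize_image(image: np.ndarray, stride: int) -> np.ndarray:
    """Vectorized state indices of all 2x2 patches of one image."""
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    rows = np.arange(0, h - 1, stride)
    cols = np.arange(0, w - 1, stride)
    # stack the four pixels of each patch along the last axis
    vals = np.stack(
        [
            img[np.ix_(rows, cols)],
            img[np.ix_(rows, cols + 1)],
            img[np.ix_(rows + 1, cols)],
            img[np.ix_(rows + 1, cols + 1)],
        ],
        axis=-1,
    ).reshape(-1, 4)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    v = np.divide(vals - mean, sd, out=np.zeros_like(vals), where=sd > 0)
    digits = np.where(v < -0.5, 0, np.where(v > 0.5, 2, 1))
    return digits @ _POWERS


def _hamming_distortion() -> np.ndarray:
    """81x81 Hamming distances between the 8-bit patch codes.

    Per pixel, the 2-bit codes of the three ternary levels satisfy
    ``hamming = |t_a - t_b|``, so the distance is the L1 distance between
    digit vectors; the maximum is 8.
    """
    digits = np.array([patch_state_from_index(i).digits for i in range(N_PATCH_STATES)])
    return np.abs(digits[:, None, :] - digits[None, :, :]).sum(axis=2).astype(float)


def patch_rd_problem(images, patch_stride: int = 2) -> RDProblem:
    """Empirical RD problem of ternarized 2x2 patches.

    ``q`` is the empirical distribution of patch states over all patches of
    all images (a pseudo-count of 1 keeps unobserved states strictly
    positive); the distortion is the Hamming distance between the 8-bit
    codes of the two states.
    """
    images = list(images)
    if not images:
        raise ValueError("need at least one image")
    if patch_stride < 1:
        raise ValueError("patch_stride must be positive")
    counts = np.zeros(N_PATCH_STATES)
    for img in images:
        idx = _ternarize_image(img, patch_stride)
        counts += np.bincount(idx, minlength=N_PATCH_STATES)
    q = (counts + 1.0) / (counts.sum() + N_PATCH_STATES)
    return RDProblem(q=q, d=_hamming_distortion())


def synthetic_image_generator(
    seed: int, width: int = 128, height: int = 128, count: int = 4
) -> list[np.ndarray]:
    """Grayscale images with a 1/f amplitude spectrum and random phases.

    Emulates the second-order statistics of natural scenes (power spectral
    density falling as 1/f^2) without any download; pixel values are
    rescaled to [0, 1].  Deterministic per seed.
    """
    if width <= 0 or height <= 0 or count <= 0:
        raise ValueError("width, height and count must be positive")
    rng = np.random.default_rng(seed)
    fy = np.fft.fftfreq(height)[:, None]
    fx = np.fft.fftfreq(width)[None, :]
    f = np.sqrt(fx**2 + fy**2)
    amp = np.zeros_like(f)
    np.divide(1.0, f, out=amp, where=f > 0)  # DC stays zero
    images = []
    for _ in range(count):
        phase = rng.standard_normal((height, width)) + 1j * rng.standard_normal(
            (height, width)
        )
        img = np.fft.ifft2(amp * phase).real
        lo, hi = img.min(), img.max()
        images.append((img - lo) / (hi - lo))
    return images
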