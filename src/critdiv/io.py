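"""Plain-text readers and writers shared by the CLI and the experiments.

Everything is JSON or delimited text (precision %.17g) so runs diff
cleanly and round-trip losslessly.  The matrix convention is stated in
every header: rows = outputs i, cols = inputs j.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .divergence import DivergenceSeries
from .rd import Codebook, RDProblem, RDSolution

__all__ = [
    "load_problem",
    "load_problem_text",
    "save_problem",
    "save_curve",
    "load_curve",
    "save_series",
    "load_series",
    "save_peaks",
    "write_manifest",
]

_FMT = "%.17g"
_CONVENTION = "rows=outputs, cols=inputs"


def load_problem(path) -> RDProblem:
    """Read an RD problem from JSON ``{"q": [...], "d": [[...], ...]}``.

    Validation (simplex, non-negativity, shape) happens on construction and
    failures carry the offending field in the message.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not valid JSON ({exc})") from exc
    for key in ("q", "d"):
        if key not in payload:
            raise ValueError(f"{path}: missing required field {key!r}")
    try:
        return RDProblem(q=np.asarray(payload["q"], dtype=float),
                         d=np.asarray(payload["d"], dtype=float))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def load_problem_text(q_path, d_path) -> RDProblem:
    """Read a problem from two delimited files: one row for ``q``, matrix
    rows for ``d``."""
    q = np.loadtxt(q_path, ndmin=1)
    d = np.loadtxt(d_path, ndmin=2)
    return RDProblem(q=q, d=d)


def save_problem(problem: RDProblem, path) -> None:
    path = Path(path)
    path.write_text(
        json.dumps({"q": problem.q.tolist(), "d": problem.d.tolist()}, indent=1)
        + "\n"
    )


def save_curve(solutions: list[RDSolution], directory) -> None:
    """Write an RD curve: per-point summary, codebooks, and a JSON sidecar.

    ``curve.tsv`` holds (beta, w, D, R) rows; ``codebooks.tsv`` one row per
    point — beta followed by the row-major flattened codebook; the sidecar
    carries output distributions, supports and convergence flags.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    summary = np.array([[s.beta, s.w, s.D, s.R] for s in solutions])
    np.savetxt(
        directory / "curve.tsv",
        summary,
        fmt=_FMT,
        delimiter="\t",
        header="beta\tw\tD\tR",
    )
    n_out, n_in = solutions[0].codebook.p_cond.shape
    rows = np.array(
        [np.concatenate([[s.beta], s.codebook.p_cond.ravel()]) for s in solutions]
    )
    np.savetxt(
        directory / "codebooks.tsv",
        rows,
        fmt=_FMT,
        delimiter="\t",
        header=f"beta then codebook flattened row-major, shape=({n_out},{n_in}), {_CONVENTION}",
    )
    sidecar = {
        "convention": _CONVENTION,
        "shape": [n_out, n_in],
        "points": [
            {
                "beta": s.beta,
                "w": s.w,
                "D": s.D,
                "R": s.R,
                "p_out": s.p_out.tolist(),
                "support": s.support.tolist(),
                "converged": s.converged,
            }
            for s in solutions
        ],
    }
    (directory / "curve.json").write_text(json.dumps(sidecar, indent=1) + "\n")


def load_curve(directory) -> tuple[np.ndarray, list[Codebook]]:
    """Read back (beta grid, codebooks) from a curve directory."""
    directory = Path(directory)
    shape = tuple(json.loads((directory / "curve.json").read_text())["shape"])
    rows = np.loadtxt(directory / "codebooks.tsv", ndmin=2)
    betas = rows[:, 0]
    codebooks = [Codebook(r[1:].reshape(shape)) for r in rows]
    return betas, codebooks


def save_series(series: DivergenceSeries, path) -> None:
    """Write a divergence series as (t_mid, M_raw, M_norm) columns, with a
    JSON sidecar holding the full parameter grid and source weights."""
    path = Path(path)
    np.savetxt(
        path,
        np.column_stack([series.t_mid, series.M_raw, series.M_norm]),
        fmt=_FMT,
        delimiter="\t",
        header="t_mid\tM_raw\tM_norm",
    )
    sidecar = {
        "t": series.t.tolist(),
        "q": series.q.tolist(),
        "degenerate": series.degenerate,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1) + "\n"
    )


def load_series(path) -> DivergenceSeries:
    path = Path(path)
    cols = np.loadtxt(path, ndmin=2)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        t = np.asarray(sidecar["t"], dtype=float)
        q = np.asarray(sidecar["q"], dtype=float)
        degenerate = bool(sidecar.get("degenerate", False))
    else:
        # midpoints alone determine peak finding; reconstruct a nominal grid
        t_mid = cols[:, 0]
        t = np.concatenate([[t_mid[0]], 0.5 * (t_mid[:-1] + t_mid[1:]), [t_mid[-1]]])
        q = np.array([1.0])
        degenerate = bool(np.all(cols[:, 1] == cols[0, 1]))
    return DivergenceSeries(
        t=t,
        t_mid=cols[:, 0],
        M_raw=cols[:, 1],
        M_norm=cols[:, 2],
        q=q,
        degenerate=degenerate,
    )


def save_peaks(peak_set, path) -> None:
    """Peaks as JSON ``[{"x": ..., "height": ...}, ...]``."""
    payload = [
        {"x": float(x), "height": float(h)}
        for x, h in zip(peak_set.x, peak_set.height)
    ]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def write_manifest(path, command: str, seed: int | None, params: dict) -> None:
    """Record what produced a run's outputs: command, seed, parameters and
    library versions, enough to reconstruct the run exactly."""
    import critdiv

    manifest = {
        "command": command,
        "seed": seed,
        "params": params,
        "versions": {"critdiv": critdiv.__version__, "numpy": np.__version__},
    }
    Path(path).write_text(json.dumps(manifest, indent=1) + "\n")
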