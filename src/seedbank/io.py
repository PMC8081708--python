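"""Serialisation and fixture generation.

Rate matrices and degenerate semigroups round-trip through JSON (state list
plus dense entries); jump paths and diffusion grids go to CSV with fixed
column schemas.  Floats are written with 17 significant digits so exact
quantities round-trip bit for bit.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from . import __version__
from .ctmc import JumpPath, ModelParams, RateMatrix, SampleConfig, StateSpace, build_blockcounting_Q
from .diffusion import DiffusionPathGrid
from .limits import build_aalp, build_imbalanced_limit, build_reduced_chain, telegraph_closed_form
from .timescales import build_slow_limit_matrix, matrix_norm

__all__ = [
    "rate_matrix_to_json",
    "rate_matrix_from_json",
    "semigroup_to_json",
    "jump_paths_to_csv",
    "path_grid_to_csv",
    "write_manifest",
    "generate_fixtures",
]

_FMT = "%.17g"


def _round_trip_floats(arr) -> list:
    return json.loads(json.dumps(np.asarray(arr, dtype=float).tolist()))


def rate_matrix_to_json(Q: RateMatrix) -> str:
    return json.dumps(
        {"states": [list(s) for s in Q.space.states], "entries": np.asarray(Q.entries).tolist()},
        indent=1,
    )


def rate_matrix_from_json(text: str) -> RateMatrix:
    obj = json.loads(text)
    space = StateSpace(tuple(s) for s in obj["states"])
    Q = RateMatrix(space, np.asarray(obj["entries"], dtype=float))
    Q.validate(tol=1e-9)
    return Q


def semigroup_to_json(P: np.ndarray, G: np.ndarray, states) -> str:
    return json.dumps(
        {
            "states": [list(s) for s in states],
            "P": np.asarray(P).tolist(),
            "G": np.asarray(G).tolist(),
        },
        indent=1,
    )


def jump_paths_to_csv(paths: list[JumpPath], file) -> None:
    """Write jump paths with columns ``replicate,time,n,m``."""
    w = csv.writer(file)
    w.writerow(["replicate", "time", "n", "m"])
    for r, path in enumerate(paths):
        for t, (n, m) in zip(path.times, path.states):
            w.writerow([r, _FMT % t, n, m])


def path_grid_to_csv(grid: DiffusionPathGrid, file) -> None:
    """Write recorded diffusion/jump-process values with columns
    ``replicate,time,x,y``."""
    w = csv.writer(file)
    w.writerow(["replicate", "time", "x", "y"])
    for r in range(grid.values.shape[0]):
        for k, t in enumerate(grid.times):
            w.writerow([r, _FMT % t, _FMT % grid.values[r, k, 0], _FMT % grid.values[r, k, 1]])


def write_manifest(outdir: Path, config: dict) -> Path:
    """Record the full configuration of a run so it can be reproduced."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"package": "seedbank", "version": __version__, "config": config}
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def generate_fixtures(outdir) -> dict:
    """Write the canonical small-instance matrices and expected identities.

    For samples (1,1), (2,2), (3,3) and K in {0.5, 1, 2}: the block-counting
    generator (c = 0.1), projection P, limit generator G, reduced-chain
    Q-matrix, imbalanced-island limit generator, the exact identity residual
    ``||P B P - G||`` (0 by construction) and telegraph closed-form values on
    a canonical time grid.  Regeneration is idempotent.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_grid = [0.1, 0.5, 1.0, 2.0, 5.0]
    written = {}
    for n0, m0 in [(1, 1), (2, 2), (3, 3)]:
        sample = SampleConfig(n0, m0)
        for K in (0.5, 1.0, 2.0):
            name = f"sample_{n0}_{m0}_K_{K:g}"
            aalp = build_aalp(sample, K)
            Q = build_blockcounting_Q(sample, ModelParams(c=0.1, K=K))
            B = build_slow_limit_matrix(aalp.space, K, "seedbank")
            Bhat = build_slow_limit_matrix(aalp.space, K, "two_island")
            ghat = build_imbalanced_limit(sample, K)
            reduced = build_reduced_chain(m0 + 1, K)
            p11, p10 = telegraph_closed_form(K, t_grid)
            payload = {
                "sample": [n0, m0],
                "K": K,
                "states": [list(s) for s in aalp.space.states],
                "Q_c0.1": _round_trip_floats(Q.entries),
                "P": _round_trip_floats(aalp.P),
                "G": _round_trip_floats(aalp.G),
                "G_imbalanced": _round_trip_floats(ghat.G),
                "reduced_states": [list(s) for s in reduced.space.states],
                "G_reduced": _round_trip_floats(reduced.Gbar),
                "PBP_minus_G_norm": matrix_norm(aalp.P @ B @ aalp.P - aalp.G),
                "PBhatP_minus_Ghat_norm": matrix_norm(aalp.P @ Bhat @ aalp.P - ghat.G),
                "telegraph_t": t_grid,
                "telegraph_p11": _round_trip_floats(p11),
                "telegraph_p10": _round_trip_floats(p10),
            }
            (outdir / f"{name}.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
            written[name] = payload
    return written
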