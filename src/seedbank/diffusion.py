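"""Forward-in-time frequency diffusions with a seed bank.

The seed bank diffusion tracks the frequency ``X`` of an allele in the active
population and ``Y`` in the dormant population:

    dX = c (Y - X) dt + sqrt(X (1 - X)) dB,
    dY = K c (X - Y) dt,

with migration rate ``c`` and size ratio ``K``; only the active population
reproduces, so only ``X`` carries genetic drift.  The two-island diffusion
adds independent drift noise ``alpha' sqrt(Y (1 - Y)) dB'`` in the second
island (and a scale ``alpha`` in the first).  Both are simulated by clamped
Euler-Maruyama; the weighted frequency ``K X + Y`` is a martingale and serves
as a built-in consistency check, while moment duality against the exact
block-counting semigroup (see :mod:`seedbank.duality`) bounds the
discretisation bias empirically.

The super-evolutionary rescaling observes ``(X(t/c), Y(t/c))`` as ``c`` gets
small; along that schedule the active frequency spends almost all time near
the boundaries and its law approaches the jump-process limit of
:mod:`seedbank.pdmp`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._kernels import twoisland_em
from .ctmc import ModelParams

__all__ = [
    "DiffusionState",
    "EMConfig",
    "DiffusionPathGrid",
    "simulate_seedbank_sde",
    "simulate_twoisland_sde",
    "rescale_super_evolutionary",
]

_SEED_MOD = 2**31


@dataclass(frozen=True)
class DiffusionState:
    """Allele frequencies (active, dormant) in the unit square."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.x <= 1.0 and 0.0 <= self.y <= 1.0):
            raise ValueError("frequencies must lie in [0, 1]")


@dataclass(frozen=True)
class EMConfig:
    """Euler-Maruyama settings: step, horizon, replicates, seed, output grid."""

    dt: float
    horizon: float
    reps: int
    seed: int
    record_times: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.horizon < 0:
            raise ValueError("horizon must be non-negative")
        if self.reps < 1:
            raise ValueError("need at least one replicate")
        rt = tuple(float(t) for t in self.record_times)
        if any(t < 0 or t > self.horizon + 1e-12 for t in rt):
            raise ValueError("record times must lie in [0, horizon]")
        object.__setattr__(self, "record_times", rt)


@dataclass
class DiffusionPathGrid:
    """Recorded trajectories: ``values[r, k]`` is ``(x, y)`` of replicate
    ``r`` at ``times[k]``."""

    times: np.ndarray
    values: np.ndarray

    def moment(self, n: int, m: int, k: int = -1):
        """Monte-Carlo mixed moment ``E[X^n Y^m]`` at output index ``k``:
        returns ``(estimate, standard error)``."""
        x = self.values[:, k, 0]
        y = self.values[:, k, 1]
        samples = x**n * y**m
        est = float(samples.mean())
        se = float(samples.std(ddof=1) / np.sqrt(len(samples))) if len(samples) > 1 else 0.0
        return est, se


def _replicate_seeds(seed: int, reps: int) -> np.ndarray:
    return ((int(seed) + np.arange(reps)) % _SEED_MOD).astype(np.int64)


def _run_em(start: DiffusionState, params: ModelParams, cfg: EMConfig,
            alpha: float, alpha_prime: float) -> DiffusionPathGrid:
    n_steps = int(np.ceil(cfg.horizon / cfg.dt)) if cfg.horizon > 0 else 0
    rec_steps = np.array(sorted(int(round(t / cfg.dt)) for t in cfg.record_times), dtype=np.int64)
    rec_steps = np.minimum(rec_steps, n_steps)
    order = np.argsort([int(round(t / cfg.dt)) for t in cfg.record_times], kind="stable")
    out = np.empty((cfg.reps, len(rec_steps), 2))
    twoisland_em(
        start.x, start.y, params.c, params.K, alpha, alpha_prime,
        cfg.dt, n_steps, rec_steps, _replicate_seeds(cfg.seed, cfg.reps), out,
    )
    # undo the sort so columns follow cfg.record_times order
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    return DiffusionPathGrid(times=np.asarray(cfg.record_times), values=out[:, inv, :])


def simulate_seedbank_sde(start: DiffusionState, params: ModelParams, cfg: EMConfig) -> DiffusionPathGrid:
    """Simulate the seed bank diffusion (drift-only dormant coordinate).

    The state is clamped to the unit square after every step and the drift
    coefficient is evaluated at the clamped state, so the corners ``(0,0)``
    and ``(1,1)`` are exactly absorbing.  Deterministic under ``cfg.seed``.
    """
    _check_dt(params, cfg.dt)
    return _run_em(start, params, cfg, alpha=1.0, alpha_prime=0.0)


def simulate_twoisland_sde(start: DiffusionState, params: ModelParams, cfg: EMConfig) -> DiffusionPathGrid:
    """Simulate the two-island diffusion with independent noise per island.

    With ``alpha_prime = 0`` and ``alpha = 1`` this reproduces
    :func:`simulate_seedbank_sde` path for path under the same seed.
    """
    _check_dt(params, cfg.dt)
    return _run_em(start, params, cfg, alpha=params.alpha, alpha_prime=params.alpha_prime)


def _check_dt(params: ModelParams, dt: float) -> None:
    limit = 1.0 / (params.c * (1.0 + params.K))
    if dt >= limit:
        raise ValueError(
            f"step size dt = {dt:g} risks drift overshoot: require dt < 1/(c (1+K)) = {limit:g}"
        )


def rescale_super_evolutionary(
    start: DiffusionState,
    params: ModelParams,
    cfg: EMConfig,
    model: str = "seedbank",
) -> DiffusionPathGrid:
    """Observe the diffusion on the super-evolutionary timescale ``t -> t/c``.

    ``cfg.horizon`` and ``cfg.record_times`` are on the limit timescale; the
    simulation runs to ``horizon / c`` and reports ``(X(t/c), Y(t/c))``.
    With ``c = 1`` this is the identity.  A warning is issued when ``dt`` is
    not reduced alongside ``c`` (the bias of the scheme grows with the number
    of unresolved fixation excursions).
    """
    c = params.c
    if c < 1.0 and cfg.dt > 0.01 * c:
        warnings.warn(
            "step size dt should shrink with c (dt <~ c * 1e-3) to control "
            "discretisation bias on the super-evolutionary timescale",
            RuntimeWarning,
            stacklevel=2,
        )
    inner = EMConfig(
        dt=cfg.dt,
        horizon=cfg.horizon / c,
        reps=cfg.reps,
        seed=cfg.seed,
        record_times=tuple(t / c for t in cfg.record_times),
    )
    if model == "seedbank":
        grid = simulate_seedbank_sde(start, params, inner)
    elif model == "twoisland":
        grid = simulate_twoisland_sde(start, params, inner)
    else:
        raise ValueError("model must be 'seedbank' or 'twoisland'")
    return DiffusionPathGrid(times=np.asarray(cfg.record_times), values=grid.values)
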