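"""Piecewise-deterministic limits of the seed bank frequency process.

On the super-evolutionary timescale genetic drift acts instantaneously: the
active frequency fixates immediately at 0 or 1 (with probability given by the
initial frequency) and thereafter switches between the two boundaries.  While
the active state is ``x in {0, 1}`` the dormant frequency relaxes
deterministically,

    dY = K (x - Y) dt   =>   Y(t) = x + (y0 - x) exp(-K t),

and the switching hazard is the dormant frequency of the allele currently
extinct in the active population: ``Y(t)`` from state 0 and ``1 - Y(t)``
from state 1 (a resuscitating ancient allele fixates, flipping the active
state, only if it is of the opposite type).  Because the hazard decays
exponentially its cumulative integral is finite, so jump times are sampled by
exact closed-form inversion and a path may genuinely be absorbed with no
further jumps — there is no discretisation error in this simulator.

The two-island variant keeps drift noise in the second island; its dormant
coordinate is a diffusion and is simulated by an Euler-Maruyama/thinning
hybrid instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._kernels import jumpdiffusion_em
from .diffusion import DiffusionPathGrid, EMConfig
from .limits import telegraph_closed_form

__all__ = [
    "PDMPState",
    "PDMPPath",
    "simulate_limit_pdmp",
    "evaluate_pdmp",
    "pdmp_moments",
    "simulate_limit_jumpdiffusion",
]

_SEED_MOD = 2**31


@dataclass(frozen=True)
class PDMPState:
    """Fixation state of the active population and dormant frequency."""

    x: int
    y: float

    def __post_init__(self) -> None:
        if self.x not in (0, 1):
            raise ValueError("active state must be 0 or 1")
        if not 0.0 <= self.y <= 1.0:
            raise ValueError("dormant frequency must lie in [0, 1]")


@dataclass
class PDMPPath:
    """Exact jump skeleton of the limit process.

    ``initial`` is the raw starting point in the unit square (the state at
    time 0 before the instantaneous fixation); ``initial_x`` is the boundary
    the active frequency occupies from time ``0+``.  ``jump_times`` /
    ``jump_x`` / ``y_at_jumps`` record each switch (``jump_x`` is the state
    *after* the flip; ``y`` is continuous across jumps).  ``absorbed`` marks
    paths whose residual hazard was exhausted before the horizon.
    """

    initial: tuple[float, float]
    initial_x: int
    K: float
    horizon: float
    jump_times: list[float]
    jump_x: list[int]
    y_at_jumps: list[float]
    absorbed: bool

    def segments(self):
        """Yield ``(t_start, x, y_start)`` for each inter-jump segment."""
        t, x, y = 0.0, self.initial_x, self.initial[1]
        yield t, x, y
        for tj, xj, yj in zip(self.jump_times, self.jump_x, self.y_at_jumps):
            yield tj, xj, yj


def simulate_limit_pdmp(start, K: float, horizon: float, rng: np.random.Generator) -> PDMPPath:
    """Exact realisation of the seed bank limit process from ``start``.

    The active state is initialised at 1 with probability ``x0`` (the
    fixation probability of the instantaneous drift).  Jump times invert the
    cumulative hazard in closed form: with initial hazard ``h0`` the total
    remaining hazard is ``h0 / K``, so an Exp(1) draw exceeding it means the
    path never jumps again.
    """
    x0, y0 = float(start[0]), float(start[1])
    if K <= 0:
        raise ValueError("size ratio K must be positive")
    if not (0.0 <= x0 <= 1.0 and 0.0 <= y0 <= 1.0):
        raise ValueError("start must lie in the unit square")
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    x = 1 if rng.random() < x0 else 0
    x_start = x
    t, y = 0.0, y0
    jump_times: list[float] = []
    jump_x: list[int] = []
    y_at_jumps: list[float] = []
    absorbed = False
    while True:
        h0 = y if x == 0 else 1.0 - y
        if h0 <= 0.0:
            absorbed = True
            break
        E = rng.exponential(1.0)
        if E >= h0 / K:
            absorbed = True
            break
        delta = -math.log1p(-K * E / h0) / K
        if t + delta > horizon:
            break
        t += delta
        y = x + (y - x) * math.exp(-K * delta)
        x = 1 - x
        jump_times.append(t)
        jump_x.append(x)
        y_at_jumps.append(y)
    return PDMPPath(
        initial=(x0, y0),
        initial_x=x_start,
        K=K,
        horizon=horizon,
        jump_times=jump_times,
        jump_x=jump_x,
        y_at_jumps=y_at_jumps,
        absorbed=absorbed,
    )


def evaluate_pdmp(path: PDMPPath, t_grid):
    """Closed-form evaluation of the path on a time grid.

    Returns ``(x_values, y_values)``.  At ``t = 0`` exactly, the raw initial
    point is reported (the semigroup is the identity at time zero); for
    ``t > 0`` the active value is the binary right-continuous state.
    """
    segs_t = [0.0] + list(path.jump_times)
    segs_x = [path.initial_x] + list(path.jump_x)
    segs_y = [path.initial[1]] + list(path.y_at_jumps)
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(t_grid < 0) or np.any(t_grid > path.horizon + 1e-12):
        raise ValueError("evaluation times must lie within the horizon")
    xs = np.empty_like(t_grid)
    ys = np.empty_like(t_grid)
    starts = np.asarray(segs_t)
    for i, t in enumerate(t_grid):
        if t == 0.0:
            xs[i] = path.initial[0]
            ys[i] = path.initial[1]
            continue
        k = int(np.searchsorted(starts, t, side="right") - 1)
        x, y0, t0 = segs_x[k], segs_y[k], segs_t[k]
        xs[i] = x
        ys[i] = x + (y0 - x) * math.exp(-path.K * (t - t0))
    return xs, ys


def pdmp_moments(start, K: float, t: float, n: int, m: int, reps: int, rng: np.random.Generator):
    """Monte-Carlo mixed moment ``E[X(t)^n Y(t)^m]`` of the limit process.

    Returns ``(estimate, standard_error, exact)`` where ``exact`` is the
    closed-form value for pure-active moments (``m = 0``): independent of
    ``n >= 1`` it equals ``x * p11(t) + y * p10(t)`` from the telegraph
    sub-chain, and 1 for ``n = m = 0``; otherwise ``exact`` is ``None``.
    """
    if n < 0 or m < 0:
        raise ValueError("moment indices must be non-negative")
    samples = np.empty(reps)
    for r in range(reps):
        path = simulate_limit_pdmp(start, K, t, rng)
        xs, ys = evaluate_pdmp(path, [t])
        samples[r] = xs[0] ** n * ys[0] ** m
    est = float(samples.mean())
    se = float(samples.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
    exact = None
    if m == 0:
        if n == 0:
            exact = 1.0
        else:
            p11, p10 = telegraph_closed_form(K, t)
            exact = float(start[0] * p11 + start[1] * p10)
    return est, se, exact


def simulate_limit_jumpdiffusion(start, K: float, cfg: EMConfig) -> DiffusionPathGrid:
    """Two-island limit with a diffusive second island (hybrid scheme).

    The active state is binary from ``0+`` (initial Bernoulli with success
    probability ``x0``) and flips by per-step thinning with hazard ``y``
    (from 0) or ``1 - y`` (from 1); the dormant frequency follows clamped
    Euler-Maruyama with drift ``K (X - Y)`` and diffusion ``sqrt(Y (1-Y))``.
    Requires ``dt`` small enough that the per-step flip probability stays
    below 0.1.
    """
    x0, y0 = float(start[0]), float(start[1])
    if K <= 0:
        raise ValueError("size ratio K must be positive")
    if cfg.dt >= 0.1:
        raise ValueError("thinning requires dt * max-hazard < 0.1, i.e. dt < 0.1")
    n_steps = int(np.ceil(cfg.horizon / cfg.dt)) if cfg.horizon > 0 else 0
    rec = sorted(range(len(cfg.record_times)), key=lambda i: int(round(cfg.record_times[i] / cfg.dt)))
    rec_steps = np.array([min(int(round(cfg.record_times[i] / cfg.dt)), n_steps) for i in rec], dtype=np.int64)
    seeds = ((int(cfg.seed) + np.arange(cfg.reps)) % _SEED_MOD).astype(np.int64)
    out = np.empty((cfg.reps, len(rec_steps), 2))
    jumpdiffusion_em(x0, y0, K, cfg.dt, n_steps, rec_steps, seeds, out)
    inv = np.empty(len(rec), dtype=int)
    inv[rec] = np.arange(len(rec))
    return DiffusionPathGrid(times=np.asarray(cfg.record_times), values=out[:, inv, :])
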