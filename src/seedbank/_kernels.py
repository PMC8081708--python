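"""Compiled Euler-Maruyama kernels.

Replicate ``r`` seeds its own Mersenne stream with ``seeds[r]`` so results are
reproducible regardless of execution order; Gaussian increments come from an
inlined Box-Muller transform (two normals per trig evaluation) for speed.
All clamping keeps the state in the unit square and the diffusion coefficient
is evaluated at the clamped state.
"""

import numpy as np
from numba import njit

_TWO_PI = 6.283185307179586


@njit(cache=False, fastmath=True)
def twoisland_em(x0, y0, c, K, alpha, alpha_prime, dt, n_steps, rec_steps, seeds, out):
    """Clamped Euler-Maruyama for the two-island / seed bank SDE.

    ``out`` has shape (reps, n_rec, 2); ``rec_steps`` are sorted step indices
    (duplicates allowed).  With ``alpha_prime == 0`` no island-2 noise is
    drawn, so the pure seed bank model consumes the identical random stream.
    """
    sqdt = np.sqrt(dt)
    for r in range(seeds.shape[0]):
        np.random.seed(seeds[r])
        x = x0
        y = y0
        have = False
        spare = 0.0
        j = 0
        for i in range(n_steps + 1):
            while j < rec_steps.shape[0] and rec_steps[j] == i:
                out[r, j, 0] = x
                out[r, j, 1] = y
                j += 1
            if i == n_steps:
                break
            if have:
                z = spare
                have = False
            else:
                u1 = 1.0 - np.random.random()
                u2 = np.random.random()
                rad = np.sqrt(-2.0 * np.log(u1))
                z = rad * np.cos(_TWO_PI * u2)
                spare = rad * np.sin(_TWO_PI * u2)
                have = True
            dx = c * (y - x) * dt + alpha * np.sqrt(max(0.0, x * (1.0 - x))) * (z * sqdt)
            if alpha_prime > 0.0:
                if have:
                    z2 = spare
                    have = False
                else:
                    u1 = 1.0 - np.random.random()
                    u2 = np.random.random()
                    rad = np.sqrt(-2.0 * np.log(u1))
                    z2 = rad * np.cos(_TWO_PI * u2)
                    spare = rad * np.sin(_TWO_PI * u2)
                    have = True
                dy = c * K * (x - y) * dt + alpha_prime * np.sqrt(max(0.0, y * (1.0 - y))) * (
                    z2 * sqdt
                )
            else:
                dy = c * K * (x - y) * dt
            x = min(1.0, max(0.0, x + dx))
            y = min(1.0, max(0.0, y + dy))


@njit(cache=False, fastmath=True)
def jumpdiffusion_em(xprob, y0, K, dt, n_steps, rec_steps, seeds, out):
    """Hybrid scheme for the two-island jump-diffusion limit.

    The active frequency is binary from time 0+: it starts at 1 with
    probability ``xprob`` (the fixation probability) and flips by per-step
    thinning with hazard ``y`` (from 0) or ``1 - y`` (from 1); the dormant
    frequency follows clamped Euler-Maruyama with drift ``K (x - y)`` and
    diffusion ``sqrt(y (1 - y))``.
    """
    sqdt = np.sqrt(dt)
    for r in range(seeds.shape[0]):
        np.random.seed(seeds[r])
        x = 1.0 if np.random.random() < xprob else 0.0
        y = y0
        have = False
        spare = 0.0
        j = 0
        for i in range(n_steps + 1):
            while j < rec_steps.shape[0] and rec_steps[j] == i:
                out[r, j, 0] = x
                out[r, j, 1] = y
                j += 1
            if i == n_steps:
                break
            lam = y if x == 0.0 else 1.0 - y
            flip = np.random.random() < lam * dt
            if have:
                z = spare
                have = False
            else:
                u1 = 1.0 - np.random.random()
                u2 = np.random.random()
                rad = np.sqrt(-2.0 * np.log(u1))
                z = rad * np.cos(_TWO_PI * u2)
                spare = rad * np.sin(_TWO_PI * u2)
                have = True
            dy = K * (x - y) * dt + np.sqrt(max(0.0, y * (1.0 - y))) * (z * sqdt)
            y = min(1.0, max(0.0, y + dy))
            if flip:
                x = 1.0 - x
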