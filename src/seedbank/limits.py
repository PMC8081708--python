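"""Exact limit genealogies of the strong seed bank on the fast timescale.

When dormancy periods are much longer than the coalescent timescale and time
is sped up by ``1/c``, coalescence becomes instantaneous: for every positive
time at most one active ancestral lineage survives, and the genealogy is
driven purely by dormancy initiation and resuscitation (with immediate
coalescence on resuscitation).  This module constructs that limit — the
*ancient ancestral lines process* — in three equivalent forms:

* the degenerate semigroup ``Pi(t) = P e^{tG}`` on the full lineage grid,
  where ``P`` instantly collapses every state with active lineages to a
  single active lineage and ``G`` is the (non-Q-matrix) limit generator;
* the reduced chain on ``{0, 1} x {0, ..., m_max}`` whose conservative
  Q-matrix generates the same dynamics after the initial collapse, and which
  is the object one actually simulates;
* the closed-form telegraph sub-chain ``(1,0) <-> (0,1)`` that governs every
  start with no dormant lineages.

A two-island variant with imbalanced island sizes (island-2 coalescence
surviving in the limit) is provided alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .ctmc import JumpPath, RateMatrix, SampleConfig, StateSpace, binom2, gillespie_simulate
from .timescales import DegenerateSemigroup

__all__ = [
    "AALPSpec",
    "ReducedChainSpec",
    "build_projection",
    "build_aalp",
    "build_reduced_chain",
    "build_imbalanced_limit",
    "restriction_identity_check",
    "telegraph_closed_form",
    "simulate_aalp",
    "limit_mixed_moment",
]


def build_projection(space: StateSpace) -> np.ndarray:
    """Instantaneous-coalescence projection on the full lineage grid.

    Every state with ``n >= 1`` active lineages is sent with mass one to
    ``(1, m)``; states with no active lineage are fixed.  The result is a
    binary idempotent stochastic matrix.
    """
    n_states = len(space)
    P = np.zeros((n_states, n_states))
    for i, (n, m) in enumerate(space):
        target = (1, m) if n >= 1 else (0, m)
        P[i, space.index(target)] = 1.0
    return P


def _aalp_generator(space: StateSpace, K: float) -> np.ndarray:
    """Limit generator on the full grid (negative off-diagonals allowed).

    From any state: resuscitation-with-coalescence at rate ``K*m`` into
    ``(1, m-1)``; from states with active lineages, dormancy at rate 1 into
    ``(0, m+1)`` and mass ``-1-K*m`` at column ``(1, m)``; from empty-active
    states, ``-K*m`` on the diagonal.  Dormancy targets outside the finite
    grid are dropped; such rows are collapsed to zero mass by the projection
    for every positive time and never carry probability from a genuine start.
    """
    n_states = len(space)
    G = np.zeros((n_states, n_states))
    for i, (n, m) in enumerate(space):
        if m >= 1 and (1, m - 1) in space:
            G[i, space.index((1, m - 1))] += K * m
        if n >= 1:
            if (0, m + 1) in space:
                G[i, space.index((0, m + 1))] += 1.0
            G[i, space.index((1, m))] += -1.0 - K * m
        else:
            G[i, space.index((0, m))] += -K * m
    return G


@dataclass
class AALPSpec:
    """Ancient ancestral lines process for a given sample and size ratio."""

    sample: SampleConfig
    K: float
    space: StateSpace
    P: np.ndarray
    G: np.ndarray
    semigroup: DegenerateSemigroup


def build_aalp(sample: SampleConfig, K: float) -> AALPSpec:
    """Construct the ancient ancestral lines process on the full grid."""
    if K <= 0:
        raise ValueError("size ratio K must be positive")
    space = StateSpace.full_grid(sample)
    P = build_projection(space)
    G = _aalp_generator(space, K)
    return AALPSpec(sample=sample, K=K, space=space, P=P, G=G,
                    semigroup=DegenerateSemigroup(P, G))


@dataclass
class ReducedChainSpec:
    """Collapsed limit genealogy on ``{0,1} x {0,...,m_max}``.

    ``Gbar`` is a genuine conservative Q-matrix: resuscitation-with-
    coalescence at rate ``K*m`` into ``(1, m-1)`` and, from ``(1, m)``,
    dormancy at rate 1 into ``(0, m+1)``.  The boundary row ``(1, m_max)``
    omits the dormancy move (its target lies outside the truncation) and is
    unreachable from any start with ``m <= m_max - 1``, so the truncated
    dynamics are exact on reachable states.
    """

    m_max: int
    K: float
    space: StateSpace
    Gbar: np.ndarray

    def transition(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("time must be non-negative")
        return expm(t * self.Gbar)

    def rate_matrix(self) -> RateMatrix:
        return RateMatrix(self.space, self.Gbar)


def build_reduced_chain(m_max: int, K: float) -> ReducedChainSpec:
    if m_max < 1:
        raise ValueError("m_max must be at least 1")
    if K <= 0:
        raise ValueError("size ratio K must be positive")
    space = StateSpace.reduced(m_max)
    n_states = len(space)
    G = np.zeros((n_states, n_states))
    for i, (n, m) in enumerate(space):
        if m >= 1:
            G[i, space.index((1, m - 1))] += K * m
        if n == 1 and (0, m + 1) in space:
            G[i, space.index((0, m + 1))] += 1.0
    np.fill_diagonal(G, -G.sum(axis=1))
    return ReducedChainSpec(m_max=m_max, K=K, space=space, Gbar=G)


def restriction_identity_check(aalp: AALPSpec, reduced: ReducedChainSpec, t_grid) -> float:
    """Maximum deviation between the two computations of the limit semigroup.

    The degenerate semigroup ``P e^{tG}`` restricted to the reduced index set
    ``{0,1} x {0,...,m_max}`` must coincide with ``e^{t*Gbar}``: the full
    generator never creates states outside the reduced space, so its powers
    restrict exactly.  Both sides are computed by independent matrix
    exponentials; the reduced side is exponentiated on a one-slot extension
    of the truncation so that every compared row has its reachable closure
    inside both finite matrices.  Rows of the common set whose closure does
    not fit (possible only for tiny samples) are skipped.
    """
    if not math.isclose(aalp.K, reduced.K):
        raise ValueError("mismatched K between full and reduced constructions")
    m_max = reduced.m_max
    N = aalp.sample.total
    ext = build_reduced_chain(m_max + 1, reduced.K)
    common = [(n, m) for n in (0, 1) for m in range(m_max + 1)]
    rows = [
        (n, m)
        for (n, m) in common
        if (m + 1 if n == 1 else m) <= min(ext.m_max, N)
    ]
    full_rows = np.array([aalp.space.index(s) for s in rows])
    full_cols = np.array([aalp.space.index(s) for s in common])
    red_rows = np.array([ext.space.index(s) for s in rows])
    red_cols = np.array([ext.space.index(s) for s in common])
    dev = 0.0
    for t in t_grid:
        full = aalp.semigroup(t)[np.ix_(full_rows, full_cols)]
        red = ext.transition(t)[np.ix_(red_rows, red_cols)]
        dev = max(dev, float(np.max(np.abs(full - red))))
    return dev


def telegraph_closed_form(K: float, t):
    """Two-state closed form for the single-lineage limit genealogy.

    The sub-chain ``(1,0) <-> (0,1)`` jumps at rate 1 (dormancy) and ``K``
    (resuscitation); for any start with ``n >= 1`` active and no dormant
    lineages the limit genealogy is exactly this telegraph process.  Returns
    ``(p11, p10)``: the probabilities of being active resp. dormant at time
    ``t`` when starting active, with ``p11 = (K + e^{-(1+K)t}) / (1+K)``.
    """
    if K <= 0:
        raise ValueError("size ratio K must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    p11 = (K + np.exp(-(1.0 + K) * t)) / (1.0 + K)
    return p11, 1.0 - p11


def build_imbalanced_limit(sample: SampleConfig, K: float) -> DegenerateSemigroup:
    """Two-island limit with island-2 coalescence surviving the scaling.

    When the island-2 coalescence scale shrinks proportionally to the
    migration rate, the limit keeps instantaneous coalescence in island 1 but
    ordinary pairwise coalescence ``binom(m, 2)`` among island-2 lineages.
    The projection is unchanged; the limit generator gains the island-2
    coalescence terms (combined with resuscitation for rows with active
    lineages).
    """
    if K <= 0:
        raise ValueError("size ratio K must be positive")
    space = StateSpace.full_grid(sample)
    P = build_projection(space)
    n_states = len(space)
    G = np.zeros((n_states, n_states))
    for i, (n, m) in enumerate(space):
        if n >= 1:
            if m >= 1 and (1, m - 1) in space:
                G[i, space.index((1, m - 1))] += K * m + binom2(m)
            if (0, m + 1) in space:
                G[i, space.index((0, m + 1))] += 1.0
            G[i, space.index((1, m))] += -binom2(m) - 1.0 - K * m
        else:
            if m >= 1 and (1, m - 1) in space:
                G[i, space.index((1, m - 1))] += K * m
            if m >= 2 and (0, m - 1) in space:
                G[i, space.index((0, m - 1))] += binom2(m)
            G[i, space.index((0, m))] += -binom2(m) - K * m
    return DegenerateSemigroup(P, G)


def simulate_aalp(
    sample: SampleConfig,
    K: float,
    horizon: float,
    rng: np.random.Generator,
    m_max: int | None = None,
) -> JumpPath:
    """Exact realisation of the limit genealogy.

    The limit generator ``G`` carries negative off-diagonal entries and is
    never used as a jump-rate table.  Instead the instantaneous collapse is
    applied once — ``(n0, m0) -> (1, m0)`` for ``n0 >= 1`` — and the reduced
    conservative chain is simulated exactly with Gillespie's algorithm.  The
    collapse is recorded as a jump at time ``0+`` whenever it moves the state.
    """
    if m_max is None:
        m_max = sample.m0 + 1
    reduced = build_reduced_chain(m_max, K)
    start = (min(sample.n0, 1), sample.m0)
    path = gillespie_simulate(reduced.rate_matrix(), start, horizon, rng)
    if start != (sample.n0, sample.m0):
        path = JumpPath([0.0] + path.times, [(sample.n0, sample.m0)] + path.states)
    return path


def limit_mixed_moment(x: float, y: float, K: float, t: float, n: int, m: int) -> float:
    """Exact mixed moment ``E[X(t)^n Y(t)^m]`` of the limit frequency process.

    By moment duality this equals the expectation of ``x^N y^M`` under the
    limit genealogy started from ``(n, m)``; for ``t > 0`` the genealogy
    lives on the reduced space, so the dual start collapses to
    ``(min(n,1), m)`` and the value is a row of ``e^{t*Gbar}`` integrated
    against the monomials (``0^0 = 1``).
    """
    if n < 0 or m < 0:
        raise ValueError("moment indices must be non-negative")
    if n == 0 and m == 0:
        return 1.0
    if t == 0:
        return float(x**n * y**m)
    reduced = build_reduced_chain(m + 1, K)
    row = reduced.transition(t)[reduced.space.index((min(n, 1), m))]
    vals = np.array([x**nn * y**mm for (nn, mm) in reduced.space])
    return float(row @ vals)
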