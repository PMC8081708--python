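"""Finite-state continuous-time Markov chains for seed bank genealogies.

This module builds the block-counting (line-counting) chains that describe the
genealogy of a sample from a population with a seed bank: the pair ``(n, m)``
counts the active and dormant ancestral lineages of the sample.  Active
lineages coalesce pairwise, initiate dormancy at rate ``c`` each, and dormant
lineages resuscitate at rate ``c*K`` each, where ``K`` is the ratio of active
to dormant population size.  A structured (two-island) variant additionally
allows coalescence among dormant/island-2 lineages.

Alongside the generator (Q-) matrices the module provides the exact transition
semigroup via the matrix exponential and a generic Gillespie jump-chain
simulator, which together serve as the exact oracle and the Monte-Carlo engine
for everything downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

__all__ = [
    "binom2",
    "ModelParams",
    "SampleConfig",
    "StateSpace",
    "RateMatrix",
    "JumpPath",
    "build_blockcounting_Q",
    "build_structured_Q",
    "transition_matrix",
    "gillespie_simulate",
    "gillespie_endpoints",
    "reachable_states",
]


def binom2(n: int) -> int:
    """Number of unordered pairs among ``n`` lineages, zero for ``n <= 1``."""
    return n * (n - 1) // 2 if n >= 2 else 0


@dataclass(frozen=True)
class ModelParams:
    """Rates of the seed bank / two-island models.

    Parameters
    ----------
    c
        Migration (dormancy initiation / resuscitation) rate per active
        lineage; dimensionless after measuring time on the coalescent scale.
    K
        Ratio of active to dormant population size.  Resuscitation acts at
        rate ``c*K`` per dormant lineage.
    alpha, alpha_prime
        Coalescence scales of island 1 (active) and island 2 (dormant).  The
        pure seed bank model is ``alpha = 1``, ``alpha_prime = 0`` (no
        reproduction in the seed bank).
    """

    c: float
    K: float
    alpha: float = 1.0
    alpha_prime: float = 0.0

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError(f"migration rate c must be positive, got {self.c}")
        if not self.K > 0:
            raise ValueError(f"size ratio K must be positive, got {self.K}")
        if self.alpha < 0 or self.alpha_prime < 0:
            raise ValueError("coalescence scales alpha, alpha_prime must be non-negative")


@dataclass(frozen=True)
class SampleConfig:
    """Initial sample: ``n0`` active and ``m0`` dormant lineages."""

    n0: int
    m0: int

    def __post_init__(self) -> None:
        if self.n0 < 0 or self.m0 < 0:
            raise ValueError("lineage counts must be non-negative")
        if self.n0 + self.m0 < 1:
            raise ValueError("the sample must contain at least one lineage")

    @property
    def total(self) -> int:
        return self.n0 + self.m0


class StateSpace:
    """Deterministically ordered list of lineage-count states ``(n, m)``.

    The full grid for a sample of ``n0 + m0`` lineages is
    ``{0, ..., n0+m0}^2`` enumerated row-major in ``n`` then ``m``; the
    reduced space used by the collapsed limit genealogy is
    ``{0, 1} x {0, ..., m_max}``.
    """

    def __init__(self, states) -> None:
        self.states: list[tuple[int, int]] = [tuple(s) for s in states]
        self._index = {s: i for i, s in enumerate(self.states)}
        if len(self._index) != len(self.states):
            raise ValueError("duplicate states in enumeration")

    @classmethod
    def full_grid(cls, sample: SampleConfig) -> "StateSpace":
        N = sample.total
        return cls((n, m) for n in range(N + 1) for m in range(N + 1))

    @classmethod
    def reduced(cls, m_max: int) -> "StateSpace":
        if m_max < 1:
            raise ValueError("m_max must be at least 1")
        return cls((n, m) for n in (0, 1) for m in range(m_max + 1))

    def index(self, state) -> int:
        return self._index[tuple(state)]

    def __contains__(self, state) -> bool:
        return tuple(state) in self._index

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self):
        return iter(self.states)


@dataclass
class RateMatrix:
    """A conservative generator matrix over a :class:`StateSpace`.

    ``entries[i, j]`` is the rate (events per unit time) of the jump from
    ``space.states[i]`` to ``space.states[j]``; the diagonal is the negative
    off-diagonal row sum so every row sums to zero.
    """

    space: StateSpace
    entries: np.ndarray

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        n = len(self.space)
        if self.entries.shape != (n, n):
            raise ValueError("entries must be square over the state space")

    def validate(self, tol: float = 1e-12) -> None:
        """Raise if the matrix is not a conservative Q-matrix."""
        off = self.entries.copy()
        np.fill_diagonal(off, 0.0)
        if not np.all(np.isfinite(self.entries)):
            raise ValueError("rate matrix has non-finite entries")
        if off.min() < 0:
            raise ValueError("negative off-diagonal rate")
        rowsum = np.abs(self.entries.sum(axis=1)).max()
        if rowsum > tol:
            raise ValueError(f"rows do not sum to zero (max deviation {rowsum:g})")

    @property
    def exit_rates(self) -> np.ndarray:
        return -np.diag(self.entries)


@dataclass
class JumpPath:
    """A right-continuous piecewise-constant realisation of a jump chain."""

    times: list[float]
    states: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have equal length")
        if self.times and self.times[0] != 0.0:
            raise ValueError("paths start at time 0")

    def state_at(self, t: float) -> tuple[int, int]:
        """State at time ``t`` (right-continuous convention)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return self.states[max(idx, 0)]


def reachable_states(space: StateSpace) -> list[int]:
    """Indices of grid states a sample can actually visit.

    The full grid enumerates all of ``{0..n0+m0}^2`` for indexing simplicity,
    but the total lineage count never increases, so states with
    ``n + m > n0 + m0`` are unreachable; diagnostics that compare truncated
    prelimit matrices against analytic limits restrict to these rows.
    """
    N = max(n for n, _ in space.states)
    return [i for i, (n, m) in enumerate(space) if n + m <= N]


def _conservative(space: StateSpace, rate_of) -> RateMatrix:
    n = len(space)
    entries = np.zeros((n, n))
    for i, (a, b) in enumerate(space):
        for target, rate in rate_of(a, b):
            if rate > 0 and target in space:
                entries[i, space.index(target)] += rate
    np.fill_diagonal(entries, 0.0)
    np.fill_diagonal(entries, -entries.sum(axis=1))
    return RateMatrix(space, entries)


def build_blockcounting_Q(sample: SampleConfig, params: ModelParams) -> RateMatrix:
    """Generator of the seed bank block-counting chain on the full grid.

    From state ``(n, m)``: coalescence ``(n-1, m)`` at rate ``binom(n, 2)``,
    dormancy ``(n-1, m+1)`` at rate ``c*n``, resuscitation ``(n+1, m-1)`` at
    rate ``c*K*m``.  Dormant lineages never coalesce.
    """
    space = StateSpace.full_grid(sample)
    c, K = params.c, params.K

    def rates(n, m):
        yield (n - 1, m), float(binom2(n))
        yield (n - 1, m + 1), c * n
        yield (n + 1, m - 1), c * K * m

    return _conservative(space, rates)


def build_structured_Q(sample: SampleConfig, params: ModelParams) -> RateMatrix:
    """Generator of the two-island structured-coalescent block-counting chain.

    As :func:`build_blockcounting_Q` with island-specific coalescence scales:
    ``alpha*binom(n,2)`` in island 1 and ``alpha_prime*binom(m,2)`` in
    island 2 (the seed bank model is ``alpha=1, alpha_prime=0``).
    """
    space = StateSpace.full_grid(sample)
    c, K = params.c, params.K
    a, ap = params.alpha, params.alpha_prime

    def rates(n, m):
        yield (n - 1, m), a * binom2(n)
        yield (n, m - 1), ap * binom2(m)
        yield (n - 1, m + 1), c * n
        yield (n + 1, m - 1), c * K * m

    return _conservative(space, rates)


def transition_matrix(Q: RateMatrix, t: float) -> np.ndarray:
    """Exact transition semigroup ``exp(t*Q)``; rows are probability vectors."""
    if t < 0:
        raise ValueError("time must be non-negative")
    if t == 0:
        return np.eye(len(Q.space))
    return expm(t * Q.entries)


def _jump_tables(Q: RateMatrix):
    """Per-state jump targets, cumulative rates and total exit rates."""
    entries = Q.entries
    targets, cum, totals = [], [], []
    for i in range(len(Q.space)):
        row = entries[i].copy()
        row[i] = 0.0
        nz = np.nonzero(row > 0)[0]
        targets.append(nz)
        cum.append(np.cumsum(row[nz]))
        totals.append(row[nz].sum())
    return targets, cum, np.array(totals)


def gillespie_simulate(
    Q: RateMatrix,
    start,
    horizon: float,
    rng: np.random.Generator,
) -> JumpPath:
    """Exact jump-chain realisation of the chain generated by ``Q``.

    Holding times are exponential with the state's total exit rate and the
    next state is drawn proportionally to the off-diagonal rates.  The path is
    truncated at ``horizon``; an absorbing state (total rate zero) terminates
    it cleanly.
    """
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    targets, cum, totals = _jump_tables(Q)
    i = Q.space.index(start)
    times, states = [0.0], [Q.space.states[i]]
    t = 0.0
    while True:
        total = totals[i]
        if total <= 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t > horizon:
            break
        k = int(np.searchsorted(cum[i], rng.random() * total, side="right"))
        k = min(k, len(targets[i]) - 1)
        i = int(targets[i][k])
        times.append(t)
        states.append(Q.space.states[i])
    return JumpPath(times, states)


def gillespie_endpoints(
    Q: RateMatrix,
    start,
    horizon: float,
    reps: int,
    seed: int,
) -> np.ndarray:
    """Time-``horizon`` states of ``reps`` independent Gillespie paths.

    Replicate ``r`` uses the generator seeded with ``seed + r`` so results do
    not depend on execution order.  Returns an ``(reps, 2)`` integer array.
    """
    targets, cum, totals = _jump_tables(Q)
    i0 = Q.space.index(start)
    out = np.empty((reps, 2), dtype=np.int64)
    for r in range(reps):
        rng = np.random.default_rng(seed + r)
        i = i0
        t = 0.0
        while True:
            total = totals[i]
            if total <= 0.0:
                break
            t += rng.exponential(1.0 / total)
            if t > horizon:
                break
            k = int(np.searchsorted(cum[i], rng.random() * total, side="right"))
            k = min(k, len(targets[i]) - 1)
            i = int(targets[i][k])
        out[r] = Q.space.states[i]
    return out
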