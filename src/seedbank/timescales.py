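"""Separation-of-timescales engine for finite continuous-time Markov chains.

When some transitions of a chain act much faster than others, speeding time up
so that the slow transitions become order one makes the fast ones act
instantaneously.  The rescaled chains then converge to a *degenerate* limit
with transition semigroup

    Pi(t) = P exp(t G),   t > 0,   Pi(0) = Id,

where ``P`` is an idempotent stochastic matrix (the projection induced by the
instantaneous transitions) and ``G = lim P B_k P`` is the limit generator
(which need not be a Q-matrix: it can carry negative off-diagonal entries on
rows the projection collapses).  This module provides the generic numerical
machinery: discretisation of a chain, the fast/slow (A/B) decomposition of its
one-step matrix, extraction of ``P`` from high powers of the fast part,
extraction of ``G``, evaluation of the degenerate semigroup, and a diagnostic
for the jump-probability condition under which the discretised limit carries
over to the continuous-time chain.

The seed bank chain is the motivating example: with migration rate ``c -> 0``,
step scale ``a = c^-2`` and time speed-up ``b = c^-3`` the fast part is pure
coalescence, ``P`` sends every state with at least one active lineage to a
single active lineage, and ``G`` drives dormancy/resuscitation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .ctmc import RateMatrix, StateSpace, binom2

__all__ = [
    "ScalingSchedule",
    "Decomposition",
    "DegenerateSemigroup",
    "matrix_norm",
    "discretise",
    "coalescence_fast_mask",
    "decompose",
    "extract_projection",
    "build_slow_limit_matrix",
    "limit_generator",
    "degenerate_semigroup",
    "check_timescale_condition",
]


@dataclass(frozen=True)
class ScalingSchedule:
    """Decreasing migration rates ``c`` with step scale ``a = c^-2`` and
    time speed-up ``b = c^-3`` (so the observed timescale is ``b/a = 1/c``)."""

    c_seq: tuple[float, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.c_seq, dtype=float)
        if c.size == 0 or np.any(c <= 0):
            raise ValueError("c values must be positive")
        if np.any(np.diff(c) >= 0):
            raise ValueError("c values must be strictly decreasing")
        object.__setattr__(self, "c_seq", tuple(float(x) for x in c))

    @property
    def a_seq(self) -> np.ndarray:
        return np.asarray(self.c_seq) ** -2.0

    @property
    def b_seq(self) -> np.ndarray:
        return np.asarray(self.c_seq) ** -3.0


@dataclass
class Decomposition:
    """One-step matrix split ``Pi = A + B/b`` into fast (A) and slow (B) parts."""

    A: np.ndarray
    B: np.ndarray
    b: float


def matrix_norm(A: np.ndarray) -> float:
    """Maximum absolute row sum (the operator infinity-norm)."""
    A = np.asarray(A, dtype=float)
    return float(np.max(np.sum(np.abs(A), axis=1)))


def discretise(Q: RateMatrix, a: float) -> np.ndarray:
    """One-step transition matrix of the chain observed every ``1/a`` units.

    Computed as the exact matrix exponential ``exp(Q/a)`` rather than a
    first-order expansion, so the only error in downstream limits is the one
    the scaling itself introduces.
    """
    if a <= 0:
        raise ValueError("step scale a must be positive")
    return expm(Q.entries / a)


def coalescence_fast_mask(space: StateSpace) -> np.ndarray:
    """Fast-transition mask for the seed bank / two-island chains.

    Marks the active-lineage coalescence moves ``(n, m) -> (n-1, m)`` and the
    diagonal; everything else (migration, island-2 coalescence) is slow.
    """
    n_states = len(space)
    mask = np.zeros((n_states, n_states), dtype=bool)
    for i, (n, m) in enumerate(space):
        mask[i, i] = True
        if n >= 2 and (n - 1, m) in space:
            mask[i, space.index((n - 1, m))] = True
    return mask


def decompose(Pi: np.ndarray, mask: np.ndarray, b: float) -> Decomposition:
    """Split a stochastic matrix into fast part ``A`` and slow part ``B``.

    ``A`` keeps the masked (fast) off-diagonal entries with its diagonal
    adjusted to make it stochastic; ``B = b * (Pi - A)`` carries everything
    else.  Raises if the mask would force a negative diagonal.
    """
    Pi = np.asarray(Pi, dtype=float)
    A = np.where(mask, Pi, 0.0)
    np.fill_diagonal(A, 0.0)
    diag = 1.0 - A.sum(axis=1)
    if np.any(diag < 0):
        raise ValueError("fast mask keeps more than unit mass in a row; A would not be stochastic")
    A[np.arange(len(A)), np.arange(len(A))] = diag
    B = b * (Pi - A)
    return Decomposition(A=A, B=B, b=float(b))


def extract_projection(
    A: np.ndarray,
    a: float,
    C_grid=(1.0, 10.0, 100.0),
    snap_tol: float = 1e-6,
):
    """Numerical projection limit of the fast part: ``P = lim A^r``.

    Computes ``A^r`` for ``r = ceil(C*a)`` over the ``C`` grid via repeated
    squaring, snaps the entries of the largest power to {0, 1} (they must lie
    within ``snap_tol`` of a binary value), verifies idempotence and returns
    ``(P, diagnostics)`` where the diagnostics carry the norm decay sequence
    ``||A^r - P||``.

    Raises ``RuntimeError`` if no stabilisation is detected (final norm above
    0.1) or the stabilised matrix is not a binary projection.
    """
    A = np.asarray(A, dtype=float)
    C_grid = sorted(float(C) for C in C_grid)
    rs = [int(np.ceil(C * a)) for C in C_grid]
    powers = {r: np.linalg.matrix_power(A, r) for r in rs}
    tail = powers[rs[-1]]
    P = np.round(tail)
    if np.max(np.abs(tail - P)) > snap_tol:
        raise RuntimeError(
            "no projection stabilisation: entries of the largest power are not "
            f"within {snap_tol:g} of binary values"
        )
    if not np.array_equal(P @ P, P):
        raise RuntimeError("stabilised matrix is not idempotent")
    norms = [matrix_norm(powers[r] - P) for r in rs]
    if norms[-1] > 0.1:
        raise RuntimeError(f"fast part did not stabilise: ||A^r - P|| = {norms[-1]:g} at C = {C_grid[-1]:g}")
    diagnostics = {"C_grid": C_grid, "r": rs, "norm_decay": norms}
    return P, diagnostics


def build_slow_limit_matrix(space: StateSpace, K: float, model: str = "seedbank") -> np.ndarray:
    """Limit of the slow parts ``B_k`` for the seed bank / two-island chains.

    Entry pattern from ``(n, m)``: dormancy ``n`` to ``(n-1, m+1)``,
    resuscitation ``K*m`` to ``(n+1, m-1)``, and for the two-island model
    additionally island-2 coalescence ``binom(m, 2)`` to ``(n, m-1)``; the
    diagonal is minus the sum of those rates (targets outside the finite grid
    are dropped on both sides of the limit identities, so the diagonal keeps
    the full printed value).
    """
    if model not in ("seedbank", "two_island"):
        raise ValueError("model must be 'seedbank' or 'two_island'")
    n_states = len(space)
    B = np.zeros((n_states, n_states))
    for i, (n, m) in enumerate(space):
        diag = 0.0
        if n >= 1 and (n - 1, m + 1) in space:
            B[i, space.index((n - 1, m + 1))] += n
        diag -= n
        if m >= 1 and (n + 1, m - 1) in space:
            B[i, space.index((n + 1, m - 1))] += K * m
        diag -= K * m
        if model == "two_island":
            if m >= 2 and (n, m - 1) in space:
                B[i, space.index((n, m - 1))] += binom2(m)
            diag -= binom2(m)
        B[i, i] += diag
    return B


def limit_generator(
    P: np.ndarray,
    B_seq=None,
    B: np.ndarray | None = None,
    tol: float = 1e-3,
):
    """Limit generator ``G = lim P B_k P`` of the slow dynamics.

    Either route may be used: a sequence ``B_seq`` of slow matrices along the
    scaling schedule (the limit is detected by a Cauchy criterion in the
    matrix norm; successive differences must be non-increasing with the last
    below ``tol``), or the analytic limit matrix ``B`` for which ``P B P`` is
    exact.  Returns ``(G, diagnostics)``; when both are supplied the exact
    product is returned as ``G`` and the sequence serves as a cross-check.
    """
    P = np.asarray(P, dtype=float)
    diagnostics: dict = {}
    G = None
    if B_seq is not None:
        G_seq = [P @ np.asarray(Bk, dtype=float) @ P for Bk in B_seq]
        if len(G_seq) < 2:
            raise ValueError("need at least two slow matrices to detect a limit")
        diffs = [matrix_norm(G_seq[i] - G_seq[i - 1]) for i in range(1, len(G_seq))]
        diagnostics["cauchy_diffs"] = diffs
        if diffs[-1] > tol or any(d2 > d1 * 1.5 for d1, d2 in zip(diffs, diffs[1:])):
            raise RuntimeError(
                f"P B_k P sequence is not Cauchy at tolerance {tol:g}: diffs {diffs}"
            )
        G = G_seq[-1]
    if B is not None:
        G_exact = P @ np.asarray(B, dtype=float) @ P
        if G is not None:
            diagnostics["seq_vs_exact"] = matrix_norm(G - G_exact)
        G = G_exact
    if G is None:
        raise ValueError("supply B_seq and/or the limit matrix B")
    return G, diagnostics


def degenerate_semigroup(P: np.ndarray, G: np.ndarray, t: float) -> np.ndarray:
    """Evaluate the degenerate semigroup: identity at ``t = 0``, else ``P e^{tG}``."""
    if t < 0:
        raise ValueError("time must be non-negative")
    if t == 0:
        return np.eye(len(P))
    return np.asarray(P, dtype=float) @ expm(t * np.asarray(G, dtype=float))


@dataclass
class DegenerateSemigroup:
    """The pair ``(P, G)`` with evaluation rule ``Pi(t) = P e^{tG}``.

    ``P`` must be exactly idempotent and ``G`` must commute with it as
    ``P G = G P = G`` (checked to 1e-12 at construction).  The semigroup is
    not standard: ``Pi(0+) = P`` differs from ``Pi(0) = Id``.
    """

    P: np.ndarray
    G: np.ndarray

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if not np.array_equal(self.P @ self.P, self.P):
            raise ValueError("P is not exactly idempotent")
        if matrix_norm(self.P @ self.G - self.G) > 1e-12 or matrix_norm(self.G @ self.P - self.G) > 1e-12:
            raise ValueError("G does not satisfy P G = G P = G")

    def __call__(self, t: float) -> np.ndarray:
        return degenerate_semigroup(self.P, self.G, t)


def check_timescale_condition(Q_seq, a_seq) -> dict:
    """Diagnostic for the discretisation-fineness condition.

    The discretised limit transfers to the continuous-time chains when the
    maximal exit rate ``q_k`` is negligible against the step scale ``a_k``
    (the chain almost never jumps within one step).  Reports ``q_k``, the
    ratios ``q_k / a_k`` and whether they decrease strictly towards zero.
    """
    a_seq = np.asarray(list(a_seq), dtype=float)
    q_seq = np.array([float(Q.exit_rates.max()) for Q in Q_seq])
    if q_seq.size != a_seq.size:
        raise ValueError("schedules are not aligned")
    ratios = q_seq / a_seq
    decreasing = bool(np.all(np.diff(ratios) < 0))
    return {
        "q_seq": q_seq,
        "ratios": ratios,
        "strictly_decreasing": decreasing,
        "passes": decreasing,
    }
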