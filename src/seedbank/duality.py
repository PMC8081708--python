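"""Moment-duality verification engine and convergence experiments.

The forward frequency process and the backward lineage-counting chain are
linked by moment duality,

    E^{x,y}[ X(t)^n Y(t)^m ] = E_{n,m}[ x^{N(t)} y^{M(t)} ],

which holds for the seed bank diffusion against the block-counting chain of
the seed bank coalescent, and again — after passing to the super-evolutionary
limit — for the jump process against the collapsed limit genealogy.  The
right-hand side is computable exactly from a matrix exponential, so duality
turns every Monte-Carlo forward simulation into a sharply testable quantity.
This module produces those checks (:class:`DualityReport`) and the scripted
convergence experiments along a vanishing-migration schedule
(:class:`ConvergenceReport`), exercising both directions of the limit: the
genealogy converging to the ancient ancestral lines process and the diffusion
converging to the piecewise-deterministic jump process.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .ctmc import ModelParams, RateMatrix, SampleConfig, build_blockcounting_Q, gillespie_endpoints, transition_matrix
from .diffusion import DiffusionState, EMConfig, rescale_super_evolutionary, simulate_seedbank_sde
from .limits import build_aalp, limit_mixed_moment, telegraph_closed_form
from .pdmp import evaluate_pdmp, simulate_limit_pdmp
from .timescales import ScalingSchedule

__all__ = [
    "MomentIndex",
    "DualityReport",
    "ConvergenceReport",
    "dual_moment_exact",
    "duality_check_seedbank",
    "duality_check_limit",
    "convergence_experiment_backward",
    "convergence_experiment_forward",
    "tv_distance",
    "pdmp_generator_moment",
    "reduced_generator_moment",
]


@dataclass(frozen=True)
class MomentIndex:
    """Exponents of the mixed moment ``x^n y^m`` / start of the dual chain."""

    n: int
    m: int

    def __post_init__(self) -> None:
        if self.n < 0 or self.m < 0:
            raise ValueError("moment indices must be non-negative")


@dataclass
class DualityReport:
    """Exact dual expectation vs Monte-Carlo forward moment."""

    index: MomentIndex
    start: tuple[float, float]
    t: float
    exact: float
    estimate: float
    se: float
    reps: int
    tolerance: float

    @property
    def z(self) -> float:
        return (self.estimate - self.exact) / self.se if self.se > 0 else float("inf")

    @property
    def passed(self) -> bool:
        return abs(self.estimate - self.exact) <= self.tolerance

    def as_dict(self) -> dict:
        return {
            "n": self.index.n, "m": self.index.m,
            "x": self.start[0], "y": self.start[1], "t": self.t,
            "exact": self.exact, "estimate": self.estimate, "se": self.se,
            "reps": self.reps, "z": self.z, "tolerance": self.tolerance,
            "pass": self.passed,
        }


@dataclass
class ConvergenceReport:
    """Per-``c`` discrepancy against the limit along a scaling schedule."""

    c_values: list[float]
    metric_values: list[float]
    noise_floor: float
    final_threshold: float | None = None
    extras: dict = field(default_factory=dict)

    @property
    def monotone(self) -> bool:
        """Non-increasing up to twice the sampling-noise floor."""
        m = self.metric_values
        return all(m[i] <= m[i - 1] + 2.0 * self.noise_floor for i in range(1, len(m)))

    @property
    def final_ok(self) -> bool:
        if self.final_threshold is None:
            return True
        return self.metric_values[-1] <= self.final_threshold

    def as_dict(self) -> dict:
        return {
            "c_values": list(self.c_values),
            "metric_values": [float(v) for v in self.metric_values],
            "noise_floor": self.noise_floor,
            "monotone": self.monotone,
            "final_ok": self.final_ok,
            **{k: v for k, v in self.extras.items()},
        }


def tv_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Total-variation distance between two pmfs on the same finite space."""
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())


def dual_moment_exact(n: int, m: int, x: float, y: float, t: float, Q: RateMatrix) -> float:
    """Exact dual expectation ``E_{n,m}[x^N(t) y^M(t)]`` from ``e^{tQ}``.

    Sums the transition row from ``(n, m)`` against the monomials
    ``x^nbar y^mbar`` with the convention ``0^0 = 1``.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    row = transition_matrix(Q, t)[Q.space.index((n, m))]
    vals = np.array([x**nn * y**mm for (nn, mm) in Q.space])
    return float(row @ vals)


def duality_check_seedbank(
    index: MomentIndex,
    start: DiffusionState,
    params: ModelParams,
    t: float,
    cfg: EMConfig,
    bias_coefficient: float = 1.0,
) -> DualityReport:
    """Check forward/backward moment duality for the seed bank model.

    The exact side is the dual expectation under the block-counting chain of
    the seed bank coalescent; the forward side is the Euler-Maruyama estimate
    of ``E[X(t)^n Y(t)^m]``.  The pass band is ``4 * SE`` plus a
    discretisation-bias allowance ``bias_coefficient * dt``.
    """
    n, m = index.n, index.m
    if n + m == 0:
        exact = 1.0
    else:
        Q = build_blockcounting_Q(SampleConfig(n0=n, m0=m), params)
        exact = dual_moment_exact(n, m, start.x, start.y, t, Q)
    run_cfg = EMConfig(dt=cfg.dt, horizon=t, reps=cfg.reps, seed=cfg.seed, record_times=(t,))
    grid = simulate_seedbank_sde(start, params, run_cfg)
    est, se = grid.moment(n, m, k=0)
    if se > 0.05:
        warnings.warn("standard error above 0.05: increase replicates for an informative check",
                      RuntimeWarning, stacklevel=2)
    tol = 4.0 * se + bias_coefficient * cfg.dt
    return DualityReport(index=index, start=(start.x, start.y), t=t,
                         exact=exact, estimate=est, se=se, reps=cfg.reps, tolerance=tol)


def duality_check_limit(
    index: MomentIndex,
    start,
    K: float,
    t: float,
    reps: int,
    seed: int,
) -> DualityReport:
    """Check moment duality between the limit jump process and the collapsed
    limit genealogy.

    The exact side comes from the reduced-chain matrix exponential (for any
    ``n >= 1`` it equals the value at ``n = 1``, since the genealogy has at
    most one active lineage at positive times); the forward side is the
    Monte-Carlo moment of the exactly simulated jump process, so no bias
    allowance is needed.
    """
    x, y = float(start[0]), float(start[1])
    exact = limit_mixed_moment(x, y, K, t, index.n, index.m)
    rng = np.random.default_rng(seed)
    samples = np.empty(reps)
    for r in range(reps):
        path = simulate_limit_pdmp((x, y), K, t, rng)
        xs, ys = evaluate_pdmp(path, [t])
        samples[r] = xs[0] ** index.n * ys[0] ** index.m
    est = float(samples.mean())
    se = float(samples.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
    if se > 0.05:
        warnings.warn("standard error above 0.05: increase replicates for an informative check",
                      RuntimeWarning, stacklevel=2)
    return DualityReport(index=index, start=(x, y), t=t, exact=exact,
                         estimate=est, se=se, reps=reps, tolerance=4.0 * se)


def convergence_experiment_backward(
    sample: SampleConfig,
    K: float,
    schedule: ScalingSchedule,
    t: float,
    reps: int,
    seed: int,
    final_threshold: float | None = None,
) -> ConvergenceReport:
    """Genealogy side of the scaling limit: sped-up block counting vs the
    ancient ancestral lines process.

    For each ``c`` the block-counting chain is Gillespie-simulated to time
    ``t / c`` and its empirical law is compared in total variation with the
    corresponding row of the limit semigroup ``P e^{tG}``.
    """
    aalp = build_aalp(sample, K)
    limit_row = aalp.semigroup(t)[aalp.space.index((sample.n0, sample.m0))]
    # sampling-noise scale of the TV statistic against a fixed law
    noise_floor = 0.5 * float(np.sqrt(limit_row * (1.0 - limit_row) / reps).sum())
    metrics = []
    for j, c in enumerate(schedule.c_seq):
        Q = build_blockcounting_Q(sample, ModelParams(c=c, K=K))
        ends = gillespie_endpoints(Q, (sample.n0, sample.m0), t / c, reps, seed + 10_000 * j)
        counts = np.zeros(len(aalp.space))
        for n, m in ends:
            counts[aalp.space.index((int(n), int(m)))] += 1
        metrics.append(tv_distance(counts / reps, limit_row))
    return ConvergenceReport(c_values=list(schedule.c_seq), metric_values=metrics,
                             noise_floor=noise_floor, final_threshold=final_threshold)


def convergence_experiment_forward(
    start: DiffusionState,
    K: float,
    schedule: ScalingSchedule,
    t: float,
    dt_base: float,
    reps: int,
    seed: int,
) -> ConvergenceReport:
    """Frequency side of the scaling limit: rescaled diffusion moments vs the
    jump-process limit.

    For each ``c`` the seed bank diffusion is simulated with step
    ``dt = dt_base * c`` to time ``t / c`` and the first moments of both
    coordinates are compared with the exact limit values (telegraph closed
    form for ``X``, reduced-chain exponential for ``Y``).  The boundary
    fraction ``P{X within 0.05 of {0, 1}}`` is reported alongside: it must
    grow towards 1 as the limit concentrates on the boundaries.
    """
    p11, p10 = telegraph_closed_form(K, t)
    exact_x = start.x * float(p11) + start.y * float(p10)
    exact_y = limit_mixed_moment(start.x, start.y, K, t, 0, 1)
    metrics, gaps_y, boundary_fracs, ses = [], [], [], []
    for j, c in enumerate(schedule.c_seq):
        params = ModelParams(c=c, K=K)
        cfg = EMConfig(dt=dt_base * c, horizon=t, reps=reps, seed=seed + 10_000 * j,
                       record_times=(t,))
        grid = rescale_super_evolutionary(start, params, cfg)
        xv = grid.values[:, 0, 0]
        yv = grid.values[:, 0, 1]
        metrics.append(abs(float(xv.mean()) - exact_x))
        gaps_y.append(abs(float(yv.mean()) - exact_y))
        boundary_fracs.append(float(((xv <= 0.05) | (xv >= 0.95)).mean()))
        ses.append(float(xv.std(ddof=1) / np.sqrt(reps)))
    return ConvergenceReport(
        c_values=list(schedule.c_seq),
        metric_values=metrics,
        noise_floor=max(ses),
        extras={"gap_y": gaps_y, "boundary_fraction": boundary_fracs,
                "exact_x": exact_x, "exact_y": exact_y, "se_x": ses},
    )


def pdmp_generator_moment(x: float, y: float, n: int, m: int, K: float) -> float:
    """Limit-process generator applied to the monomial ``(x, y) -> x^n y^m``.

    For ``x in {0, 1}``: switching terms ``(1-x) y (f(1,y) - f(x,y)) +
    x (1-y) (f(0,y) - f(x,y))`` plus the relaxation drift
    ``K (x - y) df/dy``.
    """
    f = lambda a, b: a**n * b**m
    drift = K * (x - y) * (x**n * m * y ** (m - 1) if m >= 1 else 0.0)
    return (1.0 - x) * y * (f(1.0, y) - f(x, y)) + x * (1.0 - y) * (f(0.0, y) - f(x, y)) + drift


def reduced_generator_moment(x: float, y: float, n: int, m: int, K: float) -> float:
    """Collapsed-genealogy generator applied to ``(n, m) -> x^n y^m``.

    Acting on the dual variable: resuscitation ``K m (f(1, m-1) - f(n, m))``
    plus, for ``n = 1``, dormancy ``f(0, m+1) - f(n, m)``.  For ``x`` in
    ``{0, 1}`` this agrees exactly with :func:`pdmp_generator_moment` — the
    analytic heart of the limit duality.
    """
    if n not in (0, 1):
        raise ValueError("the collapsed genealogy has at most one active lineage")
    S = lambda nn, mm: x**nn * y**mm
    out = K * m * (S(1, m - 1) - S(n, m)) if m >= 1 else 0.0
    if n == 1:
        out += S(0, m + 1) - S(n, m)
    return out
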