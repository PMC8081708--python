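"""Separation-of-timescales machinery: decomposition, projection, limit generator."""

import numpy as np
import pytest

import seedbank as sb
from seedbank.ctmc import reachable_states


def _seedbank_setup(sample, K, c):
    Q = sb.build_blockcounting_Q(sample, sb.ModelParams(c=c, K=K))
    a, b = c**-2, c**-3
    Pi = sb.discretise(Q, a)
    mask = sb.coalescence_fast_mask(Q.space)
    return Q, Pi, sb.decompose(Pi, mask, b), a, b


def test_matrix_norm_examples():
    assert sb.matrix_norm(np.eye(5)) == 1.0
    stoch = np.array([[0.25, 0.75], [0.5, 0.5]])
    assert sb.matrix_norm(stoch) == 1.0
    # difference of a stochastic matrix and its projection limit is in [0, 2]
    P = sb.build_projection(sb.StateSpace.full_grid(sb.SampleConfig(2, 1)))
    assert 0.0 <= sb.matrix_norm(np.eye(len(P)) - P) <= 2.0


def test_discretise_step_matrix():
    """One-step matrix is exp(Q/a): stochastic, near identity for large a, and
    the coalescence entry follows its small-c expansion at the c^3 scale."""
    sample = sb.SampleConfig(2, 0)
    Q = sb.build_blockcounting_Q(sample, sb.ModelParams(c=0.1, K=1.0))
    Pi = sb.discretise(Q, 100.0)
    sp = Q.space
    assert abs(Pi[sp.index((2, 0)), sp.index((1, 0))] - 0.01) < 1e-4
    assert np.abs(Pi.sum(axis=1) - 1.0).max() < 1e-12
    # a -> infinity limit is the identity
    assert np.abs(sb.discretise(Q, 1e12) - np.eye(len(sp))).max() < 1e-10
    with pytest.raises(ValueError):
        sb.discretise(Q, 0.0)


@pytest.mark.parametrize("c", [0.1, 0.05, 0.02])
def test_decompose_fast_and_slow_parts(c):
    """A carries the coalescence probabilities (leading order binom(n,2) c^2,
    error o(c^3)); B approaches the analytic slow matrix; reassembly is exact."""
    sample = sb.SampleConfig(3, 2)
    Q, Pi, dec, a, b = _seedbank_setup(sample, 1.0, c)
    sp = Q.space
    entry = dec.A[sp.index((3, 1)), sp.index((2, 1))]
    assert abs(entry - 3 * c**2) < c**3
    # dormancy entry of B tends to n = 1
    assert abs(dec.B[sp.index((1, 1)), sp.index((0, 2))] - 1.0) < 5 * c
    assert np.abs(dec.A + dec.B / b - Pi).max() < 1e-14


def test_decompose_rejects_overfull_mask():
    sample = sb.SampleConfig(2, 1)
    Q, Pi, _, a, b = _seedbank_setup(sample, 1.0, 0.1)
    mask = np.ones((len(Q.space), len(Q.space)), dtype=bool)
    bad = Pi.copy()
    # forcing all mass into A with a doctored matrix whose row exceeds 1
    bad[0, :] = 2.0 / len(Q.space)
    with pytest.raises(ValueError):
        sb.decompose(bad, mask, b)


def test_extract_projection_recovers_instantaneous_coalescence():
    """High powers of the fast part collapse every state with active lineages
    to a single active lineage, exactly reproducing the analytic projection."""
    for n0, m0 in [(3, 2), (2, 2), (5, 1), (4, 4)]:
        sample = sb.SampleConfig(n0, m0)
        Q, Pi, dec, a, b = _seedbank_setup(sample, 1.0, 0.05)
        P, diag = sb.extract_projection(dec.A, a)
        assert np.array_equal(P, sb.build_projection(Q.space))
        assert np.array_equal(P @ P, P)
        # Markov-inequality envelope on the norm decay
        for C, norm in zip(diag["C_grid"], diag["norm_decay"]):
            assert norm <= 2 * (sample.total - 1) / C + 1e-9


def test_extract_projection_fails_loudly_without_stabilisation():
    # a slowly mixing stochastic matrix with no binary limit at small powers
    A = np.array([[0.9999, 0.0001], [0.0001, 0.9999]])
    with pytest.raises(RuntimeError):
        sb.extract_projection(A, a=10.0, C_grid=(1.0,))


def test_limit_generator_exact_products():
    """P B P reproduces the analytic limit generators of both models exactly."""
    for n0, m0 in [(2, 2), (3, 3), (5, 1)]:
        sample = sb.SampleConfig(n0, m0)
        for K in (0.5, 1.0, 2.0):
            aalp = sb.build_aalp(sample, K)
            B = sb.build_slow_limit_matrix(aalp.space, K, "seedbank")
            G, _ = sb.limit_generator(aalp.P, B=B)
            assert np.array_equal(G, aalp.G)
            Bhat = sb.build_slow_limit_matrix(aalp.space, K, "two_island")
            Ghat, _ = sb.limit_generator(aalp.P, B=Bhat)
            ghat = sb.build_imbalanced_limit(sample, K)
            assert np.array_equal(Ghat, ghat.G)
            assert sb.matrix_norm(aalp.P @ G - G) < 1e-12
            assert sb.matrix_norm(G @ aalp.P - G) < 1e-12


def test_limit_generator_cauchy_sequence():
    """P B_k P computed from exact matrix exponentials is Cauchy and approaches
    the analytic product on the physically reachable rows."""
    sample, K = sb.SampleConfig(3, 2), 1.0
    aalp = sb.build_aalp(sample, K)
    B_seq = []
    for c in (0.05, 0.02, 0.01, 0.005):
        _, _, dec, _, _ = _seedbank_setup(sample, K, c)
        B_seq.append(dec.B)
    G_seq, diag = sb.limit_generator(aalp.P, B_seq=B_seq, tol=1e-2)
    diffs = diag["cauchy_diffs"]
    assert all(d2 < d1 for d1, d2 in zip(diffs, diffs[1:]))
    rows = reachable_states(aalp.space)
    assert np.abs((G_seq - aalp.G)[rows]).max() < 1e-3
    with pytest.raises(RuntimeError):
        sb.limit_generator(aalp.P, B_seq=B_seq[:2], tol=1e-12)


def test_degenerate_semigroup_properties():
    """Pi(0) = Id but Pi(0+) = P; Chapman-Kolmogorov holds; rows are pmfs."""
    sample, K = sb.SampleConfig(2, 2), 1.5
    aalp = sb.build_aalp(sample, K)
    sg = aalp.semigroup
    assert np.array_equal(sg(0.0), np.eye(len(aalp.space)))
    assert np.abs(sg(1e-12) - aalp.P).max() < 1e-10
    for s, t in [(0.3, 0.7), (1.0, 2.0)]:
        assert np.abs(sg(s) @ sg(t) - sg(s + t)).max() < 1e-10
    rows = reachable_states(aalp.space)
    for t in (0.01, 0.1, 1.0, 10.0):
        rowsums = sg(t).sum(axis=1)[rows]
        assert np.abs(rowsums - 1.0).max() < 1e-10
    with pytest.raises(ValueError):
        sg(-1.0)


def test_discretised_powers_converge_to_degenerate_semigroup():
    """Pi_k^{floor(t b_k)} approaches P e^{tG} monotonically along the schedule."""
    sample, K, t = sb.SampleConfig(3, 2), 1.0, 1.0
    aalp = sb.build_aalp(sample, K)
    target = aalp.semigroup(t)
    norms = []
    for c in (0.2, 0.1, 0.05):
        _, Pi, _, a, b = _seedbank_setup(sample, K, c)
        power = np.linalg.matrix_power(Pi, int(t * b))
        norms.append(sb.matrix_norm(power - target))
    assert norms[0] > norms[1] > norms[2]


def test_timescale_condition_diagnostics():
    """Exit rates stay bounded while the step scale diverges; a constant-rate
    chain with constant scale is flagged as failing (negative control)."""
    sample, K = sb.SampleConfig(2, 2), 1.0
    schedule = sb.ScalingSchedule((0.2, 0.1, 0.05, 0.01))
    Q_seq = [sb.build_blockcounting_Q(sample, sb.ModelParams(c=c, K=K)) for c in schedule.c_seq]
    out = sb.check_timescale_condition(Q_seq, schedule.a_seq)
    assert out["passes"]
    q = out["q_seq"]
    assert np.all(q <= 6 + 0.2 * 4 + 0.2 * K * 4 + 1e-12)
    assert out["ratios"][0] <= 0.068 * 4  # loose envelope; c=0.2 entry
    # c = 0.1 entry matches the displayed bound
    i = schedule.c_seq.index(0.1)
    assert out["ratios"][i] <= 0.068
    const = sb.check_timescale_condition([Q_seq[0]] * 3, [25.0] * 3)
    assert not const["passes"]


def test_scaling_schedule_validation():
    with pytest.raises(ValueError):
        sb.ScalingSchedule((0.1, 0.2))
    with pytest.raises(ValueError):
        sb.ScalingSchedule((0.1, -0.05))
    sched = sb.ScalingSchedule((0.2, 0.1))
    assert np.allclose(sched.b_seq / sched.a_seq, [5.0, 10.0])
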