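"""Block-counting chains: generator construction, exact semigroup, Gillespie."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import seedbank as sb


def test_blockcounting_rates_match_model():
    """Coalescence, dormancy and resuscitation rates as defined by the model."""
    Q = sb.build_blockcounting_Q(sb.SampleConfig(2, 0), sb.ModelParams(c=1.0, K=1.0))
    sp = Q.space
    assert Q.entries[sp.index((2, 0)), sp.index((1, 0))] == 1.0  # one pair
    Q = sb.build_blockcounting_Q(sb.SampleConfig(1, 0), sb.ModelParams(c=0.5, K=1.0))
    sp = Q.space
    assert Q.entries[sp.index((1, 0)), sp.index((0, 1))] == 0.5  # c * n
    # no lineages, no events
    assert np.all(Q.entries[sp.index((0, 0))] == 0.0)


def test_structured_rates_and_reduction_to_seedbank():
    sample = sb.SampleConfig(0, 3)
    Q = sb.build_structured_Q(sample, sb.ModelParams(c=1.0, K=1.0, alpha=1.0, alpha_prime=1.0))
    sp = Q.space
    # island-2 coalescence among 3 dormant lineages: 3 pairs
    assert Q.entries[sp.index((0, 3)), sp.index((0, 2))] == 3.0
    # alpha' = 0 with alpha = 1 reproduces the seed bank generator exactly
    sample = sb.SampleConfig(3, 2)
    params = sb.ModelParams(c=0.7, K=1.3, alpha=1.0, alpha_prime=0.0)
    Qs = sb.build_structured_Q(sample, params)
    Qb = sb.build_blockcounting_Q(sample, params)
    assert np.array_equal(Qs.entries, Qb.entries)


@given(
    n0=st.integers(0, 4),
    m0=st.integers(0, 4),
    c=st.floats(0.01, 5.0),
    K=st.floats(0.1, 5.0),
    ap=st.floats(0.0, 2.0),
)
@settings(derandomize=True, max_examples=40, deadline=None)
def test_rate_matrices_are_conservative(n0, m0, c, K, ap):
    """Rows sum to zero with non-negative off-diagonal rates, any parameters."""
    if n0 + m0 == 0:
        return
    sample = sb.SampleConfig(n0, m0)
    params = sb.ModelParams(c=c, K=K, alpha=1.0, alpha_prime=ap)
    for Q in (sb.build_blockcounting_Q(sample, params), sb.build_structured_Q(sample, params)):
        Q.validate(tol=1e-10)


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        sb.ModelParams(c=0.0, K=1.0)
    with pytest.raises(ValueError):
        sb.ModelParams(c=1.0, K=-1.0)
    with pytest.raises(ValueError):
        sb.SampleConfig(0, 0)


def test_transition_matrix_identity_and_stochastic(small_sample, default_params):
    Q = sb.build_blockcounting_Q(small_sample, default_params)
    assert np.array_equal(sb.transition_matrix(Q, 0.0), np.eye(len(Q.space)))
    for t in (0.1, 1.0, 10.0):
        T = sb.transition_matrix(Q, t)
        assert np.abs(T.sum(axis=1) - 1.0).max() < 1e-12
        assert T.min() > -1e-13
    with pytest.raises(ValueError):
        sb.transition_matrix(Q, -1.0)


def test_two_state_chain_closed_form():
    """Single-lineage chain (1,0) <-> (0,1) solves the telegraph equations."""
    c, K = 0.8, 1.7
    Q = sb.build_blockcounting_Q(sb.SampleConfig(1, 0), sb.ModelParams(c=c, K=K))
    sp = Q.space
    i = sp.index((1, 0))
    for t in (0.3, 1.0, 4.0):
        T = sb.transition_matrix(Q, t)
        # rates c and c*K: closed form with effective time c*t and ratio K
        expected = (K + np.exp(-(1 + K) * c * t)) / (1 + K)
        assert abs(T[i, i] - expected) < 1e-12


def test_gillespie_deterministic_and_absorbing(small_sample, default_params):
    Q = sb.build_blockcounting_Q(small_sample, default_params)
    p1 = sb.gillespie_simulate(Q, (2, 2), 5.0, np.random.default_rng(7))
    p2 = sb.gillespie_simulate(Q, (2, 2), 5.0, np.random.default_rng(7))
    assert p1.times == p2.times and p1.states == p2.states
    # absorbing start terminates immediately
    p0 = sb.gillespie_simulate(Q, (0, 0), 5.0, np.random.default_rng(7))
    assert p0.times == [0.0] and p0.states == [(0, 0)]


@given(seed=st.integers(0, 2**16))
@settings(derandomize=True, max_examples=25, deadline=None)
def test_total_lineage_count_never_increases(seed):
    """Coalescence decreases n+m, migration preserves it; paths never gain lineages."""
    Q = sb.build_blockcounting_Q(sb.SampleConfig(3, 2), sb.ModelParams(c=0.8, K=1.5))
    path = sb.gillespie_simulate(Q, (3, 2), 10.0, np.random.default_rng(seed))
    totals = [n + m for (n, m) in path.states]
    assert all(b <= a for a, b in zip(totals, totals[1:]))


def test_first_jump_split_matches_competing_exponentials(rng):
    """From (2,0): coalescence wins against dormancy with odds 1 : 2c."""
    c = 0.6
    Q = sb.build_blockcounting_Q(sb.SampleConfig(2, 0), sb.ModelParams(c=c, K=1.0))
    reps = 10_000
    wins = 0
    for _ in range(reps):
        # horizon 10 sees the first jump with probability 1 - exp(-22)
        path = sb.gillespie_simulate(Q, (2, 0), 10.0, rng)
        if len(path.states) > 1 and path.states[1] == (1, 0):
            wins += 1
    p = 1.0 / (1.0 + 2 * c)
    se = np.sqrt(p * (1 - p) / reps)
    assert abs(wins / reps - p) < 4 * se


def test_gillespie_marginal_matches_matrix_exponential():
    """Empirical time-t law agrees with the exact semigroup row (TV <= 0.03)."""
    sample, params = sb.SampleConfig(2, 1), sb.ModelParams(c=1.0, K=2.0)
    Q = sb.build_blockcounting_Q(sample, params)
    t, reps = 1.0, 10_000
    ends = sb.gillespie_endpoints(Q, (2, 1), t, reps, seed=11)
    counts = np.zeros(len(Q.space))
    for n, m in ends:
        counts[Q.space.index((int(n), int(m)))] += 1
    row = sb.transition_matrix(Q, t)[Q.space.index((2, 1))]
    assert sb.tv_distance(counts / reps, row) <= 0.03
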