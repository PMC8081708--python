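"""Limit genealogies: projection, limit generators, reduced chain, closed forms."""

import numpy as np
import pytest
from scipy.linalg import expm

import seedbank as sb


def test_projection_entries():
    """All states with active lineages collapse to a single active lineage."""
    aalp = sb.build_aalp(sb.SampleConfig(3, 2), 1.0)
    sp = aalp.space
    row = aalp.P[sp.index((3, 2))]
    assert row[sp.index((1, 2))] == 1.0
    assert row.sum() == 1.0
    assert np.array_equal(np.unique(aalp.P), [0.0, 1.0])
    assert np.array_equal(aalp.P @ aalp.P, aalp.P)
    # empty-active states are fixed
    assert aalp.P[sp.index((0, 3)), sp.index((0, 3))] == 1.0


def test_limit_generator_entries():
    """Resuscitation-with-coalescence rate K m; dormancy rate 1; negative
    off-diagonal mass on collapsed rows."""
    K = 1.4
    aalp = sb.build_aalp(sb.SampleConfig(3, 3), K)
    sp = aalp.space
    assert aalp.G[sp.index((1, 3)), sp.index((1, 2))] == 3 * K
    assert aalp.G[sp.index((1, 1)), sp.index((0, 2))] == 1.0
    # a negative off-diagonal entry on a row the projection collapses
    assert aalp.G[sp.index((2, 1)), sp.index((1, 1))] == -1.0 - K
    with pytest.raises(ValueError):
        sb.build_aalp(sb.SampleConfig(2, 2), 0.0)


def test_reduced_chain_entries_and_conservation():
    K = 0.9
    red = sb.build_reduced_chain(4, K)
    sp = red.space
    assert red.Gbar[sp.index((1, 2)), sp.index((0, 3))] == 1.0
    assert red.Gbar[sp.index((0, 2)), sp.index((1, 1))] == 2 * K
    # zero row sums (exact for dyadic K; one ulp of slack for K = 0.9)
    assert np.abs(red.Gbar.sum(axis=1)).max() < 1e-14
    red_dyadic = sb.build_reduced_chain(4, 0.5)
    assert np.abs(red_dyadic.Gbar.sum(axis=1)).max() == 0.0
    off = red.Gbar.copy()
    np.fill_diagonal(off, 0.0)
    assert off.min() >= 0.0


def test_restriction_identity_grid():
    """The collapsed semigroup computed two independent ways agrees to 1e-9,
    with no error growth in t."""
    for K in (0.5, 1.0, 2.0):
        for n0, m0 in [(2, 2), (3, 3), (5, 1)]:
            aalp = sb.build_aalp(sb.SampleConfig(n0, m0), K)
            red = sb.build_reduced_chain(m0 + 1, K)
            dev = sb.restriction_identity_check(aalp, red, [0.1, 1.0, 5.0])
            assert dev < 1e-9
    # near t = 0 both sides approach the projection / identity on the reduced space
    aalp = sb.build_aalp(sb.SampleConfig(3, 3), 1.0)
    red = sb.build_reduced_chain(4, 1.0)
    assert sb.restriction_identity_check(aalp, red, [1e-8]) < 1e-9


def test_limit_semigroup_support():
    """For every t > 0, mass lives on {0,1} x {0..m0+1} only."""
    sample, K = sb.SampleConfig(3, 2), 1.0
    aalp = sb.build_aalp(sample, K)
    support = {(n, m) for n in (0, 1) for m in range(sample.m0 + 2)}
    off = [i for i, s in enumerate(aalp.space) if s not in support]
    rows = [aalp.space.index((n, m)) for (n, m) in aalp.space
            if n + m <= sample.total and m <= sample.m0]
    for t in (0.05, 1.0, 5.0):
        block = aalp.semigroup(t)[np.ix_(rows, off)]
        assert np.abs(block).max() < 1e-10


def test_telegraph_closed_form_against_expm():
    for K in (0.5, 1.0, 2.0, 3.7):
        M = np.array([[-1.0, 1.0], [K, -K]])
        for t in np.linspace(0.0, 5.0, 21):
            p11, p10 = sb.telegraph_closed_form(K, t)
            T = expm(t * M)
            assert abs(p11 - T[0, 0]) < 1e-12 and abs(p10 - T[0, 1]) < 1e-12
    p11, _ = sb.telegraph_closed_form(2.0, 0.0)
    assert p11 == 1.0
    p11, _ = sb.telegraph_closed_form(2.0, 1e6)
    assert abs(p11 - 2.0 / 3.0) < 1e-12


def test_imbalanced_limit_generator_entries():
    """Island-2 coalescence survives the limit: combined rate Km + binom(m,2)."""
    K = 1.0
    sg = sb.build_imbalanced_limit(sb.SampleConfig(3, 3), K)
    space = sb.StateSpace.full_grid(sb.SampleConfig(3, 3))
    assert sg.G[space.index((1, 3)), space.index((1, 2))] == 3 * K + 3
    assert sg.G[space.index((0, 3)), space.index((0, 2))] == 3.0
    # pair count vanishes for a single dormant lineage
    assert sg.G[space.index((0, 1)), space.index((1, 0))] == K
    assert sg.G[space.index((0, 1)), space.index((0, 0))] == 0.0


def test_aalp_simulation_marginals_match_semigroup():
    """Gillespie on the reduced chain (after the initial collapse) reproduces
    the degenerate-semigroup row within a 4-SE total-variation band."""
    sample, K, t, reps = sb.SampleConfig(2, 2), 1.0, 1.0, 10_000
    aalp = sb.build_aalp(sample, K)
    row = aalp.semigroup(t)[aalp.space.index((sample.n0, sample.m0))]
    counts = {}
    for r in range(reps):
        path = sb.simulate_aalp(sample, K, t, np.random.default_rng(1000 + r))
        s = path.state_at(t)
        counts[s] = counts.get(s, 0) + 1
    emp = np.zeros(len(aalp.space))
    for s, k in counts.items():
        emp[aalp.space.index(s)] = k / reps
    tv = sb.tv_distance(emp, row)
    noise = 0.5 * float(np.sqrt(row * (1 - row) / reps).sum())
    assert tv <= 4 * noise


def test_limit_mixed_moment_basics():
    assert sb.limit_mixed_moment(0.3, 0.8, 1.0, 0.0, 2, 1) == pytest.approx(0.3**2 * 0.8)
    assert sb.limit_mixed_moment(0.3, 0.8, 1.0, 1.3, 0, 0) == 1.0
    # active moments do not depend on n >= 1 at positive times
    a = sb.limit_mixed_moment(0.3, 0.8, 1.0, 1.3, 1, 0)
    b = sb.limit_mixed_moment(0.3, 0.8, 1.0, 1.3, 5, 0)
    assert abs(a - b) < 1e-12
    p11, p10 = sb.telegraph_closed_form(1.0, 1.3)
    assert abs(a - (0.3 * p11 + 0.8 * p10)) < 1e-12
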