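"""One round of DG_{k,n} play: roles, endowments, matching, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dgevolve import (
    GameSpec,
    RoleAssignment,
    assign_roles,
    draw_endowment,
    per_step_variance,
    play_round,
)
from dgevolve.io_config import make_rng


def test_assign_roles_fraction_and_partition(rng):
    spec = GameSpec(k=1, n=2)
    ids = list(range(10_000))
    roles = assign_roles(ids, spec, rng)
    assert sorted(roles.dictators + roles.recipients) == ids
    # Bernoulli(1/2): 5 sigma band around 5000
    assert abs(len(roles.dictators) - 5000) < 5 * 50


def test_assign_roles_single_agent_both_outcomes(rng):
    spec = GameSpec(k=1, n=3)
    outcomes = {len(assign_roles([0], spec, rng).dictators) for _ in range(200)}
    assert outcomes == {0, 1}  # sometimes dictator, sometimes recipient


def test_assign_roles_deterministic_replay():
    spec = GameSpec(k=2, n=3)
    ids = list(range(100))
    a = assign_roles(ids, spec, make_rng(7, "roles"))
    b = assign_roles(ids, spec, make_rng(7, "roles"))
    assert a.dictators == b.dictators and a.recipients == b.recipients


def test_role_assignment_rejects_overlap():
    with pytest.raises(ValueError):
        RoleAssignment(dictators=[1, 2], recipients=[2, 3])


def test_draw_endowment_statistics(rng):
    spec = GameSpec(k=1, n=2, endowment_sd=0.0)
    assert draw_endowment(spec, rng) == 10.0
    noisy = GameSpec(k=1, n=2, endowment_sd=1.0)
    draws = draw_endowment(noisy, rng, size=100_000)
    assert np.all(draws >= 0)
    assert draws.mean() == pytest.approx(10.0, abs=0.05)
    assert draws.std() == pytest.approx(1.0, abs=0.05)


def test_play_round_even_split(rng):
    spec = GameSpec(k=1, n=2, endowment_sd=0.0)
    roles = RoleAssignment(dictators=[0], recipients=[1])
    delta = play_round(roles, {0: 0.5}, spec, rng)
    assert delta == {0: 5.0, 1: 5.0}


def test_play_round_non_generous_multi_dictator(rng):
    spec = GameSpec(k=2, n=3, endowment_sd=0.0)  # R = 7.5
    roles = RoleAssignment(dictators=[0, 1], recipients=[2])
    delta = play_round(roles, {0: 0.0, 1: 0.0}, spec, rng)
    assert delta == {0: 7.5, 1: 7.5, 2: 0.0}


def test_play_round_edge_cases(rng):
    spec = GameSpec(k=1, n=3, endowment_sd=0.0)  # R = 15, two recipients/game
    # no dictators: all deltas zero
    delta = play_round(RoleAssignment(recipients=[1, 2]), {}, spec, rng)
    assert delta == {1: 0.0, 2: 0.0}
    # no recipients: dictator keeps the full endowment
    delta = play_round(RoleAssignment(dictators=[0]), {0: 0.9}, spec, rng)
    assert delta == {0: 15.0}
    # too few recipients: the single recipient is played twice by one dictator
    delta = play_round(RoleAssignment(dictators=[0], recipients=[1]), {0: 0.4}, spec, rng)
    assert delta[0] == pytest.approx(15.0 * 0.6)
    assert delta[1] == pytest.approx(15.0 * 0.4)  # both shares of 0.4*15/2
    # too few dictators: some recipients get nothing
    delta = play_round(
        RoleAssignment(dictators=[0], recipients=[1, 2, 3, 4]), {0: 1.0}, spec, rng
    )
    assert sorted(delta[i] for i in (1, 2, 3, 4)) == pytest.approx([0.0, 0.0, 7.5, 7.5])


def test_play_round_missing_strategy_errors(rng):
    spec = GameSpec(k=1, n=2)
    with pytest.raises(KeyError):
        play_round(RoleAssignment(dictators=[0], recipients=[1]), {}, spec, rng)


@settings(max_examples=30, deadline=None)
@given(
    k=st.integers(1, 3),
    extra=st.integers(1, 3),
    n_agents=st.integers(2, 40),
    p_idx=st.integers(0, 10),
    seed=st.integers(0, 2**16),
)
def test_conservation_property(k, extra, n_agents, p_idx, seed):
    """Sum of deltas equals sum of drawn endowments whenever both roles occur."""
    spec = GameSpec(k=k, n=k + extra, endowment_sd=0.0)
    rng = np.random.default_rng(seed)
    roles = assign_roles(list(range(n_agents)), spec, rng)
    strategies = {a: p_idx / 10 for a in range(n_agents)}
    delta = play_round(roles, strategies, spec, rng)
    if roles.dictators and roles.recipients:
        total_endowment = len(roles.dictators) * spec.base_endowment
        assert sum(delta.values()) == pytest.approx(total_endowment)
    assert all(delta[a] >= 0 for a in roles.recipients)


def test_mean_delta_approaches_expected_return(rng):
    spec = GameSpec(k=1, n=3, endowment_sd=0.0)
    ids = list(range(30_000))
    roles = assign_roles(ids, spec, rng)
    delta = play_round(roles, {a: 0.3 for a in ids}, spec, rng)
    assert np.mean(list(delta.values())) == pytest.approx(spec.expected_return, rel=0.02)


def test_empirical_variance_matches_closed_form(rng):
    """One-step delta variance in a large homogeneous group converges to the formula."""
    spec = GameSpec(k=2, n=3, endowment_sd=0.0)
    ids = list(range(60_000))
    roles = assign_roles(ids, spec, rng)
    delta = play_round(roles, {a: 0.2 for a in ids}, spec, rng)
    values = np.array(list(delta.values()))
    assert values.var() == pytest.approx(per_step_variance(spec, 0.2), rel=0.03)


def test_play_round_bit_identical_replay():
    spec = GameSpec(k=1, n=4)
    ids = list(range(500))
    strategies = {a: 0.7 for a in ids}
    results = []
    for _ in range(2):
        rng = make_rng(99, "round")
        roles = assign_roles(ids, spec, rng)
        results.append(play_round(roles, strategies, spec, rng))
    assert results[0] == results[1]
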