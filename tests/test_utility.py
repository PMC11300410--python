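import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import decidenet as dn
from decidenet.catalog import DIMENSIONS
from decidenet.utility import (
    DOWN,
    UP,
    JOINT_STATES,
    additive_decomposition,
    badness,
    build_utility_table,
    rank_states,
    utility_from_rank,
)

EQUAL = {"ecological": 50.0, "economic": 50.0, "sociocultural": 50.0}
DISTINCT = {"ecological": 100.0, "economic": 50.0, "sociocultural": 25.0}
TWO_TIED = {"ecological": 100.0, "economic": 50.0, "sociocultural": 50.0}

# dimension scores reachable from 1-2 objectives on the quarter grid
grid_scores = st.sampled_from([0.0, 12.5, 25.0, 37.5, 50.0, 62.5, 75.0, 87.5, 100.0])
scores_strategy = st.fixed_dictionaries({d: grid_scores for d in DIMENSIONS})


def key(state):
    return tuple(state[d] for d in DIMENSIONS)


def by_n_decreasing(n):
    return [key(s) for s in JOINT_STATES if sum(x == DOWN for x in key(s)) == n]


# ---------------------------------------------------------------------------
# dimension scores and badness
# ---------------------------------------------------------------------------

def test_dimension_scores_average_objective_percents(catalog):
    s = dn.generate_session(dn.SynthConfig(seed=5), catalog)
    focal = s.focal_user_group
    scores = dn.dimension_scores(s, focal, catalog=catalog)
    for dim in DIMENSIONS:
        expected = np.mean([
            dn.importance_to_percent(o.importance_by_stakeholder[focal])
            for o in s.objectives
            if catalog.objective(o.objective_id).dimension == dim
        ])
        assert scores[dim] == pytest.approx(expected)


def test_dimension_scores_missing_entry_raises(catalog):
    s = dn.generate_session(dn.SynthConfig(seed=5), catalog)
    with pytest.raises(KeyError):
        dn.dimension_scores(s, "not-a-group", catalog=catalog)


def test_badness_examples():
    all_up = dict.fromkeys(DIMENSIONS, UP)
    all_down = dict.fromkeys(DIMENSIONS, DOWN)
    econ_down = dict(all_up, economic=DOWN)
    assert badness(all_up, DISTINCT) == 0
    assert badness(all_down, DISTINCT) == 175
    assert badness(econ_down, DISTINCT) == 50


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def test_three_way_tie_ranks_3_and_6():
    ranks = rank_states(EQUAL)
    assert ranks[key(dict.fromkeys(DIMENSIONS, UP))] == 1
    assert ranks[key(dict.fromkeys(DIMENSIONS, DOWN))] == 8
    for k in by_n_decreasing(1):
        assert ranks[k] == 3
    for k in by_n_decreasing(2):
        assert ranks[k] == 6


def test_distinct_scores_rank_1_to_8():
    ranks = rank_states(DISTINCT)
    assert sorted(ranks.values()) == list(range(1, 9))
    # badness order: subset sums 0,25,50,75,100,125,150,175
    sums = sorted(
        sum(combo) for r in range(4) for combo in itertools.combinations(DISTINCT.values(), r)
    )
    assert sums == [0, 25, 50, 75, 100, 125, 150, 175]
    order = sorted(ranks, key=ranks.get)
    assert [badness(dict(zip(DIMENSIONS, k)), DISTINCT) for k in order] == sums


def test_two_tied_midrank():
    ranks = rank_states(TWO_TIED, "midrank")
    assert sorted(ranks.values()) == [1, 2.5, 2.5, 4.5, 4.5, 6.5, 6.5, 8]


def test_two_tied_paper_literal_lookup():
    ranks = rank_states(TWO_TIED, "paper_literal")
    assert sorted(ranks.values()) == [1, 1.5, 1.5, 3.5, 5.5, 6.5, 6.5, 8]
    # the heavy dimension decreasing alone sits fourth in the badness order
    eco_down = key({"ecological": DOWN, "economic": UP, "sociocultural": UP})
    both_light_down = key({"ecological": UP, "economic": DOWN, "sociocultural": DOWN})
    assert ranks[eco_down] == 3.5
    assert ranks[both_light_down] == 5.5


def test_paper_literal_matches_midrank_without_two_way_tie():
    for scores in (EQUAL, DISTINCT):
        assert rank_states(scores, "paper_literal") == rank_states(scores, "midrank")


@settings(max_examples=200, deadline=None, derandomize=True)
@given(scores=scores_strategy)
def test_midranks_sum_to_36(scores):
    assert sum(rank_states(scores).values()) == pytest.approx(36)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(scores=scores_strategy, policy=st.sampled_from(["midrank", "paper_literal"]))
def test_rank_extremes_and_monotonicity(scores, policy):
    ranks = rank_states(scores, policy)
    best = ranks[key(dict.fromkeys(DIMENSIONS, UP))]
    worst = ranks[key(dict.fromkeys(DIMENSIONS, DOWN))]
    assert all(best <= r <= worst for r in ranks.values())
    # flipping any dimension up->down never improves the rank
    for state in JOINT_STATES:
        for d in DIMENSIONS:
            if state[d] == UP:
                flipped = dict(state, **{d: DOWN})
                assert ranks[key(flipped)] >= ranks[key(state)]


# ---------------------------------------------------------------------------
# rank -> utility
# ---------------------------------------------------------------------------

def test_utility_anchors():
    assert utility_from_rank(1) == 100
    assert utility_from_rank(8) == 0
    assert utility_from_rank(3) == pytest.approx(100 * 5 / 7, abs=1e-12)


def test_printed_coefficients_close_to_anchored_line():
    for r in range(1, 9):
        diff = abs(utility_from_rank(r, "printed_coefficients") - utility_from_rank(r))
        assert diff < 0.01


def test_rank_out_of_range_rejected():
    with pytest.raises(ValueError):
        utility_from_rank(0.5)
    with pytest.raises(ValueError):
        utility_from_rank(8.5)


# ---------------------------------------------------------------------------
# utility table
# ---------------------------------------------------------------------------

def test_equal_scores_table_values():
    table = build_utility_table(EQUAL)
    values = sorted(table.values(), reverse=True)
    assert values[0] == 100
    assert values[1:4] == pytest.approx([100 * 5 / 7] * 3)
    assert values[4:7] == pytest.approx([100 * 2 / 7] * 3)
    assert values[7] == 0


@settings(max_examples=200, deadline=None, derandomize=True)
@given(scores=scores_strategy, policy=st.sampled_from(["midrank", "paper_literal"]))
def test_table_monotone_and_anchored(scores, policy):
    table = build_utility_table(scores, policy)
    for state in JOINT_STATES:
        for d in DIMENSIONS:
            if state[d] == UP:
                worse = dict(state, **{d: DOWN})
                assert table[key(worse)] <= table[key(state)] + 1e-9
    if all(v > 0 for v in scores.values()):
        assert table[key(dict.fromkeys(DIMENSIONS, UP))] == pytest.approx(100)
        assert table[key(dict.fromkeys(DIMENSIONS, DOWN))] == pytest.approx(0)


def test_table_permutation_symmetry():
    table = build_utility_table(DISTINCT)
    permuted_scores = {
        "ecological": DISTINCT["economic"],
        "economic": DISTINCT["sociocultural"],
        "sociocultural": DISTINCT["ecological"],
    }
    permuted = build_utility_table(permuted_scores)
    # permuting the scores permutes the table identically
    for state in JOINT_STATES:
        moved = {
            "ecological": state["economic"],
            "economic": state["sociocultural"],
            "sociocultural": state["ecological"],
        }
        assert permuted[key(moved)] == pytest.approx(table[key(state)])


# ---------------------------------------------------------------------------
# additive decomposition
# ---------------------------------------------------------------------------

def exactly_additive_table(drops=(50.0, 30.0, 20.0)):
    table = {}
    for state in JOINT_STATES:
        k = key(state)
        table[k] = 100.0 - sum(
            drop for drop, s in zip(drops, k) if s == DOWN
        )
    return table


def test_additive_table_has_zero_residual():
    fit = additive_decomposition(exactly_additive_table())
    assert fit.max_residual == pytest.approx(0, abs=1e-9)
    assert fit.effects["ecological"][DOWN] == pytest.approx(-50)
    assert fit.effects["economic"][DOWN] == pytest.approx(-30)
    assert fit.effects["sociocultural"][DOWN] == pytest.approx(-20)


def test_rank_based_table_is_not_additive():
    fit = additive_decomposition(build_utility_table(EQUAL))
    assert fit.max_residual > 1.0  # clearly non-additive
    # least squares: residual is symmetric across the 8 states
    assert fit.max_residual == pytest.approx(25 / 7)


def test_decomposition_permutation_invariant():
    fit = additive_decomposition(build_utility_table(DISTINCT))
    permuted_scores = {
        "ecological": DISTINCT["sociocultural"],
        "economic": DISTINCT["ecological"],
        "sociocultural": DISTINCT["economic"],
    }
    fit_p = additive_decomposition(build_utility_table(permuted_scores))
    assert fit_p.max_residual == pytest.approx(fit.max_residual)
    assert fit_p.effects["economic"][DOWN] == pytest.approx(fit.effects["ecological"][DOWN])
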