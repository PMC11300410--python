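import pytest

import decidenet as dn
from decidenet.network import NetworkError
from conftest import make_micro_session


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "n_obj_per_dim,n_factors,expected_nodes",
    [(2, 2, 11), (1, 0, 6), (1, 1, 7), (2, 0, 9), (1, 2, 8)],
)
def test_stochastic_node_count(catalog, n_obj_per_dim, n_factors, expected_nodes):
    s = dn.generate_session(
        dn.SynthConfig(seed=7, n_objectives_per_dimension=n_obj_per_dim,
                       n_external_factors=n_factors),
        catalog,
    )
    net = dn.assemble_network(s, catalog)
    assert net.n_stochastic_nodes == expected_nodes


def test_missing_prediction_names_triple(valid_session, catalog):
    dropped = valid_session.predictions.pop()
    with pytest.raises(NetworkError) as err:
        dn.assemble_network(valid_session, catalog)
    assert dropped.objective_id in str(err.value)


def test_factor_probabilities_from_uncertainty(micro_session, catalog):
    net = dn.assemble_network(micro_session, catalog)
    fac = micro_session.external_factors[0]
    probs = net.factor_probs[fac.factor_id]
    assert probs[fac.anticipated] == pytest.approx(0.75)
    assert probs[fac.alternative] == pytest.approx(0.25)


# ---------------------------------------------------------------------------
# expected utility
# ---------------------------------------------------------------------------

def test_all_predictions_5_not_quite_100(catalog):
    # probabilities are capped at 0.9, so even the best entries stay below 100
    s = make_micro_session(catalog, pred_anticipated=5, pred_alternative=5)
    net = dn.assemble_network(s, catalog)
    eu = dn.expected_utility(net, 1)
    assert 85 < eu < 100


def test_certain_achievement_gives_100(catalog):
    # with an overridden prediction map reaching ~1.0 the best state is certain
    mapping = dn.ScaleMapping(
        prediction_map={1: 1e-12, 2: 0.3, 3: 0.5, 4: 0.7, 5: 1 - 1e-12}
    )
    s = make_micro_session(catalog, pred_anticipated=5, pred_alternative=5)
    net = dn.assemble_network(s, catalog, mapping=mapping)
    assert dn.expected_utility(net, 1) == pytest.approx(100, abs=1e-6)
    s2 = make_micro_session(catalog, pred_anticipated=1, pred_alternative=1)
    net2 = dn.assemble_network(s2, catalog, mapping=mapping)
    assert dn.expected_utility(net2, 1) == pytest.approx(0, abs=1e-6)


def test_micro_example_expected_utility(micro_session, catalog):
    """One factor at Pr(anticipated)=0.75, equal importance, achievement
    probability 0.9 under the anticipated scenario and 0.5 otherwise:
    0.75 * 91.0286 + 0.25 * 50 = 80.771."""
    net = dn.assemble_network(micro_session, catalog)
    assert dn.expected_utility(net, 1) == pytest.approx(80.771, abs=1e-3)
    assert dn.brute_force_expected_utility(net, 1) == pytest.approx(80.771, abs=1e-3)


def test_oracle_equivalence_across_configurations(catalog):
    for seed in range(12):
        s = dn.generate_session(
            dn.SynthConfig(
                seed=seed,
                n_objectives_per_dimension=1 + seed % 2,
                n_external_factors=seed % 3,
            ),
            catalog,
        )
        net = dn.assemble_network(s, catalog)
        for k in (1, 2):
            assert dn.expected_utility(net, k) == pytest.approx(
                dn.brute_force_expected_utility(net, k), abs=1e-9
            )


def test_additive_form_exact_for_additive_table(micro_session, catalog):
    net = dn.assemble_network(micro_session, catalog)
    # replace the utility node with an exactly additive table
    from decidenet.utility import JOINT_STATES, DOWN
    from dataclasses import replace

    drops = {"ecological": 50.0, "economic": 30.0, "sociocultural": 20.0}
    table = {}
    for state in JOINT_STATES:
        k = tuple(state[d] for d in drops)
        table[k] = 100.0 - sum(drops[d] for d in drops if state[d] == DOWN)
    additive_net = replace(net, utility_table=table)
    for k in (1, 2):
        assert dn.expected_utility_additive(additive_net, k) == pytest.approx(
            dn.expected_utility(additive_net, k), abs=1e-9
        )


def test_additive_form_differs_by_residual_for_rank_table(micro_session, catalog):
    net = dn.assemble_network(micro_session, catalog)
    canonical = dn.expected_utility(net, 1)
    additive = dn.expected_utility_additive(net, 1)
    assert canonical != pytest.approx(additive, abs=1e-6)
    from decidenet.utility import additive_decomposition

    residual = additive_decomposition(net.utility_table).max_residual
    assert abs(canonical - additive) <= residual + 1e-9


def test_monotone_in_prediction_scores(catalog):
    base = make_micro_session(catalog, pred_anticipated=3, pred_alternative=3)
    net = dn.assemble_network(base, catalog)
    eu_base = dn.expected_utility(net, 1)
    for i, p in enumerate(base.predictions):
        if p.option_index != 1 or p.score == 5:
            continue
        bumped = make_micro_session(catalog, pred_anticipated=3, pred_alternative=3)
        bumped.predictions[i] = dn.PredictionEntry(
            p.objective_id, p.option_index, dict(p.scenario_assignment), p.score + 1
        )
        eu_bumped = dn.expected_utility(dn.assemble_network(bumped, catalog), 1)
        assert eu_bumped >= eu_base - 1e-12


# ---------------------------------------------------------------------------
# comparison across stakeholders
# ---------------------------------------------------------------------------

def test_identical_options_tie(catalog):
    s = make_micro_session(catalog)  # option 2 copies option 1's scores
    res = dn.compare_options(s, catalog)
    assert res.focal[1] == pytest.approx(res.focal[2], abs=1e-9)
    assert res.recommended_focal is None
    assert res.recommended_aggregate is None


def test_dominating_option_recommended(catalog):
    s = make_micro_session(
        catalog,
        pred_anticipated=5, pred_alternative=4,
        pred_anticipated_2=2, pred_alternative_2=2,
    )
    res = dn.compare_options(s, catalog)
    assert res.focal[1] > res.focal[2]
    assert res.aggregate[1] > res.aggregate[2]
    assert res.recommended_focal == s.options[0].option_label


def test_single_stakeholder_aggregate_equals_focal(catalog):
    s = dn.generate_session(dn.SynthConfig(seed=9, n_stakeholders=1), catalog)
    res = dn.compare_options(s, catalog)
    assert res.per_stakeholder.keys() == {s.focal_user_group}
    for k in (1, 2):
        assert res.aggregate[k] == pytest.approx(res.focal[k])


def test_aggregate_within_stakeholder_range(valid_session, catalog):
    for aggregation in ("weighted", "unweighted"):
        res = dn.compare_options(valid_session, catalog, aggregation=aggregation)
        for k in (1, 2):
            values = [v[k] for v in res.per_stakeholder.values()]
            assert min(values) - 1e-9 <= res.aggregate[k] <= max(values) + 1e-9
            assert 0 <= res.aggregate[k] <= 100


def test_unweighted_aggregation_is_plain_mean(valid_session, catalog):
    res = dn.compare_options(valid_session, catalog, aggregation="unweighted")
    n = len(res.per_stakeholder)
    for k in (1, 2):
        mean = sum(v[k] for v in res.per_stakeholder.values()) / n
        assert res.aggregate[k] == pytest.approx(mean)


def test_invalid_session_rejected(valid_session, catalog):
    valid_session.options[0] = dn.ResourceAllocation("a", "time", {"x": 10, "y": 10})
    with pytest.raises(NetworkError, match="invalid"):
        dn.compare_options(valid_session, catalog)


def test_label_permutation_invariance(catalog):
    """Relabelling which dimensions the objectives sit under (moving the
    importance scores with them) leaves every expected utility unchanged."""
    s1 = make_micro_session(
        catalog, importance={"ecological": 5, "economic": 3, "sociocultural": 2}
    )
    s2 = make_micro_session(
        catalog, importance={"ecological": 2, "economic": 5, "sociocultural": 3}
    )
    res1 = dn.compare_options(s1, catalog)
    res2 = dn.compare_options(s2, catalog)
    for k in (1, 2):
        assert res1.focal[k] == pytest.approx(res2.focal[k], abs=1e-9)


# ---------------------------------------------------------------------------
# EVPI
# ---------------------------------------------------------------------------

def test_evpi_zero_when_preference_scenario_independent(catalog):
    # option 1 dominates under both scenarios
    s = make_micro_session(
        catalog,
        pred_anticipated=5, pred_alternative=5,
        pred_anticipated_2=2, pred_alternative_2=2,
    )
    values = dn.evpi(s, catalog)
    assert values[s.external_factors[0].factor_id] == pytest.approx(0, abs=1e-9)


def test_evpi_positive_when_preference_flips(catalog):
    # option 1 wins under the anticipated scenario, option 2 under the other;
    # maximal uncertainty makes the scenarios equiprobable
    s = make_micro_session(
        catalog, uncertainty=5,
        pred_anticipated=5, pred_alternative=1,
        pred_anticipated_2=1, pred_alternative_2=5,
    )
    fid = s.external_factors[0].factor_id
    value = dn.evpi(s, catalog)[fid]
    assert value > 0
    # hand enumeration: by symmetry E(U_1) = E(U_2) = (EU_good + EU_bad) / 2,
    # while perfect information always yields EU_good
    net = dn.assemble_network(s, catalog)
    eu1, eu2 = (dn.expected_utility(net, k) for k in (1, 2))
    assert eu1 == pytest.approx(eu2, abs=1e-9)
    probs = dict(net.factor_probs[fid])
    clamped_eus = []
    for scen in s.external_factors[0].scenario_pair:
        net.factor_probs[fid].update({x: 1.0 if x == scen else 0.0 for x in probs})
        clamped_eus.append(max(dn.expected_utility(net, k) for k in (1, 2)))
        net.factor_probs[fid].update(probs)
    expected = 0.5 * sum(clamped_eus) - eu1
    assert value == pytest.approx(expected, abs=1e-9)


def test_evpi_zero_without_residual_uncertainty(catalog):
    s = make_micro_session(
        catalog, uncertainty=1,
        pred_anticipated=5, pred_alternative=1,
        pred_anticipated_2=1, pred_alternative_2=5,
    )
    values = dn.evpi(s, catalog)
    assert values[s.external_factors[0].factor_id] == pytest.approx(0, abs=1e-9)


def test_evpi_unknown_factor_rejected(micro_session, catalog):
    with pytest.raises(KeyError):
        dn.evpi(micro_session, catalog, factor_id="not-selected")


def test_evpi_nonnegative_on_random_sessions(catalog):
    for seed in range(8):
        s = dn.generate_session(
            dn.SynthConfig(seed=100 + seed, n_external_factors=1 + seed % 2), catalog
        )
        for value in dn.evpi(s, catalog).values():
            assert value >= 0
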