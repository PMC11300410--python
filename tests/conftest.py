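import pytest

import decidenet as dn


@pytest.fixture(scope="session")
def catalog():
    return dn.default_catalog()


def make_micro_session(catalog, importance=3, uncertainty=3,
                       pred_anticipated=5, pred_alternative=3,
                       pred_anticipated_2=None, pred_alternative_2=None):
    """Smallest interesting session: one objective per dimension, one
    external factor, single (focal-only) stakeholder.

    Option 1 predictions use (pred_anticipated, pred_alternative); option 2
    defaults to the same scores unless the *_2 values are given.
    """
    fac = catalog.external_factors[0]
    objs = [
        catalog.objectives_in_dimension(d)[0].id
        for d in ("ecological", "economic", "sociocultural")
    ]
    imp = dict(importance) if isinstance(importance, dict) else None
    session = dn.Session(
        management_unit="unit",
        time_frame="10 years",
        focal_user_group="hunters",
        stakeholders=[],
        objectives=[
            dn.SelectedObjective(
                o,
                {"hunters": imp[catalog.objective(o).dimension]}
                if imp else {"hunters": importance},
            )
            for o in objs
        ],
        external_factors=[
            dn.SelectedExternalFactor(fac.id, fac.scenario_pairs[0], uncertainty)
        ],
        options=[
            dn.ResourceAllocation("option-A", "time", {"quota": 60, "season": 40}),
            dn.ResourceAllocation("option-B", "money", {"fencing": 50, "forage": 50}),
        ],
    )
    ant, alt = fac.scenario_pairs[0]
    scores = {
        (1, ant): pred_anticipated,
        (1, alt): pred_alternative,
        (2, ant): pred_anticipated_2 if pred_anticipated_2 is not None else pred_anticipated,
        (2, alt): pred_alternative_2 if pred_alternative_2 is not None else pred_alternative,
    }
    session.predictions = [
        dn.PredictionEntry(o, k, {fac.id: scen}, scores[(k, scen)])
        for o in objs
        for k in (1, 2)
        for scen in (ant, alt)
    ]
    return session


@pytest.fixture
def micro_session(catalog):
    return make_micro_session(catalog)


@pytest.fixture
def valid_session(catalog):
    return dn.generate_session(dn.SynthConfig(seed=11), catalog)
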