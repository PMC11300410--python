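"""Seeded generator of valid synthetic elicitation sessions.

Every downstream stage (validation, utility construction, network
computation, reporting) is exercised against sessions produced here; no
external data exist for this kind of workshop elicitation.  A generated
session emulates what a facilitated group would enter: 5-point scores
everywhere, 1–2 objectives per sustainability dimension, 0–2 external
factors, two options allocating integer percentages (summing to 100) over
2–4 actions, and a complete prediction grid.

Generation is deterministic: one ``numpy`` random stream per call, seeded
from the config, with the seed recorded in the emitted session's metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalog import DIMENSIONS, FactorCatalog, default_catalog
from .session import (
    PredictionEntry,
    ResourceAllocation,
    SelectedExternalFactor,
    SelectedObjective,
    Session,
    StakeholderEntry,
    prediction_grid,
)

__all__ = ["SynthConfig", "generate_session", "generate_fixture_suite"]


@dataclass(frozen=True)
class SynthConfig:
    """Shape and score distribution of a generated session.

    ``n_stakeholders`` counts all groups holding importance entries,
    including the focal user (minimum 1 = focal only).
    ``score_distribution`` weights the 5-point scores used for importance,
    uncertainty, and predictions; the default is a mild central tendency,
    as workshop entries cluster around the middle of the scale.
    """

    seed: int = 0
    n_objectives_per_dimension: int = 2
    n_external_factors: int = 2
    n_actions_per_option: int = 3
    n_stakeholders: int = 6
    score_distribution: tuple[float, ...] = (0.1, 0.2, 0.3, 0.25, 0.15)

    def __post_init__(self) -> None:
        if not 1 <= self.n_objectives_per_dimension <= 2:
            raise ValueError("n_objectives_per_dimension must be 1 or 2")
        if not 0 <= self.n_external_factors <= 2:
            raise ValueError("n_external_factors must be 0, 1, or 2")
        if not 2 <= self.n_actions_per_option <= 4:
            raise ValueError("n_actions_per_option must be 2-4")
        if self.n_stakeholders < 1:
            raise ValueError("n_stakeholders must be >= 1")
        if len(self.score_distribution) != 5 or any(
            w < 0 for w in self.score_distribution
        ) or sum(self.score_distribution) <= 0:
            raise ValueError("score_distribution must be 5 non-negative weights")


def _draw_score(rng: np.random.Generator, weights) -> int:
    p = np.asarray(weights, dtype=float)
    return int(rng.choice(np.arange(1, 6), p=p / p.sum()))


def _integer_allocation(rng: np.random.Generator, n: int) -> list[int]:
    """Positive integer percentages over n actions summing to exactly 100,
    by largest-remainder rounding of random weights."""
    raw = rng.integers(1, 11, size=n).astype(float)
    exact = 100.0 * raw / raw.sum()
    floors = np.floor(exact).astype(int)
    floors = np.maximum(floors, 1)
    shortfall = 100 - int(floors.sum())
    order = np.argsort(-(exact - np.floor(exact)))
    for i in range(abs(shortfall)):
        floors[order[i % n]] += 1 if shortfall > 0 else -1
    return [int(x) for x in floors]


def generate_session(config: SynthConfig, catalog: FactorCatalog | None = None) -> Session:
    """Generate one valid session; identical config → identical session."""
    catalog = catalog or default_catalog()
    rng = np.random.default_rng(config.seed)
    w = config.score_distribution

    groups = [g.id for g in catalog.stakeholder_groups]
    if len(groups) < config.n_stakeholders:
        raise ValueError(
            f"catalog has {len(groups)} stakeholder groups, "
            f"{config.n_stakeholders} requested"
        )
    chosen_groups = [
        str(g) for g in rng.choice(groups, size=config.n_stakeholders, replace=False)
    ]
    focal = chosen_groups[0]
    stakeholders = [
        StakeholderEntry(group_id=g, relative_importance=_draw_score(rng, w))
        for g in chosen_groups[1:]
    ]

    objectives = []
    for dim in DIMENSIONS:
        pool = [o.id for o in catalog.objectives_in_dimension(dim)]
        if len(pool) < config.n_objectives_per_dimension:
            raise ValueError(f"catalog has too few objectives under {dim!r}")
        picks = rng.choice(pool, size=config.n_objectives_per_dimension, replace=False)
        for oid in picks:
            objectives.append(
                SelectedObjective(
                    objective_id=str(oid),
                    importance_by_stakeholder={
                        g: _draw_score(rng, w) for g in chosen_groups
                    },
                    adapted_definition=f"{oid} in the focal management unit",
                    current_status="as surveyed at session start",
                    desired_status="improved or stable over the time frame",
                )
            )

    factor_pool = [f.id for f in catalog.external_factors]
    if len(factor_pool) < config.n_external_factors:
        raise ValueError("catalog has too few external factors")
    external_factors = []
    for fid in rng.choice(factor_pool, size=config.n_external_factors, replace=False):
        fac = catalog.external_factor(str(fid))
        pair = fac.scenario_pairs[int(rng.integers(len(fac.scenario_pairs)))]
        if rng.integers(2):  # either trajectory may be the anticipated one
            pair = (pair[1], pair[0])
        external_factors.append(
            SelectedExternalFactor(
                factor_id=str(fid),
                scenario_pair=pair,
                uncertainty=_draw_score(rng, w),
            )
        )

    action_pool = [a.id for a in catalog.actions]
    options = []
    for k in (1, 2):
        acts = [str(a) for a in rng.choice(
            action_pool, size=config.n_actions_per_option, replace=False
        )]
        pcts = _integer_allocation(rng, len(acts))
        options.append(
            ResourceAllocation(
                option_label=f"option-{k}",
                resource_type="time" if k == 1 else "money",
                allocations=dict(zip(acts, pcts)),
            )
        )

    session = Session(
        management_unit="synthetic management unit",
        time_frame="10 years",
        focal_user_group=focal,
        stakeholders=stakeholders,
        objectives=objectives,
        external_factors=external_factors,
        options=options,
        predictions=[],
        metadata={"generator": "decidenet.synthgen", "seed": int(config.seed)},
    )
    session.predictions = [
        PredictionEntry(
            objective_id=oid,
            option_index=k,
            scenario_assignment=assign,
            score=_draw_score(rng, w),
        )
        for (oid, k, assign) in prediction_grid(session)
    ]
    return session


def _with_scores(session: Session, importance: int | None = None,
                 prediction: int | None = None) -> Session:
    """Copy a session overriding every importance and/or prediction score."""
    objectives = [
        SelectedObjective(
            objective_id=o.objective_id,
            importance_by_stakeholder={
                g: (importance if importance is not None else s)
                for g, s in o.importance_by_stakeholder.items()
            },
            adapted_definition=o.adapted_definition,
            current_status=o.current_status,
            desired_status=o.desired_status,
        )
        for o in session.objectives
    ]
    predictions = [
        PredictionEntry(
            objective_id=p.objective_id,
            option_index=p.option_index,
            scenario_assignment=dict(p.scenario_assignment),
            score=(prediction if prediction is not None else p.score),
        )
        for p in session.predictions
    ]
    return Session(
        management_unit=session.management_unit,
        time_frame=session.time_frame,
        focal_user_group=session.focal_user_group,
        stakeholders=list(session.stakeholders),
        objectives=objectives,
        external_factors=list(session.external_factors),
        options=list(session.options),
        predictions=predictions,
        metadata=dict(session.metadata),
    )


def generate_fixture_suite(seed: int = 0, catalog: FactorCatalog | None = None) -> dict[str, Session]:
    """A deterministic collection of edge-case sessions: all-tied importance,
    all-distinct dimension importance, degenerate predictions (all 1s / all
    5s), a single-stakeholder session, and 0/1/2 external factors."""
    catalog = catalog or default_catalog()
    base = generate_session(SynthConfig(seed=seed), catalog)
    suite: dict[str, Session] = {
        "all_ties": _with_scores(base, importance=3),
        "predictions_all_1": _with_scores(base, prediction=1),
        "predictions_all_5": _with_scores(base, prediction=5),
        "single_stakeholder": generate_session(
            SynthConfig(seed=seed + 1, n_stakeholders=1), catalog
        ),
        "factors_0": generate_session(
            SynthConfig(seed=seed + 2, n_external_factors=0), catalog
        ),
        "factors_1": generate_session(
            SynthConfig(seed=seed + 3, n_external_factors=1), catalog
        ),
        "factors_2": generate_session(
            SynthConfig(seed=seed + 4, n_external_factors=2), catalog
        ),
    }

    # all-distinct dimension scores: one objective per dimension with
    # importance 5 / 3 / 2 -> dimension scores 100 / 50 / 25
    distinct = generate_session(
        SynthConfig(seed=seed + 5, n_objectives_per_dimension=1), catalog
    )
    per_dim = {"ecological": 5, "economic": 3, "sociocultural": 2}
    objectives = [
        SelectedObjective(
            objective_id=o.objective_id,
            importance_by_stakeholder={
                g: per_dim[catalog.objective(o.objective_id).dimension]
                for g in o.importance_by_stakeholder
            },
        )
        for o in distinct.objectives
    ]
    distinct.objectives = objectives
    suite["all_distinct"] = distinct
    return suite
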