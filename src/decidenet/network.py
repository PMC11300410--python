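"""Bayesian decision network over a validated session.

Topology (fixed): one decision node with the two resource-allocation options;
one binary chance node per selected external factor (its two scenarios); one
binary chance node per selected objective (achieve / fail the desired
condition), whose conditional probability table comes from the 5-point
outcome predictions; one binary chance node per sustainability dimension
(up_or_stable / decrease), whose probability is the mean of its objectives'
achievement probabilities given the option and the external-factor scenario
assignment; and one utility node holding the stakeholder's 8-state utility
table.  At the maximal configuration (2 factors, 6 objectives, 3 dimensions)
that is 11 stochastic nodes.

Expected utility of an option is computed three ways:

* :func:`expected_utility` — the canonical computation: enumerate scenario
  assignments, combine the three conditionally independent dimension
  probabilities into the 8 joint-state probabilities, and weight the joint
  utility table.
* :func:`expected_utility_additive` — the additive-decomposition form
  Σ_i Σ_j Pr(dim_ij) · U_ij (+ constant): exact whenever the utility table
  is additive, otherwise off by the additivity residual.
* :func:`brute_force_expected_utility` — full enumeration of every joint
  configuration of all stochastic nodes (≤ 2^11); the oracle the canonical
  computation is verified against.

:func:`compare_options` runs the network once per stakeholder group (each
with their own utility table) and aggregates expected satisfaction across
groups; :func:`evpi` prices perfect information about one external factor.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .catalog import DIMENSIONS, FactorCatalog, default_catalog
from .scales import (
    DEFAULT_MAPPING,
    ScaleMapping,
    importance_to_percent,
    prediction_to_probability,
    uncertainty_to_probability,
)
from .session import Session, scenario_assignments, validate_session
from .utility import (
    DOWN,
    JOINT_STATES,
    UP,
    additive_decomposition,
    build_utility_table,
    dimension_scores,
)

__all__ = [
    "DecisionNetwork",
    "ComparisonResult",
    "NetworkError",
    "assemble_network",
    "expected_utility",
    "expected_utility_additive",
    "brute_force_expected_utility",
    "compare_options",
    "evpi",
    "network_summary",
]

_EU_TOL = 1e-9


class NetworkError(ValueError):
    """Raised when a network cannot be assembled from the session."""


def _assignment_key(assignment: Mapping[str, str]) -> tuple:
    return tuple(sorted(assignment.items()))


@dataclass(frozen=True)
class DecisionNetwork:
    """Assembled network for one stakeholder's utility table.

    ``objective_cpt`` maps (objective_id, option_index, assignment_key) to
    the probability of achieving the desired condition; ``factor_probs``
    maps factor_id to {scenario_label: probability}.
    """

    options: tuple[str, str]
    factor_ids: tuple[str, ...]
    factor_probs: dict[str, dict[str, float]]
    objective_ids: tuple[str, ...]
    objectives_by_dimension: dict[str, tuple[str, ...]]
    objective_cpt: dict[tuple, float]
    utility_table: dict[tuple[str, ...], float]
    stakeholder: str
    assignments: tuple[tuple, ...]  # assignment keys, all-anticipated first
    settings: dict = field(default_factory=dict)

    @property
    def n_stochastic_nodes(self) -> int:
        """External-factor + objective + dimension chance nodes."""
        return len(self.factor_ids) + len(self.objective_ids) + len(DIMENSIONS)

    def assignment_probability(self, key: tuple) -> float:
        p = 1.0
        for fid, scenario in key:
            p *= self.factor_probs[fid][scenario]
        return p

    def dimension_probability(
        self, dimension: str, option_index: int, key: tuple
    ) -> float:
        """Pr(dimension up_or_stable | option, scenario assignment): the mean
        achievement probability over the dimension's objectives."""
        objs = self.objectives_by_dimension[dimension]
        return float(
            np.mean([self.objective_cpt[(oid, option_index, key)] for oid in objs])
        )


def assemble_network(
    session: Session,
    catalog: FactorCatalog | None = None,
    mapping: ScaleMapping = DEFAULT_MAPPING,
    tie_policy: str = "midrank",
    utility_mode: str = "anchored",
    stakeholder: str | None = None,
) -> DecisionNetwork:
    """Build the decision network for one stakeholder group (default: the
    focal user).  The session must already be valid; an incomplete
    prediction grid raises :class:`NetworkError` naming the missing triple."""
    catalog = catalog or default_catalog()
    stakeholder = stakeholder or session.focal_user_group

    if len(session.options) != 2:
        raise NetworkError(f"exactly 2 options required, got {len(session.options)}")

    factor_probs: dict[str, dict[str, float]] = {}
    for fac in sorted(session.external_factors, key=lambda f: f.factor_id):
        p = uncertainty_to_probability(fac.uncertainty, mapping)
        factor_probs[fac.factor_id] = {fac.anticipated: p, fac.alternative: 1.0 - p}
    factor_ids = tuple(factor_probs)

    assignments = tuple(
        _assignment_key(a) for a in scenario_assignments(session.external_factors)
    )

    predictions = {p.key(): p.score for p in session.predictions}
    objective_cpt: dict[tuple, float] = {}
    objective_ids = tuple(o.objective_id for o in session.objectives)
    for oid in objective_ids:
        for k in (1, 2):
            for key in assignments:
                score = predictions.get((oid, k, key))
                if score is None:
                    raise NetworkError(
                        f"missing prediction for objective {oid!r}, option {k}, "
                        f"scenarios {dict(key)!r}"
                    )
                objective_cpt[(oid, k, key)] = prediction_to_probability(score, mapping)

    by_dim: dict[str, list[str]] = {d: [] for d in DIMENSIONS}
    for oid in objective_ids:
        by_dim[catalog.objective(oid).dimension].append(oid)
    for dim, objs in by_dim.items():
        if not objs:
            raise NetworkError(f"no objective under dimension {dim!r}")

    scores = dimension_scores(session, stakeholder, mapping, catalog)
    table = build_utility_table(scores, tie_policy, utility_mode)

    return DecisionNetwork(
        options=(session.options[0].option_label, session.options[1].option_label),
        factor_ids=factor_ids,
        factor_probs=factor_probs,
        objective_ids=objective_ids,
        objectives_by_dimension={d: tuple(v) for d, v in by_dim.items()},
        objective_cpt=objective_cpt,
        utility_table=table,
        stakeholder=stakeholder,
        assignments=assignments,
        settings={
            "tie_policy": tie_policy,
            "utility_mode": utility_mode,
            "scale_mapping": mapping.to_dict(),
            "dimension_scores": scores,
        },
    )


def _joint_state_probability(
    network: DecisionNetwork, option_index: int, key: tuple
) -> dict[tuple[str, ...], float]:
    """Probability of each of the 8 joint dimension states given option and
    scenario assignment (dimensions conditionally independent)."""
    p_up = {
        d: network.dimension_probability(d, option_index, key) for d in DIMENSIONS
    }
    out: dict[tuple[str, ...], float] = {}
    for state in JOINT_STATES:
        prob = 1.0
        for d in DIMENSIONS:
            prob *= p_up[d] if state[d] == UP else 1.0 - p_up[d]
        out[tuple(state[d] for d in DIMENSIONS)] = prob
    return out


def expected_utility(network: DecisionNetwork, option_index: int) -> float:
    """Canonical E(U_k): marginalize the joint utility table over scenario
    assignments and joint dimension states."""
    total = 0.0
    for key in network.assignments:
        w = network.assignment_probability(key)
        joint = _joint_state_probability(network, option_index, key)
        total += w * sum(p * network.utility_table[s] for s, p in joint.items())
    return total


def expected_utility_additive(network: DecisionNetwork, option_index: int) -> float:
    """E(U_k) in the additive-decomposition form: the constant plus, for each
    dimension and state, the marginal state probability times the fitted
    per-dimension contribution.  Matches :func:`expected_utility` to 1e-9
    whenever the utility table is exactly additive."""
    fit = additive_decomposition(network.utility_table)
    total = fit.constant
    for dim in DIMENSIONS:
        p_up = sum(
            network.assignment_probability(key)
            * network.dimension_probability(dim, option_index, key)
            for key in network.assignments
        )
        total += p_up * fit.effects[dim][UP] + (1.0 - p_up) * fit.effects[dim][DOWN]
    return total


def brute_force_expected_utility(network: DecisionNetwork, option_index: int) -> float:
    """Oracle: enumerate the full joint distribution of every stochastic node
    (factor scenarios × objective states × dimension states) and sum
    probability × utility."""
    total = 0.0
    factor_axes = [
        [(fid, s, p) for s, p in network.factor_probs[fid].items()]
        for fid in network.factor_ids
    ]
    for factor_combo in itertools.product(*factor_axes):
        key = _assignment_key({fid: s for fid, s, _ in factor_combo})
        p_factors = float(np.prod([p for *_, p in factor_combo])) if factor_combo else 1.0

        obj_axes = [
            [
                (network.objective_cpt[(oid, option_index, key)]),
                (1.0 - network.objective_cpt[(oid, option_index, key)]),
            ]
            for oid in network.objective_ids
        ]
        dim_axes = []
        for d in DIMENSIONS:
            p_up = network.dimension_probability(d, option_index, key)
            dim_axes.append([(UP, p_up), (DOWN, 1.0 - p_up)])

        for obj_combo in itertools.product(*obj_axes):
            p_objs = float(np.prod(obj_combo)) if obj_combo else 1.0
            for dim_combo in itertools.product(*dim_axes):
                state = tuple(s for s, _ in dim_combo)
                p_dims = float(np.prod([p for _, p in dim_combo]))
                total += p_factors * p_objs * p_dims * network.utility_table[state]
    return total


# ---------------------------------------------------------------------------
# Option comparison across stakeholders
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """Expected satisfaction per option: focal user, every stakeholder group,
    and the aggregate, plus the recommendation and a record of the settings
    (scale mappings, tie policy, utility mode, aggregation) used."""

    options: tuple[str, str]
    focal_group: str
    focal: dict[int, float]
    per_stakeholder: dict[str, dict[int, float]]
    aggregate: dict[int, float]
    weights: dict[str, float]
    recommended_focal: str | None
    recommended_aggregate: str | None
    settings: dict

    @staticmethod
    def _recommend(values: Mapping[int, float], options: tuple[str, str]) -> str | None:
        if abs(values[1] - values[2]) <= _EU_TOL:
            return None
        return options[0] if values[1] > values[2] else options[1]

    def to_dict(self) -> dict:
        return {
            "options": list(self.options),
            "focal_group": self.focal_group,
            "focal": {str(k): v for k, v in self.focal.items()},
            "per_stakeholder": {
                g: {str(k): v for k, v in vals.items()}
                for g, vals in self.per_stakeholder.items()
            },
            "aggregate": {str(k): v for k, v in self.aggregate.items()},
            "weights": dict(self.weights),
            "recommended_focal": self.recommended_focal,
            "recommended_aggregate": self.recommended_aggregate,
            "settings": self.settings,
        }

    def summary(self) -> str:
        """Plain-text table of expected satisfaction per option and group."""
        lines = [
            f"Expected satisfaction (0-100) — options: "
            f"1 = {self.options[0]!r}, 2 = {self.options[1]!r}",
            f"{'group':<20} {'weight':>7} {'E(U_1)':>8} {'E(U_2)':>8}",
        ]
        for gid, vals in self.per_stakeholder.items():
            tag = f"{gid} (focal)" if gid == self.focal_group else gid
            lines.append(
                f"{tag:<20} {self.weights[gid]:>7.3f} {vals[1]:>8.2f} {vals[2]:>8.2f}"
            )
        lines.append(
            f"{'aggregate':<20} {'':>7} {self.aggregate[1]:>8.2f} {self.aggregate[2]:>8.2f}"
        )
        rec_f = self.recommended_focal or "no preference"
        rec_a = self.recommended_aggregate or "no preference"
        lines.append(f"recommended (focal user): {rec_f}")
        lines.append(f"recommended (aggregate):  {rec_a}")
        return "\n".join(lines)


def compare_options(
    session: Session,
    catalog: FactorCatalog | None = None,
    mapping: ScaleMapping = DEFAULT_MAPPING,
    tie_policy: str = "midrank",
    utility_mode: str = "anchored",
    aggregation: str = "weighted",
    check_valid: bool = True,
) -> ComparisonResult:
    """Compare the two options by expected satisfaction for the focal user,
    each stakeholder group, and the stakeholder aggregate.

    Aggregation ``weighted`` (default) weights each group by its elicited
    relative importance mapped to percent (focal user at the maximum score's
    weight); ``unweighted`` averages all groups equally.
    """
    catalog = catalog or default_catalog()
    if check_valid:
        violations = validate_session(session, catalog)
        if violations:
            raise NetworkError(
                "session invalid: " + "; ".join(str(x) for x in violations[:5])
            )
    if aggregation not in ("weighted", "unweighted"):
        raise ValueError(f"unknown aggregation {aggregation!r}")

    raw_weights = {session.focal_user_group: importance_to_percent(5, mapping)}
    for s in session.stakeholders:
        raw_weights[s.group_id] = importance_to_percent(s.relative_importance, mapping)
    if aggregation == "unweighted":
        raw_weights = {g: 1.0 for g in raw_weights}
    wsum = sum(raw_weights.values())
    weights = {g: w / wsum for g, w in raw_weights.items()}

    per_stakeholder: dict[str, dict[int, float]] = {}
    for gid in session.stakeholder_group_ids():
        net = assemble_network(
            session, catalog, mapping, tie_policy, utility_mode, stakeholder=gid
        )
        per_stakeholder[gid] = {k: expected_utility(net, k) for k in (1, 2)}

    focal = per_stakeholder[session.focal_user_group]
    aggregate = {
        k: sum(weights[g] * per_stakeholder[g][k] for g in per_stakeholder)
        for k in (1, 2)
    }
    options = (session.options[0].option_label, session.options[1].option_label)
    return ComparisonResult(
        options=options,
        focal_group=session.focal_user_group,
        focal=focal,
        per_stakeholder=per_stakeholder,
        aggregate=aggregate,
        weights=weights,
        recommended_focal=ComparisonResult._recommend(focal, options),
        recommended_aggregate=ComparisonResult._recommend(aggregate, options),
        settings={
            "tie_policy": tie_policy,
            "utility_mode": utility_mode,
            "aggregation": aggregation,
            "scale_mapping": mapping.to_dict(),
        },
    )


# ---------------------------------------------------------------------------
# Expected value of perfect information
# ---------------------------------------------------------------------------

def evpi(
    session: Session,
    catalog: FactorCatalog | None = None,
    mapping: ScaleMapping = DEFAULT_MAPPING,
    tie_policy: str = "midrank",
    utility_mode: str = "anchored",
    factor_id: str | None = None,
) -> dict[str, float]:
    """Expected value of perfect information about external factors, for the
    focal user: learn the factor's scenario before deciding, pick the best
    option per scenario, and compare with deciding under uncertainty.

    Returns ``{factor_id: evpi}`` for the requested factor (or all selected
    factors when ``factor_id`` is None).  Always non-negative; zero whenever
    the optimal option does not depend on the scenario.
    """
    catalog = catalog or default_catalog()
    selected = {f.factor_id: f for f in session.external_factors}
    if factor_id is not None:
        if factor_id not in selected:
            raise KeyError(f"factor {factor_id!r} is not selected in this session")
        targets = [factor_id]
    else:
        targets = list(selected)

    net = assemble_network(session, catalog, mapping, tie_policy, utility_mode)
    prior_best = max(expected_utility(net, k) for k in (1, 2))

    out: dict[str, float] = {}
    for fid in targets:
        fac = selected[fid]
        value = 0.0
        for scenario in fac.scenario_pair:
            p_scenario = net.factor_probs[fid][scenario]
            if p_scenario == 0.0:
                continue
            clamped = dict(net.factor_probs)
            clamped[fid] = {s: (1.0 if s == scenario else 0.0) for s in fac.scenario_pair}
            conditional = DecisionNetwork(
                options=net.options,
                factor_ids=net.factor_ids,
                factor_probs=clamped,
                objective_ids=net.objective_ids,
                objectives_by_dimension=net.objectives_by_dimension,
                objective_cpt=net.objective_cpt,
                utility_table=net.utility_table,
                stakeholder=net.stakeholder,
                assignments=net.assignments,
                settings=net.settings,
            )
            value += p_scenario * max(expected_utility(conditional, k) for k in (1, 2))
        gain = value - prior_best
        out[fid] = 0.0 if abs(gain) < _EU_TOL else gain
    return out


def network_summary(network: DecisionNetwork) -> str:
    """Plain-text node/CPT listing for inspection."""
    lines = [
        f"Decision network for stakeholder {network.stakeholder!r}",
        f"decision node: options {network.options[0]!r} / {network.options[1]!r}",
        f"stochastic nodes: {network.n_stochastic_nodes} "
        f"({len(network.factor_ids)} factors, {len(network.objective_ids)} objectives, "
        f"{len(DIMENSIONS)} dimensions)",
    ]
    for fid in network.factor_ids:
        probs = ", ".join(f"{s!r}: {p:.4f}" for s, p in network.factor_probs[fid].items())
        lines.append(f"factor {fid}: {probs}")
    for oid in network.objective_ids:
        lines.append(f"objective {oid}: Pr(achieve | option, scenarios)")
        for k in (1, 2):
            for key in network.assignments:
                lines.append(
                    f"  option {k}, {dict(key)!r}: "
                    f"{network.objective_cpt[(oid, k, key)]:.4f}"
                )
    lines.append("utility node (joint dimension states, order "
                 f"{' / '.join(DIMENSIONS)}):")
    for state in JOINT_STATES:
        key = tuple(state[d] for d in DIMENSIONS)
        arrows = "".join("↑" if s == UP else "↓" for s in key)
        lines.append(f"  {arrows}: {network.utility_table[key]:.4f}")
    return "\n".join(lines)
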