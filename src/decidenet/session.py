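"""Session data model: one complete elicitation for a management unit.

A session records everything a workshop participant (the *focal user*) enters:
the decision context, the other stakeholder groups and their importance
relative to the focal user, the selected objectives with per-stakeholder
importance scores, up to two external factors with scenario pairs and
uncertainty scores, exactly two resource-allocation options over 2–4 actions,
and a 5-point outcome prediction for every objective × option ×
external-factor-scenario combination.

Loading and saving never validate content; :func:`validate_session` is the
single, explicit validation entry point and returns machine-readable
violations instead of raising.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .catalog import DIMENSIONS, FactorCatalog

__all__ = [
    "StakeholderEntry",
    "SelectedObjective",
    "SelectedExternalFactor",
    "ResourceAllocation",
    "PredictionEntry",
    "Session",
    "Violation",
    "SessionFormatError",
    "validate_session",
    "load_session",
    "save_session",
    "prediction_grid",
]

ALLOC_TOL = 1e-9


class SessionFormatError(ValueError):
    """Raised when a session file cannot be parsed or misses required keys."""


@dataclass(frozen=True)
class StakeholderEntry:
    """A stakeholder group and its importance relative to the focal user
    (5-point scale; the focal user is implicitly at the maximum)."""

    group_id: str
    relative_importance: int


@dataclass(frozen=True)
class SelectedObjective:
    """A catalog objective adapted to the unit, with an importance score
    (1–5) per stakeholder group, focal user included."""

    objective_id: str
    importance_by_stakeholder: Mapping[str, int]
    adapted_definition: str = ""
    current_status: str = ""
    desired_status: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "importance_by_stakeholder", dict(self.importance_by_stakeholder)
        )


@dataclass(frozen=True)
class SelectedExternalFactor:
    """A selected external factor: a scenario pair (first label = anticipated
    trajectory) plus the focal user's uncertainty score (1–5)."""

    factor_id: str
    scenario_pair: tuple[str, str]
    uncertainty: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "scenario_pair", tuple(self.scenario_pair))

    @property
    def anticipated(self) -> str:
        return self.scenario_pair[0]

    @property
    def alternative(self) -> str:
        return self.scenario_pair[1]


@dataclass(frozen=True)
class ResourceAllocation:
    """One decision option: a percentage split of a resource (time or money)
    over 2–4 selected actions, summing to 100."""

    option_label: str
    resource_type: str
    allocations: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "allocations", dict(self.allocations))


@dataclass(frozen=True)
class PredictionEntry:
    """Predicted outcome (1–5) for one objective under one option and one
    assignment of scenarios to the selected external factors."""

    objective_id: str
    option_index: int
    scenario_assignment: Mapping[str, str]
    score: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "scenario_assignment", dict(self.scenario_assignment))

    def key(self) -> tuple:
        return (
            self.objective_id,
            self.option_index,
            tuple(sorted(self.scenario_assignment.items())),
        )


@dataclass
class Session:
    management_unit: str
    time_frame: str
    focal_user_group: str
    stakeholders: list[StakeholderEntry] = field(default_factory=list)
    objectives: list[SelectedObjective] = field(default_factory=list)
    external_factors: list[SelectedExternalFactor] = field(default_factory=list)
    options: list[ResourceAllocation] = field(default_factory=list)
    predictions: list[PredictionEntry] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def stakeholder_group_ids(self) -> list[str]:
        """All groups holding importance entries: focal user first."""
        return [self.focal_user_group] + [s.group_id for s in self.stakeholders]


# ---------------------------------------------------------------------------
# Prediction grid
# ---------------------------------------------------------------------------

def scenario_assignments(
    factors: Sequence[SelectedExternalFactor],
) -> list[dict[str, str]]:
    """Every assignment of one scenario to each selected factor.

    Factors are taken in lexicographic order of their ids; per factor the
    anticipated scenario comes first, so the all-anticipated assignment leads.
    With no factors the single empty assignment is returned.
    """
    ordered = sorted(factors, key=lambda f: f.factor_id)
    axes = [[(f.factor_id, f.anticipated), (f.factor_id, f.alternative)] for f in ordered]
    return [dict(combo) for combo in itertools.product(*axes)]


def prediction_grid(session: Session) -> list[tuple[str, int, dict[str, str]]]:
    """The ordered list of (objective_id, option_index, scenario_assignment)
    triples a complete session must predict: objectives in selection order,
    option 1 then 2, scenario combinations in the :func:`scenario_assignments`
    order.  Length is n_objectives × 2 × 2^e."""
    combos = scenario_assignments(session.external_factors)
    return [
        (obj.objective_id, k, dict(assign))
        for obj in session.objectives
        for k in (1, 2)
        for assign in combos
    ]


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    code: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.code}] {self.message}"


def _score_ok(value) -> bool:
    return isinstance(value, int) and not isinstance(value, bool) and 1 <= value <= 5


def validate_session(session: Session, catalog: FactorCatalog) -> list[Violation]:
    """Check every session invariant against the catalog.

    Returns one :class:`Violation` per problem (empty list = valid); invalid
    content never raises.
    """
    v: list[Violation] = []
    add = lambda code, msg: v.append(Violation(code, msg))

    known_groups = {g.id for g in catalog.stakeholder_groups}
    known_objectives = {o.id: o for o in catalog.objectives}
    known_factors = {f.id: f for f in catalog.external_factors}
    known_actions = {a.id for a in catalog.actions}

    # stakeholders
    if session.focal_user_group not in known_groups:
        add("unknown-id", f"focal user group {session.focal_user_group!r} not in catalog")
    seen_groups = {session.focal_user_group}
    for s in session.stakeholders:
        if s.group_id not in known_groups:
            add("unknown-id", f"stakeholder group {s.group_id!r} not in catalog")
        if s.group_id in seen_groups:
            add("duplicate-stakeholder", f"group {s.group_id!r} listed twice")
        seen_groups.add(s.group_id)
        if not _score_ok(s.relative_importance):
            add("score-range",
                f"relative importance of {s.group_id!r} is {s.relative_importance!r}, must be 1-5")

    # objectives: 1-2 per dimension, all dimensions represented
    group_ids = session.stakeholder_group_ids()
    per_dim: dict[str, int] = {d: 0 for d in DIMENSIONS}
    seen_obj: set[str] = set()
    for obj in session.objectives:
        cat_obj = known_objectives.get(obj.objective_id)
        if cat_obj is None:
            add("unknown-id", f"objective {obj.objective_id!r} not in catalog")
        else:
            per_dim[cat_obj.dimension] += 1
        if obj.objective_id in seen_obj:
            add("duplicate-objective", f"objective {obj.objective_id!r} selected twice")
        seen_obj.add(obj.objective_id)
        for gid in group_ids:
            if gid not in obj.importance_by_stakeholder:
                add("missing-importance",
                    f"objective {obj.objective_id!r}: no importance entry for group {gid!r}")
        for gid, score in obj.importance_by_stakeholder.items():
            if not _score_ok(score):
                add("score-range",
                    f"objective {obj.objective_id!r}: importance {score!r} for "
                    f"{gid!r} must be 1-5")
    for dim, count in per_dim.items():
        if count == 0:
            add("missing-dimension", f"no objective selected for dimension {dim!r}")
        elif count > 2:
            add("too-many-objectives-per-dimension",
                f"{count} objectives under dimension {dim!r}, at most 2 allowed")

    # external factors
    if len(session.external_factors) > 2:
        add("too-many-external-factors",
            f"{len(session.external_factors)} external factors selected, at most 2 allowed")
    seen_fac: set[str] = set()
    for fac in session.external_factors:
        cat_fac = known_factors.get(fac.factor_id)
        if cat_fac is None:
            add("unknown-id", f"external factor {fac.factor_id!r} not in catalog")
        elif set(fac.scenario_pair) not in [set(p) for p in cat_fac.scenario_pairs]:
            add("bad-scenario-pair",
                f"factor {fac.factor_id!r}: pair {fac.scenario_pair!r} not among "
                "the catalog's admissible pairs")
        if fac.factor_id in seen_fac:
            add("duplicate-factor", f"factor {fac.factor_id!r} selected twice")
        seen_fac.add(fac.factor_id)
        if not _score_ok(fac.uncertainty):
            add("score-range",
                f"factor {fac.factor_id!r}: uncertainty {fac.uncertainty!r} must be 1-5")

    # options
    if len(session.options) != 2:
        add("options-count", f"{len(session.options)} options given, exactly 2 required")
    for idx, opt in enumerate(session.options, start=1):
        n = len(opt.allocations)
        if n < 2:
            add("too-few-actions", f"option {idx}: {n} actions allocated, at least 2 required")
        elif n > 4:
            add("too-many-actions", f"option {idx}: {n} actions allocated, at most 4 allowed")
        if opt.resource_type not in ("time", "money"):
            add("bad-resource-type",
                f"option {idx}: resource type {opt.resource_type!r} must be time or money")
        total = 0.0
        for aid, pct in opt.allocations.items():
            if aid not in known_actions:
                add("unknown-id", f"option {idx}: action {aid!r} not in catalog")
            if not isinstance(pct, (int, float)) or pct < 0:
                add("negative-allocation",
                    f"option {idx}: allocation {pct!r} for {aid!r} must be non-negative")
                continue
            if pct == 0:
                add("zero-allocation",
                    f"option {idx}: selected action {aid!r} received 0% "
                    "(selection implies investment)")
            total += float(pct)
        if abs(total - 100.0) > ALLOC_TOL:
            add("allocation-sum", f"option {idx}: allocations sum to {total:g}, must be 100")

    # predictions: exactly the grid, no extras or duplicates
    required = {
        (oid, k, tuple(sorted(assign.items())))
        for (oid, k, assign) in prediction_grid(session)
    }
    seen_pred: set[tuple] = set()
    for pred in session.predictions:
        key = pred.key()
        if key in seen_pred:
            add("duplicate-prediction",
                f"duplicate prediction for objective {pred.objective_id!r}, "
                f"option {pred.option_index}, scenarios {dict(key[2])!r}")
        seen_pred.add(key)
        if key not in required:
            add("unexpected-prediction",
                f"prediction for objective {pred.objective_id!r}, option "
                f"{pred.option_index}, scenarios {dict(key[2])!r} does not match "
                "the required grid")
        if not _score_ok(pred.score):
            add("score-range",
                f"prediction for objective {pred.objective_id!r}: score "
                f"{pred.score!r} must be 1-5")
    for key in sorted(required - seen_pred):
        oid, k, assign = key
        add("missing-prediction",
            f"no prediction for objective {oid!r}, option {k}, scenarios {dict(assign)!r}")

    return v


# ---------------------------------------------------------------------------
# Serialization (YAML canonical, JSON equivalent)
# ---------------------------------------------------------------------------

def session_to_dict(session: Session) -> dict:
    data = {
        "management_unit": session.management_unit,
        "time_frame": session.time_frame,
        "focal_user_group": session.focal_user_group,
        "stakeholders": [asdict(s) for s in session.stakeholders],
        "objectives": [
            {
                "objective_id": o.objective_id,
                "adapted_definition": o.adapted_definition,
                "current_status": o.current_status,
                "desired_status": o.desired_status,
                "importance_by_stakeholder": dict(o.importance_by_stakeholder),
            }
            for o in session.objectives
        ],
        "external_factors": [
            {
                "factor_id": f.factor_id,
                "scenario_pair": list(f.scenario_pair),
                "uncertainty": f.uncertainty,
            }
            for f in session.external_factors
        ],
        "options": [
            {
                "option_label": o.option_label,
                "resource_type": o.resource_type,
                "allocations": dict(o.allocations),
            }
            for o in session.options
        ],
        "predictions": [
            {
                "objective_id": p.objective_id,
                "option_index": p.option_index,
                "scenario_assignment": dict(p.scenario_assignment),
                "score": p.score,
            }
            for p in session.predictions
        ],
    }
    if session.metadata:
        data["metadata"] = dict(session.metadata)
    return data


_REQUIRED_KEYS = (
    "management_unit",
    "time_frame",
    "focal_user_group",
    "stakeholders",
    "objectives",
    "external_factors",
    "options",
    "predictions",
)


def session_from_dict(data: dict) -> Session:
    if not isinstance(data, dict):
        raise SessionFormatError(f"session document must be a mapping, got {type(data).__name__}")
    missing = [k for k in _REQUIRED_KEYS if k not in data]
    if missing:
        raise SessionFormatError(f"session document missing keys: {', '.join(missing)}")
    try:
        return Session(
            management_unit=data["management_unit"],
            time_frame=data["time_frame"],
            focal_user_group=data["focal_user_group"],
            stakeholders=[StakeholderEntry(**s) for s in data["stakeholders"]],
            objectives=[SelectedObjective(**o) for o in data["objectives"]],
            external_factors=[
                SelectedExternalFactor(
                    factor_id=f["factor_id"],
                    scenario_pair=tuple(f["scenario_pair"]),
                    uncertainty=f["uncertainty"],
                )
                for f in data["external_factors"]
            ],
            options=[ResourceAllocation(**o) for o in data["options"]],
            predictions=[PredictionEntry(**p) for p in data["predictions"]],
            metadata=dict(data.get("metadata", {})),
        )
    except (TypeError, KeyError) as exc:
        raise SessionFormatError(f"malformed session record: {exc}") from exc


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    return "json" if path.suffix.lower() == ".json" else "yaml"


def save_session(session: Session, path: str | Path, format: str | None = None) -> None:
    """Serialize a session to YAML (canonical) or JSON. No validation."""
    path = Path(path)
    data = session_to_dict(session)
    fmt = _infer_format(path, format)
    if fmt == "yaml":
        path.write_text(yaml.safe_dump(data, sort_keys=False, allow_unicode=True), encoding="utf-8")
    elif fmt == "json":
        path.write_text(json.dumps(data, indent=2), encoding="utf-8")
    else:
        raise ValueError(f"unknown session format {fmt!r}")


def load_session(path: str | Path, format: str | None = None) -> Session:
    """Parse a session file.  Structure (keys/types) is checked; content is
    not — run :func:`validate_session` explicitly."""
    path = Path(path)
    fmt = _infer_format(path, format)
    text = path.read_text(encoding="utf-8")
    if fmt == "yaml":
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise SessionFormatError(f"cannot parse {path}: {exc}") from exc
    elif fmt == "json":
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise SessionFormatError(f"cannot parse {path}: line {exc.lineno}: {exc.msg}") from exc
    else:
        raise ValueError(f"unknown session format {fmt!r}")
    return session_from_dict(data)
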