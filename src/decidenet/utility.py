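"""Rank-based utility over joint sustainability-dimension states.

Each of the three sustainability dimensions (ecological, economic,
sociocultural) is a binary chance variable with future trajectories
``up_or_stable`` vs ``decrease``, giving 8 joint states.  A stakeholder's
satisfaction with each joint state is derived in four steps from their
objective importance scores:

1. score each dimension as the mean of its objectives' importance percents;
2. order the 8 joint states from best (rank 1) to worst (rank 8) — the
   ordering criterion is *badness*: the sum of importance scores of the
   decreasing dimensions;
3. anchor rank 1 at utility 100 and rank 8 at utility 0;
4. map rank to utility along the straight line through the anchors,
   averaging ranks among tying states.

Two tie policies exist.  ``midrank`` (default) gives every group of
badness-tied states the mean of the integer ranks they span.
``paper_literal`` reproduces the published special-case rank tables: under a
three-way tie of dimension scores the one-decreasing states share rank 3 and
the two-decreasing states rank 6 (identical to midrank); when exactly two
dimension scores tie, the positional ranks (1, 1.5, 1.5, 3.5, 5.5, 6.5, 6.5,
8) are applied along the badness order as published — a lookup, since those
half-step adjustments follow no ordering we could derive.

Two rank→utility modes exist.  ``anchored`` (default) is the exact line
through (1, 100) and (8, 0): U = 100·(8−r)/7.  ``printed_coefficients`` uses
the rounded published regression U = 114.29 − 14.286·r; the two differ by
less than 0.01 utility units over ranks 1–8.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .catalog import DIMENSIONS, FactorCatalog
from .scales import ScaleMapping, DEFAULT_MAPPING, importance_to_percent
from .session import Session

__all__ = [
    "UP",
    "DOWN",
    "JOINT_STATES",
    "joint_states",
    "n_decreasing",
    "dimension_scores",
    "badness",
    "rank_states",
    "utility_from_rank",
    "build_utility_table",
    "AdditiveFit",
    "additive_decomposition",
    "TIE_POLICIES",
    "UTILITY_MODES",
]

UP = "up_or_stable"
DOWN = "decrease"

TIE_POLICIES = ("midrank", "paper_literal")
UTILITY_MODES = ("anchored", "printed_coefficients")

_TIE_TOL = 1e-9

# Joint states as mappings dimension -> state, in a fixed enumeration order
# (all-up first, all-down last).
JOINT_STATES: tuple[Mapping[str, str], ...] = tuple(
    dict(zip(DIMENSIONS, combo))
    for combo in itertools.product((UP, DOWN), repeat=len(DIMENSIONS))
)


def joint_states() -> tuple[Mapping[str, str], ...]:
    """The 8 joint trajectory states over the three dimensions."""
    return JOINT_STATES


def _state_key(state: Mapping[str, str]) -> tuple[str, ...]:
    return tuple(state[d] for d in DIMENSIONS)


def n_decreasing(state: Mapping[str, str]) -> int:
    return sum(1 for d in DIMENSIONS if state[d] == DOWN)


def dimension_scores(
    session: Session,
    stakeholder: str,
    mapping: ScaleMapping = DEFAULT_MAPPING,
    catalog: FactorCatalog | None = None,
) -> dict[str, float]:
    """Per-dimension importance score for one stakeholder group: the mean of
    importance percents over that dimension's selected objectives.

    ``catalog`` resolves objective→dimension; it defaults to the bundled
    catalog.  Raises ``KeyError`` when the stakeholder lacks an importance
    entry for a selected objective.
    """
    if catalog is None:
        from .catalog import default_catalog

        catalog = default_catalog()
    per_dim: dict[str, list[float]] = {d: [] for d in DIMENSIONS}
    for obj in session.objectives:
        dim = catalog.objective(obj.objective_id).dimension
        if stakeholder not in obj.importance_by_stakeholder:
            raise KeyError(
                f"stakeholder {stakeholder!r} has no importance entry for "
                f"objective {obj.objective_id!r}"
            )
        score = obj.importance_by_stakeholder[stakeholder]
        per_dim[dim].append(importance_to_percent(score, mapping))
    for dim, vals in per_dim.items():
        if not vals:
            raise ValueError(f"no objective selected under dimension {dim!r}")
    return {dim: float(np.mean(vals)) for dim, vals in per_dim.items()}


def badness(state: Mapping[str, str], scores: Mapping[str, float]) -> float:
    """Ordering criterion: total importance of the decreasing dimensions.
    Zero for the all-up state; the full score sum for the all-down state."""
    return float(sum(scores[d] for d in DIMENSIONS if state[d] == DOWN))


def _ordered_states(scores: Mapping[str, float]) -> list[Mapping[str, str]]:
    # Deterministic badness order; among equal badness, fewer decreasing
    # dimensions first (matches the published two-tie state numbering), then
    # a fixed lexicographic key.
    return sorted(
        JOINT_STATES,
        key=lambda s: (badness(s, scores), n_decreasing(s), _state_key(s)),
    )


_PAPER_TWO_TIE_RANKS = (1.0, 1.5, 1.5, 3.5, 5.5, 6.5, 6.5, 8.0)


def _score_tie_pattern(scores: Mapping[str, float]) -> str:
    vals = [scores[d] for d in DIMENSIONS]
    eq = lambda a, b: abs(a - b) <= _TIE_TOL
    pairs = sum(eq(a, b) for a, b in itertools.combinations(vals, 2))
    if pairs == 3:
        return "all"
    if pairs == 1:
        return "two"
    return "none"


def rank_states(
    scores: Mapping[str, float], policy: str = "midrank"
) -> dict[tuple[str, ...], float]:
    """Rank the 8 joint states (best = 1, worst = 8) with tie averaging.

    Returns a mapping from the state key ``(eco_state, econ_state,
    socio_state)`` to its (possibly fractional) rank.  Midranks always sum
    to 36.  Under ``paper_literal`` the published lookup replaces midranks
    when exactly two dimension scores tie.
    """
    if policy not in TIE_POLICIES:
        raise ValueError(f"unknown tie policy {policy!r}, expected one of {TIE_POLICIES}")
    ordered = _ordered_states(scores)

    if policy == "paper_literal" and _score_tie_pattern(scores) == "two":
        return {
            _state_key(state): rank
            for state, rank in zip(ordered, _PAPER_TWO_TIE_RANKS)
        }

    # midrank over groups of equal badness (paper_literal's all-tied table
    # of ranks 1,3,3,3,6,6,6,8 coincides with the midrank result)
    ranks: dict[tuple[str, ...], float] = {}
    pos = 0
    for _, group in itertools.groupby(
        ordered, key=lambda s: round(badness(s, scores) / _TIE_TOL)
    ):
        members = list(group)
        span = range(pos + 1, pos + len(members) + 1)
        mid = sum(span) / len(members)
        for state in members:
            ranks[_state_key(state)] = mid
        pos += len(members)
    return ranks


def utility_from_rank(r: float, mode: str = "anchored") -> float:
    """Map a rank in [1, 8] to a 0–100 utility.

    ``anchored``: U = 100·(8−r)/7, the exact line through (1, 100) and
    (8, 0).  ``printed_coefficients``: U = 114.29 − 14.286·r, the rounded
    published form of the same line.
    """
    if not 1.0 - _TIE_TOL <= r <= 8.0 + _TIE_TOL:
        raise ValueError(f"rank {r} outside [1, 8]")
    if mode == "anchored":
        return 100.0 * (8.0 - r) / 7.0
    if mode == "printed_coefficients":
        return 114.29 - 14.286 * r
    raise ValueError(f"unknown utility mode {mode!r}, expected one of {UTILITY_MODES}")


def build_utility_table(
    scores: Mapping[str, float],
    policy: str = "midrank",
    mode: str = "anchored",
) -> dict[tuple[str, ...], float]:
    """Utility (0–100) per joint state: rank the states, then map ranks to
    utilities.  With the default anchored mode the best state gets exactly
    100 and the worst exactly 0 whenever every dimension score is positive."""
    ranks = rank_states(scores, policy)
    return {key: utility_from_rank(r, mode) for key, r in ranks.items()}


@dataclass(frozen=True)
class AdditiveFit:
    """Least-squares main-effects decomposition of a utility table.

    ``constant`` plus the per-dimension, per-state ``effects`` reproduce the
    table exactly when (and only when) the table is additive; otherwise
    ``max_residual`` reports the largest absolute deviation over the 8
    states.  Effects use ``up_or_stable`` as the reference level (effect 0).
    """

    constant: float
    effects: dict[str, dict[str, float]]
    fitted: dict[tuple[str, ...], float]
    max_residual: float

    def predicted(self, key: tuple[str, ...]) -> float:
        total = self.constant
        for dim, state in zip(DIMENSIONS, key):
            total += self.effects[dim][state]
        return total


def additive_decomposition(table: Mapping[tuple[str, ...], float]) -> AdditiveFit:
    """Fit U(state) ≈ c + Σ_i U_i(state_i) over the 8 joint states by least
    squares and report the per-dimension contributions and the additivity
    residual.  A rank-derived table is generally *not* exactly additive."""
    keys = [_state_key(s) for s in JOINT_STATES]
    y = np.array([table[k] for k in keys], dtype=float)
    # design: intercept + one indicator per dimension (1 = decrease)
    X = np.column_stack(
        [np.ones(len(keys))]
        + [[1.0 if k[i] == DOWN else 0.0 for k in keys] for i in range(len(DIMENSIONS))]
    )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted_vals = X @ beta
    effects = {
        dim: {UP: 0.0, DOWN: float(beta[i + 1])} for i, dim in enumerate(DIMENSIONS)
    }
    fitted = {k: float(v) for k, v in zip(keys, fitted_vals)}
    max_residual = float(np.max(np.abs(y - fitted_vals)))
    return AdditiveFit(float(beta[0]), effects, fitted, max_residual)
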