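"""Conversion of 5-point elicitation entries into percentages and
probabilities — the backend arithmetic hidden from the elicitation frontend.

Three fixed lookup tables drive everything downstream:

* ``importance_map`` — importance score → percent weight
  (1→0, 2→25, 3→50, 4→75, 5→100).
* ``uncertainty_map`` — uncertainty score → probability of the *anticipated*
  external-factor scenario; quarter-of-a-half steps from certainty (1→1.0)
  to maximal uncertainty (5→0.5), i.e. 1 − 0.125·(u−1).  The complement goes
  to the other scenario.
* ``prediction_map`` — outcome-prediction score → probability the objective
  reaches its desired condition; 0.1 + 0.2·(s−1), symmetric about the neutral
  midpoint 0.5 and avoiding degenerate 0/1 probabilities.

The probability tables are conventions of this package (the source tool keeps
its constants private); both can be overridden, and every report records the
mapping actually used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "ScaleMapping",
    "ScaleError",
    "DEFAULT_MAPPING",
    "importance_to_percent",
    "uncertainty_to_probability",
    "prediction_to_probability",
]

_SCORES = (1, 2, 3, 4, 5)
_TOL = 1e-9


class ScaleError(ValueError):
    """Raised for out-of-range scores or invalid mapping overrides."""


def _check_keys(m: Mapping[int, float], name: str) -> None:
    if set(m) != set(_SCORES):
        raise ScaleError(f"{name} must map exactly the scores 1-5, got keys {sorted(m)}")


@dataclass(frozen=True)
class ScaleMapping:
    """The three score→value tables; constructing an invalid override fails."""

    importance_map: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.0, 2: 25.0, 3: 50.0, 4: 75.0, 5: 100.0}
    )
    uncertainty_map: Mapping[int, float] = field(
        default_factory=lambda: {1: 1.0, 2: 0.875, 3: 0.75, 4: 0.625, 5: 0.5}
    )
    prediction_map: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.1, 2: 0.3, 3: 0.5, 4: 0.7, 5: 0.9}
    )

    def __post_init__(self) -> None:
        imp = {k: float(v) for k, v in self.importance_map.items()}
        unc = {k: float(v) for k, v in self.uncertainty_map.items()}
        pred = {k: float(v) for k, v in self.prediction_map.items()}
        object.__setattr__(self, "importance_map", imp)
        object.__setattr__(self, "uncertainty_map", unc)
        object.__setattr__(self, "prediction_map", pred)

        _check_keys(imp, "importance_map")
        _check_keys(unc, "uncertainty_map")
        _check_keys(pred, "prediction_map")
        for s in _SCORES:
            if not 0.0 <= imp[s] <= 100.0:
                raise ScaleError(f"importance_map[{s}]={imp[s]} outside [0, 100]")
            if not 0.5 - _TOL <= unc[s] <= 1.0 + _TOL:
                raise ScaleError(f"uncertainty_map[{s}]={unc[s]} outside [0.5, 1]")
            if not 0.0 < pred[s] < 1.0:
                raise ScaleError(f"prediction_map[{s}]={pred[s]} outside (0, 1)")
        for lo, hi in zip(_SCORES, _SCORES[1:]):
            if imp[hi] < imp[lo] - _TOL:
                raise ScaleError("importance_map must be non-decreasing in score")
            if unc[hi] > unc[lo] + _TOL:
                raise ScaleError("uncertainty_map must be non-increasing in score")
            if pred[hi] <= pred[lo]:
                raise ScaleError("prediction_map must be strictly increasing in score")

    def to_dict(self) -> dict:
        return {
            "importance_map": dict(self.importance_map),
            "uncertainty_map": dict(self.uncertainty_map),
            "prediction_map": dict(self.prediction_map),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ScaleMapping":
        defaults = cls()
        kwargs = {}
        for name in ("importance_map", "uncertainty_map", "prediction_map"):
            table = data.get(name)
            if table is None:
                kwargs[name] = getattr(defaults, name)
            else:
                kwargs[name] = {int(k): float(v) for k, v in table.items()}
        return cls(**kwargs)


DEFAULT_MAPPING = ScaleMapping()


def _lookup(score: int, table: Mapping[int, float], name: str) -> float:
    if not isinstance(score, int) or isinstance(score, bool) or score not in table:
        raise ScaleError(f"{name} score must be an integer 1-5, got {score!r}")
    return table[score]


def importance_to_percent(score: int, mapping: ScaleMapping = DEFAULT_MAPPING) -> float:
    """Importance score (1–5) → percent weight (default 0/25/50/75/100)."""
    return _lookup(score, mapping.importance_map, "importance")


def uncertainty_to_probability(score: int, mapping: ScaleMapping = DEFAULT_MAPPING) -> float:
    """Uncertainty score (1–5) → probability of the anticipated scenario;
    the other scenario receives the complement."""
    return _lookup(score, mapping.uncertainty_map, "uncertainty")


def prediction_to_probability(score: int, mapping: ScaleMapping = DEFAULT_MAPPING) -> float:
    """Prediction score (1–5) → probability the objective achieves its
    desired condition under the predicted option/scenario combination."""
    return _lookup(score, mapping.prediction_map, "prediction")
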