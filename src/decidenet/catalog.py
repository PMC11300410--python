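"""Factor catalog: the selectable universe of objectives, external factors,
actions, and stakeholder groups.

A session (one elicitation for a management unit) draws all of its references
from a :class:`FactorCatalog`.  The bundled default catalog describes wild
ungulate management and contains 24 objectives (7 ecological, 7 economic,
10 sociocultural), 8 external factors, 21 actions, and 6 stakeholder groups.
The entry texts are representative examples; users can supply their own
catalog via :func:`load_catalog`.

CSV interchange uses one record type per file inside a directory
(``objectives.csv``, ``external_factors.csv``, ``actions.csv``,
``stakeholders.csv``); JSON holds all four lists in one document.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

DIMENSIONS = ("ecological", "economic", "sociocultural")

__all__ = [
    "DIMENSIONS",
    "ObjectiveDef",
    "ExternalFactorDef",
    "ActionDef",
    "StakeholderGroupDef",
    "FactorCatalog",
    "CatalogError",
    "default_catalog",
    "load_catalog",
    "save_catalog",
]


class CatalogError(ValueError):
    """Raised when a catalog violates its invariants or fails to parse."""


@dataclass(frozen=True)
class ObjectiveDef:
    """A management objective, phrased verb–noun, under one sustainability
    dimension (ecological, economic, or sociocultural)."""

    id: str
    label: str
    dimension: str
    definition: str = ""

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSIONS:
            raise CatalogError(
                f"objective {self.id!r}: unknown dimension {self.dimension!r} "
                f"(expected one of {DIMENSIONS})"
            )


@dataclass(frozen=True)
class ExternalFactorDef:
    """A driver largely outside management control.

    ``scenario_pairs`` lists the admissible trajectory pairs; each pair holds
    two mutually exclusive, exhaustive trajectory labels.
    """

    id: str
    label: str
    definition: str = ""
    scenario_pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        pairs = tuple(tuple(p) for p in self.scenario_pairs)
        object.__setattr__(self, "scenario_pairs", pairs)
        for pair in pairs:
            if len(pair) != 2 or pair[0] == pair[1]:
                raise CatalogError(
                    f"external factor {self.id!r}: scenario pair {pair!r} must "
                    "hold exactly 2 distinct labels"
                )


@dataclass(frozen=True)
class ActionDef:
    """A management action resources can be allocated to."""

    id: str
    label: str
    definition: str = ""


@dataclass(frozen=True)
class StakeholderGroupDef:
    """A sector that affects or is affected by the management decision."""

    id: str
    label: str


def _check_unique(records: Iterable, kind: str) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise CatalogError(f"duplicate {kind} id {rec.id!r}")
        seen.add(rec.id)


@dataclass(frozen=True)
class FactorCatalog:
    """The four selectable factor lists, with per-list id uniqueness."""

    objectives: tuple[ObjectiveDef, ...] = ()
    external_factors: tuple[ExternalFactorDef, ...] = ()
    actions: tuple[ActionDef, ...] = ()
    stakeholder_groups: tuple[StakeholderGroupDef, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "objectives", tuple(self.objectives))
        object.__setattr__(self, "external_factors", tuple(self.external_factors))
        object.__setattr__(self, "actions", tuple(self.actions))
        object.__setattr__(self, "stakeholder_groups", tuple(self.stakeholder_groups))
        _check_unique(self.objectives, "objective")
        _check_unique(self.external_factors, "external factor")
        _check_unique(self.actions, "action")
        _check_unique(self.stakeholder_groups, "stakeholder group")

    # -- lookup helpers -------------------------------------------------
    def objective(self, oid: str) -> ObjectiveDef:
        return _find(self.objectives, oid, "objective")

    def external_factor(self, fid: str) -> ExternalFactorDef:
        return _find(self.external_factors, fid, "external factor")

    def action(self, aid: str) -> ActionDef:
        return _find(self.actions, aid, "action")

    def stakeholder_group(self, gid: str) -> StakeholderGroupDef:
        return _find(self.stakeholder_groups, gid, "stakeholder group")

    def objectives_in_dimension(self, dimension: str) -> tuple[ObjectiveDef, ...]:
        return tuple(o for o in self.objectives if o.dimension == dimension)


def _find(records: Sequence, rid: str, kind: str):
    for rec in records:
        if rec.id == rid:
            return rec
    raise KeyError(f"unknown {kind} id {rid!r}")


# ---------------------------------------------------------------------------
# Bundled default catalog (representative wild-ungulate-management entries)
# ---------------------------------------------------------------------------

_ECOLOGICAL = [
    ("regen", "Maintain forest regeneration", "Natural regeneration of site-typical tree species succeeds without protection measures."),
    ("habitat", "Conserve habitat diversity", "Structural and compositional diversity of wildlife habitats is conserved."),
    ("pophealth", "Sustain healthy wildlife populations", "Ungulate populations remain in good body condition and age structure."),
    ("flora", "Protect sensitive plant communities", "Browsing-sensitive plant communities persist at reference sites."),
    ("soil", "Prevent soil degradation", "Trampling and concentration damage to soils stays within tolerance."),
    ("connect", "Maintain habitat connectivity", "Seasonal movement corridors between habitats remain functional."),
    ("biodiv", "Promote forest biodiversity", "Mixed-species stands and associated fauna are promoted."),
]

_ECONOMIC = [
    ("browsecost", "Reduce browsing damage costs", "Costs from browsing and bark-stripping damage to timber decline."),
    ("timber", "Sustain timber revenue", "Timber production value of managed stands is maintained."),
    ("lease", "Maintain hunting lease income", "Income from hunting leases remains attractive to landowners."),
    ("cropdmg", "Reduce crop damage", "Damage by ungulates to agricultural crops declines."),
    ("compensation", "Limit compensation payments", "Obligatory damage-compensation payments stay affordable."),
    ("venison", "Sustain venison revenue", "Revenue from game meat marketing is maintained."),
    ("mgmtcost", "Limit management costs", "Recurring costs of wildlife-management measures stay within budget."),
]

_SOCIOCULTURAL = [
    ("tradition", "Maintain hunting tradition", "Regional hunting culture and customs remain viable."),
    ("trust", "Improve stakeholder trust", "Mutual trust among land-use sectors improves."),
    ("acceptance", "Increase public acceptance", "Public acceptance of wildlife management measures increases."),
    ("recreation", "Maintain recreational access", "Recreational use of forests remains possible and attractive."),
    ("roadsafety", "Improve road safety", "Wildlife-vehicle collisions decline."),
    ("cooperation", "Strengthen cross-boundary cooperation", "Cooperation among neighbouring hunting grounds strengthens."),
    ("landscape", "Preserve cultural landscape", "The characteristic cultural landscape is preserved."),
    ("viewing", "Increase wildlife viewing opportunities", "Opportunities to experience wildlife increase."),
    ("conflict", "Reduce user-group conflict", "Open conflict between user groups declines."),
    ("knowledge", "Improve knowledge transfer", "Knowledge about the managed system is shared among groups."),
]

_EXTERNAL_FACTORS = [
    ("climate", "Climate trend", "Direction of regional climate over the time frame.",
     (("warmer and drier", "near historical conditions"),)),
    ("timbermkt", "Timber market", "Development of timber prices.",
     (("prices rise", "prices stagnate or fall"),)),
    ("landuse", "Land-use change", "Conversion pressure on forest and farmland.",
     (("conversion accelerates", "land use stays stable"),)),
    ("disease", "Wildlife disease", "Occurrence of a major wildlife disease outbreak.",
     (("outbreak occurs", "no outbreak"),)),
    ("predators", "Large predator return", "Re-establishment of wolf or lynx in the unit.",
     (("predators establish", "predators stay absent"),)),
    ("tourism", "Tourism pressure", "Intensity of outdoor recreation in the unit.",
     (("pressure increases", "pressure stays stable"),)),
    ("policy", "Agricultural and forest policy", "Direction of subsidy and regulation policy.",
     (("regulation tightens", "policy stays as today"),)),
    ("attitudes", "Societal attitudes to hunting", "Public opinion about hunting.",
     (("attitudes become critical", "attitudes stay supportive"),)),
]

_ACTIONS = [
    ("quota", "Increase harvest quota", "Raise the yearly culling plan for the unit."),
    ("sexratio", "Adjust sex and age harvest ratio", "Shift harvest toward specific sex/age classes."),
    ("season", "Extend hunting season", "Lengthen the legal hunting period."),
    ("coordhunt", "Coordinate hunts across districts", "Synchronise drive hunts among neighbouring grounds."),
    ("restzones", "Establish wildlife rest zones", "Designate disturbance-free refuge areas."),
    ("fencing", "Install protective fencing", "Fence regeneration areas or sensitive crops."),
    ("singletree", "Apply single-tree protection", "Protect individual young trees mechanically or chemically."),
    ("forage", "Improve forage habitat", "Create and maintain forage areas inside the forest."),
    ("diversion", "Create browsing diversion areas", "Offer attractive browse away from sensitive stands."),
    ("winterfeed", "Provide winter feeding", "Operate winter feeding stations."),
    ("reducefeed", "Reduce supplemental feeding", "Phase out year-round supplemental feeding."),
    ("trails", "Channel visitor flows", "Steer recreation onto designated trails."),
    ("inform", "Run public information campaigns", "Inform the public about wildlife management."),
    ("roadwarn", "Install wildlife warning systems", "Equip road sections with crossing warnings."),
    ("prohunter", "Employ professional hunters", "Engage professional hunting staff."),
    ("training", "Train hunters", "Offer training in efficient, low-disturbance hunting."),
    ("dmgmonitor", "Monitor damage", "Systematically survey browsing and crop damage."),
    ("popmonitor", "Monitor populations", "Run standardized population counts."),
    ("vegmonitor", "Monitor vegetation", "Run browsing-impact vegetation surveys."),
    ("roundtable", "Hold stakeholder round tables", "Institutionalise regular multi-sector meetings."),
    ("compscheme", "Adjust compensation scheme", "Revise how damage compensation is assessed and paid."),
]

_STAKEHOLDERS = [
    ("hunters", "Hunters"),
    ("forestowners", "Forest owners"),
    ("farmers", "Farmers"),
    ("conservation", "Nature conservation"),
    ("tourismsec", "Tourism and recreation"),
    ("agency", "State forestry agency"),
]


def default_catalog() -> FactorCatalog:
    """Return the bundled catalog: 24 objectives (7/7/10 across dimensions),
    8 external factors, 21 actions, 6 stakeholder groups."""
    objectives = tuple(
        ObjectiveDef(i, lbl, dim, d)
        for dim, rows in (
            ("ecological", _ECOLOGICAL),
            ("economic", _ECONOMIC),
            ("sociocultural", _SOCIOCULTURAL),
        )
        for (i, lbl, d) in rows
    )
    factors = tuple(ExternalFactorDef(i, lbl, d, pairs) for i, lbl, d, pairs in _EXTERNAL_FACTORS)
    actions = tuple(ActionDef(i, lbl, d) for i, lbl, d in _ACTIONS)
    groups = tuple(StakeholderGroupDef(i, lbl) for i, lbl in _STAKEHOLDERS)
    return FactorCatalog(objectives, factors, actions, groups)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_CSV_FILES = {
    "objectives": ("objectives.csv", ["id", "label", "dimension", "definition"]),
    "external_factors": ("external_factors.csv", ["id", "label", "definition", "scenario_pairs"]),
    "actions": ("actions.csv", ["id", "label", "definition"]),
    "stakeholder_groups": ("stakeholders.csv", ["id", "label"]),
}


def _encode_pairs(pairs: Sequence[tuple[str, str]]) -> str:
    return ";".join(f"{a}|{b}" for a, b in pairs)


def _decode_pairs(text: str, fid: str) -> tuple[tuple[str, str], ...]:
    if not text:
        return ()
    out = []
    for chunk in text.split(";"):
        parts = chunk.split("|")
        if len(parts) != 2:
            raise CatalogError(
                f"external factor {fid!r}: malformed scenario pair {chunk!r}"
            )
        out.append((parts[0], parts[1]))
    return tuple(out)


def catalog_to_dict(catalog: FactorCatalog) -> dict:
    return {
        "objectives": [
            {"id": o.id, "label": o.label, "dimension": o.dimension, "definition": o.definition}
            for o in catalog.objectives
        ],
        "external_factors": [
            {
                "id": f.id,
                "label": f.label,
                "definition": f.definition,
                "scenario_pairs": [list(p) for p in f.scenario_pairs],
            }
            for f in catalog.external_factors
        ],
        "actions": [
            {"id": a.id, "label": a.label, "definition": a.definition}
            for a in catalog.actions
        ],
        "stakeholder_groups": [
            {"id": g.id, "label": g.label} for g in catalog.stakeholder_groups
        ],
    }


def catalog_from_dict(data: dict) -> FactorCatalog:
    try:
        objectives = tuple(ObjectiveDef(**o) for o in data.get("objectives", []))
        factors = tuple(
            ExternalFactorDef(
                id=f["id"],
                label=f["label"],
                definition=f.get("definition", ""),
                scenario_pairs=tuple(tuple(p) for p in f.get("scenario_pairs", [])),
            )
            for f in data.get("external_factors", [])
        )
        actions = tuple(ActionDef(**a) for a in data.get("actions", []))
        groups = tuple(StakeholderGroupDef(**g) for g in data.get("stakeholder_groups", []))
    except (TypeError, KeyError) as exc:
        raise CatalogError(f"malformed catalog record: {exc}") from exc
    return FactorCatalog(objectives, factors, actions, groups)


def save_catalog(catalog: FactorCatalog, path: str | Path, format: str = "json") -> None:
    """Write a catalog as one JSON document or a directory of four CSV files."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(catalog_to_dict(catalog), indent=2), encoding="utf-8")
    elif format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        data = catalog_to_dict(catalog)
        for key, (fname, header) in _CSV_FILES.items():
            with open(path / fname, "w", newline="", encoding="utf-8") as fh:
                writer = csv.DictWriter(fh, fieldnames=header)
                writer.writeheader()
                for rec in data[key]:
                    row = dict(rec)
                    if key == "external_factors":
                        row["scenario_pairs"] = _encode_pairs(rec["scenario_pairs"])
                    writer.writerow(row)
    else:
        raise ValueError(f"unknown catalog format {format!r}")


def load_catalog(path: str | Path, format: str | None = None) -> FactorCatalog:
    """Load a catalog from JSON (single file) or CSV (directory of four files).

    Format is inferred from the path when not given: a directory means CSV.
    All catalog invariants are checked; violations raise :class:`CatalogError`
    naming the offending record.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.is_dir() else "json"
    if format == "json":
        try:
            data = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise CatalogError(f"cannot parse {path}: {exc}") from exc
        return catalog_from_dict(data)
    if format == "csv":
        data: dict = {}
        for key, (fname, header) in _CSV_FILES.items():
            fpath = path / fname
            if not fpath.exists():
                data[key] = []
                continue
            with open(fpath, newline="", encoding="utf-8") as fh:
                rows = list(csv.DictReader(fh))
            if key == "external_factors":
                for row in rows:
                    row["scenario_pairs"] = _decode_pairs(
                        row.get("scenario_pairs", ""), row.get("id", "?")
                    )
            data[key] = rows
        return catalog_from_dict(data)
    raise ValueError(f"unknown catalog format {format!r}")
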