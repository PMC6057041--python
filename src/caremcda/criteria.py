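"""Decision criteria for evaluating integrated-care programmes.

Criteria are outcome concepts structured along the Triple Aim (population
health & well-being, experience of care, costs).  A core set of eight
outcomes applies to every evaluation; four programme-type-specific
supplements extend it for population health management, frail elderly,
palliative/oncology, and multi-life-domain programmes.

Each criterion carries an explicit value direction (benefit: higher raw
score is better; cost: higher is worse) and a declared worst/best scale
range, both required downstream for standardization and for truncating
performance distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import yaml

AIMS = ("health_wellbeing", "experience", "costs")
DIRECTIONS = ("benefit", "cost")
SET_TAGS = (
    "core",
    "population_health_mgmt",
    "frail_elderly",
    "palliative_oncology",
    "multi_life_domains",
)


@dataclass(frozen=True)
class Criterion:
    """One decision criterion (outcome concept).

    ``scale_worst`` / ``scale_best`` bound the natural measurement scale;
    for cost-direction criteria the worst value is numerically the larger
    one.  ``set_tag`` records which criteria set the criterion belongs to.
    """

    id: str
    label: str
    aim: str
    direction: str
    scale_worst: float
    scale_best: float
    set_tag: str = "core"

    def __post_init__(self) -> None:
        if self.aim not in AIMS:
            raise ValueError(f"unknown aim {self.aim!r}; expected one of {AIMS}")
        if self.direction not in DIRECTIONS:
            raise ValueError(
                f"unknown direction {self.direction!r}; expected one of {DIRECTIONS}"
            )
        if self.set_tag not in SET_TAGS:
            raise ValueError(
                f"unknown set_tag {self.set_tag!r}; expected one of {SET_TAGS}"
            )
        if self.scale_worst == self.scale_best:
            raise ValueError(
                f"criterion {self.id!r}: scale_worst must differ from scale_best"
            )
        # direction=cost iff higher raw value is worse, i.e. worst end above best end
        if self.direction == "cost" and self.scale_worst < self.scale_best:
            raise ValueError(
                f"criterion {self.id!r}: cost direction requires scale_worst > scale_best"
            )
        if self.direction == "benefit" and self.scale_worst > self.scale_best:
            raise ValueError(
                f"criterion {self.id!r}: benefit direction requires scale_worst < scale_best"
            )

    @property
    def scale_min(self) -> float:
        return min(self.scale_worst, self.scale_best)

    @property
    def scale_max(self) -> float:
        return max(self.scale_worst, self.scale_best)


@dataclass(frozen=True)
class CriteriaSet:
    """Ordered, validated collection of criteria."""

    criteria: tuple[Criterion, ...]
    name: str = "unnamed"

    def __post_init__(self) -> None:
        ids = [c.id for c in self.criteria]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate criterion ids in set {self.name!r}: {dupes}")

    def __iter__(self) -> Iterator[Criterion]:
        return iter(self.criteria)

    def __len__(self) -> int:
        return len(self.criteria)

    def __contains__(self, cid: str) -> bool:
        return any(c.id == cid for c in self.criteria)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.criteria)

    def get(self, cid: str) -> Criterion:
        for c in self.criteria:
            if c.id == cid:
                return c
        raise KeyError(f"criterion {cid!r} not in set {self.name!r}")

    def subset(self, ids: Iterable[str], name: str | None = None) -> "CriteriaSet":
        ids = list(ids)
        return CriteriaSet(
            tuple(self.get(i) for i in ids),
            name=name or f"{self.name}_subset",
        )


def _c(cid, label, aim, direction, worst, best, tag="core") -> Criterion:
    return Criterion(cid, label, aim, direction, float(worst), float(best), tag)


# Core outcome set.  Scale ranges follow the worked-example performance
# ranges; cost bounds are a currency-scale default and may be overridden.
_CORE = (
    _c("physical_functioning", "Physical functioning", "health_wellbeing", "benefit", 0, 100),
    _c("psychological_wellbeing", "Psychological well-being", "health_wellbeing", "benefit", 0, 100),
    _c("social_participation", "Social participation & relationships", "health_wellbeing", "benefit", 0, 4),
    _c("resilience", "Resilience", "health_wellbeing", "benefit", 1, 5),
    _c("enjoyment_of_life", "Enjoyment of life", "health_wellbeing", "benefit", 0, 4),
    _c("person_centeredness", "Person-centeredness", "experience", "benefit", 1, 4),
    _c("continuity_of_care", "Continuity of care", "experience", "benefit", 1, 5),
    _c("total_costs", "Total health and social care costs", "costs", "cost", 8500, 5500),
)

# Programme-type-specific supplements.  The source defines these at concept
# level only; scales default to 0-100 (or 100-0 for cost direction) and are
# meant to be overridden from a catalog file when real instruments are mapped.
_SUPPLEMENTS: dict[str, tuple[Criterion, ...]] = {
    "population_health_mgmt": (
        _c("activation_engagement", "Activation & engagement", "health_wellbeing", "benefit", 0, 100, "population_health_mgmt"),
        _c("burden_of_medication", "Burden of medication", "experience", "cost", 100, 0, "population_health_mgmt"),
        _c("acs_hospital_admissions", "Ambulatory care sensitive hospital admissions", "costs", "cost", 100, 0, "population_health_mgmt"),
        _c("hospital_readmissions", "Hospital re-admissions", "costs", "cost", 100, 0, "population_health_mgmt"),
    ),
    "frail_elderly": (
        _c("autonomy", "Autonomy", "health_wellbeing", "benefit", 0, 100, "frail_elderly"),
        _c("informal_care_burden", "Burden of informal caregiving", "experience", "cost", 100, 0, "frail_elderly"),
        _c("living_at_home", "Living at home", "costs", "benefit", 0, 100, "frail_elderly"),
        _c("falls_admissions", "Falls leading to ER or hospital admissions", "costs", "cost", 100, 0, "frail_elderly"),
    ),
    "palliative_oncology": (
        _c("mortality", "Mortality", "health_wellbeing", "cost", 100, 0, "palliative_oncology"),
        _c("pain_other_symptoms", "Pain and other symptoms", "health_wellbeing", "cost", 100, 0, "palliative_oncology"),
        _c("compassionate_care", "Compassionate care", "experience", "benefit", 0, 100, "palliative_oncology"),
        _c("timely_access", "Timely access to care", "experience", "benefit", 0, 100, "palliative_oncology"),
        _c("preferred_place_of_death", "Preferred place of death", "experience", "benefit", 0, 100, "palliative_oncology"),
    ),
    "multi_life_domains": (
        _c("self_sufficiency", "Self-sufficiency", "health_wellbeing", "benefit", 0, 100, "multi_life_domains"),
        _c("informal_care_burden", "Burden of informal caregiving", "experience", "cost", 100, 0, "multi_life_domains"),
        _c("justice_contacts", "Justice contacts", "costs", "cost", 100, 0, "multi_life_domains"),
    ),
}

PROGRAMME_TAGS = tuple(_SUPPLEMENTS)


def build_core_set(cost_worst: float = 8500.0, cost_best: float = 5500.0) -> CriteriaSet:
    """Return the eight-criterion core outcome set.

    Parameters
    ----------
    cost_worst, cost_best
        Currency bounds for the total-costs criterion (worst is the higher
        amount).  Costs are country-specific, so these are configurable.
    """
    crits = []
    for c in _CORE:
        if c.id == "total_costs":
            c = replace(c, scale_worst=float(cost_worst), scale_best=float(cost_best))
        crits.append(c)
    return CriteriaSet(tuple(crits), name="core")


def build_programme_set(
    tag: str, cost_worst: float = 8500.0, cost_best: float = 5500.0
) -> CriteriaSet:
    """Return the core set extended with the supplement for one programme type."""
    if tag not in _SUPPLEMENTS:
        raise ValueError(
            f"unknown programme type {tag!r}; valid tags: {sorted(_SUPPLEMENTS)}"
        )
    core = build_core_set(cost_worst, cost_best)
    return CriteriaSet(core.criteria + _SUPPLEMENTS[tag], name=tag)


# ---------------------------------------------------------------------------
# Catalog serialization (lossless round trip)

def criteria_to_records(cs: CriteriaSet) -> list[dict]:
    return [
        {
            "id": c.id,
            "label": c.label,
            "aim": c.aim,
            "direction": c.direction,
            "scale_worst": c.scale_worst,
            "scale_best": c.scale_best,
            "set_tag": c.set_tag,
        }
        for c in cs
    ]


def criteria_from_records(records: Iterable[dict], name: str = "catalog") -> CriteriaSet:
    return CriteriaSet(
        tuple(
            Criterion(
                id=r["id"],
                label=r["label"],
                aim=r["aim"],
                direction=r["direction"],
                scale_worst=float(r["scale_worst"]),
                scale_best=float(r["scale_best"]),
                set_tag=r.get("set_tag", "core"),
            )
            for r in records
        ),
        name=name,
    )


def write_catalog(cs: CriteriaSet, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"name": cs.name, "criteria": criteria_to_records(cs)},
            fh,
            sort_keys=False,
        )


def read_catalog(path) -> CriteriaSet:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return criteria_from_records(doc["criteria"], name=doc.get("name", "catalog"))
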