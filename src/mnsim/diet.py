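"""Meal patterns, dishes and daily diet scenarios.

A :class:`DietScenario` is a country/setting/population-group cell plus a
plan of meals, each meal being a list of (dish, portion multiplier) pairs.
Scenarios flatten deterministically to per-day ingredient masses, which are
totalled against a composition table to a per-day nutrient vector.
"""

from __future__ import annotations

import tomllib
import warnings
from dataclasses import dataclass, replace
from types import MappingProxyType
from typing import Mapping

from .composition import (
    PER_DAY,
    CompositionTable,
    NutrientVector,
    ValidationError,
)

__all__ = [
    "ResolutionError",
    "Dish",
    "MealPlan",
    "PopulationGroup",
    "NPNL",
    "PL",
    "DietScenario",
    "resolve_daily_ingredients",
    "daily_intake",
    "substitute_food",
    "add_food",
    "scenario_to_toml",
    "scenario_from_toml",
]


class ResolutionError(LookupError):
    """A dish or food reference could not be resolved; names the id."""


@dataclass(frozen=True)
class Dish:
    """A recipe: ingredient masses in grams as consumed."""

    dish_id: str
    ingredients: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if not self.dish_id:
            raise ValidationError("dish_id must be non-empty")
        ingredients = tuple((fid, float(g)) for fid, g in self.ingredients)
        for fid, grams in ingredients:
            if not fid:
                raise ValidationError(f"dish {self.dish_id!r}: empty food_id")
            if grams <= 0:
                raise ValidationError(
                    f"dish {self.dish_id!r}: non-positive mass {grams} for {fid!r}"
                )
        object.__setattr__(self, "ingredients", ingredients)


@dataclass(frozen=True)
class MealPlan:
    """Ordered meals, each a list of (dish_id, portion multiplier)."""

    meals: tuple[tuple[str, tuple[tuple[str, float], ...]], ...]

    def __post_init__(self) -> None:
        meals = tuple(
            (label, tuple((did, float(m)) for did, m in dishes)) for label, dishes in self.meals
        )
        for label, dishes in meals:
            for did, mult in dishes:
                if mult <= 0:
                    raise ValidationError(
                        f"meal {label!r}: non-positive multiplier {mult} for dish {did!r}"
                    )
        object.__setattr__(self, "meals", meals)

    def __len__(self) -> int:
        return len(self.meals)


@dataclass(frozen=True)
class PopulationGroup:
    """Reference group of women of reproductive age with an assumed body weight."""

    id: str
    body_weight_kg: float

    def __post_init__(self) -> None:
        if self.id not in ("NPNL", "PL"):
            raise ValidationError(f"unknown population group {self.id!r}")
        if self.body_weight_kg <= 0:
            raise ValidationError("body weight must be positive")


NPNL = PopulationGroup("NPNL", 55.0)
PL = PopulationGroup("PL", 65.0)

_COUNTRIES = ("benin", "ghana")
_SETTINGS = ("urban", "rural")


@dataclass(frozen=True)
class DietScenario:
    country: str
    setting: str
    group: PopulationGroup
    plan: MealPlan
    dishes: Mapping[str, Dish]

    def __post_init__(self) -> None:
        if self.country not in _COUNTRIES:
            raise ValidationError(f"unknown country {self.country!r}")
        if self.setting not in _SETTINGS:
            raise ValidationError(f"unknown setting {self.setting!r}")
        registry = MappingProxyType(dict(self.dishes))
        object.__setattr__(self, "dishes", registry)
        for label, dishes in self.plan.meals:
            for did, _ in dishes:
                if did not in registry:
                    raise ResolutionError(
                        f"meal {label!r} references unknown dish {did!r}"
                    )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DietScenario):
            return NotImplemented
        return (
            self.country == other.country
            and self.setting == other.setting
            and self.group == other.group
            and self.plan == other.plan
            and dict(self.dishes) == dict(other.dishes)
        )

    __hash__ = None  # type: ignore[assignment]


def resolve_daily_ingredients(scenario: DietScenario) -> list[tuple[str, float]]:
    """Flatten a scenario to one (food_id, grams/day) entry per distinct food.

    Output order is deterministic (sorted by food_id).
    """
    totals: dict[str, float] = {}
    for label, dishes in scenario.plan.meals:
        for dish_id, multiplier in dishes:
            try:
                dish = scenario.dishes[dish_id]
            except KeyError:
                raise ResolutionError(
                    f"meal {label!r} references unknown dish {dish_id!r}"
                ) from None
            for food_id, grams in dish.ingredients:
                totals[food_id] = totals.get(food_id, 0.0) + multiplier * grams
    return sorted(totals.items())


def daily_intake(
    scenario: DietScenario,
    table: CompositionTable,
    supplements: NutrientVector | None = None,
) -> NutrientVector:
    """Total per-day nutrient intake: Σ grams × density/100, plus supplements."""
    total = NutrientVector.zero(PER_DAY)
    for food_id, grams in resolve_daily_ingredients(scenario):
        try:
            item = table[food_id]
        except KeyError:
            raise ResolutionError(f"food {food_id!r} not in composition table") from None
        total = total + item.composition.intake_for(grams)
    if supplements is not None:
        if supplements.basis != PER_DAY:
            raise ValidationError("supplements must be a per-day vector")
        total = total + supplements
    return total


def substitute_food(
    scenario: DietScenario,
    old: str,
    new: str,
    table: CompositionTable | None = None,
) -> DietScenario:
    """Replace every occurrence of ``old`` by ``new`` at identical mass.

    Mass-preserving by construction.  If ``old`` occurs nowhere the scenario
    is returned unchanged with a warning.  When a table is supplied, ``new``
    must resolve against it.
    """
    if table is not None and new not in table:
        raise ResolutionError(f"substitute food {new!r} not in composition table")
    occurs = any(
        fid == old for dish in scenario.dishes.values() for fid, _ in dish.ingredients
    )
    if not occurs:
        warnings.warn(f"substitute_food: {old!r} does not occur in any dish; no-op")
        return scenario
    if old == new:
        return scenario
    new_dishes = {}
    for dish_id, dish in scenario.dishes.items():
        new_dishes[dish_id] = Dish(
            dish_id,
            tuple((new if fid == old else fid, g) for fid, g in dish.ingredients),
        )
    return replace(scenario, dishes=new_dishes)


def add_food(scenario: DietScenario, food_id: str, grams: float, label: str | None = None) -> DietScenario:
    """Append an extra eating occasion containing a single food."""
    if grams <= 0:
        raise ValidationError("added grams must be positive")
    base = label or f"addition:{food_id}"
    existing = {lbl for lbl, _ in scenario.plan.meals}
    meal_label = base
    i = 2
    while meal_label in existing:
        meal_label = f"{base}#{i}"
        i += 1
    dish_id = f"_add_{food_id}_{len(scenario.dishes)}"
    dishes = dict(scenario.dishes)
    dishes[dish_id] = Dish(dish_id, ((food_id, grams),))
    plan = MealPlan(scenario.plan.meals + ((meal_label, ((dish_id, 1.0),)),))
    return replace(scenario, plan=plan, dishes=dishes)


# ---------------------------------------------------------------------------
# TOML scenario files

def _toml_str(s: str) -> str:
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'


def scenario_to_toml(scenario: DietScenario) -> str:
    """Serialize a scenario to the TOML exchange format."""
    lines = [
        "[scenario]",
        f"country = {_toml_str(scenario.country)}",
        f"setting = {_toml_str(scenario.setting)}",
        f"group = {_toml_str(scenario.group.id)}",
        f"body_weight_kg = {scenario.group.body_weight_kg!r}",
        "",
    ]
    for dish_id in sorted(scenario.dishes):
        dish = scenario.dishes[dish_id]
        ingredients = ", ".join(
            f"[{_toml_str(fid)}, {g!r}]" for fid, g in dish.ingredients
        )
        lines += ["[[dish]]", f"id = {_toml_str(dish_id)}", f"ingredients = [{ingredients}]", ""]
    for label, dishes in scenario.plan.meals:
        entries = ", ".join(f"[{_toml_str(did)}, {m!r}]" for did, m in dishes)
        lines += ["[[meal]]", f"label = {_toml_str(label)}", f"dishes = [{entries}]", ""]
    return "\n".join(lines)


def scenario_from_toml(text: str) -> DietScenario:
    """Parse a scenario from the TOML exchange format."""
    data = tomllib.loads(text)
    try:
        meta = data["scenario"]
        group = PopulationGroup(meta["group"], float(meta.get("body_weight_kg", 55.0)))
        dishes = {
            d["id"]: Dish(d["id"], tuple((fid, float(g)) for fid, g in d["ingredients"]))
            for d in data.get("dish", [])
        }
        plan = MealPlan(
            tuple(
                (m["label"], tuple((did, float(mult)) for did, mult in m["dishes"]))
                for m in data.get("meal", [])
            )
        )
        return DietScenario(
            country=meta["country"],
            setting=meta["setting"],
            group=group,
            plan=plan,
            dishes=dishes,
        )
    except KeyError as exc:
        raise ValidationError(f"scenario TOML missing key: {exc}") from None
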