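"""Intervention layers and their composition with a base diet.

Four layer types are supported: fortification (additive, per-vehicle),
biofortification (wholesale composition replacement), supplementation
(per-day vector addition) and food swaps (add a food, or replace one food
by another at identical mass).  ``compose_bundle`` applies layers in the
fixed order biofortification -> fortification -> swaps -> supplements and
reports per-layer marginal contributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping, Union

from .composition import (
    IODINE_MASS_FRACTION,
    PER_100G,
    PER_DAY,
    RETINOL_IU,
    RETINYL_PALMITATE_MASS,
    CompositionTable,
    FoodItem,
    NutrientVector,
    UnknownFoodError,
    ValidationError,
    VitaminAQuantity,
    iodate_to_iodine,
    to_ug_rae,
)
from .diet import DietScenario, add_food, daily_intake, substitute_food

__all__ = [
    "InterventionError",
    "BundleError",
    "FORTIFICANTS",
    "Fortificant",
    "FortificantAddition",
    "FortificationSpec",
    "BiofortificationSpec",
    "SupplementSpec",
    "FoodSwapSpec",
    "InterventionLayer",
    "ScenarioBundle",
    "apply_fortification",
    "apply_biofortification",
    "apply_supplement",
    "compose_bundle",
    "ComposeResult",
    "layer_label",
]


class InterventionError(ValueError):
    """Invalid intervention specification or application failure."""


class BundleError(InterventionError):
    """Conflicting or unsatisfiable layer combination."""


# ---------------------------------------------------------------------------
# Fortificant registry

@dataclass(frozen=True)
class Fortificant:
    """A fortification compound: target nutrient and elemental mass fraction.

    ``nutrient`` is None for compounds outside the six tracked nutrients
    (B vitamins other than niacin/folate); they contribute nothing but are
    accepted so real premix specifications can be written down verbatim.
    """

    compound: str
    nutrient: str | None
    elemental_fraction: float = 1.0
    kind: str = "mass"  # mass | iodate | retinyl_palmitate


FORTIFICANTS: Mapping[str, Fortificant] = MappingProxyType(
    {
        "ferrous_fumarate": Fortificant("ferrous_fumarate", "iron", 0.328),
        "zinc_oxide": Fortificant("zinc_oxide", "zinc", 0.803),
        "niacin": Fortificant("niacin", "niacin", 1.0),
        "niacinamide": Fortificant("niacinamide", "niacin", 1.0),
        "folic_acid": Fortificant("folic_acid", "folate", 1.0),
        "thiamine": Fortificant("thiamine", None),
        "thiamine_mononitrate": Fortificant("thiamine_mononitrate", None),
        "riboflavin": Fortificant("riboflavin", None),
        "pyridoxine": Fortificant("pyridoxine", None),
        "cyanocobalamin": Fortificant("cyanocobalamin", None),
        "KIO3": Fortificant("KIO3", "iodine", IODINE_MASS_FRACTION["KIO3"], kind="iodate"),
        "NaIO3": Fortificant("NaIO3", "iodine", IODINE_MASS_FRACTION["NaIO3"], kind="iodate"),
        "Ca_IO3_2": Fortificant(
            "Ca_IO3_2", "iodine", IODINE_MASS_FRACTION["Ca_IO3_2"], kind="iodate"
        ),
        "retinyl_palmitate": Fortificant(
            "retinyl_palmitate", "vitamin_a", kind="retinyl_palmitate"
        ),
    }
)

# "g/t" (grams per tonne) == "mg/kg" == "ppm" == "ug/g": mg compound per kg vehicle
_MASS_PER_KG_UNITS = ("g/t", "mg/kg", "ppm", "ug/g")


@dataclass(frozen=True)
class FortificantAddition:
    """One fortificant at a level, with an explicit unit string.

    Levels are compound mass unless ``elemental_equivalent`` is set, in which
    case the stated mass is counted directly as the nutrient (fraction 1).
    """

    compound: str
    level: float
    unit: str
    elemental_equivalent: bool = False

    def __post_init__(self) -> None:
        if self.compound not in FORTIFICANTS:
            raise InterventionError(f"unknown fortificant {self.compound!r}")
        if self.level < 0:
            raise InterventionError("fortification level must be non-negative")
        if self.unit not in _MASS_PER_KG_UNITS + ("IU/g",):
            raise InterventionError(f"unknown level unit {self.unit!r}")
        if self.unit == "IU/g" and FORTIFICANTS[self.compound].kind != "retinyl_palmitate":
            raise InterventionError("IU/g levels only apply to retinol esters")

    def per_100g(self) -> NutrientVector:
        """Nutrient mass added per 100 g of vehicle, in canonical units."""
        fort = FORTIFICANTS[self.compound]
        if fort.nutrient is None:
            return NutrientVector.zero(PER_100G)
        if self.unit == "IU/g":
            # IU per g vehicle -> µg RAE per 100 g
            rae_per_g = to_ug_rae(VitaminAQuantity(RETINOL_IU, self.level))
            return NutrientVector({"vitamin_a": rae_per_g * 100.0}, basis=PER_100G)
        # mass-per-kg family: level is mg compound per kg == mg per 100 g / 10
        mg_per_100g = self.level / 10.0
        if fort.kind == "retinyl_palmitate":
            rae = to_ug_rae(VitaminAQuantity(RETINYL_PALMITATE_MASS, mg_per_100g))
            return NutrientVector({"vitamin_a": rae}, basis=PER_100G)
        if fort.kind == "iodate":
            if self.elemental_equivalent:
                iodine_mg = mg_per_100g
            else:
                iodine_mg = iodate_to_iodine(self.compound, mg_per_100g)
            return NutrientVector({"iodine": iodine_mg * 1000.0}, basis=PER_100G)
        fraction = 1.0 if self.elemental_equivalent else fort.elemental_fraction
        elemental_mg = mg_per_100g * fraction
        if fort.nutrient in ("folate",):  # canonical unit µg
            return NutrientVector({fort.nutrient: elemental_mg * 1000.0}, basis=PER_100G)
        return NutrientVector({fort.nutrient: elemental_mg}, basis=PER_100G)


@dataclass(frozen=True)
class FortificationSpec:
    """Fortify one vehicle food with a list of fortificant additions."""

    vehicle: str
    additions: tuple[FortificantAddition, ...]
    mandatory: bool = True
    compliance: float = 1.0  # fraction of vehicle adequately fortified; untested vs tables

    def __post_init__(self) -> None:
        object.__setattr__(self, "additions", tuple(self.additions))
        if not 0.0 <= self.compliance <= 1.0:
            raise InterventionError("compliance must be within [0, 1]")

    def added_per_100g(self) -> NutrientVector:
        total = NutrientVector.zero(PER_100G)
        for addition in self.additions:
            total = total + addition.per_100g()
        return total.scale(self.compliance)


@dataclass(frozen=True)
class BiofortificationSpec:
    """Replace a food's composition wholesale by the biofortified variant."""

    target: str
    replacement: NutrientVector

    def __post_init__(self) -> None:
        if self.replacement.basis != PER_100G:
            raise InterventionError("replacement composition must be per-100 g")


@dataclass(frozen=True)
class SupplementSpec:
    """Per-day supplement doses; a single high dose counts in full on the day."""

    name: str
    doses: NutrientVector
    schedule: str = "daily"

    def __post_init__(self) -> None:
        if self.doses.basis != PER_DAY:
            raise InterventionError("supplement doses must be per-day")
        if self.schedule not in ("daily", "single_high_dose"):
            raise InterventionError(f"unknown schedule {self.schedule!r}")


@dataclass(frozen=True)
class FoodSwapSpec:
    """Add a food to the day, or replace one food by another at equal mass."""

    action: str  # "add" | "replace"
    food_id: str | None = None
    grams: float | None = None
    old_id: str | None = None
    new_id: str | None = None

    def __post_init__(self) -> None:
        if self.action == "add":
            if not self.food_id or self.grams is None or self.grams <= 0:
                raise InterventionError("add swap requires food_id and grams > 0")
        elif self.action == "replace":
            if not self.old_id or not self.new_id:
                raise InterventionError("replace swap requires old_id and new_id")
        else:
            raise InterventionError(f"unknown swap action {self.action!r}")


InterventionLayer = Union[FortificationSpec, BiofortificationSpec, SupplementSpec, FoodSwapSpec]

_LAYER_ORDER = {BiofortificationSpec: 0, FortificationSpec: 1, FoodSwapSpec: 2, SupplementSpec: 3}


def layer_label(layer: InterventionLayer) -> str:
    if isinstance(layer, FortificationSpec):
        return f"fortification:{layer.vehicle}"
    if isinstance(layer, BiofortificationSpec):
        return f"biofortification:{layer.target}"
    if isinstance(layer, SupplementSpec):
        return f"supplement:{layer.name}"
    if layer.action == "add":
        return f"swap:add:{layer.food_id}"
    return f"swap:replace:{layer.old_id}->{layer.new_id}"


@dataclass(frozen=True)
class ScenarioBundle:
    """A base diet scenario plus an ordered list of intervention layers."""

    base: DietScenario
    layers: tuple[InterventionLayer, ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        vehicles = [l.vehicle for l in self.layers if isinstance(l, FortificationSpec)]
        dupes = {v for v in vehicles if vehicles.count(v) > 1}
        if dupes:
            raise BundleError(f"multiple fortification layers for vehicle(s) {sorted(dupes)}")


# ---------------------------------------------------------------------------
# Application operations

def apply_fortification(table: CompositionTable, spec: FortificationSpec) -> CompositionTable:
    """Return a copy of the table with the vehicle's composition augmented."""
    if spec.vehicle not in table:
        raise UnknownFoodError(f"fortification vehicle {spec.vehicle!r} not in table")
    item = table[spec.vehicle]
    fortified = FoodItem(
        food_id=item.food_id,
        name=item.name,
        state=item.state,
        composition=item.composition + spec.added_per_100g(),
        tags=item.tags,
    )
    return table.with_item(fortified)


def apply_biofortification(table: CompositionTable, spec: BiofortificationSpec) -> CompositionTable:
    """Return a copy of the table with the target's composition replaced."""
    if spec.target not in table:
        raise UnknownFoodError(f"biofortification target {spec.target!r} not in table")
    item = table[spec.target]
    replaced = FoodItem(
        food_id=item.food_id,
        name=item.name,
        state=item.state,
        composition=spec.replacement,
        tags=item.tags,
    )
    return table.with_item(replaced)


def apply_supplement(intake: NutrientVector, spec: SupplementSpec) -> NutrientVector:
    """Element-wise addition of supplement doses to a per-day intake."""
    if intake.basis != PER_DAY:
        raise ValidationError("supplement applies to a per-day intake vector")
    return intake + spec.doses


def _apply_swap(scenario: DietScenario, table: CompositionTable, swap: FoodSwapSpec) -> DietScenario:
    if swap.action == "add":
        if swap.food_id not in table:
            raise UnknownFoodError(f"swap food {swap.food_id!r} not in table")
        return add_food(scenario, swap.food_id, swap.grams)
    return substitute_food(scenario, swap.old_id, swap.new_id, table)


@dataclass(frozen=True)
class ComposeResult:
    """Resolved intake of a bundle plus per-layer marginal contributions."""

    total: NutrientVector
    base: NutrientVector
    contributions: Mapping[str, Mapping[str, float]]
    table: CompositionTable
    scenario: DietScenario


def compose_bundle(bundle: ScenarioBundle, table: CompositionTable) -> ComposeResult:
    """Resolve a bundle to a per-day intake.

    Layers apply in the fixed order biofortification -> fortification ->
    food swaps -> supplements (stable within each class).  The contribution
    of a layer is the intake difference it makes given all layers applied
    before it; contributions of additive layers sum to total - base.
    """
    ordered = sorted(bundle.layers, key=lambda l: _LAYER_ORDER[type(l)])
    scenario = bundle.base
    current_table = table
    supplements = NutrientVector.zero(PER_DAY)

    def intake() -> NutrientVector:
        return daily_intake(scenario, current_table, supplements=supplements)

    base = daily_intake(bundle.base, table)
    previous = intake()  # equals base: no layers applied yet
    contributions: dict[str, dict[str, float]] = {}
    for layer in ordered:
        if isinstance(layer, BiofortificationSpec):
            current_table = apply_biofortification(current_table, layer)
        elif isinstance(layer, FortificationSpec):
            current_table = apply_fortification(current_table, layer)
        elif isinstance(layer, FoodSwapSpec):
            scenario = _apply_swap(scenario, current_table, layer)
        else:
            supplements = supplements + layer.doses
        now = intake()
        label = layer_label(layer)
        i = 2
        while label in contributions:
            label = f"{layer_label(layer)}#{i}"
            i += 1
        contributions[label] = {
            n: now.get(n) - previous.get(n) for n in now.amounts
        }
        previous = now
    return ComposeResult(
        total=previous,
        base=base,
        contributions=MappingProxyType(contributions),
        table=current_table,
        scenario=scenario,
    )
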