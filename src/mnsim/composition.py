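"""Food composition data model, CSV I/O and nutrient-unit conversions.

Six micronutrients are tracked, each with a fixed canonical unit:
iron (mg), zinc (mg), vitamin A (µg RE), niacin (mg), folate (µg),
iodine (µg).  Food compositions are expressed per 100 g edible portion;
daily intakes use the same units per day.  The vitamin A converters
handle IU retinol, retinyl palmitate mass, β-carotene mass and preformed
RAE; iodate salts convert to elemental iodine by atomic-mass fractions.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import IO, Iterable, Mapping

__all__ = [
    "CompositionError",
    "ParseError",
    "ValidationError",
    "UnknownFoodError",
    "NUTRIENT_IDS",
    "NUTRIENT_UNITS",
    "PER_100G",
    "PER_DAY",
    "Nutrient",
    "NutrientVector",
    "FoodItem",
    "CompositionTable",
    "TableDialect",
    "DEFAULT_DIALECT",
    "CSV_COLUMNS",
    "read_composition_table",
    "write_composition_table",
    "VitaminAQuantity",
    "RETINOL_IU",
    "RETINYL_PALMITATE_MASS",
    "BETA_CAROTENE_MASS",
    "PREFORMED_RAE",
    "UG_RAE_PER_IU_RETINOL",
    "UG_RAE_PER_MG_RETINYL_PALMITATE",
    "DEFAULT_BETA_CAROTENE_RATIO",
    "to_ug_rae",
    "IODINE_MASS_FRACTION",
    "iodate_to_iodine",
    "parse_amount",
]


class CompositionError(ValueError):
    """Base class for composition-table and conversion failures."""


class ParseError(CompositionError):
    """Malformed input while reading a composition table."""


class ValidationError(CompositionError):
    """Semantically invalid value (negative amount, duplicate id, ...)."""


class UnknownFoodError(KeyError):
    """Lookup of a food_id that is not present in the table."""


# canonical units, fixed per nutrient id
NUTRIENT_UNITS: Mapping[str, str] = MappingProxyType(
    {
        "iron": "mg",
        "zinc": "mg",
        "vitamin_a": "ug_re",
        "niacin": "mg",
        "folate": "ug",
        "iodine": "ug",
    }
)
NUTRIENT_IDS: tuple[str, ...] = tuple(NUTRIENT_UNITS)

PER_100G = "per_100g"
PER_DAY = "per_day"
_BASES = (PER_100G, PER_DAY)


@dataclass(frozen=True)
class Nutrient:
    """A tracked micronutrient; the unit is attached to the id."""

    id: str

    def __post_init__(self) -> None:
        if self.id not in NUTRIENT_UNITS:
            raise ValidationError(f"unknown nutrient id {self.id!r}")

    @property
    def unit(self) -> str:
        return NUTRIENT_UNITS[self.id]


class NutrientVector:
    """Amounts of the six tracked nutrients on a stated basis.

    All amounts are non-negative; missing nutrients are zero.  Arithmetic
    never mixes bases: adding two vectors requires identical bases, and
    ``intake_for`` is the only way to move from per-100 g to per-day.
    """

    __slots__ = ("_amounts", "_basis")

    def __init__(self, amounts: Mapping[str, float] | None = None, *, basis: str) -> None:
        if basis not in _BASES:
            raise ValidationError(f"unknown basis {basis!r}; expected one of {_BASES}")
        clean = dict.fromkeys(NUTRIENT_IDS, 0.0)
        for nid, amount in (amounts or {}).items():
            if nid not in NUTRIENT_UNITS:
                raise ValidationError(f"unknown nutrient id {nid!r}")
            value = float(amount)
            if not math.isfinite(value):
                raise ValidationError(f"non-finite amount for {nid!r}: {amount!r}")
            if value < 0:
                raise ValidationError(f"negative amount for {nid!r}: {amount!r}")
            clean[nid] = value
        self._amounts: Mapping[str, float] = MappingProxyType(clean)
        self._basis = basis

    @classmethod
    def zero(cls, basis: str) -> "NutrientVector":
        return cls({}, basis=basis)

    @property
    def basis(self) -> str:
        return self._basis

    @property
    def amounts(self) -> Mapping[str, float]:
        return self._amounts

    def get(self, nutrient_id: str) -> float:
        if nutrient_id not in NUTRIENT_UNITS:
            raise ValidationError(f"unknown nutrient id {nutrient_id!r}")
        return self._amounts[nutrient_id]

    def __add__(self, other: "NutrientVector") -> "NutrientVector":
        if not isinstance(other, NutrientVector):
            return NotImplemented
        if other._basis != self._basis:
            raise ValidationError(
                f"cannot add vectors with mixed bases ({self._basis!r} + {other._basis!r})"
            )
        return NutrientVector(
            {n: self._amounts[n] + other._amounts[n] for n in NUTRIENT_IDS},
            basis=self._basis,
        )

    def scale(self, factor: float) -> "NutrientVector":
        if factor < 0:
            raise ValidationError("scale factor must be non-negative")
        return NutrientVector(
            {n: self._amounts[n] * factor for n in NUTRIENT_IDS}, basis=self._basis
        )

    def intake_for(self, grams: float) -> "NutrientVector":
        """Per-day intake contributed by ``grams`` of a per-100 g composition."""
        if self._basis != PER_100G:
            raise ValidationError("intake_for requires a per-100 g composition vector")
        if grams < 0:
            raise ValidationError("grams must be non-negative")
        return NutrientVector(
            {n: self._amounts[n] * grams / 100.0 for n in NUTRIENT_IDS}, basis=PER_DAY
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NutrientVector):
            return NotImplemented
        return self._basis == other._basis and dict(self._amounts) == dict(other._amounts)

    def __hash__(self) -> int:
        return hash((self._basis, tuple(self._amounts[n] for n in NUTRIENT_IDS)))

    def approx_equal(self, other: "NutrientVector", rel: float = 1e-9, abs_tol: float = 1e-9) -> bool:
        if self._basis != other._basis:
            return False
        return all(
            math.isclose(self._amounts[n], other._amounts[n], rel_tol=rel, abs_tol=abs_tol)
            for n in NUTRIENT_IDS
        )

    def __repr__(self) -> str:
        nonzero = {n: v for n, v in self._amounts.items() if v}
        return f"NutrientVector({nonzero!r}, basis={self._basis!r})"


_STATES = ("raw", "cooked")


@dataclass(frozen=True)
class FoodItem:
    """One food with its per-100 g composition."""

    food_id: str
    name: str
    state: str
    composition: NutrientVector
    tags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.food_id:
            raise ValidationError("food_id must be non-empty")
        if self.state not in _STATES:
            raise ValidationError(f"state must be one of {_STATES}, got {self.state!r}")
        if self.composition.basis != PER_100G:
            raise ValidationError("food composition must be on a per-100 g basis")
        object.__setattr__(self, "tags", frozenset(self.tags))


class CompositionTable:
    """Immutable map food_id -> FoodItem; interventions return modified copies."""

    def __init__(self, items: Iterable[FoodItem] = (), provenance: str = "") -> None:
        foods: dict[str, FoodItem] = {}
        for item in items:
            if item.food_id in foods:
                raise ValidationError(f"duplicate food_id {item.food_id!r}")
            foods[item.food_id] = item
        self._foods: Mapping[str, FoodItem] = MappingProxyType(foods)
        self.provenance = provenance

    def __getitem__(self, food_id: str) -> FoodItem:
        try:
            return self._foods[food_id]
        except KeyError:
            raise UnknownFoodError(f"unknown food_id {food_id!r}") from None

    def __contains__(self, food_id: str) -> bool:
        return food_id in self._foods

    def __iter__(self):
        return iter(self._foods.values())

    def __len__(self) -> int:
        return len(self._foods)

    @property
    def food_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self._foods))

    def with_item(self, item: FoodItem) -> "CompositionTable":
        """Return a copy with ``item`` added or replacing an existing entry."""
        foods = dict(self._foods)
        foods[item.food_id] = item
        return CompositionTable(foods.values(), provenance=self.provenance)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CompositionTable):
            return NotImplemented
        return dict(self._foods) == dict(other._foods)

    def __hash__(self) -> int:  # pragma: no cover - not used as a key
        return hash(tuple(sorted(self._foods)))


# ---------------------------------------------------------------------------
# CSV I/O

CSV_COLUMNS = (
    "food_id",
    "name",
    "state",
    "iron_mg",
    "zinc_mg",
    "vitamin_a_ug_re",
    "niacin_mg",
    "folate_ug",
    "iodine_ug",
    "tags",
)

_DEFAULT_NUTRIENT_COLUMNS: Mapping[str, str] = MappingProxyType(
    {
        "iron": "iron_mg",
        "zinc": "zinc_mg",
        "vitamin_a": "vitamin_a_ug_re",
        "niacin": "niacin_mg",
        "folate": "folate_ug",
        "iodine": "iodine_ug",
    }
)


@dataclass(frozen=True)
class TableDialect:
    """Column mapping for composition CSVs.

    ``nutrient_scale`` holds per-nutrient multiplicative factors applied on
    read to convert the column's unit to the canonical one (e.g. a column in
    mg for folate would use scale 1000).  Canonicalization is idempotent
    because scales live in the dialect, not the data.
    """

    food_id: str = "food_id"
    name: str = "name"
    state: str = "state"
    tags: str = "tags"
    nutrient_columns: Mapping[str, str] = field(default_factory=lambda: _DEFAULT_NUTRIENT_COLUMNS)
    nutrient_scale: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for nid in self.nutrient_columns:
            if nid not in NUTRIENT_UNITS:
                raise ValidationError(f"dialect maps unknown nutrient id {nid!r}")
        for nid, scale in self.nutrient_scale.items():
            if nid not in NUTRIENT_UNITS:
                raise ValidationError(f"dialect scales unknown nutrient id {nid!r}")
            if scale <= 0:
                raise ValidationError(f"non-positive scale for {nid!r}")


DEFAULT_DIALECT = TableDialect()


def parse_amount(text: str, *, row: int | None = None, column: str | None = None) -> float:
    """Parse a non-negative decimal, accepting comma decimal separators."""
    where = f" (row {row}, column {column!r})" if row is not None else ""
    raw = (text or "").strip().replace(",", ".")
    if raw == "":
        return 0.0
    try:
        value = float(raw)
    except ValueError:
        raise ParseError(f"cannot parse amount {text!r}{where}") from None
    if not math.isfinite(value):
        raise ParseError(f"non-finite amount {text!r}{where}")
    if value < 0:
        raise ValidationError(f"negative amount {text!r}{where}")
    return value


def read_composition_table(
    source: IO[str] | Iterable[str],
    dialect: TableDialect = DEFAULT_DIALECT,
    provenance: str = "",
) -> CompositionTable:
    """Read a composition CSV (header row required) into a table.

    Raises :class:`ParseError` with the offending row number on malformed
    input, and :class:`ValidationError` on negative amounts or duplicate ids.
    """
    reader = csv.DictReader(source)
    if reader.fieldnames is None:
        raise ParseError("empty input: missing header row")
    required = [dialect.food_id, *dialect.nutrient_columns.values()]
    missing = [c for c in required if c not in reader.fieldnames]
    if missing:
        raise ParseError(f"missing required columns: {missing}")

    items: list[FoodItem] = []
    seen: set[str] = set()
    for row in reader:
        rownum = reader.line_num
        if None in row or any(v is None for v in row.values()):
            raise ParseError(f"malformed CSV row {rownum}: wrong number of fields")
        food_id = (row.get(dialect.food_id) or "").strip()
        if not food_id:
            raise ParseError(f"missing food_id at row {rownum}")
        if food_id in seen:
            raise ValidationError(f"duplicate food_id {food_id!r} at row {rownum}")
        seen.add(food_id)
        amounts: dict[str, float] = {}
        for nid, col in dialect.nutrient_columns.items():
            value = parse_amount(row.get(col, ""), row=rownum, column=col)
            amounts[nid] = value * dialect.nutrient_scale.get(nid, 1.0)
        tags_raw = (row.get(dialect.tags) or "").strip()
        tags = frozenset(t for t in (p.strip() for p in tags_raw.split(";")) if t)
        items.append(
            FoodItem(
                food_id=food_id,
                name=(row.get(dialect.name) or food_id).strip(),
                state=(row.get(dialect.state) or "cooked").strip() or "cooked",
                composition=NutrientVector(amounts, basis=PER_100G),
                tags=tags,
            )
        )
    return CompositionTable(items, provenance=provenance)


def write_composition_table(table: CompositionTable, stream: IO[str]) -> None:
    """Write a table using the default column schema (companion of the reader)."""
    writer = csv.writer(stream, lineterminator="\n")
    writer.writerow(CSV_COLUMNS)
    for food_id in table.food_ids:
        item = table[food_id]
        comp = item.composition
        writer.writerow(
            [
                item.food_id,
                item.name,
                item.state,
                repr(comp.get("iron")),
                repr(comp.get("zinc")),
                repr(comp.get("vitamin_a")),
                repr(comp.get("niacin")),
                repr(comp.get("folate")),
                repr(comp.get("iodine")),
                ";".join(sorted(item.tags)),
            ]
        )


# ---------------------------------------------------------------------------
# Vitamin A conversions

RETINOL_IU = "retinol_iu"  # magnitude in IU
RETINYL_PALMITATE_MASS = "retinyl_palmitate_mass"  # magnitude in mg
BETA_CAROTENE_MASS = "beta_carotene_mass"  # magnitude in µg
PREFORMED_RAE = "preformed_rae"  # magnitude already in µg RAE
_VA_FORMS = (RETINOL_IU, RETINYL_PALMITATE_MASS, BETA_CAROTENE_MASS, PREFORMED_RAE)

UG_RAE_PER_IU_RETINOL = 0.3
UG_RAE_PER_MG_RETINYL_PALMITATE = 550.0
DEFAULT_BETA_CAROTENE_RATIO = 12.0  # µg β-carotene per µg RE; per-food configurable


@dataclass(frozen=True)
class VitaminAQuantity:
    """A vitamin A quantity in one of the supported forms."""

    form: str
    magnitude: float
    conversion_factor: float = DEFAULT_BETA_CAROTENE_RATIO

    def __post_init__(self) -> None:
        if self.form not in _VA_FORMS:
            raise ValidationError(f"unknown vitamin A form {self.form!r}")
        if self.magnitude < 0:
            raise ValidationError("vitamin A magnitude must be non-negative")
        if self.form == BETA_CAROTENE_MASS and self.conversion_factor <= 0:
            raise ValidationError("β-carotene conversion factor must be positive")


def to_ug_rae(
    q: VitaminAQuantity,
    *,
    iu_factor: float = UG_RAE_PER_IU_RETINOL,
    palmitate_factor: float = UG_RAE_PER_MG_RETINYL_PALMITATE,
) -> float:
    """Convert a vitamin A quantity to µg RAE.

    IU retinol × 0.3; retinyl palmitate mass (mg) × 550; β-carotene mass
    (µg) ÷ the per-food conversion factor; preformed RAE passes through.
    """
    if q.form == RETINOL_IU:
        return q.magnitude * iu_factor
    if q.form == RETINYL_PALMITATE_MASS:
        return q.magnitude * palmitate_factor
    if q.form == BETA_CAROTENE_MASS:
        return q.magnitude / q.conversion_factor
    if q.form == PREFORMED_RAE:
        return q.magnitude
    raise ValidationError(f"unknown vitamin A form {q.form!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# Iodate -> elemental iodine

_ATOMIC_MASS = {"K": 39.0983, "Na": 22.98977, "Ca": 40.078, "I": 126.90447, "O": 15.999}

IODINE_MASS_FRACTION: Mapping[str, float] = MappingProxyType(
    {
        "KIO3": _ATOMIC_MASS["I"]
        / (_ATOMIC_MASS["K"] + _ATOMIC_MASS["I"] + 3 * _ATOMIC_MASS["O"]),
        "NaIO3": _ATOMIC_MASS["I"]
        / (_ATOMIC_MASS["Na"] + _ATOMIC_MASS["I"] + 3 * _ATOMIC_MASS["O"]),
        "Ca_IO3_2": 2
        * _ATOMIC_MASS["I"]
        / (_ATOMIC_MASS["Ca"] + 2 * (_ATOMIC_MASS["I"] + 3 * _ATOMIC_MASS["O"])),
    }
)


def iodate_to_iodine(compound: str, mass_mg: float) -> float:
    """Elemental iodine (mg) delivered by ``mass_mg`` of an iodate salt."""
    if compound not in IODINE_MASS_FRACTION:
        raise ValidationError(
            f"unknown iodate compound {compound!r}; expected one of {sorted(IODINE_MASS_FRACTION)}"
        )
    if mass_mg < 0:
        raise ValidationError("iodate mass must be non-negative")
    return mass_mg * IODINE_MASS_FRACTION[compound]
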