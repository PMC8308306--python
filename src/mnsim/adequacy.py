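"""Reference-value registry and coverage/risk computation.

Percentages of EAR/RNI/UL are rounded half-away-from-zero to integers to
match reporting conventions; risk classification always uses the unrounded
intake.  The iodine UL can also be derived from a body-weight rule
(µg/kg/day × kg).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from types import MappingProxyType
from typing import IO, Iterable, Mapping

from .composition import (
    NUTRIENT_IDS,
    NUTRIENT_UNITS,
    PER_DAY,
    NutrientVector,
    ValidationError,
    parse_amount,
)
from .diet import PopulationGroup

__all__ = [
    "MissingReferenceError",
    "ReferenceValue",
    "ReferenceSet",
    "iodine_ul",
    "round_half_away",
    "NutrientCoverage",
    "CoverageResult",
    "coverage",
    "classify",
    "BELOW_EAR",
    "EAR_TO_RNI",
    "ADEQUATE",
    "ABOVE_UL",
    "WITHIN_UL",
    "NO_UL_ASSESSMENT",
    "REFERENCE_CSV_COLUMNS",
    "read_reference_csv",
    "write_reference_csv",
]


class MissingReferenceError(KeyError):
    """No reference value registered for a (nutrient, group) pair."""


BELOW_EAR = "below_EAR"
EAR_TO_RNI = "EAR_to_RNI"
ADEQUATE = "adequate"
ABOVE_UL = "above_UL"
WITHIN_UL = "within_UL"
NO_UL_ASSESSMENT = "no_UL_assessment"


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (e.g. 33.5 -> 34, -0.5 -> -1)."""
    if not math.isfinite(x):
        raise ValidationError(f"cannot round non-finite value {x!r}")
    quantum = Decimal(1).scaleb(-ndigits)
    result = float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))
    return result


@dataclass(frozen=True)
class ReferenceValue:
    """EAR/RNI/UL for one nutrient and population group, per day."""

    nutrient: str
    group: str
    ear: float
    rni: float
    ul: float | None = None
    bioavailability: str | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.nutrient not in NUTRIENT_UNITS:
            raise ValidationError(f"unknown nutrient id {self.nutrient!r}")
        if self.ear <= 0:
            raise ValidationError(f"{self.nutrient}/{self.group}: EAR must be positive")
        if self.rni <= 0:
            raise ValidationError(f"{self.nutrient}/{self.group}: RNI must be positive")
        if self.ul is not None and self.ul <= 0:
            raise ValidationError(f"{self.nutrient}/{self.group}: UL must be positive when present")


DEFAULT_IODINE_UL_RATES: Mapping[str, float] = MappingProxyType({"NPNL": 30.0, "PL": 40.0})


def iodine_ul(rate_ug_per_kg_day: float, body_weight_kg: float) -> float:
    """Iodine UL (µg/day) from a per-kg rate and an assumed body weight."""
    if rate_ug_per_kg_day <= 0:
        raise ValidationError("iodine UL rate must be positive")
    if body_weight_kg <= 0:
        raise ValidationError("body weight must be positive")
    return rate_ug_per_kg_day * body_weight_kg


class ReferenceSet:
    """Registry of reference values keyed by (nutrient, group)."""

    def __init__(
        self,
        values: Iterable[ReferenceValue],
        iodine_ul_rates: Mapping[str, float] = DEFAULT_IODINE_UL_RATES,
    ) -> None:
        table: dict[tuple[str, str], ReferenceValue] = {}
        for rv in values:
            key = (rv.nutrient, rv.group)
            if key in table:
                raise ValidationError(f"duplicate reference value for {key}")
            table[key] = rv
        self._table = MappingProxyType(table)
        self.iodine_ul_rates = MappingProxyType(dict(iodine_ul_rates))

    def get(self, nutrient: str, group: str) -> ReferenceValue:
        try:
            return self._table[(nutrient, group)]
        except KeyError:
            raise MissingReferenceError(
                f"no reference value for nutrient {nutrient!r}, group {group!r}"
            ) from None

    def values(self) -> tuple[ReferenceValue, ...]:
        return tuple(self._table[k] for k in sorted(self._table))

    def iodine_ul_for(self, group: PopulationGroup) -> float:
        """UL from the body-weight rule (may differ from the registered UL)."""
        try:
            rate = self.iodine_ul_rates[group.id]
        except KeyError:
            raise MissingReferenceError(f"no iodine UL rate for group {group.id!r}") from None
        return iodine_ul(rate, group.body_weight_kg)

    def require_complete(self, group: str) -> None:
        missing = [n for n in NUTRIENT_IDS if (n, group) not in self._table]
        if missing:
            raise MissingReferenceError(
                f"reference set incomplete for group {group!r}: missing {missing}"
            )


@dataclass(frozen=True)
class NutrientCoverage:
    """Coverage of one nutrient: intake, integer percentages and risk class."""

    nutrient: str
    intake: float
    pct_ear: int
    pct_rni: int
    pct_ul: int | None
    risk: str
    excess: str


@dataclass(frozen=True)
class CoverageResult:
    group: str
    per_nutrient: Mapping[str, NutrientCoverage]

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_nutrient", MappingProxyType(dict(self.per_nutrient)))


def _classify_one(intake: float, rv: ReferenceValue) -> tuple[str, str]:
    """(risk class, excess assessment) from unrounded intake and thresholds."""
    if rv.ul is not None and intake > rv.ul:
        risk = ABOVE_UL
    elif intake < rv.ear:
        risk = BELOW_EAR
    elif intake < rv.rni:
        risk = EAR_TO_RNI
    else:
        risk = ADEQUATE
    if rv.ul is None:
        excess = NO_UL_ASSESSMENT
    elif intake > rv.ul:
        excess = ABOVE_UL
    else:
        excess = WITHIN_UL
    return risk, excess


def coverage(intake: NutrientVector, refs: ReferenceSet, group: PopulationGroup) -> CoverageResult:
    """Percent coverage of EAR/RNI/UL and risk class for every nutrient."""
    if intake.basis != PER_DAY:
        raise ValidationError("coverage requires a per-day intake vector")
    refs.require_complete(group.id)
    out: dict[str, NutrientCoverage] = {}
    for nutrient in NUTRIENT_IDS:
        amount = intake.get(nutrient)
        rv = refs.get(nutrient, group.id)
        risk, excess = _classify_one(amount, rv)
        out[nutrient] = NutrientCoverage(
            nutrient=nutrient,
            intake=amount,
            pct_ear=int(round_half_away(100.0 * amount / rv.ear)),
            pct_rni=int(round_half_away(100.0 * amount / rv.rni)),
            pct_ul=None if rv.ul is None else int(round_half_away(100.0 * amount / rv.ul)),
            risk=risk,
            excess=excess,
        )
    return CoverageResult(group=group.id, per_nutrient=out)


def classify(result: CoverageResult) -> dict[str, str]:
    """Risk summary per nutrient from an existing coverage result."""
    return {nutrient: cov.risk for nutrient, cov in result.per_nutrient.items()}


# ---------------------------------------------------------------------------
# Reference-value CSV

REFERENCE_CSV_COLUMNS = ("nutrient", "group", "ear", "rni", "ul", "bioavailability", "source")


def read_reference_csv(stream: IO[str] | Iterable[str]) -> ReferenceSet:
    reader = csv.DictReader(stream)
    values = []
    for row in reader:
        ul_raw = (row.get("ul") or "").strip()
        values.append(
            ReferenceValue(
                nutrient=row["nutrient"].strip(),
                group=row["group"].strip(),
                ear=parse_amount(row["ear"], row=reader.line_num, column="ear"),
                rni=parse_amount(row["rni"], row=reader.line_num, column="rni"),
                ul=None if ul_raw == "" else parse_amount(ul_raw, row=reader.line_num, column="ul"),
                bioavailability=(row.get("bioavailability") or "").strip() or None,
                source=(row.get("source") or "").strip(),
            )
        )
    return ReferenceSet(values)


def write_reference_csv(refs: ReferenceSet, stream: IO[str]) -> None:
    writer = csv.writer(stream, lineterminator="\n")
    writer.writerow(REFERENCE_CSV_COLUMNS)
    for rv in refs.values():
        writer.writerow(
            [
                rv.nutrient,
                rv.group,
                repr(rv.ear),
                repr(rv.rni),
                "" if rv.ul is None else repr(rv.ul),
                rv.bioavailability or "",
                rv.source,
            ]
        )
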