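"""Coverage report rows and rendering to CSV, JSON or markdown.

Intakes are reported at one decimal place (half away from zero) and
percentages as integers; both are fixed when the row is built from a
coverage result, and the renderers only format — they never re-round.
Raw unrounded intakes are carried alongside (under ``raw`` in JSON) so
tests can check renderer fidelity.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass
from types import MappingProxyType
from typing import Iterable, Mapping

from .adequacy import ABOVE_UL, CoverageResult, round_half_away
from .composition import NUTRIENT_IDS, ValidationError

__all__ = [
    "ReportFormatError",
    "ReportCell",
    "ReportRow",
    "report_row",
    "render_report",
    "parse_report_json",
    "validate_report_payload",
    "REPORT_FORMATS",
]

REPORT_FORMATS = ("csv", "json", "markdown")


class ReportFormatError(ValueError):
    """Unknown output format or structurally invalid report payload."""


@dataclass(frozen=True)
class ReportCell:
    intake: float  # 1 decimal place
    raw_intake: float
    pct_ear: int
    pct_rni: int
    pct_ul: int | None
    risk: str
    excess: str


@dataclass(frozen=True)
class ReportRow:
    """One scenario's coverage over the six nutrients, in fixed column order."""

    label: str
    cells: Mapping[str, ReportCell]

    def __post_init__(self) -> None:
        missing = [n for n in NUTRIENT_IDS if n not in self.cells]
        if missing:
            raise ValidationError(f"report row {self.label!r} missing nutrients {missing}")
        object.__setattr__(self, "cells", MappingProxyType(dict(self.cells)))


def report_row(label: str, result: CoverageResult) -> ReportRow:
    """Build a report row from an adequacy coverage result."""
    cells = {}
    for nutrient in NUTRIENT_IDS:
        cov = result.per_nutrient[nutrient]
        cells[nutrient] = ReportCell(
            intake=round_half_away(cov.intake, 1),
            raw_intake=cov.intake,
            pct_ear=cov.pct_ear,
            pct_rni=cov.pct_rni,
            pct_ul=cov.pct_ul,
            risk=cov.risk,
            excess=cov.excess,
        )
    return ReportRow(label=label, cells=cells)


_CSV_HEADER = ("scenario", "nutrient", "intake", "pct_ear", "pct_rni", "pct_ul", "risk", "excess")


def _render_csv(rows: Iterable[ReportRow]) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(_CSV_HEADER)
    for row in rows:
        for nutrient in NUTRIENT_IDS:
            cell = row.cells[nutrient]
            writer.writerow(
                [
                    row.label,
                    nutrient,
                    repr(cell.intake),
                    cell.pct_ear,
                    cell.pct_rni,
                    "" if cell.pct_ul is None else cell.pct_ul,
                    cell.risk,
                    cell.excess,
                ]
            )
    return buf.getvalue()


def _payload(rows: Iterable[ReportRow]) -> dict:
    return {
        "format": "mnsim-report/1",
        "rows": [
            {
                "label": row.label,
                "nutrients": {
                    nutrient: {
                        "intake": row.cells[nutrient].intake,
                        "pct_ear": row.cells[nutrient].pct_ear,
                        "pct_rni": row.cells[nutrient].pct_rni,
                        "pct_ul": row.cells[nutrient].pct_ul,
                        "risk": row.cells[nutrient].risk,
                        "excess": row.cells[nutrient].excess,
                        "raw": {"intake": row.cells[nutrient].raw_intake},
                    }
                    for nutrient in NUTRIENT_IDS
                },
            }
            for row in rows
        ],
    }


def validate_report_payload(obj: object) -> None:
    """Structural validation of a JSON report payload."""
    if not isinstance(obj, dict) or obj.get("format") != "mnsim-report/1":
        raise ReportFormatError("not an mnsim report payload")
    rows = obj.get("rows")
    if not isinstance(rows, list):
        raise ReportFormatError("payload 'rows' must be a list")
    for row in rows:
        if not isinstance(row, dict) or "label" not in row:
            raise ReportFormatError("row missing label")
        nutrients = row.get("nutrients")
        if not isinstance(nutrients, dict):
            raise ReportFormatError("row missing nutrients mapping")
        for nutrient in NUTRIENT_IDS:
            cell = nutrients.get(nutrient)
            if not isinstance(cell, dict):
                raise ReportFormatError(f"row {row.get('label')!r} missing {nutrient}")
            for key in ("intake", "pct_ear", "pct_rni", "pct_ul", "risk", "excess", "raw"):
                if key not in cell:
                    raise ReportFormatError(f"cell {nutrient} missing field {key!r}")


def _render_json(rows: Iterable[ReportRow]) -> str:
    payload = _payload(rows)
    validate_report_payload(payload)
    return json.dumps(payload, indent=2, sort_keys=True, ensure_ascii=False) + "\n"


_MD_NUTRIENT_HEADER = {
    "iron": "Fe (mg)",
    "zinc": "Zn (mg)",
    "vitamin_a": "Vit. A (µg RE)",
    "niacin": "Niacin (mg)",
    "folate": "Folate (µg)",
    "iodine": "Iodine (µg)",
}


def _flag(cell: ReportCell) -> str:
    # stands in for the published tables' shading: recommendation or limit reached
    if cell.excess == ABOVE_UL:
        return "!UL"
    if cell.pct_rni >= 100:
        return "*"
    return ""


def _render_markdown(rows: Iterable[ReportRow]) -> str:
    lines = []
    header = ["Scenario", "Quantity", *[_MD_NUTRIENT_HEADER[n] for n in NUTRIENT_IDS]]
    lines.append("| " + " | ".join(header) + " |")
    lines.append("|" + "---|" * len(header))
    for row in rows:
        cells = [row.cells[n] for n in NUTRIENT_IDS]
        lines.append(
            "| " + " | ".join([row.label, "intake", *[repr(c.intake) for c in cells]]) + " |"
        )
        lines.append(
            "| " + " | ".join(["", "%EAR", *[str(c.pct_ear) for c in cells]]) + " |"
        )
        lines.append(
            "| " + " | ".join(["", "%RNI", *[str(c.pct_rni) for c in cells]]) + " |"
        )
        lines.append(
            "| "
            + " | ".join(
                ["", "%UL", *["" if c.pct_ul is None else str(c.pct_ul) for c in cells]]
            )
            + " |"
        )
        lines.append(
            "| " + " | ".join(["", "flag", *[_flag(c) for c in cells]]) + " |"
        )
    return "\n".join(lines) + "\n"


def render_report(rows: Iterable[ReportRow], fmt: str) -> str:
    """Render report rows deterministically in the requested format."""
    rows = list(rows)
    if fmt == "csv":
        return _render_csv(rows)
    if fmt == "json":
        return _render_json(rows)
    if fmt == "markdown":
        return _render_markdown(rows)
    raise ReportFormatError(f"unknown report format {fmt!r}; expected one of {REPORT_FORMATS}")


def parse_report_json(text: str) -> list[ReportRow]:
    """Parse a JSON report back into rows (inverse of the JSON renderer)."""
    payload = json.loads(text)
    validate_report_payload(payload)
    rows = []
    for row in payload["rows"]:
        cells = {}
        for nutrient in NUTRIENT_IDS:
            cell = row["nutrients"][nutrient]
            cells[nutrient] = ReportCell(
                intake=cell["intake"],
                raw_intake=cell["raw"]["intake"],
                pct_ear=cell["pct_ear"],
                pct_rni=cell["pct_rni"],
                pct_ul=cell["pct_ul"],
                risk=cell["risk"],
                excess=cell["excess"],
            )
        rows.append(ReportRow(label=row["label"], cells=cells))
    return rows
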