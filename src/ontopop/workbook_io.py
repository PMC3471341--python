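"""Template persistence: Excel workbooks, a TSV dialect, and workflows.

Workbooks carry the grid on a data sheet and the column validation sets
on a *hidden* worksheet — one record per allowed term holding the cell
range it validates, the term's full URI, its label and the source
ontology URI.  Native dropdown data-validations reference the hidden
ranges, so the workbook remains usable in ordinary spreadsheet tools and
re-imports with its constraints intact.

The TSV dialect (first row = column names, vertical-bar separators inside
cells) is the plain-text canonical surface; validations are supplied
externally when reading TSV.

A :class:`WorkflowConfig` bundles everything needed to re-run a
generation: ontology sources, per-column range specs, pattern script
texts, the variable → column map and the minting policy.  It round-trips
through a versioned YAML document.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import openpyxl
import yaml
from openpyxl.utils import get_column_letter
from openpyxl.worksheet.datavalidation import DataValidation

from .errors import ConfigurationError, UnsupportedVersionError, WorkbookFormatError
from .ontology_store import TermRef, ValidationSet, label_or_fragment
from .template_model import Cell, ColumnDef, Template, parse_cell

__all__ = [
    "WorkbookLayout",
    "WorkflowConfig",
    "write_workbook",
    "read_workbook",
    "write_tsv",
    "read_tsv",
    "save_workflow",
    "load_workflow",
]

HIDDEN_SHEET_NAME = "_ontology_validation"
WORKFLOW_VERSION = 1


@dataclass
class WorkbookLayout:
    data_sheet_name: str = "Template"
    hidden_sheet_name: str = HIDDEN_SHEET_NAME


# ---------------------------------------------------------------------------
# XLSX


def write_workbook(template: Template, path, layout: WorkbookLayout | None = None) -> None:
    """Write the template as an .xlsx workbook with validation dropdowns.

    The hidden sheet holds one row per validation-set member:
    ``(cell range, term URI, label, source ontology URI)``.
    """
    layout = layout or WorkbookLayout()
    wb = openpyxl.Workbook()
    data = wb.active
    data.title = layout.data_sheet_name
    hidden = wb.create_sheet(layout.hidden_sheet_name)
    hidden.sheet_state = "hidden"
    hidden.append(["range", "uri", "label", "source_ontology"])

    for ci, col in enumerate(template.columns, start=1):
        data.cell(row=1, column=ci, value=col.name)
    for ri, row in enumerate(template.rows, start=2):
        for ci, col in enumerate(template.columns, start=1):
            data.cell(row=ri, column=ci, value=row[col.name].normalized())

    n_data_rows = max(template.n_rows, 1)
    for ci, col in enumerate(template.columns, start=1):
        if col.validation is None:
            continue
        letter = get_column_letter(ci)
        cell_range = f"{letter}2:{letter}{n_data_rows + 1}"
        start = hidden.max_row + 1
        for member in col.validation.members:
            hidden.append([
                cell_range,
                member.iri,
                member.label or "",
                member.source_ontology or "",
            ])
        end = hidden.max_row
        if end >= start:
            dv = DataValidation(
                type="list",
                formula1=f"'{layout.hidden_sheet_name}'!$C${start}:$C${end}",
                allow_blank=True,
                showDropDown=False,
            )
            data.add_data_validation(dv)
            dv.add(cell_range)
    try:
        wb.save(path)
    except OSError as exc:
        raise OSError(f"cannot write workbook {path}: {exc}") from exc


def _range_column_letter(cell_range: str) -> str:
    first = cell_range.split(":", 1)[0]
    return "".join(ch for ch in first if ch.isalpha())


def read_workbook(path, identifier: str | None = None) -> Template:
    """Read a workbook back into a validated :class:`Template`.

    Validation sets are reconstructed from the hidden sheet and every cell
    is re-parsed against its column's set.  A bare spreadsheet (no hidden
    sheet) loads with no validations, so every non-empty token is unknown.
    Malformed hidden-sheet records are skipped with a warning.
    """
    try:
        wb = openpyxl.load_workbook(path, data_only=True)
    except Exception as exc:
        raise WorkbookFormatError(f"cannot read workbook {path}: {exc}") from exc

    hidden = wb[HIDDEN_SHEET_NAME] if HIDDEN_SHEET_NAME in wb.sheetnames else None
    data = None
    for name in wb.sheetnames:
        if name != HIDDEN_SHEET_NAME:
            data = wb[name]
            break
    if data is None:
        raise WorkbookFormatError(f"workbook {path} has no data sheet")

    validations: dict[str, list[TermRef]] = {}
    if hidden is not None:
        for i, row in enumerate(hidden.iter_rows(min_row=2, values_only=True), start=2):
            if row is None or all(v in (None, "") for v in row):
                continue
            cell_range, uri = (row + (None,) * 4)[:2]
            label, source = (row + (None,) * 4)[2:4]
            if not cell_range or not uri:
                warnings.warn(
                    f"skipping malformed validation record at hidden-sheet row {i}"
                )
                continue
            letter = _range_column_letter(str(cell_range))
            validations.setdefault(letter, []).append(
                TermRef(
                    iri=str(uri),
                    label=str(label) if label else None,
                    source_ontology=str(source) if source else None,
                )
            )

    header = next(data.iter_rows(min_row=1, max_row=1, values_only=True), ())
    columns: list[ColumnDef] = []
    for ci, name in enumerate(header, start=1):
        letter = get_column_letter(ci)
        col_name = str(name) if name not in (None, "") else letter
        vset = None
        if letter in validations:
            members = {t.iri: t for t in validations[letter]}
            vset = ValidationSet(members=tuple(members[i] for i in sorted(members)))
        columns.append(ColumnDef(name=col_name, validation=vset))

    rows: list[dict[str, Cell]] = []
    for raw_row in data.iter_rows(min_row=2, values_only=True):
        if raw_row is None or all(v in (None, "") for v in raw_row):
            continue
        record: dict[str, Cell] = {}
        for col, value in zip(columns, raw_row):
            record[col.name] = parse_cell(
                "" if value is None else str(value), col.validation
            )
        rows.append(record)
    return Template(
        columns=columns,
        rows=rows,
        identifier=identifier or Path(str(path)).stem,
    )


# ---------------------------------------------------------------------------
# TSV dialect


def write_tsv(template: Template, path) -> None:
    """Plain-text dialect: header row of column names, '|'-separated cells."""
    lines = ["\t".join(template.column_names)]
    for row in template.rows:
        lines.append("\t".join(row[c].normalized() for c in template.column_names))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_tsv(
    path,
    validations: Mapping[str, ValidationSet] | None = None,
    identifier: str | None = None,
    snapshot=None,
) -> Template:
    """Read the TSV dialect; *validations* maps column name → set."""
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.split("\n") if ln != ""]
    if not lines:
        raise WorkbookFormatError(f"empty TSV template {path}")
    names = lines[0].split("\t")
    validations = validations or {}
    columns = [ColumnDef(name=n, validation=validations.get(n)) for n in names]
    raw_rows = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        raw_rows.append({n: (cells[i] if i < len(cells) else "") for i, n in enumerate(names)})
    return Template.from_rows(
        columns, raw_rows,
        identifier=identifier or Path(str(path)).stem,
        snapshot=snapshot,
    )


# ---------------------------------------------------------------------------
# Workflow configuration


@dataclass
class WorkflowConfig:
    """Everything needed to re-run a template → ontology generation."""

    ontologies: list[dict] = field(default_factory=list)  # {path, dialect}
    prefixes: dict[str, str] = field(default_factory=dict)
    ranges: dict[str, dict] = field(default_factory=dict)
    # column name -> {ontology, root (CURIE), selector, relations: [..]}
    scripts: list[dict] = field(default_factory=list)  # {id, text}
    variable_map: dict[str, str] = field(default_factory=dict)  # ?var -> column
    minting: dict = field(default_factory=dict)
    # {namespace, prefix, width, next_index}
    ontology_iri: str = "http://purl.org/ontopop/generated"

    def validate(self) -> None:
        for var in self.variable_map:
            if not any(var in s.get("text", "") for s in self.scripts):
                raise ConfigurationError(
                    f"mapped variable {var} appears in no pattern script"
                )

    def to_dict(self) -> dict:
        return {
            "version": WORKFLOW_VERSION,
            "ontologies": self.ontologies,
            "prefixes": self.prefixes,
            "ranges": self.ranges,
            "scripts": self.scripts,
            "variable_map": self.variable_map,
            "minting": self.minting,
            "ontology_iri": self.ontology_iri,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "WorkflowConfig":
        version = data.get("version")
        if version != WORKFLOW_VERSION:
            raise UnsupportedVersionError(
                f"workflow version {version!r} not supported (expected {WORKFLOW_VERSION})"
            )
        return cls(
            ontologies=list(data.get("ontologies", [])),
            prefixes=dict(data.get("prefixes", {})),
            ranges={k: dict(v) for k, v in data.get("ranges", {}).items()},
            scripts=list(data.get("scripts", [])),
            variable_map=dict(data.get("variable_map", {})),
            minting=dict(data.get("minting", {})),
            ontology_iri=data.get("ontology_iri", "http://purl.org/ontopop/generated"),
        )


def save_workflow(config: WorkflowConfig, path) -> None:
    config.validate()
    Path(path).write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True, default_flow_style=False),
        encoding="utf-8",
    )


def load_workflow(path) -> WorkflowConfig:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"workflow file {path} is not a mapping document")
    config = WorkflowConfig.from_dict(data)
    config.validate()
    return config
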