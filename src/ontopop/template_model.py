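"""Tabular templates with per-column term validation.

A template is a grid in which each row describes one entity and each
column one relationship slot; column values are constrained to a
:class:`~ontopop.ontology_store.ValidationSet`.  Cells may carry several
values separated by a vertical bar — each token is validated on its own.
Tokens that resolve against the column's set are *resolved* (rendered
green in a spreadsheet UI); free-text tokens are *unknown* (red) and act
as placeholders for terms to be minted later.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .ontology_store import (
    OntologySnapshot,
    TermRef,
    ValidationSet,
    find_by_label,
    label_or_fragment,
    normalize_label,
)

__all__ = [
    "ColumnDef",
    "CellToken",
    "Cell",
    "Template",
    "ValidationReport",
    "parse_cell",
    "autocomplete",
    "validate_template",
]

SEPARATOR = "|"

RESOLVED = "resolved"
UNKNOWN = "unknown"
EMPTY = "empty"


@dataclass(frozen=True)
class ColumnDef:
    name: str
    validation: ValidationSet | None = None
    relation_hint: str | None = None


@dataclass(frozen=True)
class CellToken:
    """One value of a cell: the raw text plus its validation status."""

    raw: str
    status: str
    term: TermRef | None = None

    def __post_init__(self) -> None:
        if (self.status == RESOLVED) != (self.term is not None):
            raise ValueError("token status 'resolved' iff a term is attached")


@dataclass(frozen=True)
class Cell:
    tokens: tuple[CellToken, ...] = ()
    warnings: tuple[str, ...] = ()

    def normalized(self) -> str:
        """Canonical raw text: token raws re-joined with the separator.

        Literal separators inside a token are escaped back, so
        ``parse_cell(cell.normalized())`` reproduces the same tokens.
        """
        return SEPARATOR.join(t.raw.replace(SEPARATOR, "\\" + SEPARATOR)
                              for t in self.tokens)

    @property
    def status(self) -> str:
        if not self.tokens:
            return EMPTY
        if any(t.status == UNKNOWN for t in self.tokens):
            return UNKNOWN
        return RESOLVED


@dataclass
class Template:
    """Ordered columns plus row records (column name → :class:`Cell`)."""

    columns: list[ColumnDef]
    rows: list[dict[str, Cell]] = field(default_factory=list)
    identifier: str = "template"

    def __post_init__(self) -> None:
        names = [c.name for c in self.columns]
        if len(names) != len(set(names)):
            raise ValueError("column names must be unique")
        empty = Cell()
        for row in self.rows:
            for name in names:
                row.setdefault(name, empty)

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]

    def column(self, name: str) -> ColumnDef:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)

    def cell(self, row_index: int, column: str) -> Cell:
        """Cell at 1-based *row_index* (all user-facing indices are 1-based)."""
        return self.rows[row_index - 1][column]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @classmethod
    def from_rows(
        cls,
        columns: Sequence[ColumnDef],
        raw_rows: Iterable[Mapping[str, str]],
        identifier: str = "template",
        snapshot: OntologySnapshot | None = None,
    ) -> "Template":
        """Build a template from raw cell texts, parsing each against its
        column's validation set."""
        cols = list(columns)
        rows = []
        for raw in raw_rows:
            row = {}
            for col in cols:
                row[col.name] = parse_cell(
                    raw.get(col.name, ""), col.validation, snapshot=snapshot
                )
            rows.append(row)
        return cls(columns=cols, rows=rows, identifier=identifier)


# ---------------------------------------------------------------------------
# Cell parsing


def _split_values(raw: str) -> list[str]:
    """Split on unescaped '|'; a backslash escapes a literal separator."""
    pieces: list[str] = []
    buf: list[str] = []
    i = 0
    while i < len(raw):
        ch = raw[i]
        if ch == "\\" and i + 1 < len(raw) and raw[i + 1] == SEPARATOR:
            buf.append(SEPARATOR)
            i += 2
            continue
        if ch == SEPARATOR:
            pieces.append("".join(buf))
            buf = []
            i += 1
            continue
        buf.append(ch)
        i += 1
    pieces.append("".join(buf))
    return pieces


_CURIE_RE = re.compile(r"^[A-Za-z_][\w.-]*:\S+$")


def _resolve_token(
    piece: str,
    validation: ValidationSet | None,
    snapshot: OntologySnapshot | None,
) -> CellToken:
    if validation is not None:
        hits = find_by_label(piece, validation)
        if hits:
            return CellToken(raw=piece, status=RESOLVED, term=hits[0])
        for m in validation.members:
            if m.curie and m.curie == piece:
                return CellToken(raw=piece, status=RESOLVED, term=m)
        for m in validation.members:
            if m.iri == piece:
                return CellToken(raw=piece, status=RESOLVED, term=m)
    if snapshot is not None:
        if piece.startswith("http://") or piece.startswith("https://"):
            if piece in snapshot.terms:
                return CellToken(raw=piece, status=RESOLVED, term=snapshot.terms[piece])
        elif _CURIE_RE.match(piece):
            hit = snapshot.term_by_curie(piece)
            if hit is not None:
                return CellToken(raw=piece, status=RESOLVED, term=hit)
    return CellToken(raw=piece, status=UNKNOWN)


def parse_cell(
    raw: str,
    validation: ValidationSet | None = None,
    snapshot: OntologySnapshot | None = None,
) -> Cell:
    """Parse one raw cell text into validated tokens.

    The text is split on the vertical bar, each piece trimmed and resolved
    first by label, then by CURIE, then by full IRI against *validation*.
    Pieces that match nothing become ``unknown`` tokens — invalid content
    is data (a placeholder for a new term), never a failure.  Without a
    validation set a piece only resolves if it is the CURIE or IRI of a
    term in *snapshot*.
    """
    tokens: list[CellToken] = []
    warnings: list[str] = []
    seen: set[str] = set()
    for piece in _split_values(raw):
        piece = piece.strip()
        if not piece:
            continue
        token = _resolve_token(piece, validation, snapshot)
        key = normalize_label(piece)
        if key in seen:
            warnings.append(f"duplicate value {piece!r} in cell")
        seen.add(key)
        tokens.append(token)
    return Cell(tokens=tuple(tokens), warnings=tuple(warnings))


# ---------------------------------------------------------------------------
# Auto-completion


def autocomplete(prefix: str, validation: ValidationSet, limit: int = 10) -> list[str]:
    """Display texts matching *prefix* as a case-insensitive substring.

    Texts that start with the prefix rank before mere substring matches;
    ties break alphabetically, so the result order is deterministic.  An
    empty prefix matches every member.
    """
    if limit < 1:
        raise ValueError("limit must be >= 1")
    needle = normalize_label(prefix)
    scored = []
    for text in validation.display_texts():
        hay = normalize_label(text)
        if needle in hay:
            scored.append((0 if hay.startswith(needle) else 1, hay, text))
    scored.sort()
    out: list[str] = []
    for _, _, text in scored:
        if text not in out:
            out.append(text)
    return out[:limit]


# ---------------------------------------------------------------------------
# Whole-template validation


@dataclass(frozen=True)
class ColumnCounts:
    resolved: int = 0
    unknown: int = 0
    empty: int = 0

    @property
    def total(self) -> int:
        return self.resolved + self.unknown + self.empty


@dataclass
class ValidationReport:
    """Every red token plus per-column cell-status tallies."""

    template_identifier: str
    unknown_tokens: list[tuple[int, str, str]]  # (1-based row, column, raw)
    column_counts: dict[str, ColumnCounts]
    cell_warnings: list[tuple[int, str, str]] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.unknown_tokens

    def to_tsv(self) -> str:
        lines = ["row\tcolumn\traw\tstatus"]
        for row, col, raw in self.unknown_tokens:
            lines.append(f"{row}\t{col}\t{raw}\t{UNKNOWN}")
        return "\n".join(lines) + "\n"

    def summary(self) -> str:
        lines = [f"Template {self.template_identifier!r}:"]
        for col, counts in self.column_counts.items():
            lines.append(
                f"  column {col}: {counts.resolved} resolved, "
                f"{counts.unknown} unknown, {counts.empty} empty"
            )
        if self.unknown_tokens:
            lines.append(f"  {len(self.unknown_tokens)} unknown token(s):")
            for row, col, raw in self.unknown_tokens:
                lines.append(f"    row {row}, column {col}: {raw!r}")
        else:
            lines.append("  all tokens resolved")
        return "\n".join(lines)


def validate_template(template: Template) -> ValidationReport:
    """Tally token validity across the whole grid.

    Pure function of the template — repeated calls yield identical reports.
    A cell counts as *unknown* when any of its tokens is unknown, *empty*
    when it has no tokens, else *resolved*.
    """
    unknown: list[tuple[int, str, str]] = []
    warnings: list[tuple[int, str, str]] = []
    counts: dict[str, dict[str, int]] = {
        c.name: {RESOLVED: 0, UNKNOWN: 0, EMPTY: 0} for c in template.columns
    }
    for i, row in enumerate(template.rows, start=1):
        for col in template.column_names:
            cell = row[col]
            counts[col][cell.status] += 1
            for tok in cell.tokens:
                if tok.status == UNKNOWN:
                    unknown.append((i, col, tok.raw))
            for w in cell.warnings:
                warnings.append((i, col, w))
    return ValidationReport(
        template_identifier=template.identifier,
        unknown_tokens=unknown,
        column_counts={
            name: ColumnCounts(
                resolved=c[RESOLVED], unknown=c[UNKNOWN], empty=c[EMPTY]
            )
            for name, c in counts.items()
        },
        cell_warnings=warnings,
    )
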