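"""Variable-free (ground) class expressions and axioms.

This is the small OWL fragment the pattern expander produces: named
classes, existential restrictions (``prop some filler``) and intersections,
combined into SubClassOf / EquivalentTo axioms plus Declaration and label
AnnotationAssertion axioms for newly minted terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Union

from .ontology_store import TermRef, label_or_fragment

__all__ = [
    "GroundClass",
    "GroundSome",
    "GroundIntersection",
    "GroundExpr",
    "GroundAxiom",
    "ProvenanceTag",
    "intersection_of",
    "render_expr",
]


@dataclass(frozen=True)
class GroundClass:
    term: TermRef


@dataclass(frozen=True)
class GroundSome:
    prop: TermRef
    filler: "GroundExpr"


@dataclass(frozen=True)
class GroundIntersection:
    conjuncts: tuple["GroundExpr", ...]

    def __post_init__(self) -> None:
        if len(self.conjuncts) < 2:
            raise ValueError("intersection needs >= 2 conjuncts; use intersection_of")


GroundExpr = Union[GroundClass, GroundSome, GroundIntersection]


def intersection_of(exprs: Iterable[GroundExpr]) -> GroundExpr:
    """Conjunction with flattening and syntactic de-duplication.

    Nested intersections are flattened; duplicate conjuncts (identical
    AST) are dropped keeping the first occurrence.  A single surviving
    conjunct is returned unwrapped.
    """
    flat: list[GroundExpr] = []
    for e in exprs:
        if isinstance(e, GroundIntersection):
            flat.extend(e.conjuncts)
        else:
            flat.append(e)
    out: list[GroundExpr] = []
    for e in flat:
        if e not in out:
            out.append(e)
    if not out:
        raise ValueError("empty intersection")
    if len(out) == 1:
        return out[0]
    return GroundIntersection(conjuncts=tuple(out))


@dataclass(frozen=True)
class GroundAxiom:
    """One generated axiom.

    ``kind`` is SubClassOf / EquivalentTo for logical axioms, Declaration
    for minted-class declarations, AnnotationAssertion for their labels
    (then ``annotation`` carries the literal).
    """

    kind: str  # SubClassOf | EquivalentTo | Declaration | AnnotationAssertion
    subject: TermRef
    object: GroundExpr | None = None
    annotation: str | None = None

    KINDS = ("SubClassOf", "EquivalentTo", "Declaration", "AnnotationAssertion")
    LOGICAL = ("SubClassOf", "EquivalentTo")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown axiom kind {self.kind!r}")
        if self.kind in self.LOGICAL and self.object is None:
            raise ValueError(f"{self.kind} axiom requires an object expression")

    @property
    def is_logical(self) -> bool:
        return self.kind in self.LOGICAL


@dataclass(frozen=True)
class ProvenanceTag:
    """Where a generated axiom came from: template row × pattern script."""

    template_id: str
    row_index: int  # 1-based; 0 for axioms not tied to a single row
    script_id: str
    timestamp: str = "1970-01-01T00:00:00Z"


def term_text(term: TermRef) -> str:
    """CURIE if derivable, else IRI fragment — the Manchester rendering."""
    return term.curie or label_or_fragment(
        term if term.label is None else TermRef(iri=term.iri)
    )


def render_expr(expr: GroundExpr, parenthesize_restrictions: bool = False) -> str:
    """Manchester-syntax text for a ground class expression.

    Inside an intersection, restriction conjuncts are parenthesized:
    ``A and (p some B)``.
    """
    if isinstance(expr, GroundClass):
        return term_text(expr.term)
    if isinstance(expr, GroundSome):
        filler = render_expr(expr.filler)
        if isinstance(expr.filler, (GroundIntersection,)):
            filler = f"({filler})"
        text = f"{term_text(expr.prop)} some {filler}"
        return f"({text})" if parenthesize_restrictions else text
    parts = [render_expr(c, parenthesize_restrictions=True) for c in expr.conjuncts]
    return " and ".join(parts)
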