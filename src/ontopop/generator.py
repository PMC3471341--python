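"""Compile a populated template into a generated OWL ontology.

Per row: bind resolved cell tokens to pattern variables, mint IRIs for
unknown (free-text) tokens, expand every pattern script, and tag each
generated axiom with provenance (template id, row, script id, timestamp).
The result renders to Manchester syntax for review and serializes to
Turtle or RDF/XML through :mod:`rdflib`.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence, Union

import rdflib
from rdflib import OWL, RDF, RDFS, BNode, Literal, Namespace, URIRef

from .axioms import (
    GroundAxiom,
    GroundClass,
    GroundExpr,
    GroundIntersection,
    GroundSome,
    ProvenanceTag,
    render_expr,
    term_text,
)
from .errors import BindingError, ConfigurationError, MintOverflowError
from .ontology_store import (
    OntologySnapshot,
    PrefixMap,
    TermRef,
    normalize_label,
)
from .pattern_lang import PatternScript, Resolver, expand, input_variables
from .template_model import RESOLVED, Template, UNKNOWN

__all__ = [
    "UnknownTerm",
    "Binding",
    "MintPolicy",
    "MintRegistry",
    "GeneratedOntology",
    "RunReportEntry",
    "bind_row",
    "mint_unknown",
    "make_resolver",
    "generate",
    "render_manchester",
    "serialize_rdf",
    "axiom_multiset",
    "parse_generated",
]

#: Annotation namespace used for axiom provenance.
PROV = Namespace("http://purl.org/ontopop/provenance#")

FIXED_TIMESTAMP = "1970-01-01T00:00:00Z"


@dataclass(frozen=True)
class UnknownTerm:
    """Placeholder for a free-text token awaiting identifier minting."""

    raw: str


Binding = dict[str, list[Union[TermRef, UnknownTerm]]]


@dataclass
class MintPolicy:
    """How new identifiers are generated: ``namespace + PREFIX_NNNNNNN``.

    ``width`` is the zero-padded digit count; ``next_index`` the next
    counter value.  The exemplar policy (kupo namespace, width 7) mints
    IRIs like ``.../KUPO_0001028``.
    """

    namespace: str
    prefix: str
    width: int = 7
    next_index: int = 1

    def local_name(self, index: int) -> str:
        return f"{self.prefix.upper()}_{index:0{self.width}d}"


class MintRegistry:
    """Label → minted TermRef memory for one generation run.

    The same (whitespace/case-normalized) label always receives the same
    IRI within a run; distinct labels receive distinct IRIs.
    """

    def __init__(self, policy: MintPolicy, existing_iris: set[str] | None = None):
        # private copy: minting must not mutate the caller's policy, so a
        # workflow context can be re-run reproducibly
        self.policy = replace(policy)
        self.existing_iris = existing_iris or set()
        self.by_label: dict[str, TermRef] = {}
        self.minted: list[tuple[str, TermRef]] = []  # (label, term) in mint order

    def mint(self, label: str) -> TermRef:
        key = normalize_label(label)
        if key in self.by_label:
            return self.by_label[key]
        policy = self.policy
        while True:
            if policy.next_index >= 10 ** policy.width:
                raise MintOverflowError(
                    f"identifier counter exhausted at width {policy.width}"
                )
            local = policy.local_name(policy.next_index)
            iri = policy.namespace + local
            policy.next_index += 1
            if iri not in self.existing_iris:
                break
        term = TermRef(
            iri=iri,
            curie=f"{policy.prefix}:{local}",
            label=label,
            source_ontology=policy.namespace,
            is_minted=True,
        )
        self.existing_iris.add(iri)
        self.by_label[key] = term
        self.minted.append((label, term))
        return term


def bind_row(
    template: Template,
    row_index: int,
    column_map: Mapping[str, str],
) -> Binding:
    """Collect one row's values per pattern variable.

    *column_map* maps variable name → column name.  Resolved tokens carry
    their :class:`TermRef`; unknown tokens become :class:`UnknownTerm`
    placeholders for minting; empty cells give empty lists.  Row indices
    are 1-based.
    """
    if not 1 <= row_index <= template.n_rows:
        raise ConfigurationError(f"row {row_index} out of range 1..{template.n_rows}")
    missing = [c for c in column_map.values() if c not in template.column_names]
    if missing:
        raise ConfigurationError(f"column_map names missing columns: {missing}")
    binding: Binding = {}
    for var, col in column_map.items():
        cell = template.cell(row_index, col)
        values: list[Union[TermRef, UnknownTerm]] = []
        for tok in cell.tokens:
            if tok.status == RESOLVED:
                values.append(tok.term)
            elif tok.status == UNKNOWN:
                values.append(UnknownTerm(raw=tok.raw))
        binding[var] = values
    return binding


def mint_unknown(
    binding: Binding, policy: MintPolicy, registry: MintRegistry | None = None
) -> Binding:
    """Replace every placeholder with a freshly minted (or re-used) term.

    The *registry* carries the counter state and label memory; when None a
    fresh one is created from *policy* (single-shot use).
    """
    if registry is None:
        registry = MintRegistry(policy)
    out: Binding = {}
    for var, values in binding.items():
        out[var] = [
            registry.mint(v.raw) if isinstance(v, UnknownTerm) else v for v in values
        ]
    return out


# ---------------------------------------------------------------------------
# Name resolution for pattern expansion


def make_resolver(
    snapshot: OntologySnapshot,
    prefix_map: PrefixMap,
    default_namespace: str = "http://purl.org/ontopop/local#",
) -> Resolver:
    """Resolver for names appearing literally in pattern scripts.

    CURIEs expand through the prefix map (and pick up the snapshot's term
    when loaded); bare class names resolve by label against the snapshot
    (so ``cell`` finds the class labelled *cell*); bare property names
    resolve by fragment or label, else are synthesized under
    *default_namespace* so patterns may use relations that no loaded
    vocabulary declares.
    """

    def resolver(name: str, role: str) -> TermRef:
        if ":" in name:
            iri = prefix_map.expand(name)
            pool = snapshot.property_terms if role == "property" else snapshot.terms
            if iri in pool:
                return pool[iri]
            return TermRef(iri=iri, curie=name)
        if role == "class":
            hit = snapshot.term_by_label(name)
            if hit is not None:
                return hit
        else:
            for t in snapshot.property_terms.values():
                frag = t.iri.rsplit("#", 1)[-1].rsplit("/", 1)[-1]
                if frag == name or (t.label and normalize_label(t.label) == normalize_label(name)):
                    return t
        return TermRef(iri=default_namespace + name, label=name)

    return resolver


# ---------------------------------------------------------------------------
# Generation


@dataclass(frozen=True)
class RunReportEntry:
    row_index: int
    script_id: str
    axioms_emitted: int
    minted_labels: tuple[str, ...] = ()


@dataclass
class GeneratedOntology:
    """Ground axioms plus the minted-term registry and provenance tags."""

    ontology_iri: str
    prefix_map: PrefixMap
    axioms: list[tuple[GroundAxiom, ProvenanceTag]] = field(default_factory=list)
    minted_terms: list[tuple[str, TermRef]] = field(default_factory=list)
    run_report: list[RunReportEntry] = field(default_factory=list)

    @property
    def logical_axioms(self) -> list[GroundAxiom]:
        return [ax for ax, _ in self.axioms if ax.is_logical]

    def subjects_in_order(self) -> list[TermRef]:
        seen: dict[str, TermRef] = {}
        for ax, _ in self.axioms:
            seen.setdefault(ax.subject.iri, ax.subject)
        return list(seen.values())


def generate(
    template: Template,
    scripts: Sequence[PatternScript],
    column_map: Mapping[str, str],
    policy: MintPolicy,
    snapshot: OntologySnapshot,
    prefix_map: PrefixMap,
    ontology_iri: str = "http://purl.org/ontopop/generated",
    timestamp: str = FIXED_TIMESTAMP,
) -> GeneratedOntology:
    """Run every pattern script over every template row.

    The output is deterministic given the policy's starting counter: rows
    are processed top to bottom, scripts in the given order, and the
    axiom list is row-major.  Minted classes additionally receive a
    Declaration axiom and a label annotation at the row where they are
    first minted.  Rows contributing zero logical axioms are still
    recorded in the run report.
    """
    needed = set()
    for script in scripts:
        needed.update(input_variables(script))
    unmapped = sorted(needed - set(column_map))
    if unmapped:
        raise ConfigurationError(f"input variables without a column binding: {unmapped}")

    registry = MintRegistry(policy, existing_iris=set(snapshot.terms))
    resolver = make_resolver(snapshot, prefix_map)
    out = GeneratedOntology(ontology_iri=ontology_iri, prefix_map=prefix_map)

    for row_index in range(1, template.n_rows + 1):
        raw_binding = bind_row(template, row_index, column_map)
        minted_before = len(registry.minted)
        binding = mint_unknown(raw_binding, policy, registry)
        new_mints = registry.minted[minted_before:]
        for label, term in new_mints:
            tag = ProvenanceTag(
                template_id=template.identifier,
                row_index=row_index,
                script_id="minting",
                timestamp=timestamp,
            )
            out.axioms.append((GroundAxiom(kind="Declaration", subject=term), tag))
            out.axioms.append(
                (GroundAxiom(kind="AnnotationAssertion", subject=term, annotation=label), tag)
            )
        for script in scripts:
            row_values = {
                v: binding.get(v, []) for v in input_variables(script)
            }
            try:
                axioms = expand(script, row_values, resolver)
            except BindingError as exc:
                raise BindingError(exc.variable, row=row_index) from exc
            tag = ProvenanceTag(
                template_id=template.identifier,
                row_index=row_index,
                script_id=script.identifier,
                timestamp=timestamp,
            )
            out.axioms.extend((ax, tag) for ax in axioms)
            out.run_report.append(
                RunReportEntry(
                    row_index=row_index,
                    script_id=script.identifier,
                    axioms_emitted=len(axioms),
                    minted_labels=tuple(label for label, _ in new_mints),
                )
            )
    out.minted_terms = list(registry.minted)
    return out


# ---------------------------------------------------------------------------
# Manchester rendering


def render_manchester(ontology: GeneratedOntology) -> str:
    """Frame-per-class Manchester syntax text.

    One ``Class:`` frame per subject in first-generation order; within a
    frame, label annotations, then the ``EquivalentTo:`` block, then the
    ``SubClassOf:`` block with comma-separated entries.  Restriction
    conjuncts inside intersections are parenthesized (``A and (p some B)``).
    """
    lines: list[str] = []
    for prefix, ns in ontology.prefix_map.namespaces().items():
        lines.append(f"Prefix: {prefix}: <{ns}>")
    if lines:
        lines.append("")
    lines.append(f"Ontology: <{ontology.ontology_iri}>")
    lines.append("")

    by_subject: dict[str, dict[str, list]] = {}
    order: list[TermRef] = []
    for ax, _tag in ontology.axioms:
        slot = by_subject.get(ax.subject.iri)
        if slot is None:
            slot = {"EquivalentTo": [], "SubClassOf": [], "labels": []}
            by_subject[ax.subject.iri] = slot
            order.append(ax.subject)
        if ax.kind == "AnnotationAssertion":
            slot["labels"].append(ax.annotation)
        elif ax.kind in ("EquivalentTo", "SubClassOf"):
            rendered = render_expr(ax.object)
            if isinstance(ax.object, GroundIntersection):
                # already conjunct-rendered with parenthesized restrictions
                pass
            elif isinstance(ax.object, GroundSome):
                rendered = render_expr(ax.object)
            if rendered not in slot[ax.kind]:
                slot[ax.kind].append(rendered)

    for subject in order:
        slot = by_subject[subject.iri]
        lines.append(f"Class: {term_text(subject)}")
        lines.append("")
        for label in slot["labels"]:
            lines.append(f"    Annotations: rdfs:label \"{label}\"")
            lines.append("")
        if slot["EquivalentTo"]:
            lines.append("    EquivalentTo:")
            for i, entry in enumerate(slot["EquivalentTo"]):
                comma = "," if i < len(slot["EquivalentTo"]) - 1 else ""
                lines.append(f"        {entry}{comma}")
            lines.append("")
        if slot["SubClassOf"]:
            lines.append("    SubClassOf:")
            for i, entry in enumerate(slot["SubClassOf"]):
                comma = "," if i < len(slot["SubClassOf"]) - 1 else ""
                lines.append(f"        {entry}{comma}")
            lines.append("")
    return "\n".join(lines).rstrip() + "\n"


# ---------------------------------------------------------------------------
# RDF serialization and parse-back


def _make_list(g: rdflib.Graph, members) -> BNode:
    """Well-formed rdf:first/rdf:rest chain (built by hand for reliability)."""
    head = RDF.nil
    for member in reversed(members):
        cell = BNode()
        g.add((cell, RDF.first, member))
        g.add((cell, RDF.rest, head))
        head = cell
    return head


def _read_list(g: rdflib.Graph, head) -> list:
    items = []
    while head is not None and head != RDF.nil:
        items.append(g.value(head, RDF.first))
        head = g.value(head, RDF.rest)
    return items


def _expr_node(g: rdflib.Graph, expr: GroundExpr):
    if isinstance(expr, GroundClass):
        return URIRef(expr.term.iri)
    if isinstance(expr, GroundSome):
        node = BNode()
        g.add((node, RDF.type, OWL.Restriction))
        g.add((node, OWL.onProperty, URIRef(expr.prop.iri)))
        g.add((node, OWL.someValuesFrom, _expr_node(g, expr.filler)))
        return node
    node = BNode()
    g.add((node, RDF.type, OWL.Class))
    members = [_expr_node(g, c) for c in expr.conjuncts]
    g.add((node, OWL.intersectionOf, _make_list(g, members)))
    return node


def serialize_rdf(ontology: GeneratedOntology, format: str = "turtle") -> str:
    """Standard OWL-in-RDF mapping of the generated ontology.

    SubClassOf axioms become ``rdfs:subClassOf`` triples (restrictions as
    blank-node ``owl:Restriction``); EquivalentTo becomes
    ``owl:equivalentClass`` with an ``owl:intersectionOf`` list; provenance
    tags ride on ``owl:Axiom`` annotation bundles.
    """
    if format not in ("turtle", "rdfxml"):
        raise ValueError(f"unknown RDF format {format!r}")
    g = rdflib.Graph()
    for prefix, ns in ontology.prefix_map.namespaces().items():
        g.bind(prefix, Namespace(ns))
    g.bind("ontopop-prov", PROV)
    onto = URIRef(ontology.ontology_iri)
    g.add((onto, RDF.type, OWL.Ontology))

    declared: set[str] = set()

    def declare_class(term: TermRef) -> None:
        if term.iri not in declared:
            g.add((URIRef(term.iri), RDF.type, OWL.Class))
            declared.add(term.iri)

    def declare_expr_terms(expr: GroundExpr) -> None:
        if isinstance(expr, GroundClass):
            declare_class(expr.term)
        elif isinstance(expr, GroundSome):
            g.add((URIRef(expr.prop.iri), RDF.type, OWL.ObjectProperty))
            declare_expr_terms(expr.filler)
        else:
            for c in expr.conjuncts:
                declare_expr_terms(c)

    for ax, tag in ontology.axioms:
        subj = URIRef(ax.subject.iri)
        if ax.kind == "Declaration":
            declare_class(ax.subject)
            continue
        if ax.kind == "AnnotationAssertion":
            g.add((subj, RDFS.label, Literal(ax.annotation)))
            continue
        declare_class(ax.subject)
        declare_expr_terms(ax.object)
        obj_node = _expr_node(g, ax.object)
        pred = RDFS.subClassOf if ax.kind == "SubClassOf" else OWL.equivalentClass
        g.add((subj, pred, obj_node))
        ann = BNode()
        g.add((ann, RDF.type, OWL.Axiom))
        g.add((ann, OWL.annotatedSource, subj))
        g.add((ann, OWL.annotatedProperty, pred))
        g.add((ann, OWL.annotatedTarget, obj_node))
        g.add((ann, PROV.templateId, Literal(tag.template_id)))
        g.add((ann, PROV.rowIndex, Literal(tag.row_index)))
        g.add((ann, PROV.scriptId, Literal(tag.script_id)))
        g.add((ann, PROV.generatedAt, Literal(tag.timestamp)))

    text = g.serialize(format="turtle" if format == "turtle" else "xml")
    if format == "turtle" and not _reparses_isomorphic(g, text):
        # rdflib's Turtle pretty-printer can occasionally detach list cells
        # holding nested blank nodes; fall back to the N-Triples subset of
        # Turtle, which serializes every triple explicitly.
        text = g.serialize(format="nt")
    return text


def _reparses_isomorphic(g: rdflib.Graph, text: str) -> bool:
    from rdflib.compare import to_isomorphic

    check = rdflib.Graph()
    try:
        check.parse(data=text, format="turtle")
    except Exception:
        return False
    return to_isomorphic(check) == to_isomorphic(g)


def _parse_expr(g: rdflib.Graph, node) -> tuple:
    """Canonical tuple form of an expression node in a parsed graph."""
    if isinstance(node, URIRef):
        return ("class", str(node))
    if (node, RDF.type, OWL.Restriction) in g:
        prop = g.value(node, OWL.onProperty)
        filler = g.value(node, OWL.someValuesFrom)
        return ("some", str(prop), _parse_expr(g, filler))
    list_node = g.value(node, OWL.intersectionOf)
    if list_node is not None:
        items = [_parse_expr(g, m) for m in _read_list(g, list_node)]
        return ("and", tuple(items))
    return ("class", str(node))


def _canonical_expr(expr: GroundExpr) -> tuple:
    if isinstance(expr, GroundClass):
        return ("class", expr.term.iri)
    if isinstance(expr, GroundSome):
        return ("some", expr.prop.iri, _canonical_expr(expr.filler))
    return ("and", tuple(_canonical_expr(c) for c in expr.conjuncts))


def axiom_multiset(ontology: GeneratedOntology) -> Counter:
    """Multiset of canonicalized axioms — the round-trip comparison key."""
    counter: Counter = Counter()
    for ax, _ in ontology.axioms:
        if ax.kind == "Declaration":
            counter[("Declaration", ax.subject.iri)] += 1
        elif ax.kind == "AnnotationAssertion":
            counter[("AnnotationAssertion", ax.subject.iri, ax.annotation)] += 1
        else:
            counter[(ax.kind, ax.subject.iri, _canonical_expr(ax.object))] += 1
    return counter


def parse_generated(document: str, format: str = "turtle") -> Counter:
    """Re-parse a serialized generated ontology into an axiom multiset.

    Covers logical axioms and label annotations; class declarations are
    not compared because the RDF mapping necessarily declares every named
    class an expression mentions.
    """
    g = rdflib.Graph()
    g.parse(data=document, format="turtle" if format == "turtle" else "xml")
    counter: Counter = Counter()
    for pred, kind in ((RDFS.subClassOf, "SubClassOf"), (OWL.equivalentClass, "EquivalentTo")):
        for s, o in g.subject_objects(pred):
            if not isinstance(s, URIRef):
                continue
            counter[(kind, str(s), _parse_expr(g, o))] += 1
    for s, o in g.subject_objects(RDFS.label):
        if isinstance(s, URIRef):
            counter[("AnnotationAssertion", str(s), str(o))] += 1
    return counter


def roundtrip_multisets(ontology: GeneratedOntology, format: str = "turtle") -> tuple[Counter, Counter]:
    """(original, reparsed) logical+annotation axiom multisets.

    Declaration axioms are compared only for minted subjects, because the
    RDF mapping necessarily declares every class an expression mentions.
    """
    original = Counter(
        {k: v for k, v in axiom_multiset(ontology).items() if k[0] != "Declaration"}
    )
    reparsed = Counter(
        {k: v for k, v in parse_generated(serialize_rdf(ontology, format), format).items()
         if k[0] != "Declaration" and v > 0}
    )
    return original, reparsed
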