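"""Indexed vocabulary snapshots and term validation sets.

Source vocabularies (OBO flat files, OWL as Turtle or RDF/XML) are loaded
into an :class:`OntologySnapshot`: a flat term table plus the asserted
``is_a``/``subClassOf``, ``part_of`` and instance edges.  No reasoning is
performed — range resolution works over the told hierarchy only, which is
sufficient for template validation (classification of the generated
ontology is a downstream, editor-side concern).

A :class:`RangeSpec` (root term + selector) is resolved against a snapshot
into a :class:`ValidationSet`, the ordered set of terms permitted in a
template column — e.g. *all subclasses of* ``nucleation``, or *subclasses
or parts of* the urinary system.
"""

from __future__ import annotations

import io
import re
import warnings
from collections import deque
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import obonet
import rdflib
from rdflib import OWL, RDF, RDFS

from .errors import DialectError, UnknownDialectError, UnknownTermError

__all__ = [
    "TermRef",
    "PrefixMap",
    "OntologySnapshot",
    "RangeSpec",
    "ValidationSet",
    "load_ontology",
    "resolve_range",
    "label_or_fragment",
    "find_by_label",
    "normalize_label",
    "Selector",
    "WHOLE_ONTOLOGY",
]

#: Sentinel RangeSpec root meaning "every class of the ontology".
WHOLE_ONTOLOGY = None


class Selector:
    """The four term-range selectors offered for column validation."""

    ALL_SUBCLASSES = "all-subclasses"
    DIRECT_SUBCLASSES = "direct-subclasses"
    ALL_INDIVIDUALS = "all-individuals"
    DIRECT_INDIVIDUALS = "direct-individuals"

    ALL = (ALL_SUBCLASSES, DIRECT_SUBCLASSES, ALL_INDIVIDUALS, DIRECT_INDIVIDUALS)


@dataclass(frozen=True)
class TermRef:
    """A single ontology term: IRI plus presentation/provenance metadata.

    ``curie`` is the compact form (``pato:PATO_0001407``) derived through a
    :class:`PrefixMap`; ``is_minted`` marks identifiers generated for terms
    unknown to every loaded vocabulary.
    """

    iri: str
    curie: str | None = None
    label: str | None = None
    source_ontology: str | None = None
    is_minted: bool = False

    def __post_init__(self) -> None:
        if not self.iri:
            raise ValueError("TermRef.iri must be non-empty")


def _iri_fragment(iri: str) -> str:
    if "#" in iri:
        return iri.rsplit("#", 1)[1]
    return iri.rstrip("/").rsplit("/", 1)[-1]


def label_or_fragment(term: TermRef) -> str:
    """Display text for a term: its label, else the IRI fragment."""
    if term.label:
        return term.label
    return _iri_fragment(term.iri)


_WS = re.compile(r"\s+")


def normalize_label(text: str) -> str:
    """Case-insensitive, internal-whitespace-collapsed comparison key."""
    return _WS.sub(" ", text.strip()).casefold()


class PrefixMap:
    """Ordered prefix-label → namespace mapping for CURIE round-tripping.

    Contraction picks the longest matching namespace, so nested namespaces
    behave predictably.  ``expand(contract(iri)) == iri`` whenever the IRI
    falls under a bound namespace.
    """

    def __init__(self, bindings: Mapping[str, str] | None = None):
        self._ns: dict[str, str] = {}
        if bindings:
            for prefix, namespace in bindings.items():
                self.bind(prefix, namespace)

    def bind(self, prefix: str, namespace: str) -> None:
        if not namespace:
            raise ValueError(f"prefix {prefix!r} maps to an empty namespace")
        self._ns[prefix] = namespace

    def namespaces(self) -> dict[str, str]:
        return dict(self._ns)

    def expand(self, curie: str) -> str:
        prefix, _, local = curie.partition(":")
        if prefix in self._ns:
            return self._ns[prefix] + local
        raise KeyError(f"unknown prefix {prefix!r} in CURIE {curie!r}")

    def contract(self, iri: str) -> str | None:
        """The CURIE for *iri*, or None when no namespace matches."""
        best: tuple[int, str, str] | None = None
        for prefix, namespace in self._ns.items():
            if iri.startswith(namespace) and len(iri) > len(namespace):
                if best is None or len(namespace) > best[0]:
                    best = (len(namespace), prefix, iri[len(namespace):])
        if best is None:
            return None
        return f"{best[1]}:{best[2]}"

    def copy(self) -> "PrefixMap":
        return PrefixMap(self._ns)


@dataclass
class OntologySnapshot:
    """Asserted-edge view of one loaded vocabulary.

    ``terms`` maps IRI → :class:`TermRef` for classes and individuals;
    object properties live in ``property_terms``.  Edge sets hold
    (child IRI, parent IRI) pairs for ``is_a``/``subClassOf``, (part, whole)
    for ``part_of``, and (individual, class) for instantiation.  Other OBO
    relationship types are indexed in ``other_edges`` but never traversed.
    """

    ontology_iri: str
    terms: dict[str, TermRef] = field(default_factory=dict)
    subclass_edges: set[tuple[str, str]] = field(default_factory=set)
    instance_edges: set[tuple[str, str]] = field(default_factory=set)
    partof_edges: set[tuple[str, str]] = field(default_factory=set)
    property_terms: dict[str, TermRef] = field(default_factory=dict)
    individual_iris: set[str] = field(default_factory=set)
    other_edges: set[tuple[str, str, str]] = field(default_factory=set)

    def term(self, iri: str) -> TermRef:
        if iri in self.terms:
            return self.terms[iri]
        if iri in self.property_terms:
            return self.property_terms[iri]
        raise UnknownTermError(iri)

    def term_by_curie(self, curie: str) -> TermRef | None:
        for pool in (self.terms, self.property_terms):
            for t in pool.values():
                if t.curie == curie:
                    return t
        return None

    def term_by_label(self, text: str) -> TermRef | None:
        key = normalize_label(text)
        for t in self.terms.values():
            if normalize_label(label_or_fragment(t)) == key:
                return t
        return None

    def sorted_iris(self) -> list[str]:
        return sorted(self.terms) + sorted(self.property_terms)


@dataclass(frozen=True)
class RangeSpec:
    """Which slice of an ontology a column may draw its values from."""

    source_ontology: str
    root: TermRef | None
    selector: str = Selector.ALL_SUBCLASSES
    traversal_relations: frozenset[str] = frozenset({"subclass"})
    include_root: bool = False

    def __post_init__(self) -> None:
        if self.selector not in Selector.ALL:
            raise ValueError(f"unknown selector {self.selector!r}")
        if self.selector == Selector.ALL_SUBCLASSES and not self.traversal_relations:
            raise ValueError("all-subclasses requires at least one traversal relation")
        bad = set(self.traversal_relations) - {"subclass", "part-of"}
        if bad:
            raise ValueError(f"unknown traversal relations: {sorted(bad)}")


@dataclass(frozen=True)
class ValidationSet:
    """The resolved, deterministically ordered allowed-term set."""

    members: tuple[TermRef, ...]
    spec: RangeSpec | None = None

    def __post_init__(self) -> None:
        iris = [m.iri for m in self.members]
        if len(iris) != len(set(iris)):
            raise ValueError("ValidationSet members contain duplicate IRIs")

    def __iter__(self):
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def display_texts(self) -> list[str]:
        return [label_or_fragment(m) for m in self.members]


# ---------------------------------------------------------------------------
# Loading


#: Default OBO idspace → (prefix label, namespace) mapping.  The spec of an
#: OBO id ``GO:0003093`` is one idspace + local number; the OWL-style IRI is
#: namespace + ``GO_0003093``.
DEFAULT_IDSPACE_MAP: dict[str, tuple[str, str]] = {
    "GO": ("gene_ontology", "http://purl.org/obo/owl/GO#"),
    "PATO": ("pato", "http://purl.org/obo/owl/PATO#"),
    "MA": ("MA", "http://purl.org/obo/owl/MA#"),
    "CL": ("cto", "http://purl.org/obo/owl/CTO#"),
    "KUPO": ("kupo", "http://purl.org/kup/kupo#"),
}

_PARTOF_LOCALS = {"part_of", "BFO_0000050"}


def _is_partof_property(iri: str) -> bool:
    return _iri_fragment(iri) in _PARTOF_LOCALS


def load_ontology(
    source,
    dialect: str,
    prefix_map: PrefixMap | None = None,
    idspace_map: Mapping[str, tuple[str, str]] | None = None,
) -> OntologySnapshot:
    """Parse one vocabulary document into an :class:`OntologySnapshot`.

    Parameters
    ----------
    source
        Path, text, or binary/text stream holding the document.
    dialect
        ``obo``, ``turtle`` or ``rdfxml`` (RDFS inputs go through the
        RDF paths; only ``rdfs:subClassOf`` is then populated).
    prefix_map
        Used to derive CURIEs for loaded terms (RDF dialects).
    idspace_map
        OBO idspace → (prefix, namespace); defaults cover the bundled
        miniature vocabularies.
    """
    if dialect == "obo":
        return _load_obo(source, idspace_map or DEFAULT_IDSPACE_MAP)
    if dialect in ("turtle", "rdfxml"):
        return _load_rdf(source, "turtle" if dialect == "turtle" else "xml", prefix_map)
    raise UnknownDialectError(f"unknown ontology dialect {dialect!r}")


def _as_text_stream(source) -> io.TextIOBase:
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        return open(source, "r", encoding="utf-8")
    if isinstance(source, str):
        return io.StringIO(source)
    if isinstance(source, bytes):
        return io.StringIO(source.decode("utf-8"))
    if isinstance(source, io.TextIOBase):
        return source
    return io.TextIOWrapper(source, encoding="utf-8")


def _load_obo(source, idspace_map: Mapping[str, tuple[str, str]]) -> OntologySnapshot:
    stream = _as_text_stream(source)
    try:
        graph = obonet.read_obo(stream, ignore_obsolete=True)
    except Exception as exc:  # obonet raises ValueError with term context
        raise DialectError(f"OBO parse failure: {exc}") from exc

    def to_iri(obo_id: str) -> tuple[str, str | None]:
        idspace, _, local = obo_id.partition(":")
        if not local:  # unprefixed id (e.g. a bare typedef id)
            return f"http://purl.org/obo/owl/_#{obo_id}", None
        prefix, namespace = idspace_map.get(
            idspace, (idspace.lower(), f"http://purl.org/obo/owl/{idspace}#")
        )
        local_name = f"{idspace}_{local}"
        return namespace + local_name, f"{prefix}:{local_name}"

    name = graph.graph.get("ontology") or graph.graph.get("name") or "obo"
    ontology_iri = f"http://purl.org/obo/owl/{name}"
    snap = OntologySnapshot(ontology_iri=ontology_iri)

    for node, data in graph.nodes(data=True):
        iri, curie = to_iri(node)
        snap.terms[iri] = TermRef(
            iri=iri, curie=curie, label=data.get("name"), source_ontology=ontology_iri
        )
    for child, parent, key in graph.edges(keys=True):
        child_iri, _ = to_iri(child)
        parent_iri, _ = to_iri(parent)
        if key == "is_a":
            snap.subclass_edges.add((child_iri, parent_iri))
        elif key == "part_of":
            snap.partof_edges.add((child_iri, parent_iri))
        else:
            snap.other_edges.add((child_iri, key, parent_iri))
    for typedef in graph.graph.get("typedefs", []):
        tid = typedef.get("id")
        if not tid:
            continue
        iri, curie = to_iri(tid)
        snap.property_terms[iri] = TermRef(
            iri=iri, curie=curie, label=typedef.get("name"), source_ontology=ontology_iri
        )
    for inst in graph.graph.get("instances", []):
        iid = inst.get("id")
        if not iid:
            continue
        iri, curie = to_iri(iid)
        snap.terms[iri] = TermRef(
            iri=iri, curie=curie, label=inst.get("name"), source_ontology=ontology_iri
        )
        snap.individual_iris.add(iri)
        for cls in inst.get("instance_of", []):
            cls_iri, _ = to_iri(cls)
            snap.instance_edges.add((iri, cls_iri))
    return snap


def _load_rdf(source, rdf_format: str, prefix_map: PrefixMap | None) -> OntologySnapshot:
    g = rdflib.Graph()
    try:
        if isinstance(source, (str, Path)) and "\n" not in str(source):
            g.parse(str(source), format=rdf_format)
        elif isinstance(source, str):
            g.parse(data=source, format=rdf_format)
        elif isinstance(source, bytes):
            g.parse(data=source, format=rdf_format)
        else:
            g.parse(file=source, format=rdf_format)
    except Exception as exc:
        raise DialectError(f"RDF parse failure ({rdf_format}): {exc}") from exc

    ontology_iri = ""
    for s in g.subjects(RDF.type, OWL.Ontology):
        ontology_iri = str(s)
        break

    snap = OntologySnapshot(ontology_iri=ontology_iri)

    def curie_of(iri: str) -> str | None:
        return prefix_map.contract(iri) if prefix_map else None

    def label_of(node) -> str | None:
        for lab in g.objects(node, RDFS.label):
            return str(lab)
        return None

    def add_term(node, individual: bool = False) -> None:
        if not isinstance(node, rdflib.URIRef):
            return
        iri = str(node)
        snap.terms.setdefault(
            iri,
            TermRef(
                iri=iri,
                curie=curie_of(iri),
                label=label_of(node),
                source_ontology=ontology_iri,
            ),
        )
        if individual:
            snap.individual_iris.add(iri)

    class_types = (OWL.Class, RDFS.Class)
    for ctype in class_types:
        for s in g.subjects(RDF.type, ctype):
            add_term(s)
    for s in g.subjects(RDF.type, OWL.NamedIndividual):
        add_term(s, individual=True)
    for p in g.subjects(RDF.type, OWL.ObjectProperty):
        if isinstance(p, rdflib.URIRef):
            iri = str(p)
            snap.property_terms[iri] = TermRef(
                iri=iri, curie=curie_of(iri), label=label_of(p),
                source_ontology=ontology_iri,
            )

    for child, parent in g.subject_objects(RDFS.subClassOf):
        if not isinstance(child, rdflib.URIRef):
            continue
        if isinstance(parent, rdflib.URIRef):
            add_term(child)
            add_term(parent)
            snap.subclass_edges.add((str(child), str(parent)))
        else:
            # SubClassOf(X, prop some Y) — an existential restriction
            if (parent, RDF.type, OWL.Restriction) not in g:
                continue
            prop = g.value(parent, OWL.onProperty)
            filler = g.value(parent, OWL.someValuesFrom)
            if not isinstance(prop, rdflib.URIRef) or not isinstance(filler, rdflib.URIRef):
                continue
            add_term(child)
            add_term(filler)
            if _is_partof_property(str(prop)):
                snap.partof_edges.add((str(child), str(filler)))
            else:
                snap.other_edges.add((str(child), str(prop), str(filler)))

    for inst, cls in g.subject_objects(RDF.type):
        if not isinstance(inst, rdflib.URIRef) or not isinstance(cls, rdflib.URIRef):
            continue
        if cls in (OWL.Class, RDFS.Class, OWL.NamedIndividual, OWL.Ontology,
                   OWL.ObjectProperty, OWL.AnnotationProperty, OWL.DatatypeProperty,
                   OWL.Restriction):
            continue
        if str(cls) in snap.terms:
            add_term(inst, individual=True)
            snap.instance_edges.add((str(inst), str(cls)))
    return snap


# ---------------------------------------------------------------------------
# Range resolution


def _children_adjacency(
    snapshot: OntologySnapshot, relations: Iterable[str]
) -> dict[str, list[str]]:
    adj: dict[str, list[str]] = {}
    pairs: list[tuple[str, str]] = []
    if "subclass" in relations:
        pairs.extend(snapshot.subclass_edges)
    if "part-of" in relations:
        pairs.extend(snapshot.partof_edges)
    for child, parent in sorted(pairs):
        adj.setdefault(parent, []).append(child)
    return adj


def _descendants(root_iri: str, adj: Mapping[str, Sequence[str]]) -> set[str]:
    """Visited-set BFS; cycles are tolerated and reported as a warning."""
    seen: set[str] = set()
    queue = deque(adj.get(root_iri, ()))
    cycle = False
    while queue:
        node = queue.popleft()
        if node == root_iri:
            cycle = True
            continue
        if node in seen:
            continue
        seen.add(node)
        queue.extend(adj.get(node, ()))
    if cycle:
        warnings.warn(
            f"cycle through {root_iri} in the traversal graph; closure truncated",
            stacklevel=3,
        )
    return seen


def resolve_range(spec: RangeSpec, snapshot: OntologySnapshot) -> ValidationSet:
    """Resolve a range specification into an ordered :class:`ValidationSet`.

    ``all-subclasses`` returns everything reachable from the root by one or
    more hops over the chosen traversal relations (root excluded unless
    ``spec.include_root``); ``direct-subclasses`` the one-hop children; the
    individual selectors work analogously over instantiation edges.  A
    ``root`` of ``None`` selects the whole ontology.  Members are ordered
    lexicographically by IRI so downstream serialization is reproducible.
    """
    if spec.root is not None and spec.root.iri not in snapshot.terms:
        raise UnknownTermError(spec.root.iri)

    classes_only = [
        iri for iri in snapshot.terms if iri not in snapshot.individual_iris
    ]

    if spec.root is None:
        if spec.selector in (Selector.ALL_INDIVIDUALS, Selector.DIRECT_INDIVIDUALS):
            member_iris = set(snapshot.individual_iris)
        else:
            member_iris = set(classes_only)
    elif spec.selector == Selector.ALL_SUBCLASSES:
        adj = _children_adjacency(snapshot, spec.traversal_relations)
        member_iris = _descendants(spec.root.iri, adj)
        if spec.include_root:
            member_iris.add(spec.root.iri)
    elif spec.selector == Selector.DIRECT_SUBCLASSES:
        adj = _children_adjacency(snapshot, spec.traversal_relations)
        member_iris = set(adj.get(spec.root.iri, ()))
    elif spec.selector == Selector.DIRECT_INDIVIDUALS:
        member_iris = {i for i, c in snapshot.instance_edges if c == spec.root.iri}
    else:  # all-individuals: instances of the root or any told descendant
        adj = _children_adjacency(snapshot, {"subclass"})
        class_iris = _descendants(spec.root.iri, adj) | {spec.root.iri}
        member_iris = {i for i, c in snapshot.instance_edges if c in class_iris}

    members = tuple(snapshot.terms[i] for i in sorted(member_iris))
    return ValidationSet(members=members, spec=spec)


def find_by_label(text: str, vset: ValidationSet) -> list[TermRef]:
    """Members whose display text equals *text* (case/whitespace-insensitive)."""
    key = normalize_label(text)
    return [m for m in vset.members if normalize_label(label_or_fragment(m)) == key]


def merge_snapshots(snapshots: Sequence[OntologySnapshot]) -> OntologySnapshot:
    """Union view over several loaded vocabularies (first definition wins)."""
    merged = OntologySnapshot(ontology_iri="urn:merged")
    for snap in snapshots:
        for iri, term in snap.terms.items():
            merged.terms.setdefault(iri, term)
        for iri, term in snap.property_terms.items():
            merged.property_terms.setdefault(iri, term)
        merged.subclass_edges |= snap.subclass_edges
        merged.partof_edges |= snap.partof_edges
        merged.instance_edges |= snap.instance_edges
        merged.individual_iris |= snap.individual_iris
        merged.other_edges |= snap.other_edges
    return merged
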