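"""Seeded random GeneratedOntology builder for serialization fixpoint tests."""

import random

from ontopop.axioms import (
    GroundAxiom,
    GroundClass,
    GroundIntersection,
    GroundSome,
    ProvenanceTag,
)
from ontopop.generator import GeneratedOntology
from ontopop.ontology_store import PrefixMap, TermRef


def random_ontology(rng: random.Random, case: int) -> GeneratedOntology:
    pm = PrefixMap({"t": "urn:t:"})

    def term(i):
        return TermRef(iri=f"urn:t:C{i}", curie=f"t:C{i}")

    def prop(i):
        return TermRef(iri=f"urn:t:p{i}", curie=f"t:p{i}")

    def expr(depth):
        kind = rng.choice(["class", "some", "and"] if depth else ["class", "some"])
        if kind == "class":
            return GroundClass(term(rng.randrange(8)))
        if kind == "some":
            return GroundSome(prop=prop(rng.randrange(3)), filler=expr(0))
        conjuncts = []
        for _ in range(rng.randint(2, 4)):
            e = expr(0)
            if e not in conjuncts:
                conjuncts.append(e)
        if len(conjuncts) < 2:
            conjuncts.append(GroundSome(prop=prop(2), filler=GroundClass(term(9))))
        return GroundIntersection(conjuncts=tuple(conjuncts))

    onto = GeneratedOntology(ontology_iri=f"urn:random:{case}", prefix_map=pm)
    tag = ProvenanceTag(template_id="random", row_index=1, script_id="rnd")
    seen = set()
    for _ in range(rng.randint(1, 12)):
        kind = rng.choice(["SubClassOf", "EquivalentTo"])
        axiom = GroundAxiom(kind=kind, subject=term(rng.randrange(8)), object=expr(1))
        # identical duplicate axioms are indistinguishable in an RDF graph
        # (triple-set semantics), so keep the generated axioms distinct
        key = (axiom.kind, axiom.subject.iri, axiom.object)
        if key in seen:
            continue
        seen.add(key)
        onto.axioms.append((axiom, tag))
    if rng.random() < 0.5:
        minted = term(99)
        onto.axioms.append((GroundAxiom(kind="Declaration", subject=minted), tag))
        onto.axioms.append(
            (GroundAxiom(kind="AnnotationAssertion", subject=minted,
                         annotation=f"label {case}"), tag)
        )
    return onto
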