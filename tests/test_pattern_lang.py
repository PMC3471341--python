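"""OPPL-subset parsing, rendering and pattern expansion."""

import itertools

import pytest

from ontopop.axioms import (
    GroundClass,
    GroundIntersection,
    GroundSome,
    intersection_of,
)
from ontopop.errors import (
    BindingError,
    PatternSyntaxError,
    UnsupportedConstructError,
)
from ontopop.fixtures import ANATOMY_SCRIPT, NUCLEATION_SCRIPT, PROCESS_SCRIPT
from ontopop.ontology_store import TermRef
from ontopop.pattern_lang import (
    expand,
    input_variables,
    parse_pattern,
    render_pattern,
)


def term(name: str) -> TermRef:
    return TermRef(iri=f"urn:t:{name}", curie=name)


def resolver(name: str, role: str) -> TermRef:
    return TermRef(iri=f"urn:{role}:{name}", curie=name)


class TestParsing:
    def test_nucleation_script_shape(self):
        """Two input variables, no definitions, one SubClassOf action."""
        script = parse_pattern(NUCLEATION_SCRIPT)
        assert len(script.declarations) == 2
        assert len(script.definitions) == 0
        assert len(script.actions) == 1
        assert script.actions[0].axiom_kind == "SubClassOf"

    def test_anatomy_script_shape(self):
        """Two inputs, two defined variables (one a macro), one EquivalentTo."""
        script = parse_pattern(ANATOMY_SCRIPT)
        assert input_variables(script) == ["?cell", "?anatomyPart"]
        assert len(script.definitions) == 2
        assert script.actions[0].axiom_kind == "EquivalentTo"

    def test_empty_body_rejected(self):
        with pytest.raises(PatternSyntaxError, match="no actions"):
            parse_pattern("BEGIN END;")

    def test_remove_is_an_explicit_unsupported_construct(self):
        text = "?x:CLASS\nBEGIN\nREMOVE ?x SubClassOf owl:Thing\nEND;"
        with pytest.raises(UnsupportedConstructError, match="REMOVE"):
            parse_pattern(text)

    def test_select_is_unsupported(self):
        with pytest.raises(UnsupportedConstructError, match="SELECT"):
            parse_pattern("?x:CLASS SELECT ?x BEGIN ADD ?x SubClassOf a END;")

    def test_non_class_variable_type_unsupported(self):
        with pytest.raises(UnsupportedConstructError):
            parse_pattern("?p:OBJECTPROPERTY\nBEGIN\nADD ?p SubClassOf a\nEND;")

    def test_syntax_error_carries_position(self):
        with pytest.raises(PatternSyntaxError) as err:
            parse_pattern("?x:CLASS,\n?y CLASS\nBEGIN ADD ?x SubClassOf ?y END;")
        assert err.value.line == 2

    def test_undeclared_variable_rejected(self):
        with pytest.raises(PatternSyntaxError, match=r"\?ghost"):
            parse_pattern("?x:CLASS BEGIN ADD ?ghost SubClassOf a END;")

    def test_keyword_case_insensitive(self):
        for kw in ("equivalentTo", "EquivalentTo", "EQUIVALENTTO"):
            script = parse_pattern(f"?x:CLASS begin add ?x {kw} a end;")
            assert script.actions[0].axiom_kind == "EquivalentTo"


class TestInputVariables:
    def test_process_script_inputs(self):
        assert input_variables(parse_pattern(PROCESS_SCRIPT)) == ["?cell", "?participant"]

    def test_union_of_both_kidney_scripts_has_three_inputs(self):
        names = set(input_variables(parse_pattern(ANATOMY_SCRIPT)))
        names |= set(input_variables(parse_pattern(PROCESS_SCRIPT)))
        assert names == {"?cell", "?anatomyPart", "?participant"}

    def test_every_declaration_defined_gives_empty_list(self):
        script = parse_pattern(
            "?a:CLASS = x and y\nBEGIN\nADD ?a SubClassOf z\nEND;"
        )
        assert input_variables(script) == []


class TestRoundTrip:
    @pytest.mark.parametrize(
        "text", [NUCLEATION_SCRIPT, ANATOMY_SCRIPT, PROCESS_SCRIPT],
        ids=["nucleation", "anatomy", "process"],
    )
    def test_parse_render_parse_fixpoint(self, text):
        script = parse_pattern(text)
        rendered = render_pattern(script)
        assert parse_pattern(rendered) == script


KUPO = term("kupo:KUPO_0001028")
MA = term("MA:MA_0002546")
GOS = [term("gene_ontology:GO_0003093"), term("gene_ontology:GO_0003098"),
       term("gene_ontology:GO_0003106")]
PHAGOCYTE = term("cto:CL_0000113")
MONONUCLEATE = term("pato:PATO_0001407")


class TestExpansion:
    def test_process_pattern_splits_into_four_subclass_axioms(self):
        """One cell × three processes → root conjunct + three restrictions."""
        script = parse_pattern(PROCESS_SCRIPT)
        axioms = expand(script, {"?cell": [KUPO], "?participant": GOS}, resolver)
        assert [ax.kind for ax in axioms] == ["SubClassOf"] * 4
        assert all(ax.subject == KUPO for ax in axioms)
        objs = [ax.object for ax in axioms]
        assert objs[0] == GroundClass(resolver("cell", "class"))
        assert objs[1:] == [
            GroundSome(prop=resolver("ro:participates_in", "property"),
                       filler=GroundClass(g))
            for g in GOS
        ]

    def test_anatomy_pattern_keeps_equivalence_whole(self):
        script = parse_pattern(ANATOMY_SCRIPT)
        axioms = expand(script, {"?cell": [KUPO], "?anatomyPart": [MA]}, resolver)
        assert len(axioms) == 1
        ax = axioms[0]
        assert ax.kind == "EquivalentTo" and ax.subject == KUPO
        assert isinstance(ax.object, GroundIntersection)
        assert ax.object.conjuncts == (
            GroundClass(resolver("cell", "class")),
            GroundSome(prop=resolver("ro:part_of", "property"),
                       filler=GroundClass(MA)),
        )

    def test_nucleation_pattern_single_axiom(self):
        script = parse_pattern(NUCLEATION_SCRIPT)
        axioms = expand(
            script, {"?cell": [PHAGOCYTE], "?nucleation": [MONONUCLEATE]}, resolver
        )
        assert len(axioms) == 1
        assert axioms[0].subject == PHAGOCYTE
        assert axioms[0].object == GroundSome(
            prop=resolver("hasNucleation", "property"),
            filler=GroundClass(MONONUCLEATE),
        )

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
    def test_expansion_matches_naive_substitution_oracle(self, k):
        """Macro expansion equals brute-force enumeration of substitutions.

        The oracle instantiates the conjunction by hand: the constant
        conjunct once, then one restriction per bound value, with the
        SubClassOf object split per conjunct.
        """
        script = parse_pattern(PROCESS_SCRIPT)
        values = [term(f"gene_ontology:GO_{i:07d}") for i in range(k)]
        axioms = expand(script, {"?cell": [KUPO], "?participant": values}, resolver)

        expected = [GroundClass(resolver("cell", "class"))] + [
            GroundSome(prop=resolver("ro:participates_in", "property"),
                       filler=GroundClass(v))
            for v in values
        ]
        assert [ax.object for ax in axioms] == expected
        # conjunct count before splitting: k instances → k + 1 after dedup
        assert len(axioms) == k + 1

    def test_duplicate_values_deduplicate_syntactically(self):
        script = parse_pattern(PROCESS_SCRIPT)
        axioms = expand(
            script, {"?cell": [KUPO], "?participant": [GOS[0], GOS[0]]}, resolver
        )
        assert len(axioms) == 2  # constant conjunct + one distinct restriction

    def test_zero_valued_variable_emits_nothing(self):
        script = parse_pattern(ANATOMY_SCRIPT)
        assert expand(script, {"?cell": [KUPO], "?anatomyPart": []}, resolver) == []
        assert expand(script, {"?cell": [], "?anatomyPart": [MA]}, resolver) == []

    def test_missing_binding_names_the_variable(self):
        script = parse_pattern(ANATOMY_SCRIPT)
        with pytest.raises(BindingError, match=r"\?anatomyPart"):
            expand(script, {"?cell": [KUPO]}, resolver)

    def test_expansion_is_deterministic(self):
        script = parse_pattern(PROCESS_SCRIPT)
        binding = {"?cell": [KUPO], "?participant": GOS}
        assert expand(script, binding, resolver) == expand(script, binding, resolver)

    def test_multiple_subjects_emit_per_subject(self):
        script = parse_pattern(NUCLEATION_SCRIPT)
        axioms = expand(
            script,
            {"?cell": [PHAGOCYTE, KUPO], "?nucleation": [MONONUCLEATE]},
            resolver,
        )
        assert [ax.subject for ax in axioms] == [PHAGOCYTE, KUPO]


class TestIntersectionAlgebra:
    def test_flattening_and_dedup(self):
        a, b, c = (GroundClass(term(x)) for x in "abc")
        nested = intersection_of([a, intersection_of([b, a, c])])
        assert nested == GroundIntersection(conjuncts=(a, b, c))

    def test_single_conjunct_unwrapped(self):
        a = GroundClass(term("a"))
        assert intersection_of([a, a]) == a

    def test_intersection_cardinality_bound(self):
        """After dedup: conjuncts ≤ bound values + constant conjuncts."""
        const = GroundClass(term("const"))
        for k in range(1, 6):
            for dup in range(k):
                values = [GroundClass(term(f"v{i if i != dup else 0}")) for i in range(k)]
                result = intersection_of([const] + values)
                distinct = len({v for v in values}) + 1
                conjuncts = (
                    result.conjuncts if isinstance(result, GroundIntersection) else (result,)
                )
                assert len(conjuncts) == distinct <= k + 1
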