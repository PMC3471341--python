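"""Row binding, identifier minting, generation, rendering, serialization."""

import random
import re

import pytest

from ontopop.axioms import GroundClass, GroundIntersection, GroundSome
from ontopop.errors import ConfigurationError, MintOverflowError
from ontopop.generator import (
    GeneratedOntology,
    MintPolicy,
    MintRegistry,
    ProvenanceTag,
    UnknownTerm,
    axiom_multiset,
    bind_row,
    mint_unknown,
    render_manchester,
    roundtrip_multisets,
    serialize_rdf,
)
from ontopop.axioms import GroundAxiom
from ontopop.ontology_store import PrefixMap, TermRef
from ontopop.workflow import load_template, run_generation


def policy(next_index=1, width=7, prefix="kupo"):
    return MintPolicy(
        namespace="http://purl.org/kup/kupo#",
        prefix=prefix,
        width=width,
        next_index=next_index,
    )


@pytest.fixture(scope="module")
def kup_template(bundle_dir, kup_ctx):
    return load_template(bundle_dir / "kup_template.tsv", kup_ctx)


class TestBindRow:
    def test_juxtaglomerular_row_binds_one_one_three(self, kup_template, kup_ctx):
        """Row 13: one cell name, one anatomy part, three processes."""
        binding = bind_row(kup_template, 13, kup_ctx.config.variable_map)
        assert [len(binding[v]) for v in ("?cell", "?anatomyPart", "?participant")] == [1, 1, 3]
        assert isinstance(binding["?cell"][0], UnknownTerm)
        assert binding["?anatomyPart"][0].curie == "MA:MA_0002546"

    def test_empty_row_gives_empty_lists(self, kup_ctx, kup_template):
        from ontopop.template_model import Cell, Template

        t = Template(
            columns=kup_template.columns,
            rows=[{c.name: Cell() for c in kup_template.columns}],
        )
        binding = bind_row(t, 1, kup_ctx.config.variable_map)
        assert all(v == [] for v in binding.values())

    def test_binding_matches_direct_template_lookup(self, kup_template, kup_ctx):
        """Identity oracle: binding lists equal the row's resolved tokens."""
        for row_index in range(1, kup_template.n_rows + 1):
            binding = bind_row(kup_template, row_index, kup_ctx.config.variable_map)
            for var, col in kup_ctx.config.variable_map.items():
                cell = kup_template.cell(row_index, col)
                expected = [
                    t.term if t.term is not None else UnknownTerm(raw=t.raw)
                    for t in cell.tokens
                ]
                assert binding[var] == expected

    def test_missing_column_is_a_configuration_error(self, kup_template):
        with pytest.raises(ConfigurationError, match="Z"):
            bind_row(kup_template, 1, {"?cell": "Z"})

    def test_row_out_of_range(self, kup_template):
        with pytest.raises(ConfigurationError):
            bind_row(kup_template, 99, {"?cell": "A"})


class TestMinting:
    def test_exemplar_identifier_form(self):
        """An unknown cell type mints the zero-padded kupo identifier."""
        reg = MintRegistry(policy(next_index=1028))
        binding = {"?cell": [UnknownTerm(raw="Juxtaglomerular complex cell")]}
        minted = mint_unknown(binding, reg.policy, reg)
        term = minted["?cell"][0]
        assert term.iri.endswith("KUPO_0001028")
        assert term.curie == "kupo:KUPO_0001028"
        assert term.is_minted and term.label == "Juxtaglomerular complex cell"

    def test_no_unknowns_is_identity(self):
        reg = MintRegistry(policy())
        known = TermRef(iri="urn:known")
        binding = {"?cell": [known]}
        assert mint_unknown(binding, reg.policy, reg) == binding
        assert reg.minted == []

    def test_same_label_minted_once_across_rows(self):
        reg = MintRegistry(policy(next_index=5))
        first = mint_unknown({"?x": [UnknownTerm(raw="New cell")]}, reg.policy, reg)
        second = mint_unknown({"?x": [UnknownTerm(raw="new  CELL")]}, reg.policy, reg)
        assert first["?x"][0].iri == second["?x"][0].iri
        assert reg.policy.next_index == 6  # counter advanced exactly once

    def test_distinct_labels_get_distinct_iris(self):
        reg = MintRegistry(policy())
        labels = [f"cell type {i}" for i in range(40)]
        iris = {reg.mint(lbl).iri for lbl in labels}
        assert len(iris) == len(labels)

    def test_collision_with_existing_iri_is_skipped(self):
        taken = "http://purl.org/kup/kupo#KUPO_0000001"
        reg = MintRegistry(policy(next_index=1), existing_iris={taken})
        assert reg.mint("x").iri.endswith("KUPO_0000002")

    def test_counter_exhaustion_raises(self):
        reg = MintRegistry(policy(next_index=99, width=2))
        assert reg.mint("last one fits").iri.endswith("KUPO_99")
        with pytest.raises(MintOverflowError):
            reg.mint("one too many")


class TestGenerate:
    def test_nucleation_one_row_generates_single_axiom(self, bundle_dir, nucleation_ctx):
        template = load_template(bundle_dir / "nucleation_onerow.tsv", nucleation_ctx)
        onto = run_generation(template, nucleation_ctx)
        assert len(onto.logical_axioms) == 1
        text = render_manchester(onto)
        assert "Class: cto:CL_0000113" in text
        assert "hasNucleation some pato:PATO_0001407" in text

    def test_kidney_row13_frame(self, kup_template, kup_ctx):
        """Juxtaglomerular complex cell: 1 equivalence + 4 subclass entries."""
        onto = run_generation(kup_template, kup_ctx)
        mine = [ax for ax in onto.logical_axioms
                if ax.subject.curie == "kupo:KUPO_0001028"]
        eq = [ax for ax in mine if ax.kind == "EquivalentTo"]
        sub = [ax for ax in mine if ax.kind == "SubClassOf"]
        assert len(eq) == 1 and len(sub) == 4
        assert isinstance(eq[0].object, GroundIntersection)
        fillers = {
            ax.object.filler.term.curie
            for ax in sub if isinstance(ax.object, GroundSome)
        }
        assert fillers == {
            "gene_ontology:GO_0003093",
            "gene_ontology:GO_0003098",
            "gene_ontology:GO_0003106",
        }

    def test_minted_terms_and_declarations(self, kup_template, kup_ctx):
        onto = run_generation(kup_template, kup_ctx)
        assert len(onto.minted_terms) == 13
        declared = {ax.subject.iri for ax, _ in onto.axioms if ax.kind == "Declaration"}
        assert declared == {t.iri for _, t in onto.minted_terms}

    def test_axiom_conservation_against_run_report(self, kup_template, kup_ctx):
        onto = run_generation(kup_template, kup_ctx)
        assert len(onto.logical_axioms) == sum(
            e.axioms_emitted for e in onto.run_report
        )

    def test_empty_template_generates_header_only(self, kup_ctx):
        from ontopop.template_model import ColumnDef, Template

        empty = Template(columns=[ColumnDef(name=n) for n in ("A", "C", "D")])
        onto = run_generation(empty, kup_ctx)
        assert onto.logical_axioms == []
        assert "Class:" not in render_manchester(onto)

    def test_generation_is_byte_deterministic(self, bundle_dir, kup_ctx):
        from ontopop.workbook_io import load_workflow
        from ontopop.workflow import build_context

        texts = []
        for _ in range(2):
            # fresh context: the mint counter is stateful per run
            config = load_workflow(bundle_dir / "kup_workflow.yaml")
            ctx = build_context(config, bundle_dir)
            template = load_template(bundle_dir / "kup_template.tsv", ctx)
            texts.append(render_manchester(run_generation(template, ctx)))
        assert texts[0] == texts[1]

    def test_provenance_tags_carry_row_and_script(self, kup_template, kup_ctx):
        onto = run_generation(kup_template, kup_ctx)
        tags = {tag for ax, tag in onto.axioms if ax.is_logical}
        assert all(1 <= t.row_index <= 13 for t in tags)
        assert {t.script_id for t in tags} == {"anatomy", "process"}


class TestSerialization:
    def test_example_frame_reparses_to_one_restriction_axiom(
        self, bundle_dir, nucleation_ctx
    ):
        template = load_template(bundle_dir / "nucleation_onerow.tsv", nucleation_ctx)
        onto = run_generation(template, nucleation_ctx)
        import rdflib
        from rdflib import OWL, RDFS

        g = rdflib.Graph()
        g.parse(data=serialize_rdf(onto, "turtle"), format="turtle")
        subclass = [
            (s, o) for s, o in g.subject_objects(RDFS.subClassOf)
            if isinstance(s, rdflib.URIRef)
        ]
        assert len(subclass) == 1
        _, restriction = subclass[0]
        assert g.value(restriction, OWL.someValuesFrom) is not None

    def test_empty_ontology_serializes_header_only(self):
        onto = GeneratedOntology(ontology_iri="urn:empty", prefix_map=PrefixMap())
        text = serialize_rdf(onto, "turtle")
        assert "owl:Ontology" in text
        assert "subClassOf" not in text

    def test_unknown_format_rejected(self):
        onto = GeneratedOntology(ontology_iri="urn:x", prefix_map=PrefixMap())
        with pytest.raises(ValueError):
            serialize_rdf(onto, "n3000")

    @pytest.mark.parametrize("fmt", ["turtle", "rdfxml"])
    def test_roundtrip_fixpoint_on_random_ontologies(self, fmt):
        """serialize → parse preserves the logical axiom multiset, 50×."""
        from random_ontology_support import random_ontology

        rng = random.Random(20240917)
        for case in range(50):
            onto = random_ontology(rng, case)
            original, reparsed = roundtrip_multisets(onto, fmt)
            assert original == reparsed, f"case {case}"


class TestManchesterRendering:
    def test_frames_sorted_by_first_generation_order(self, kup_template, kup_ctx):
        onto = run_generation(kup_template, kup_ctx)
        text = render_manchester(onto)
        frames = re.findall(r"^Class: (\S+)$", text, flags=re.M)
        assert frames[0] == "kupo:KUPO_0001016"
        assert "kupo:KUPO_0001028" in frames
        assert len(frames) == len(set(frames)) == 13

    def test_restriction_conjuncts_parenthesized(self, kup_template, kup_ctx):
        onto = run_generation(kup_template, kup_ctx)
        text = render_manchester(onto)
        assert "cell:CL_0000000 and (ro:part_of some MA:MA_0002546)" in text
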