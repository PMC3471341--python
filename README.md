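# ontopop

Template-driven OWL ontology population for the life sciences.

Biomedical application ontologies are often built from highly repetitive
axiom patterns: a *cell type* is a cell that is `part_of` some anatomical
structure and `participates_in` some biological process; a cell is
classified by its *nucleation*; and so on.  Domain experts hold the
knowledge that fills these patterns but rarely want to write description
logic.  `ontopop` separates the two roles: the expert fills a constrained
table, the ontologist writes a small pattern script, and the package
compiles the populated table into OWL axioms.

The pipeline is:

1. **Load vocabularies** (OBO flat files, OWL as Turtle or RDF/XML) into
   an indexed snapshot of terms, `is_a`/`subClassOf`, `part_of` and
   instantiation edges.  No reasoner runs; ranges are resolved over the
   asserted hierarchy.
2. **Resolve validation sets** — the terms allowed in a template column:
   *all subclasses* of a chosen root (optionally traversing `part_of` as
   well), *direct subclasses only*, *all individuals* or *direct
   individuals*.
3. **Validate the table.**  Cells may hold several values separated by a
   vertical bar (`a|b|c`); each token is resolved by label, CURIE or IRI
   against its column's set.  Matches are *resolved* (green); free text is
   *unknown* (red) and acts as a placeholder for a new term.
4. **Mint identifiers** for unknown terms: zero-padded IRIs such as
   `kupo:KUPO_0001028`, the same label always receiving the same IRI
   within a run.
5. **Expand patterns.**  Scripts in a subset of OPPL 2 declare class
   variables, define derived expressions, and `ADD` SubClassOf /
   EquivalentTo axioms.  The `createIntersection(?v.VALUES)` macro builds
   the conjunction of a definition instantiated once per bound value:

       ?cell:CLASS,
       ?anatomyPart:CLASS,
       ?partOfRestriction:CLASS = cell and ro:part_of some ?anatomyPart,
       ?anatomyIntersection:CLASS = createIntersection(?partOfRestriction.VALUES)
       BEGIN
       ADD ?cell equivalentTo ?anatomyIntersection
       END;

6. **Emit the ontology** in Manchester syntax for review and Turtle /
   RDF/XML for tooling, every generated axiom annotated with its
   provenance (template id, row, script, timestamp).

Templates round-trip through `.xlsx` workbooks (term sets stored on a
hidden worksheet, surfaced as native dropdown validations) or a plain
TSV dialect; a whole workflow — ontology sources, column ranges, pattern
scripts, variable bindings, minting policy — saves to a single YAML file
for re-use.

## Worked example

The package bundles miniature vocabularies so everything runs offline:

```sh
ontopop fixtures -o demo
ontopop validate demo/nucleation_partial.tsv --config demo/nucleation_workflow.yaml
```

prints

```
Template 'nucleation_partial':
  column A: 5 resolved, 1 unknown, 0 empty
  column B: 6 resolved, 0 unknown, 0 empty
  1 unknown token(s):
    row 5, column A: 'Proximal tubule epithelial cell'
```

— five cell types resolved against the cell-type ontology slice, one
free-text entry flagged red.  Generating from the one-row template:

```sh
ontopop generate demo/nucleation_onerow.tsv \
    --config demo/nucleation_workflow.yaml -o out
```

writes `out/generated.omn` containing the frame

```
Class: cto:CL_0000113

    SubClassOf:
        hasNucleation some pato:PATO_0001407
```

i.e. *every mononuclear phagocyte has mononucleate nucleation*.  The
13-row kidney template (`demo/kup_template.tsv` with
`demo/kup_workflow.yaml`) runs two patterns per row and mints new classes
for the novel cell types; its thirteenth row produces

```
Class: kupo:KUPO_0001028

    EquivalentTo:
        cell:CL_0000000 and (ro:part_of some MA:MA_0002546)

    SubClassOf:
        cell:CL_0000000,
        ro:participates_in some gene_ontology:GO_0003093,
        ro:participates_in some gene_ontology:GO_0003098,
        ro:participates_in some gene_ontology:GO_0003106
```

— the juxtaglomerular complex cell defined by its anatomical location,
with participation in three renal regulation processes.

## Layout

| module | role |
| --- | --- |
| `ontopop.ontology_store` | OBO/OWL loading, prefix maps, range → validation-set resolution |
| `ontopop.template_model` | cells, multi-value parsing, auto-completion, validation reports |
| `ontopop.workbook_io` | XLSX/TSV round trips, workflow configuration persistence |
| `ontopop.pattern_lang` | OPPL-subset parser, pretty-printer and expander |
| `ontopop.generator` | row binding, minting, provenance, Manchester/RDF output |
| `ontopop.fixtures`, `ontopop.cli` | offline fixture bundle and the `ontopop` command |

See `docs/methods.md` for the design notes and known limitations.
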