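# Methods

## The model: normalisation patterns over tabular knowledge

`ontopop` implements the *normalisation* style of ontology engineering:
a genus class refined by differentia, each differentia an existential
restriction over a dedicated relationship.  The knowledge lives in a
table — one row per entity, one column per relationship slot — and the
axiomatisation lives in small pattern scripts, so the two can evolve
independently.  The package's job is the mechanical part: constraining
and validating the table, and compiling (row × pattern) into ground OWL
axioms.

Only the fragment of OWL that the patterns need is generated: named
classes, existential (`some`) restrictions, intersections, SubClassOf and
EquivalentClasses axioms, plus declarations and `rdfs:label` annotations
for newly minted classes.  Universal restrictions, cardinalities,
property/individual variables and axiom removal are deliberately out of
scope.

## Range resolution without a reasoner

Validation sets are computed over the *asserted* hierarchy: `is_a` /
`rdfs:subClassOf` edges, `part_of` edges (OBO `relationship: part_of`
lines, or OWL `SubClassOf(X, part_of some Y)` restrictions), and
`rdf:type` edges for individuals.  Four selectors are offered: all
subclasses (transitive, root excluded by default, optionally traversing
`part_of` as well — kidney anatomy ranges need "subclasses **or parts**
of the urinary system"), direct subclasses, all individuals (instances
of the root or any told descendant), direct individuals.

Not running a reasoner is a documented limitation, not an accident: told
edges suffice for column validation, and classification of the
*generated* ontology belongs downstream in an ontology editor.
Consequences: inferred subsumptions never widen a validation set, and
`part_of` is traversed transitively as a plain edge relation with no
property-chain semantics.  Cycles in the traversal graph are tolerated
(visited-set search) and reported as a warning.

Member order is lexicographic by IRI everywhere, making every
downstream artifact reproducible.

## Cell parsing and matching rules

Cells split on `|`; a backslash escapes a literal bar inside a label
(some vocabulary labels contain bars in synonyms).  Tokens resolve by
label first, then CURIE, then full IRI.  Label comparison is
case-insensitive with internal whitespace collapsed — the matching rule
is otherwise unspecified in practice, and spreadsheet-authored content
is rife with case and spacing noise.  Unresolvable tokens are *data*
(status `unknown`), never errors: they are exactly the terms the minting
step will create.  Duplicate values within a cell are kept but flagged.
Auto-completion is substring-based with prefix matches ranked first; a
full regular-expression query mode was considered and left out as
under-motivated for cell entry.

## Pattern language subset

The parser is a hand-written recursive-descent parser over a small
tokenizer (the grammar is ~10 productions; a parser generator would be
heavier than the parser).  Keywords are case-insensitive because the
wild corpus of scripts mixes `SubClassOf`/`subClassOf` and
`equivalentTo`/`EquivalentTo`.  Recognized-but-unsupported OPPL 2
constructs (`REMOVE`, `SELECT`, variable constraints, non-CLASS variable
types) fail with an explicit *unsupported construct* error naming the
construct, so a user with a full OPPL script gets a useful message
rather than a generic syntax error.

Expansion semantics, in evaluation order:

* an input variable bound to *k* row values contributes a *k*-element
  value sequence;
* a defined variable whose body references multi-valued variables is
  instantiated once per combination (cartesian product in
  first-reference order — in practice one variable is multi-valued);
* `createIntersection(?v.VALUES)` conjoins the instance sequence,
  flattening nested intersections and removing *syntactically* identical
  conjuncts (first occurrence kept); a single survivor is returned
  unwrapped.  Dedup is syntactic, not semantic: two different names for
  the same class stay distinct conjuncts.
* each action emits one axiom per subject value; a **SubClassOf** action
  whose object is an intersection is split into one axiom per conjunct
  (the frame a reviewer reads lists each superclass separately), while
  an **EquivalentTo** object is kept as the whole intersection —
  splitting an equivalence would change its meaning;
* a referenced variable with *zero* values suppresses the action for
  that row (partially filled rows must not abort a batch run); a
  variable missing from the binding altogether is an error.

## Identifier minting

New IRIs are `namespace + PREFIX_NNNNNNN` with a zero-padded counter
(default width 7, matching the common OBO convention).  A per-run
registry guarantees consistency (the same normalized label always maps
to the same new IRI) and injectivity (distinct labels, distinct IRIs);
collisions with loaded IRIs are skipped; exhausting the numeric width is
a hard error.  The counter start is configurable and pinned in the
bundled kidney workflow (at 1016) so the reference row reproducibly
mints `KUPO_0001028`.  Minted classes receive a declaration and a label
annotation but deliberately no parent: the generated cell classes form a
flat list, and any hierarchy is the patterns' (or a reasoner's) job.

## Rendering and serialization

Manchester output is one frame per subject in first-generation order:
label annotations, the `EquivalentTo:` block, then the `SubClassOf:`
block, entries comma-separated, restriction conjuncts parenthesized
(`A and (p some B)`).  Names render as CURIEs when a prefix matches,
else as the IRI fragment (so an unprefixed relation renders as plain
`hasNucleation`).

RDF output uses the standard OWL mapping (blank-node `owl:Restriction`,
`owl:intersectionOf` lists, `owl:equivalentClass`), with provenance as
`owl:Axiom` annotation bundles carrying template id, row index, script
id and timestamp under a small built-in annotation vocabulary.  The
timestamp is injected text (a fixed epoch stamp by default), keeping
whole-pipeline output byte-deterministic.  Two numerical-robustness
choices: `rdf:first`/`rdf:rest` chains are built by hand rather than via
the library's collection helper, and Turtle output is verified by
re-parsing and isomorphism comparison, falling back to the N-Triples
subset of Turtle if the pretty-printer has detached any blank-node list
cell (an upstream serializer defect this guard makes harmless).  The
serialize→parse fixpoint is asserted at the level of the logical +
annotation axiom multiset; class declarations are excluded from the
comparison because the RDF mapping necessarily declares every class an
expression mentions.  Note that two *identical* axioms collapse under
RDF's triple-set semantics when their object is a named class; the
generator never produces such duplicates from distinct rows (subjects
differ), so the fixpoint holds for all pipeline output.

## Workbooks and workflows

Exported workbooks keep the grid on a visible sheet and one record per
allowed term — cell range, term URI, label, source ontology URI — on a
hidden sheet named `_ontology_validation`, referenced by native dropdown
validations; re-importing reconstructs the validation sets from that
sheet alone, so a template annotated here survives editing in any
spreadsheet tool.  Only `.xlsx` is written.  The TSV dialect (header row
of column names, `|`-separated values) is the canonical plain-text
surface because byte-exact assertions on zipped XLSX are brittle.
Workflow configurations are a single versioned YAML document; loading an
unknown version fails explicitly.  One row per entity is assumed
throughout; non-uniform spreadsheet layouts are out of scope.

## The fixture bundle

The bundle is a fixed reference corpus, not a random sample: miniature
vocabularies containing exactly the terms the reference workflows touch
(a cell-type slice with ten named cells, the nucleation quality with its
four values, a ten-term kidney partonomy with nine `part_of` edges, a
six-term biological-process slice, and the three relations), three
templates, three pattern scripts and two workflow files.  Its generation
is deterministic and digest-manifested; the `--seed` flag exists for
interface uniformity.  Two deliberate quirks:

* the Turtle cell-type ontology keeps its root in a `cell:` namespace
  and the named cells in a `cto:` namespace, so both prefixes seen in
  reference output render correctly; the OBO flavour (one idspace per
  id) maps everything to `cto:`, which is why the bundled workflows load
  the Turtle files;
* the kidney template supplies twelve plausible novel kidney-cell rows
  ahead of the juxtaglomerular row and pins the minting counter at 1016,
  so the thirteenth minted class is reproducibly `KUPO_0001028`.

What the fixtures do **not** emulate: real vocabularies are orders of
magnitude larger (lookup and closure performance at that scale is
untested here), real labels carry synonyms and obsolescence metadata the
loader ignores, and multi-expert curation noise (conflicting labels,
near-duplicates) is absent.  Passing tests therefore demonstrate the
correctness of the transformation machinery, not robustness against
messy production vocabularies.

## Problem sizes

The test suite and the acceptance script run the full pipelines on the
bundled templates (1–13 rows), check range closures against an
independent reachability oracle on random DAGs of 50–200 nodes, macro
expansion against naive substitution for up to 5 values, and the RDF
fixpoint on 50 random ontologies of up to 12 axioms — sizes at which
every property is exhaustively checkable in seconds while exercising
every code path the reference workflows use.
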