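"""Miniature offline fixtures for every worked example.

The bundle contains just enough of each source vocabulary to run the two
reference workflows without any network access:

* **mini-CTO** — a cell root plus ten named cell types (incl.
  CL_0000113 *mononuclear phagocyte*);
* **mini-PATO** — the *nucleation* quality and its four values (incl.
  PATO_0001407 *mononucleate*);
* **mini-MA** — a ten-term kidney/urinary-system partonomy (incl.
  MA_0002546 *part of afferent arteriole forming juxtaglomerular
  complex*), nine ``part_of`` edges;
* **mini-GO** — a biological-process root with renal processes
  (GO_0003093, GO_0003098, GO_0003106 under their printed labels);
* the relations (``ro:part_of``, ``ro:participates_in``,
  ``hasNucleation``), three pattern scripts, three templates and two
  workflow configurations.

Every ontology is written in both OBO and Turtle to exercise both
loaders.  Note one asymmetry: an OBO id carries a single idspace, so the
OBO flavour of mini-CTO places all CL terms in the ``cto:`` namespace,
while the Turtle flavour keeps the root in the ``cell:`` namespace (the
worked-example workflows load Turtle for this reason).  Generation is
fully deterministic; a manifest lists every file with a SHA-256 digest.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

__all__ = ["DEFAULT_PREFIXES", "make_fixtures", "fixture_files"]

DEFAULT_PREFIXES: dict[str, str] = {
    "cell": "http://purl.org/obo/owl/CL#",
    "cto": "http://purl.org/obo/owl/CTO#",
    "ro": "http://www.obofoundry.org/ro/ro.owl#",
    "kupo": "http://purl.org/kup/kupo#",
    "pato": "http://purl.org/obo/owl/PATO#",
    "MA": "http://purl.org/obo/owl/MA#",
    "gene_ontology": "http://purl.org/obo/owl/GO#",
}

#: Namespace for relations outside the prefixed vocabularies (rendered by
#: fragment, e.g. plain ``hasNucleation``).
REL_NS = "http://purl.org/kup/relation#"

# (local id, label) of the ten named cell types; the root CL_0000000 "cell"
# sits in the cell: namespace.
_CTO_CELLS = [
    ("CL_0000057", "fibroblast"),
    ("CL_0000092", "osteoclast"),
    ("CL_0000113", "mononuclear phagocyte"),
    ("CL_0000115", "endothelial cell"),
    ("CL_0000182", "hepatocyte"),
    ("CL_0000232", "erythrocyte"),
    ("CL_0000235", "macrophage"),
    ("CL_0000576", "monocyte"),
    ("CL_0000650", "mesangial cell"),
    ("CL_0000653", "podocyte"),
]

_PATO_TERMS = [
    ("PATO_0000001", "quality", None),
    ("PATO_0001404", "nucleation", "PATO_0000001"),
    ("PATO_0001405", "anucleate", "PATO_0001404"),
    ("PATO_0001406", "binucleate", "PATO_0001404"),
    ("PATO_0001407", "mononucleate", "PATO_0001404"),
    ("PATO_0001908", "multinucleate", "PATO_0001404"),
]

# (local id, label, part_of parent) — 10 terms, 9 part_of edges.
_MA_TERMS = [
    ("MA_0000325", "urinary system", None),
    ("MA_0000368", "kidney", "MA_0000325"),
    ("MA_0000592", "renal cortex", "MA_0000368"),
    ("MA_0001655", "nephron", "MA_0000592"),
    ("MA_0001656", "renal corpuscle", "MA_0001655"),
    ("MA_0001657", "glomerulus", "MA_0001656"),
    ("MA_0001660", "renal tubule", "MA_0001655"),
    ("MA_0002584", "afferent arteriole", "MA_0000592"),
    ("MA_0002547", "juxtaglomerular complex", "MA_0000592"),
    ("MA_0002546", "part of afferent arteriole forming juxtaglomerular complex",
     "MA_0002547"),
]

_GO_TERMS = [
    ("GO_0008150", "biological_process", None),
    ("GO_0003014", "renal system process", "GO_0008150"),
    ("GO_0003093", "regulation of glomerular filtration", "GO_0003014"),
    ("GO_0003098", "tubuloglomerular feedback", "GO_0003014"),
    ("GO_0003106", "regulation of glomerular filtration by angiotensin",
     "GO_0003014"),
    ("GO_0070293", "renal absorption", "GO_0003014"),
]


def _obo_header(name: str) -> str:
    return f"format-version: 1.2\nontology: {name}\n"


def _mini_cto_obo() -> str:
    out = [_obo_header("mini_cto")]
    out.append("\n[Term]\nid: CL:0000000\nname: cell\n")
    for local, label in _CTO_CELLS:
        num = local.split("_")[1]
        out.append(f"\n[Term]\nid: CL:{num}\nname: {label}\nis_a: CL:0000000 ! cell\n")
    return "".join(out)


def _mini_cto_ttl() -> str:
    cell_ns = DEFAULT_PREFIXES["cell"]
    cto_ns = DEFAULT_PREFIXES["cto"]
    out = [
        "@prefix owl: <http://www.w3.org/2002/07/owl#> .",
        "@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .",
        f"@prefix cell: <{cell_ns}> .",
        f"@prefix cto: <{cto_ns}> .",
        "",
        "<http://purl.org/obo/owl/mini_cto> a owl:Ontology .",
        "",
        'cell:CL_0000000 a owl:Class ; rdfs:label "cell" .',
    ]
    for local, label in _CTO_CELLS:
        out.append(
            f'cto:{local} a owl:Class ; rdfs:label "{label}" ; '
            "rdfs:subClassOf cell:CL_0000000 ."
        )
    return "\n".join(out) + "\n"


def _simple_obo(name: str, idspace: str, terms, relation: str | None = None) -> str:
    """OBO text for (id, label, parent) triples; parent edge is is_a unless
    *relation* names a typedef (then a relationship: line is written)."""
    out = [_obo_header(name)]
    for local, label, parent in terms:
        num = local.split("_", 1)[1]
        out.append(f"\n[Term]\nid: {idspace}:{num}\nname: {label}\n")
        if parent is not None:
            pnum = parent.split("_", 1)[1]
            if relation:
                out.append(f"relationship: {relation} {idspace}:{pnum}\n")
            else:
                out.append(f"is_a: {idspace}:{pnum}\n")
    if relation:
        out.append(f"\n[Typedef]\nid: {relation}\nname: {relation.replace('_', ' ')}\n")
    return "".join(out)


def _simple_ttl(name: str, prefix: str, terms, relation_curie: str | None = None) -> str:
    ns = DEFAULT_PREFIXES[prefix]
    out = [
        "@prefix owl: <http://www.w3.org/2002/07/owl#> .",
        "@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .",
        f"@prefix {prefix}: <{ns}> .",
    ]
    if relation_curie:
        rp, _, _ = relation_curie.partition(":")
        out.append(f"@prefix {rp}: <{DEFAULT_PREFIXES.get(rp, REL_NS)}> .")
    out += ["", f"<http://purl.org/obo/owl/{name}> a owl:Ontology .", ""]
    for local, label, parent in terms:
        line = f'{prefix}:{local} a owl:Class ; rdfs:label "{label}"'
        if parent is not None:
            if relation_curie:
                line += (
                    f" ; rdfs:subClassOf [ a owl:Restriction ; "
                    f"owl:onProperty {relation_curie} ; "
                    f"owl:someValuesFrom {prefix}:{parent} ]"
                )
            else:
                line += f" ; rdfs:subClassOf {prefix}:{parent}"
        out.append(line + " .")
    return "\n".join(out) + "\n"


def _relations_ttl() -> str:
    ro = DEFAULT_PREFIXES["ro"]
    rel = REL_NS
    return "\n".join([
        "@prefix owl: <http://www.w3.org/2002/07/owl#> .",
        "@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .",
        f"@prefix ro: <{ro}> .",
        f"@prefix rel: <{rel}> .",
        "",
        "<http://purl.org/kup/relations> a owl:Ontology .",
        "",
        'ro:part_of a owl:ObjectProperty ; rdfs:label "part of" .',
        'ro:participates_in a owl:ObjectProperty ; rdfs:label "participates in" .',
        'rel:hasNucleation a owl:ObjectProperty ; rdfs:label "hasNucleation" .',
    ]) + "\n"


def _relations_obo() -> str:
    return (
        _obo_header("relations")
        + "\n[Typedef]\nid: part_of\nname: part of\n"
        + "\n[Typedef]\nid: participates_in\nname: participates in\n"
        + "\n[Typedef]\nid: hasNucleation\nname: hasNucleation\n"
    )


NUCLEATION_SCRIPT = """\
?cell:CLASS,
?nucleation:CLASS
BEGIN
ADD ?cell SubClassOf hasNucleation some ?nucleation
END;
"""

ANATOMY_SCRIPT = """\
?cell:CLASS,
?anatomyPart:CLASS,
?partOfRestriction:CLASS = cell and ro:part_of some ?anatomyPart,
?anatomyIntersection:CLASS = createIntersection(?partOfRestriction.VALUES)
BEGIN
ADD ?cell equivalentTo ?anatomyIntersection
END;
"""

PROCESS_SCRIPT = """\
?cell:CLASS,
?participant:CLASS,
?participatesRestriction:CLASS = cell and ro:participates_in some ?participant,
?participatesIntersection:CLASS = createIntersection(?participatesRestriction.VALUES)
BEGIN
ADD ?cell SubClassOf ?participatesIntersection
END;
"""

_NUCLEATION_ROWS_VALID = [
    ("mononuclear phagocyte", "mononucleate"),
    ("erythrocyte", "anucleate"),
    ("osteoclast", "multinucleate"),
    ("hepatocyte", "binucleate"),
    ("podocyte", "mononucleate"),
    ("macrophage", "mononucleate"),
]

# Same template with the classic invalid entry at row 5, column A: the term
# is not in the cell-type validation set, so it shows red.
_NUCLEATION_ROWS_PARTIAL = [
    ("mononuclear phagocyte", "mononucleate"),
    ("erythrocyte", "anucleate"),
    ("osteoclast", "multinucleate"),
    ("hepatocyte", "binucleate"),
    ("Proximal tubule epithelial cell", "mononucleate"),
    ("macrophage", "mononucleate"),
]

# 13-row kidney template: all cell-type names are novel (minted); anatomy
# and process values resolve against mini-MA / mini-GO.  Row 13 is the
# juxtaglomerular complex cell with one anatomy and three process values.
_KUP_ROWS = [
    ("Renal principal cell", "renal tubule", "renal absorption"),
    ("Renal intercalated cell", "renal tubule", "renal absorption"),
    ("Vasa recta descending limb cell", "kidney", "renal system process"),
    ("Vasa recta ascending limb cell", "kidney", "renal system process"),
    ("Proximal tubule brush border cell", "renal tubule", "renal absorption"),
    ("Distal convoluted tubule cell", "renal tubule", "renal absorption"),
    ("Connecting tubule cell", "renal tubule", "renal absorption"),
    ("Inner medullary collecting duct cell", "renal tubule", "renal absorption"),
    ("Outer medullary collecting duct cell", "renal tubule", "renal absorption"),
    ("Macula densa cell", "juxtaglomerular complex", "tubuloglomerular feedback"),
    ("Glomerular parietal epithelial cell", "glomerulus",
     "regulation of glomerular filtration"),
    ("Afferent arteriole smooth muscle cell", "afferent arteriole",
     "regulation of glomerular filtration"),
    ("Juxtaglomerular complex cell",
     "part of afferent arteriole forming juxtaglomerular complex",
     "regulation of glomerular filtration|tubuloglomerular feedback|"
     "regulation of glomerular filtration by angiotensin"),
]


def _tsv(header: list[str], rows) -> str:
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def _nucleation_workflow() -> dict:
    return {
        "version": 1,
        "ontologies": [
            {"path": "mini_cto.ttl", "dialect": "turtle"},
            {"path": "mini_pato.ttl", "dialect": "turtle"},
            {"path": "relations.ttl", "dialect": "turtle"},
        ],
        "prefixes": dict(DEFAULT_PREFIXES),
        "ranges": {
            "A": {"ontology": "mini_cto.ttl", "root": "cell:CL_0000000",
                  "selector": "all-subclasses", "relations": ["subclass"]},
            "B": {"ontology": "mini_pato.ttl", "root": "pato:PATO_0001404",
                  "selector": "all-subclasses", "relations": ["subclass"]},
        },
        "scripts": [{"id": "nucleation", "text": NUCLEATION_SCRIPT}],
        "variable_map": {"?cell": "A", "?nucleation": "B"},
        "minting": {"namespace": DEFAULT_PREFIXES["kupo"], "prefix": "kupo",
                    "width": 7, "next_index": 1},
        "ontology_iri": "http://purl.org/kup/generated/nucleation",
    }


def _kup_workflow() -> dict:
    return {
        "version": 1,
        "ontologies": [
            {"path": "mini_cto.ttl", "dialect": "turtle"},
            {"path": "mini_ma.ttl", "dialect": "turtle"},
            {"path": "mini_go.ttl", "dialect": "turtle"},
            {"path": "relations.ttl", "dialect": "turtle"},
        ],
        "prefixes": dict(DEFAULT_PREFIXES),
        "ranges": {
            "A": {"ontology": "mini_cto.ttl", "root": "cell:CL_0000000",
                  "selector": "all-subclasses", "relations": ["subclass"]},
            "C": {"ontology": "mini_ma.ttl", "root": "MA:MA_0000325",
                  "selector": "all-subclasses",
                  "relations": ["subclass", "part-of"]},
            "D": {"ontology": "mini_go.ttl", "root": "gene_ontology:GO_0008150",
                  "selector": "all-subclasses", "relations": ["subclass"]},
        },
        "scripts": [
            {"id": "anatomy", "text": ANATOMY_SCRIPT},
            {"id": "process", "text": PROCESS_SCRIPT},
        ],
        "variable_map": {"?cell": "A", "?anatomyPart": "C", "?participant": "D"},
        # counter pinned so the 13th minted class is KUPO_0001028
        "minting": {"namespace": DEFAULT_PREFIXES["kupo"], "prefix": "kupo",
                    "width": 7, "next_index": 1016},
        "ontology_iri": "http://purl.org/kup/generated/kupo",
    }


def fixture_files() -> dict[str, str]:
    """All fixture files as ``name → content`` (deterministic)."""
    import yaml

    files = {
        "mini_cto.obo": _mini_cto_obo(),
        "mini_cto.ttl": _mini_cto_ttl(),
        "mini_pato.obo": _simple_obo("mini_pato", "PATO", _PATO_TERMS),
        "mini_pato.ttl": _simple_ttl("mini_pato", "pato", _PATO_TERMS),
        "mini_ma.obo": _simple_obo("mini_ma", "MA", _MA_TERMS, relation="part_of"),
        "mini_ma.ttl": _simple_ttl("mini_ma", "MA", _MA_TERMS, relation_curie="ro:part_of"),
        "mini_go.obo": _simple_obo("mini_go", "GO", _GO_TERMS),
        "mini_go.ttl": _simple_ttl("mini_go", "gene_ontology", _GO_TERMS),
        "relations.obo": _relations_obo(),
        "relations.ttl": _relations_ttl(),
        "nucleation_pattern.oppl": NUCLEATION_SCRIPT,
        "anatomy_pattern.oppl": ANATOMY_SCRIPT,
        "process_pattern.oppl": PROCESS_SCRIPT,
        "nucleation_valid.tsv": _tsv(["A", "B"], _NUCLEATION_ROWS_VALID),
        "nucleation_partial.tsv": _tsv(["A", "B"], _NUCLEATION_ROWS_PARTIAL),
        "nucleation_onerow.tsv": _tsv(["A", "B"], _NUCLEATION_ROWS_VALID[:1]),
        "kup_template.tsv": _tsv(["A", "C", "D"], _KUP_ROWS),
        "nucleation_workflow.yaml": yaml.safe_dump(
            _nucleation_workflow(), sort_keys=True, default_flow_style=False),
        "kup_workflow.yaml": yaml.safe_dump(
            _kup_workflow(), sort_keys=True, default_flow_style=False),
    }
    return files


def make_fixtures(output_dir, seed: int = 0, force: bool = False) -> dict[str, str]:
    """Write the bundle to *output_dir*; returns ``name → sha256`` digests.

    Content is seed-independent (the bundle is a fixed reference corpus);
    *seed* is accepted for interface uniformity.  Refuses to write into an
    existing non-empty directory unless *force* is set.  A ``manifest.json``
    lists every file with its digest.
    """
    out = Path(output_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(
            f"{out} exists and is not empty; pass force=True (--force) to overwrite"
        )
    out.mkdir(parents=True, exist_ok=True)
    digests: dict[str, str] = {}
    for name, content in sorted(fixture_files().items()):
        (out / name).write_text(content, encoding="utf-8")
        digests[name] = hashlib.sha256(content.encode("utf-8")).hexdigest()
    (out / "manifest.json").write_text(
        json.dumps({"seed": seed, "files": digests}, indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return digests
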