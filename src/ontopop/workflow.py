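"""Run a saved workflow end to end: load vocabularies, attach column
validations, execute patterns, write outputs."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .errors import ConfigurationError
from .generator import (
    FIXED_TIMESTAMP,
    GeneratedOntology,
    MintPolicy,
    generate,
    render_manchester,
    serialize_rdf,
)
from .ontology_store import (
    OntologySnapshot,
    PrefixMap,
    RangeSpec,
    ValidationSet,
    load_ontology,
    merge_snapshots,
    resolve_range,
)
from .pattern_lang import PatternScript, parse_pattern
from .template_model import Template
from .workbook_io import WorkflowConfig, read_tsv, read_workbook

__all__ = ["WorkflowContext", "build_context", "run_generation"]


@dataclass
class WorkflowContext:
    """Resolved, ready-to-run form of a :class:`WorkflowConfig`."""

    config: WorkflowConfig
    prefix_map: PrefixMap
    snapshots: dict[str, OntologySnapshot]  # keyed by source path
    merged: OntologySnapshot
    validations: dict[str, ValidationSet]  # column name -> set
    scripts: list[PatternScript]
    policy: MintPolicy


def build_context(config: WorkflowConfig, base_dir) -> WorkflowContext:
    """Load every ontology source and resolve every column range."""
    base = Path(base_dir)
    prefix_map = PrefixMap(config.prefixes)
    snapshots: dict[str, OntologySnapshot] = {}
    for src in config.ontologies:
        path = base / src["path"]
        snapshots[src["path"]] = load_ontology(
            path, src["dialect"], prefix_map=prefix_map
        )
    merged = merge_snapshots(list(snapshots.values()))

    validations: dict[str, ValidationSet] = {}
    for column, spec in config.ranges.items():
        source = spec["ontology"]
        if source not in snapshots:
            raise ConfigurationError(
                f"range for column {column!r} names unloaded ontology {source!r}"
            )
        snap = snapshots[source]
        root_curie = spec.get("root")
        root = None
        if root_curie:
            root = snap.term_by_curie(root_curie)
            if root is None:
                iri = prefix_map.expand(root_curie)
                root = snap.term(iri)
        validations[column] = resolve_range(
            RangeSpec(
                source_ontology=snap.ontology_iri,
                root=root,
                selector=spec.get("selector", "all-subclasses"),
                traversal_relations=frozenset(spec.get("relations", ["subclass"])),
            ),
            snap,
        )

    scripts = [
        parse_pattern(s["text"], identifier=s.get("id", f"script{i+1}"))
        for i, s in enumerate(config.scripts)
    ]
    minting = config.minting
    policy = MintPolicy(
        namespace=minting.get("namespace", "http://purl.org/ontopop/minted#"),
        prefix=minting.get("prefix", "new"),
        width=int(minting.get("width", 7)),
        next_index=int(minting.get("next_index", 1)),
    )
    return WorkflowContext(
        config=config,
        prefix_map=prefix_map,
        snapshots=snapshots,
        merged=merged,
        validations=validations,
        scripts=scripts,
        policy=policy,
    )


def load_template(path, context: WorkflowContext) -> Template:
    """Read a template file (TSV or XLSX) with the context's validations."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        return read_workbook(path)
    return read_tsv(path, validations=context.validations,
                    snapshot=context.merged)


def run_generation(
    template: Template,
    context: WorkflowContext,
    timestamp: str = FIXED_TIMESTAMP,
) -> GeneratedOntology:
    return generate(
        template,
        context.scripts,
        context.config.variable_map,
        context.policy,
        context.merged,
        context.prefix_map,
        ontology_iri=context.config.ontology_iri,
        timestamp=timestamp,
    )


def write_outputs(
    ontology: GeneratedOntology,
    out_dir,
    formats: Mapping[str, bool] | None = None,
) -> dict[str, Path]:
    """Write Manchester text, RDF serializations and the run report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    formats = formats or {"manchester": True, "turtle": True, "rdfxml": False}
    written: dict[str, Path] = {}
    if formats.get("manchester"):
        p = out / "generated.omn"
        p.write_text(render_manchester(ontology), encoding="utf-8")
        written["manchester"] = p
    if formats.get("turtle"):
        p = out / "generated.ttl"
        p.write_text(serialize_rdf(ontology, "turtle"), encoding="utf-8")
        written["turtle"] = p
    if formats.get("rdfxml"):
        p = out / "generated.owl"
        p.write_text(serialize_rdf(ontology, "rdfxml"), encoding="utf-8")
        written["rdfxml"] = p
    report = out / "run_report.tsv"
    lines = ["row\tscript\taxioms_emitted\tminted_terms"]
    for entry in ontology.run_report:
        lines.append(
            f"{entry.row_index}\t{entry.script_id}\t{entry.axioms_emitted}\t"
            + "|".join(entry.minted_labels)
        )
    report.write_text("\n".join(lines) + "\n", encoding="utf-8")
    written["report"] = report
    return written
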