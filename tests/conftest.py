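import pytest

from ontopop.fixtures import DEFAULT_PREFIXES, make_fixtures
from ontopop.ontology_store import PrefixMap, load_ontology
from ontopop.workbook_io import load_workflow
from ontopop.workflow import build_context


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """The miniature vocabulary/template/pattern bundle, written once."""
    out = tmp_path_factory.mktemp("fixtures")
    make_fixtures(out, force=True)
    return out


@pytest.fixture(scope="session")
def prefix_map():
    return PrefixMap(DEFAULT_PREFIXES)


@pytest.fixture(scope="session")
def pato_obo(bundle_dir):
    return load_ontology(bundle_dir / "mini_pato.obo", "obo")


@pytest.fixture(scope="session")
def pato_ttl(bundle_dir, prefix_map):
    return load_ontology(bundle_dir / "mini_pato.ttl", "turtle", prefix_map=prefix_map)


@pytest.fixture(scope="session")
def ma_obo(bundle_dir):
    return load_ontology(bundle_dir / "mini_ma.obo", "obo")


@pytest.fixture(scope="session")
def cto_ttl(bundle_dir, prefix_map):
    return load_ontology(bundle_dir / "mini_cto.ttl", "turtle", prefix_map=prefix_map)


@pytest.fixture(scope="session")
def nucleation_ctx(bundle_dir):
    config = load_workflow(bundle_dir / "nucleation_workflow.yaml")
    return build_context(config, bundle_dir)


@pytest.fixture(scope="session")
def kup_ctx(bundle_dir):
    config = load_workflow(bundle_dir / "kup_workflow.yaml")
    return build_context(config, bundle_dir)


@pytest.fixture(scope="session")
def nucleation_set(pato_ttl, prefix_map):
    """All subclasses of the nucleation quality."""
    from ontopop.ontology_store import RangeSpec, resolve_range

    root = pato_ttl.term(prefix_map.expand("pato:PATO_0001404"))
    return resolve_range(
        RangeSpec(source_ontology=pato_ttl.ontology_iri, root=root), pato_ttl
    )
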