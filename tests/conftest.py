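import pytest

from ontoassay import Ontology
from ontoassay import fixtures as fx
from ontoassay import modules as M


@pytest.fixture(scope="session")
def luciferase_suite():
    return fx.generate_luciferase_suite()


@pytest.fixture(scope="session")
def catalog_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("baomini")
    fx.generate_bao_mini(out, with_abox=True, panel=(3, 2))
    return out


@pytest.fixture(scope="session")
def catalog(catalog_dir):
    return M.ImportCatalog.load(catalog_dir / "catalog.yaml")


@pytest.fixture(scope="session")
def import_graph(catalog):
    return M.build_import_graph(catalog)


@pytest.fixture(scope="session")
def core_perspective(catalog) -> Ontology:
    return M.build_perspective(fx.CORE_PERSPECTIVE_IRI, catalog)


@pytest.fixture(scope="session")
def complete_perspective(catalog) -> Ontology:
    return M.build_perspective(fx.COMPLETE_PERSPECTIVE_IRI, catalog)
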