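"""Layered modularization: import DAG, purity rules, perspectives."""

import pytest

from ontoassay.dl import (
    AnnotationAssertion, Atomic, Declaration, EquivalentClasses, Exists,
    Ontology, RoleRef, SubClassOf, RDFS_LABEL,
)
from ontoassay.modules import (
    ConflictingMappingError, ExtractOptions, ImportCatalog, ImportGraph,
    UnknownSeedError, UnresolvedImportError, ValidationFailure,
    assert_acyclic, build_import_graph, build_perspective,
    check_self_contained, extract_module, make_combinator, validate_artifact,
)
from ontoassay.ofn import OntologyFile, serialize, write_ontology_file
from ontoassay import fixtures as fx
from ontoassay import modules as M


def _write_catalog(tmp_path, files, roots=()):
    """files: {iri: (kind, Ontology)} written to disk plus a catalog."""
    entries = {}
    for i, (iri, (kind, onto)) in enumerate(sorted(files.items())):
        rel = f"f{i}.ofn"
        write_ontology_file(onto, tmp_path / rel)
        entries[iri] = M.CatalogEntry(iri=iri, path=rel, kind=kind)
    cat = ImportCatalog(entries=entries, roots=list(roots),
                        base_dir=tmp_path)
    return cat


class TestImportGraph:
    def test_chain_and_closure(self, tmp_path):
        files = {
            "urn:A": ("module", Ontology("urn:A", direct_imports=["urn:B"])),
            "urn:B": ("module", Ontology("urn:B", direct_imports=["urn:C"])),
            "urn:C": ("module", Ontology("urn:C")),
        }
        g = build_import_graph(_write_catalog(tmp_path, files))
        assert g.edges == {("urn:A", "urn:B"), ("urn:B", "urn:C")}
        assert g.closure("urn:A") == {"urn:A", "urn:B", "urn:C"}

    def test_diamond_counts_shared_import_once(self, tmp_path):
        files = {
            "urn:A": ("module", Ontology("urn:A",
                                         direct_imports=["urn:B", "urn:C"])),
            "urn:B": ("module", Ontology("urn:B", direct_imports=["urn:D"])),
            "urn:C": ("module", Ontology("urn:C", direct_imports=["urn:D"])),
            "urn:D": ("module", Ontology("urn:D")),
        }
        g = build_import_graph(_write_catalog(tmp_path, files))
        assert len(g.closure("urn:A")) == 4

    def test_unresolved_import_is_named(self, tmp_path):
        files = {"urn:A": ("module",
                           Ontology("urn:A", direct_imports=["urn:GONE"]))}
        with pytest.raises(UnresolvedImportError, match="GONE"):
            build_import_graph(_write_catalog(tmp_path, files))

    def test_full_catalog_closure_is_the_whole_file_set(self, catalog,
                                                        import_graph):
        closure = import_graph.closure(fx.COMPLETE_PERSPECTIVE_IRI)
        assert closure == set(catalog.entries)


class TestAcyclicity:
    def test_two_cycle_reported(self, tmp_path):
        files = {
            "urn:A": ("module", Ontology("urn:A", direct_imports=["urn:B"])),
            "urn:B": ("module", Ontology("urn:B", direct_imports=["urn:A"])),
        }
        rep = assert_acyclic(build_import_graph(_write_catalog(tmp_path,
                                                               files)))
        assert not rep.passed
        assert any(r == "acyclic-imports" for r, _, _ in rep.violations)

    def test_self_import_reported(self, tmp_path):
        files = {"urn:A": ("module",
                           Ontology("urn:A", direct_imports=["urn:A"]))}
        rep = assert_acyclic(build_import_graph(_write_catalog(tmp_path,
                                                               files)))
        assert not rep.passed

    def test_tree_passes(self, import_graph):
        assert assert_acyclic(import_graph).passed


class TestPurityRules:
    def test_vocabulary_rejects_complex_subsumption(self):
        onto = Ontology("urn:v", axioms=[
            Declaration("Class", "urn:A"), Declaration("Class", "urn:B"),
            SubClassOf(Atomic("urn:A"),
                       Exists(RoleRef("urn:r"), Atomic("urn:B")))])
        rep = validate_artifact(OntologyFile(None, "urn:v", onto,
                                             kind="vocabulary"))
        assert not rep.passed
        assert rep.violations[0][0] == "vocabulary-subsumption-only"

    def test_axiomfile_rejects_class_declarations(self):
        onto = Ontology("urn:x", axioms=[Declaration("Class", "urn:A")])
        rep = validate_artifact(OntologyFile(None, "urn:x", onto,
                                             kind="axiomfile"))
        assert not rep.passed
        assert rep.violations[0][0] == "axiomfile-no-declarations"

    def test_axiomfile_allows_named_individuals(self):
        onto = Ontology("urn:x", axioms=[
            Declaration("NamedIndividual", "urn:i")])
        assert validate_artifact(OntologyFile(None, "urn:x", onto,
                                              kind="axiomfile")).passed

    def test_pure_taxonomy_passes(self):
        onto = Ontology("urn:v", axioms=[
            Declaration("Class", "urn:A"), Declaration("Class", "urn:B"),
            SubClassOf(Atomic("urn:A"), Atomic("urn:B")),
            AnnotationAssertion("urn:A", RDFS_LABEL, "a")])
        assert validate_artifact(OntologyFile(None, "urn:v", onto,
                                              kind="vocabulary")).passed

    def test_combinator_requires_cross_namespace_atomic_bridges(self):
        same_ns = Ontology("urn:c", axioms=[
            EquivalentClasses(Atomic("urn:x#A"), Atomic("urn:x#B"))])
        rep = validate_artifact(OntologyFile(None, "urn:c", same_ns,
                                             kind="combinator"))
        assert any(r == "combinator-cross-namespace"
                   for r, _, _ in rep.violations)
        complex_bridge = Ontology("urn:c", axioms=[
            SubClassOf(Atomic("urn:x#A"),
                       Exists(RoleRef("urn:r"), Atomic("urn:y#B")))])
        rep2 = validate_artifact(OntologyFile(None, "urn:c", complex_bridge,
                                              kind="combinator"))
        assert any(r == "combinator-atomic-bridges-only"
                   for r, _, _ in rep2.violations)

    def test_every_generated_file_passes_its_rule(self, import_graph):
        for iri in sorted(import_graph.files):
            rep = validate_artifact(import_graph.files[iri])
            assert rep.passed, (iri, rep.violations)


class TestSelfContainedness:
    def test_undeclared_reference_is_listed(self, tmp_path):
        onto = Ontology("urn:m", axioms=[
            SubClassOf(Atomic("urn:known"), Atomic("urn:ghost")),
            Declaration("Class", "urn:known")])
        cat = _write_catalog(tmp_path, {"urn:m": ("module", onto)})
        rep = check_self_contained(
            build_import_graph(cat).files["urn:m"], cat)
        assert not rep.passed
        assert any("ghost" in subj for _, subj, _ in rep.violations)

    def test_empty_file_is_self_contained(self, tmp_path):
        cat = _write_catalog(tmp_path,
                             {"urn:m": ("module", Ontology("urn:m"))})
        rep = check_self_contained(
            build_import_graph(cat).files["urn:m"], cat)
        assert rep.passed

    def test_generated_core_and_complete_are_self_contained(
            self, import_graph):
        for root in (fx.CORE_PERSPECTIVE_IRI, fx.COMPLETE_PERSPECTIVE_IRI):
            rep = check_self_contained(import_graph.files[root],
                                       import_graph)
            assert rep.passed, rep.violations


class TestPerspectives:
    def test_merge_is_the_union_of_closure_axiom_sets(self, catalog,
                                                      import_graph,
                                                      core_perspective):
        expected = set()
        for iri in import_graph.closure(fx.CORE_PERSPECTIVE_IRI):
            expected |= import_graph.files[iri].ontology.all_axioms()
        assert core_perspective.all_axioms() == expected
        assert not core_perspective.direct_imports

    def test_build_is_deterministic(self, catalog):
        a = build_perspective(fx.CORE_PERSPECTIVE_IRI, catalog)
        b = build_perspective(fx.CORE_PERSPECTIVE_IRI, catalog)
        assert serialize(a, fx.FIXTURE_POLICY) == \
            serialize(b, fx.FIXTURE_POLICY)

    def test_catalog_order_permutation_changes_nothing(self, catalog):
        shuffled = ImportCatalog(
            entries=dict(sorted(catalog.entries.items(), reverse=True)),
            roots=list(catalog.roots), base_dir=catalog.base_dir)
        a = build_perspective(fx.COMPLETE_PERSPECTIVE_IRI, catalog)
        b = build_perspective(fx.COMPLETE_PERSPECTIVE_IRI, shuffled)
        assert serialize(a, fx.FIXTURE_POLICY) == \
            serialize(b, fx.FIXTURE_POLICY)

    def test_validation_failure_aborts_build(self, tmp_path):
        bad = Ontology("urn:v", axioms=[
            Declaration("Class", "urn:A"),
            SubClassOf(Atomic("urn:A"),
                       Exists(RoleRef("urn:r"), Atomic("urn:A")))])
        cat = _write_catalog(tmp_path, {"urn:v": ("vocabulary", bad)})
        with pytest.raises(ValidationFailure):
            build_perspective("urn:v", cat)


class TestModuleExtraction:
    @pytest.fixture
    def taxonomy(self):
        return Ontology("urn:ext", axioms=[
            Declaration("Class", "urn:root"),
            Declaration("Class", "urn:X"), Declaration("Class", "urn:Y"),
            Declaration("Class", "urn:Z"),
            SubClassOf(Atomic("urn:X"), Atomic("urn:root")),
            SubClassOf(Atomic("urn:Y"), Atomic("urn:X")),
            SubClassOf(Atomic("urn:Z"), Atomic("urn:root")),
            AnnotationAssertion("urn:Y", RDFS_LABEL, "why")])

    def test_upward_closure(self, taxonomy):
        mod = extract_module(taxonomy, {"urn:Y"})
        sig = {d.iri for d in mod.declarations}
        assert sig == {"urn:Y", "urn:X", "urn:root"}
        assert len(mod.tbox) == 2

    def test_empty_seed_set_gives_empty_module(self, taxonomy):
        mod = extract_module(taxonomy, set())
        assert not mod.all_axioms()

    def test_annotations_copied_verbatim_when_requested(self, taxonomy):
        mod = extract_module(taxonomy, {"urn:Y"},
                             ExtractOptions(annotations=True))
        assert AnnotationAssertion("urn:Y", RDFS_LABEL, "why") in \
            mod.annotations
        bare = extract_module(taxonomy, {"urn:Y"},
                              ExtractOptions(annotations=False))
        assert not bare.annotations

    def test_monotone_in_seeds(self, taxonomy):
        small = extract_module(taxonomy, {"urn:Y"})
        big = extract_module(taxonomy, {"urn:Y", "urn:Z"})
        assert small.all_axioms() <= big.all_axioms()

    def test_unknown_seed_raises(self, taxonomy):
        with pytest.raises(UnknownSeedError):
            extract_module(taxonomy, {"urn:nope"})


class TestCombinators:
    def test_equivalence_and_subsumption_bridges(self):
        onto = make_combinator([
            ("urn:a#cell", "urn:b#cell", "equivalent"),
            ("urn:a#kinase", "urn:b#protein_kinase", "subclass"),
            ("urn:a#thing", "urn:b#item", "superclass"),
        ])
        assert EquivalentClasses(Atomic("urn:a#cell"),
                                 Atomic("urn:b#cell")) in onto.tbox
        assert SubClassOf(Atomic("urn:a#kinase"),
                          Atomic("urn:b#protein_kinase")) in onto.tbox
        assert SubClassOf(Atomic("urn:b#item"),
                          Atomic("urn:a#thing")) in onto.tbox

    def test_empty_mapping_list(self):
        assert not make_combinator([]).all_axioms()

    def test_conflicting_duplicate_is_an_error(self):
        with pytest.raises(ConflictingMappingError):
            make_combinator([("urn:a#x", "urn:b#x", "equivalent"),
                             ("urn:a#x", "urn:b#x", "subclass")])

    def test_generated_combinator_validates(self):
        onto = make_combinator(fx.COMBINATOR_MAPPINGS, iri="urn:c")
        rep = validate_artifact(OntologyFile(None, "urn:c", onto,
                                             kind="combinator"))
        assert rep.passed, rep.violations
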