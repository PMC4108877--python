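"""The generated mini ontology: counts, entailments, panel structure."""

import hashlib
from pathlib import Path

import networkx as nx
import pytest

from ontoassay.dl import Atomic, EquivalentClasses, SubClassOf, signature_of
from ontoassay.reasoner import KnowledgeBase, check_subsumption, classify
from ontoassay import fixtures as fx


class TestCatalogShape:
    def test_six_component_vocabularies(self, catalog):
        assert fx.component_vocabulary_count(catalog) == 6

    def test_eleven_external_stubs(self, catalog):
        assert fx.external_stub_count(catalog) == 11
        assert len(fx.EXTERNAL_SOURCES) == 11

    def test_generation_is_bit_deterministic(self, catalog_dir, tmp_path):
        fx.generate_bao_mini(tmp_path / "again", with_abox=True,
                             panel=(3, 2))
        for p in sorted(catalog_dir.rglob("*.ofn")):
            q = tmp_path / "again" / p.relative_to(catalog_dir)
            assert hashlib.sha256(p.read_bytes()).hexdigest() == \
                hashlib.sha256(q.read_bytes()).hexdigest(), p.name

    def test_cell_cycle_terms_are_declared(self, import_graph):
        method = import_graph.files[fx.DOC + "vocab/assay_method"].ontology
        endpoint = import_graph.files[fx.DOC + "vocab/assay_endpoint"]\
            .ontology
        declared = {d.iri for d in method.declarations} | \
                   {d.iri for d in endpoint.declarations}
        for term in ("s_phase_assessment_method", "m_phase_assessment_method",
                     "fluorescence_microscopy", "intensity_parameter",
                     "counting_parameter", "percent_apoptotic_cells",
                     "percent_mitotic_cells", "percent_interphase_cells",
                     "percent_dna_replicated_cells",
                     "percent_g2_arrested_cells",
                     "percent_mitotic_arrested_cells"):
            assert fx.b(term) in declared, term


class TestLuciferaseSuite:
    def test_all_five_assays_classify_under_uses_luciferase(
            self, luciferase_suite):
        h = classify(KnowledgeBase(luciferase_suite))
        children = h.direct_subclasses(fx.b("bioassay_uses_luciferase"))
        assert children == {fx.b(a) for a in fx.LUCIFERASE_ASSAYS}

    def test_membership_is_inference_only(self, luciferase_suite):
        bul = fx.b("bioassay_uses_luciferase")
        for ax in luciferase_suite.tbox:
            if isinstance(ax, SubClassOf) and isinstance(ax.sup, Atomic):
                assert ax.sup.iri != bul

    def test_design_method_pair_inferred_not_asserted(self,
                                                      luciferase_suite):
        coupled = fx.b("atp_coupled_enzyme_activity_measurement_method")
        quant = fx.b("atp_quantitation_using_luciferase")
        asserted = any(
            isinstance(ax, SubClassOf) and isinstance(ax.sub, Atomic)
            and isinstance(ax.sup, Atomic)
            and (ax.sub.iri, ax.sup.iri) == (coupled, quant)
            for ax in luciferase_suite.tbox)
        assert not asserted
        assert check_subsumption(KnowledgeBase(luciferase_suite),
                                 Atomic(coupled), Atomic(quant))

    def test_each_assay_has_its_own_design_method(self, luciferase_suite):
        methods = {dm for dm, _fmt in fx._ASSAY_DESIGN.values()}
        assert len(methods) == 5


class TestMeasureGroupAxioms:
    def test_subsumption_is_entailed(self, core_perspective):
        kb = KnowledgeBase(core_perspective)
        assert check_subsumption(kb, Atomic(fx.b("measure_group")),
                                 Atomic(fx.b("bioassay")))

    def test_no_asserted_atomic_subsumption(self, core_perspective):
        mg, bio = fx.b("measure_group"), fx.b("bioassay")
        for ax in core_perspective.tbox:
            if isinstance(ax, SubClassOf) and isinstance(ax.sub, Atomic) \
                    and isinstance(ax.sup, Atomic):
                assert (ax.sub.iri, ax.sup.iri) != (mg, bio)

    def test_removing_the_bioassay_definition_breaks_the_entailment(self):
        axioms = fx.generate_measure_group_axioms()
        definition = next(a for a in axioms
                          if isinstance(a, EquivalentClasses))
        from ontoassay.reasoner import _entails
        ent = SubClassOf(Atomic(fx.b("measure_group")),
                         Atomic(fx.b("bioassay")))
        assert _entails(axioms, ent)
        assert not _entails(axioms - {definition}, ent)


class TestPanelAssay:
    @pytest.mark.parametrize("m,n", [(1, 1), (3, 2), (2, 5)])
    def test_measure_group_count_formula(self, m, n):
        onto = fx.generate_panel_assay(fx.PanelSpec(m, n))
        dag = fx.panel_measure_group_dag(onto)
        assert dag.number_of_nodes() == m * n + n + 1

    def test_count_formula_exhaustively_to_five(self):
        for m in range(1, 6):
            for n in range(1, 6):
                onto = fx.generate_panel_assay(fx.PanelSpec(m, n))
                dag = fx.panel_measure_group_dag(onto)
                assert dag.number_of_nodes() == m * n + n + 1, (m, n)

    def test_two_level_aggregation_dag(self):
        m, n = 3, 2
        dag = fx.panel_measure_group_dag(
            fx.generate_panel_assay(fx.PanelSpec(m, n)))
        assert nx.is_directed_acyclic_graph(dag)
        bases = [v for v in dag if dag.out_degree(v) == 0]
        tops = [v for v in dag if dag.in_degree(v) == 0]
        assert len(bases) == m * n
        assert len(tops) == 1
        # top aggregates the n per-target groups, each aggregating m bases
        (top,) = tops
        mids = list(dag.successors(top))
        assert len(mids) == n
        for mid in mids:
            assert dag.out_degree(mid) == m

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            fx.PanelSpec(0, 2)

    def test_measure_groups_classify_under_bioassay(self):
        onto = fx.generate_panel_assay(fx.PanelSpec(2, 2))
        h = classify(KnowledgeBase(onto))
        for node in fx.panel_measure_group_dag(onto):
            assert h.is_subsumed(node, fx.b("bioassay")), node

    def test_endpoint_values_follow_the_generator_formula(self):
        onto = fx.generate_panel_assay(fx.PanelSpec(2, 3))
        values = {ax.subject.rsplit("#", 1)[1]: ax.value
                  for ax in onto.abox if hasattr(ax, "value")}
        assert values == {f"ep_ic50_k{j}": 0.5 * (j + 1)
                          for j in (1, 2, 3)}


class TestSpecValidation:
    def test_measure_group_spec_requires_known_parameter(self):
        with pytest.raises(ValueError):
            fx.MeasureGroupSpec(id="x", varied_parameter="volume")

    def test_endpoint_spec_requires_a_measure_group(self):
        with pytest.raises(ValueError):
            fx.EndpointSpec(id="e", category="ic50",
                            mode_of_action="inhibition",
                            signal_direction="decrease",
                            endpoint_action_correlation="inverse",
                            value=1.0, unit="u", measure_groups=[])
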