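"""Deterministic generator of the "mini" bioassay ontology.

This module emits a small, fully self-contained layered ontology that
emulates the structure of a production bioassay ontology: six component
vocabularies (bioassay, assay biology, assay method, assay format, assay
endpoint, screened entity) plus a property vocabulary, a core gluing
module, axiom files, eleven external stub ontologies with a combinator
layer, and two buildable perspectives (core-only and complete).

The substance encoded here is the assay-classification test bed:

* five mechanistically related luciferase assays, each annotated with a
  *different* assay design method but all relying on the
  luciferase-catalyzed reaction of luciferin and ATP — so a defined class
  ``bioassay uses luciferase`` (bioassay ⊓ ∃'has assay method'.('assay
  design method' ⊓ ∃'has participant'.'Luciferin 4-monooxygenase'))
  collects all five by inference alone;
* the design-method pair ``ATP quantitation using luciferase`` (defined
  with necessary-and-sufficient participant conditions) and ``ATP coupled
  enzyme activity measurement method`` (asserted conditions only), whose
  subsumption is derivable but never asserted;
* the measure-group axiomatization: ``bioassay`` carries a definition over
  its assay-method and endpoint restrictions and ``measure group`` is
  asserted to satisfy exactly those conditions, so the reasoner infers
  measure group ⊑ bioassay without any asserted atomic subsumption;
* an m×n kinase concentration-response profiling panel built by two-stage
  measure-group aggregation: m·n base measure groups (concentration ×
  target), n concentration-response aggregates (each carrying an IC50
  endpoint) and one profile aggregate, m·n + n + 1 groups in total.

Generation uses no randomness: two runs produce identical canonical bytes.
The separate :func:`random_ontology` generator (seeded) produces the tiny
random TBoxes used by the tableau-vs-model-search soundness suite.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx

from .dl import (
    And, AnnotationAssertion, Atomic, Axiom, ClassAssertion, ConceptExpr,
    DataAssertion, Declaration, DisjointClasses, EquivalentClasses, Exists,
    Forall, Not, ObjectPropertyAssertion, Ontology, Or, RDFS_LABEL, RoleRef,
    SubClassOf, SubObjectPropertyOf, signature_of,
)
from .modules import CatalogEntry, ImportCatalog
from .ofn import SerializationPolicy, write_ontology_file

# ---------------------------------------------------------------------------
# Namespaces
# ---------------------------------------------------------------------------

BAO = "http://example.org/bao-mini#"
DOC = "http://example.org/bao-mini/"
ABOX_NS = "http://example.org/bao-mini/abox#"

EXTERNAL_SOURCES = ("go", "clo", "uo", "ncbitaxon", "doid", "chebi",
                    "uberon", "pato", "iao", "ro", "bfo")

EXT_NS = {src: f"http://example.org/ext/{src}#" for src in EXTERNAL_SOURCES}
EXT_DOC = {src: f"http://example.org/ext/{src}" for src in EXTERNAL_SOURCES}


def b(local: str) -> str:
    """IRI of an internal term."""
    return BAO + local


def ext(src: str, local: str) -> str:
    return EXT_NS[src] + local


FIXTURE_POLICY = SerializationPolicy(prefixes={
    "bao": BAO, "abox": ABOX_NS,
    **{src: ns for src, ns in EXT_NS.items()},
})

# display labels that differ from the plain underscores-to-spaces form
_LABEL_OVERRIDES = {
    "luciferin_4_monooxygenase": "Luciferin 4-monooxygenase",
    "atp": "ATP",
    "dna": "DNA",
    "ic50": "IC50",
    "cytochrome_p450": "cytochrome P450",
    "cytochrome_p450_enzyme_activity_assay":
        "cytochrome P450 enzyme activity assay",
    "ic50_kinase_profile_endpoint": "IC50 kinase profile endpoint",
    "percent_g2_arrested_cells": "percent G2 arrested cells",
    "s_phase_assessment_method": "S phase assessment method",
    "m_phase_assessment_method": "M phase assessment method",
}


def term_label(local: str) -> str:
    return _LABEL_OVERRIDES.get(local, local.replace("_", " "))


# ---------------------------------------------------------------------------
# Vocabulary contents
# ---------------------------------------------------------------------------

# (component name, {term: parent-or-None}); parents are within the same file.
_COMPONENT_VOCABS: Dict[str, Dict[str, Optional[str]]] = {
    "bioassay": {
        "bioassay": None,
        "measure_group": None,
        "bioassay_uses_luciferase": None,
        "enzyme_activity_assay": "bioassay",
        "cell_viability_assay": "bioassay",
        "binding_assay": "bioassay",
        "gene_expression_assay": "bioassay",
        "cell_cycle_state_assay": "bioassay",
        "luciferase_reporter_gene_assay": "bioassay",
        "cell_viability_atp_quantitation_assay": "bioassay",
        "cytochrome_p450_enzyme_activity_assay": "bioassay",
        "kinase_activity_assay": "bioassay",
        "luciferase_enzyme_activity_assay": "bioassay",
        "kinase_concentration_response_profiling_panel_assay": "bioassay",
    },
    "assay_biology": {
        "biological_macromolecule": None,
        "protein": "biological_macromolecule",
        "kinase": "protein",
        "cytochrome_p450": "protein",
        "luciferin_4_monooxygenase": "protein",
        "dna": "biological_macromolecule",
        "biological_process": None,
        "cell_line_cell": None,
        "organism": None,
        "disease": None,
        "anatomical_entity": None,
        "quality": None,
    },
    "assay_method": {
        "assay_method": None,
        "assay_design_method": "assay_method",
        "physical_detection_method": "assay_method",
        "assay_readout_parameter": "assay_method",
        "intensity_parameter": "assay_readout_parameter",
        "counting_parameter": "assay_readout_parameter",
        "chemiluminescence": "physical_detection_method",
        "fluorescence_microscopy": "physical_detection_method",
        "s_phase_assessment_method": "assay_design_method",
        "m_phase_assessment_method": "assay_design_method",
        "atp_quantitation_using_luciferase": "assay_design_method",
        "atp_coupled_enzyme_activity_measurement_method":
            "assay_design_method",
        "luciferase_gene_expression_measurement_method":
            "assay_design_method",
        "luciferin_coupled_enzyme_activity_measurement_method":
            "assay_design_method",
        "luciferase_enzyme_activity_measurement_method":
            "assay_design_method",
    },
    "assay_format": {
        "assay_format": None,
        "cell_based_format": "assay_format",
        "biochemical_format": "assay_format",
    },
    "assay_endpoint": {
        "endpoint": None,
        "concentration_endpoint": "endpoint",
        "concentration_response_endpoint": "concentration_endpoint",
        "response_endpoint": "endpoint",
        "profile_endpoint": "endpoint",
        "physical_property_endpoint": "endpoint",
        "ic50": "concentration_response_endpoint",
        "percent_inhibition": "response_endpoint",
        "percent_activation": "response_endpoint",
        "ic50_kinase_profile_endpoint": "profile_endpoint",
        "percent_apoptotic_cells": "response_endpoint",
        "percent_mitotic_cells": "response_endpoint",
        "percent_interphase_cells": "response_endpoint",
        "percent_dna_replicated_cells": "response_endpoint",
        "percent_g2_arrested_cells": "response_endpoint",
        "percent_mitotic_arrested_cells": "response_endpoint",
        "mode_of_action": None,
        "ligand_function_mode_of_action": "mode_of_action",
        "inhibition": "ligand_function_mode_of_action",
        "activation": "ligand_function_mode_of_action",
        "signal_direction": None,
        "signal_increase": "signal_direction",
        "signal_decrease": "signal_direction",
        "endpoint_action_correlation": None,
        "direct_correlation": "endpoint_action_correlation",
        "inverse_correlation": "endpoint_action_correlation",
        "unit": None,
        "concentration_unit": "unit",
        "micromolar": "concentration_unit",
        "percent": "unit",
    },
    "assay_screened_entity": {
        "screened_entity": None,
        "molecular_entity": None,
        "small_molecule": "molecular_entity",
        "atp": "small_molecule",
        "luciferin": "small_molecule",
    },
}

OBJECT_PROPERTIES: Dict[str, Optional[str]] = {
    "has_assay_method": None,
    "has_assay_design_method": "has_assay_method",
    "has_physical_detection_method": "has_assay_method",
    "has_participant": None,
    "has_endpoint": None,
    "has_measure_group": None,
    "is_derived_from": None,
    "has_assay_format": None,
    "has_mode_of_action": None,
    "has_signal_direction": None,
    "has_endpoint_action_correlation": None,
}

DATA_PROPERTIES = ("has_value",)

LUCIFERASE_ASSAYS = (
    "luciferase_reporter_gene_assay",
    "cell_viability_atp_quantitation_assay",
    "cytochrome_p450_enzyme_activity_assay",
    "kinase_activity_assay",
    "luciferase_enzyme_activity_assay",
)

#: assay -> (design method, assay format)
_ASSAY_DESIGN = {
    "luciferase_reporter_gene_assay":
        ("luciferase_gene_expression_measurement_method", "cell_based_format"),
    "cell_viability_atp_quantitation_assay":
        ("atp_quantitation_using_luciferase", "cell_based_format"),
    "cytochrome_p450_enzyme_activity_assay":
        ("luciferin_coupled_enzyme_activity_measurement_method",
         "biochemical_format"),
    "kinase_activity_assay":
        ("atp_coupled_enzyme_activity_measurement_method",
         "biochemical_format"),
    "luciferase_enzyme_activity_assay":
        ("luciferase_enzyme_activity_measurement_method",
         "biochemical_format"),
}


def _vocab_axioms(terms: Dict[str, Optional[str]],
                  kind: str = "Class") -> List[Axiom]:
    out: List[Axiom] = []
    for local, parent in terms.items():
        out.append(Declaration(kind, b(local)))
        out.append(AnnotationAssertion(b(local), RDFS_LABEL,
                                       term_label(local)))
        if parent is not None:
            if kind == "Class":
                out.append(SubClassOf(Atomic(b(local)), Atomic(b(parent))))
            else:
                out.append(SubObjectPropertyOf(RoleRef(b(local)),
                                               RoleRef(b(parent))))
    return out


def component_vocabulary(name: str) -> Ontology:
    """One of the six component vocabularies, as a standalone ontology."""
    return Ontology(iri=DOC + "vocab/" + name,
                    axioms=_vocab_axioms(_COMPONENT_VOCABS[name]))


def properties_vocabulary() -> Ontology:
    axioms = _vocab_axioms(OBJECT_PROPERTIES, kind="ObjectProperty")
    for local in DATA_PROPERTIES:
        axioms.append(Declaration("DataProperty", b(local)))
        axioms.append(AnnotationAssertion(b(local), RDFS_LABEL,
                                          term_label(local)))
    return Ontology(iri=DOC + "vocab/properties", axioms=axioms)


# ---------------------------------------------------------------------------
# Axiom files
# ---------------------------------------------------------------------------

def generate_measure_group_axioms() -> Set[Axiom]:
    """The overlapping bioassay / measure-group axiomatization.

    ``bioassay`` receives a necessary-and-sufficient definition over its
    assay-method and endpoint restrictions; ``measure group`` is asserted
    to satisfy exactly those conditions but carries no asserted subsumption
    to bioassay — the subclass relation is derivable only by reasoning, as
    a simple assertion of the equivalence would be wrong (an assay can own
    many measure groups).
    """
    bioassay_def = And(
        Exists(RoleRef(b("has_assay_method")), Atomic(b("assay_method"))),
        Exists(RoleRef(b("has_endpoint")), Atomic(b("endpoint"))),
    )
    return {
        EquivalentClasses(Atomic(b("bioassay")), bioassay_def),
        SubClassOf(Atomic(b("measure_group")),
                   Exists(RoleRef(b("has_assay_method")),
                          Atomic(b("assay_method")))),
        SubClassOf(Atomic(b("measure_group")),
                   Exists(RoleRef(b("has_endpoint")),
                          Atomic(b("endpoint")))),
    }


def _luciferase_axioms() -> Set[Axiom]:
    """Defined classes and assay restrictions behind the luciferase suite."""
    luc = Atomic(b("luciferin_4_monooxygenase"))
    atp = Atomic(b("atp"))
    adm = Atomic(b("assay_design_method"))
    hp = RoleRef(b("has_participant"))
    axioms: Set[Axiom] = set()

    # bioassay uses luciferase ≡
    #   bioassay ⊓ ∃'has assay method'.('assay design method' ⊓
    #                                   ∃'has participant'.luciferase)
    axioms.add(EquivalentClasses(
        Atomic(b("bioassay_uses_luciferase")),
        And(Atomic(b("bioassay")),
            Exists(RoleRef(b("has_assay_method")),
                   And(adm, Exists(hp, luc))))))

    # ATP quantitation using luciferase: full definition.
    axioms.add(EquivalentClasses(
        Atomic(b("atp_quantitation_using_luciferase")),
        And(adm, Exists(hp, atp), Exists(hp, luc))))

    # ATP coupled enzyme activity measurement: asserted conditions only;
    # its subsumption under the class above is inference-only.
    coupled = Atomic(b("atp_coupled_enzyme_activity_measurement_method"))
    axioms.add(SubClassOf(coupled, Exists(hp, atp)))
    axioms.add(SubClassOf(coupled, Exists(hp, luc)))

    for dm in ("luciferase_gene_expression_measurement_method",
               "luciferase_enzyme_activity_measurement_method",
               "luciferin_coupled_enzyme_activity_measurement_method"):
        axioms.add(SubClassOf(Atomic(b(dm)), Exists(hp, luc)))
    axioms.add(SubClassOf(
        Atomic(b("luciferin_coupled_enzyme_activity_measurement_method")),
        Exists(hp, Atomic(b("luciferin")))))

    for assay, (dm, fmt) in _ASSAY_DESIGN.items():
        axioms.add(SubClassOf(
            Atomic(b(assay)),
            Exists(RoleRef(b("has_assay_design_method")), Atomic(b(dm)))))
        axioms.add(SubClassOf(
            Atomic(b(assay)),
            Exists(RoleRef(b("has_physical_detection_method")),
                   Atomic(b("chemiluminescence")))))
        axioms.add(SubClassOf(
            Atomic(b(assay)),
            Exists(RoleRef(b("has_assay_format")), Atomic(b(fmt)))))
    return axioms


def generate_luciferase_suite() -> Ontology:
    """Self-contained ontology of the five luciferase assays.

    Each assay is a told bioassay with its own distinct design method and
    the shared chemiluminescence detection; the luciferase participant
    reaches every design method either by direct assertion or, for the
    ATP-coupled method, through its inferred defined superclass.  Nothing
    is asserted below ``bioassay uses luciferase`` — membership is
    inference-only.
    """
    needed_classes = {
        "bioassay": None, "bioassay_uses_luciferase": None,
        "assay_method": None,
        "assay_design_method": "assay_method",
        "physical_detection_method": "assay_method",
        "chemiluminescence": "physical_detection_method",
        "assay_format": None,
        "cell_based_format": "assay_format",
        "biochemical_format": "assay_format",
        "protein": None,
        "luciferin_4_monooxygenase": "protein",
        "small_molecule": None,
        "atp": "small_molecule",
        "luciferin": "small_molecule",
    }
    for assay in LUCIFERASE_ASSAYS:
        needed_classes[assay] = "bioassay"
    for dm, _fmt in _ASSAY_DESIGN.values():
        needed_classes[dm] = "assay_design_method"
    needed_roles = {
        "has_assay_method": None,
        "has_assay_design_method": "has_assay_method",
        "has_physical_detection_method": "has_assay_method",
        "has_participant": None,
        "has_assay_format": None,
        "has_endpoint": None,
    }
    axioms = _vocab_axioms(needed_classes)
    axioms += _vocab_axioms(needed_roles, kind="ObjectProperty")
    onto = Ontology(iri=DOC + "examples/luciferase", axioms=axioms)
    for ax in _luciferase_axioms():
        onto.add(ax)
    return onto


# ---------------------------------------------------------------------------
# Panel / profile assays
# ---------------------------------------------------------------------------

@dataclass
class PanelSpec:
    """An m×n concentration-response panel: m concentrations, n targets."""

    m: int
    n: int
    target_kind: str = b("kinase")

    def __post_init__(self):
        if self.m < 1 or self.n < 1:
            raise ValueError("panel requires m >= 1 and n >= 1")


@dataclass
class MeasureGroupSpec:
    id: str
    varied_parameter: str  # "concentration" or "target"
    derived_from: List[str] = field(default_factory=list)

    def __post_init__(self):
        if self.varied_parameter not in {"concentration", "target"}:
            raise ValueError(
                f"unknown varied parameter {self.varied_parameter!r}")


@dataclass
class EndpointSpec:
    id: str
    category: str  # concentration / response / profile endpoint class
    mode_of_action: str
    signal_direction: str
    endpoint_action_correlation: str
    value: float
    unit: str
    measure_groups: List[str] = field(default_factory=list)

    def __post_init__(self):
        if self.signal_direction not in {"increase", "decrease"}:
            raise ValueError("signal direction is increase or decrease")
        if self.endpoint_action_correlation not in {"direct", "inverse"}:
            raise ValueError("correlation is direct or inverse")
        if not self.measure_groups:
            raise ValueError("an endpoint references >= 1 measure group")


def _panel_ic50(j: int) -> float:
    # fixed synthetic formula: target j gets IC50 = 0.5 * (j + 1) micromolar
    return 0.5 * (j + 1)


def generate_panel_assay(spec: PanelSpec) -> Ontology:
    """Two-stage measure-group aggregation for a kinase profiling panel.

    Base layer: one measure group per concentration × target pair.  First
    aggregation (over concentrations, via curve fitting in a real assay)
    yields one derived measure group per target carrying an IC50
    concentration-response endpoint; the second aggregation yields a single
    profile measure group carrying the IC50 kinase-profile endpoint.
    Total measure groups: m·n + n + 1.

    The output is self-contained: it embeds the measure-group
    axiomatization, so classifying it infers every measure-group class
    under ``bioassay``.
    """
    m, n = spec.m, spec.n
    terms = {
        "bioassay": None, "measure_group": None,
        "assay_method": None, "assay_design_method": "assay_method",
        "atp_coupled_enzyme_activity_measurement_method":
            "assay_design_method",
        "endpoint": None,
        "concentration_endpoint": "endpoint",
        "concentration_response_endpoint": "concentration_endpoint",
        "ic50": "concentration_response_endpoint",
        "profile_endpoint": "endpoint",
        "ic50_kinase_profile_endpoint": "profile_endpoint",
        "mode_of_action": None,
        "ligand_function_mode_of_action": "mode_of_action",
        "inhibition": "ligand_function_mode_of_action",
        "signal_direction": None, "signal_decrease": "signal_direction",
        "endpoint_action_correlation": None,
        "inverse_correlation": "endpoint_action_correlation",
        "unit": None, "concentration_unit": "unit",
        "micromolar": "concentration_unit",
        "protein": None, "kinase": "protein",
        "kinase_concentration_response_profiling_panel_assay": "bioassay",
    }
    roles = {
        "has_assay_method": None,
        "has_endpoint": None,
        "has_measure_group": None,
        "is_derived_from": None,
        "has_mode_of_action": None,
        "has_signal_direction": None,
        "has_endpoint_action_correlation": None,
    }
    axioms = _vocab_axioms(terms) + _vocab_axioms(roles, kind="ObjectProperty")
    axioms.append(Declaration("DataProperty", b("has_value")))
    onto = Ontology(iri=DOC + "examples/panel", axioms=axioms)
    for ax in generate_measure_group_axioms():
        onto.add(ax)

    mg = Atomic(b("measure_group"))
    derive = RoleRef(b("is_derived_from"))
    he = RoleRef(b("has_endpoint"))

    # targets
    for j in range(1, n + 1):
        onto.add(Declaration("Class", b(f"panel_kinase_{j}")))
        onto.add(AnnotationAssertion(b(f"panel_kinase_{j}"), RDFS_LABEL,
                                     f"panel kinase {j}"))
        onto.add(SubClassOf(Atomic(b(f"panel_kinase_{j}")),
                            Atomic(b("kinase"))))

    base_specs: List[MeasureGroupSpec] = []
    derived_specs: List[MeasureGroupSpec] = []
    for j in range(1, n + 1):
        for i in range(1, m + 1):
            base_specs.append(MeasureGroupSpec(
                id=f"mg_c{i}_k{j}", varied_parameter="concentration"))
        derived_specs.append(MeasureGroupSpec(
            id=f"mg_ic50_k{j}", varied_parameter="concentration",
            derived_from=[f"mg_c{i}_k{j}" for i in range(1, m + 1)]))
    top_spec = MeasureGroupSpec(
        id="mg_profile", varied_parameter="target",
        derived_from=[s.id for s in derived_specs])

    for s in base_specs + derived_specs + [top_spec]:
        onto.add(Declaration("Class", b(s.id)))
        onto.add(AnnotationAssertion(b(s.id), RDFS_LABEL,
                                     s.id.replace("_", " ")))
        onto.add(SubClassOf(Atomic(b(s.id)), mg))
        for src in s.derived_from:
            onto.add(SubClassOf(Atomic(b(s.id)),
                                Exists(derive, Atomic(b(src)))))
    for j, s in enumerate(derived_specs, start=1):
        onto.add(SubClassOf(Atomic(b(s.id)), Exists(he, Atomic(b("ic50")))))
    onto.add(SubClassOf(Atomic(b(top_spec.id)),
                        Exists(he, Atomic(b("ic50_kinase_profile_endpoint")))))
    onto.add(SubClassOf(
        Atomic(b("kinase_concentration_response_profiling_panel_assay")),
        Exists(RoleRef(b("has_measure_group")), Atomic(b(top_spec.id)))))

    # endpoint individuals with inert values (synthetic IC50 per target)
    for j in range(1, n + 1):
        ep = EndpointSpec(
            id=f"ep_ic50_k{j}", category="ic50",
            mode_of_action="inhibition", signal_direction="decrease",
            endpoint_action_correlation="inverse",
            value=_panel_ic50(j), unit=b("micromolar"),
            measure_groups=[f"mg_ic50_k{j}"])
        ind = ABOX_NS + ep.id
        onto.add(Declaration("NamedIndividual", ind))
        onto.add(ClassAssertion(Atomic(b(ep.category)), ind))
        onto.add(ClassAssertion(
            Exists(RoleRef(b("has_mode_of_action")),
                   Atomic(b(ep.mode_of_action))), ind))
        onto.add(ClassAssertion(
            Exists(RoleRef(b("has_signal_direction")),
                   Atomic(b("signal_decrease"))), ind))
        onto.add(ClassAssertion(
            Exists(RoleRef(b("has_endpoint_action_correlation")),
                   Atomic(b("inverse_correlation"))), ind))
        onto.add(DataAssertion(b("has_value"), ind, ep.value, ep.unit))
    return onto


def panel_measure_group_dag(onto: Ontology) -> nx.DiGraph:
    """Extract the derived-from DAG over measure-group classes.

    Nodes are classes told-subsumed by ``measure group``; an edge X → Y
    means X is derived from Y.
    """
    mg_iri = b("measure_group")
    nodes = {ax.sub.iri for ax in onto.tbox
             if isinstance(ax, SubClassOf) and isinstance(ax.sub, Atomic)
             and isinstance(ax.sup, Atomic) and ax.sup.iri == mg_iri}
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for ax in onto.tbox:
        if isinstance(ax, SubClassOf) and isinstance(ax.sub, Atomic) \
                and isinstance(ax.sup, Exists) \
                and ax.sup.role.name == b("is_derived_from") \
                and isinstance(ax.sup.filler, Atomic) \
                and ax.sub.iri in nodes and ax.sup.filler.iri in nodes:
            g.add_edge(ax.sub.iri, ax.sup.filler.iri)
    return g


# ---------------------------------------------------------------------------
# External stubs and combinators
# ---------------------------------------------------------------------------

_STUB_TERMS: Dict[str, Dict[str, Optional[str]]] = {
    "go": {"biological_process": None, "molecular_function": None,
           "cellular_component": None, "kinase_activity": "molecular_function"},
    "clo": {"cell": None, "cell_line_cell": "cell"},
    "uo": {"unit": None, "concentration_unit": "unit",
           "micromolar": "concentration_unit"},
    "ncbitaxon": {"organism": None, "eukaryota": "organism",
                  "homo_sapiens": "eukaryota"},
    "doid": {"disease": None, "cancer": "disease"},
    "chebi": {"chemical_entity": None, "atp": "chemical_entity"},
    "uberon": {"anatomical_entity": None, "organ": "anatomical_entity"},
    "pato": {"quality": None, "intensity": "quality"},
    "iao": {"information_content_entity": None,
            "data_item": "information_content_entity"},
    "ro": {},  # properties only
    "bfo": {"entity": None, "continuant": "entity", "occurrent": "entity",
            "process": "occurrent"},
}

_RO_PROPERTIES = ("has_participant", "part_of")

#: (internal, external, relation, entity)
COMBINATOR_MAPPINGS: Tuple[Tuple[str, str, str, str], ...] = (
    (b("biological_process"), ext("go", "biological_process"),
     "equivalent", "class"),
    (b("cell_line_cell"), ext("clo", "cell_line_cell"), "equivalent", "class"),
    (b("micromolar"), ext("uo", "micromolar"), "equivalent", "class"),
    (b("organism"), ext("ncbitaxon", "organism"), "equivalent", "class"),
    (b("disease"), ext("doid", "disease"), "equivalent", "class"),
    (b("small_molecule"), ext("chebi", "chemical_entity"),
     "subclass", "class"),
    (b("anatomical_entity"), ext("uberon", "anatomical_entity"),
     "equivalent", "class"),
    (b("quality"), ext("pato", "quality"), "equivalent", "class"),
    (b("endpoint"), ext("iao", "information_content_entity"),
     "subclass", "class"),
    (b("has_participant"), ext("ro", "has_participant"),
     "equivalent", "property"),
    (b("bioassay"), ext("bfo", "process"), "subclass", "class"),
)


def external_stub(src: str) -> Ontology:
    axioms: List[Axiom] = []
    for local, parent in _STUB_TERMS[src].items():
        axioms.append(Declaration("Class", ext(src, local)))
        axioms.append(AnnotationAssertion(ext(src, local), RDFS_LABEL,
                                          term_label(local)))
        if parent is not None:
            axioms.append(SubClassOf(Atomic(ext(src, local)),
                                     Atomic(ext(src, parent))))
    if src == "ro":
        for local in _RO_PROPERTIES:
            axioms.append(Declaration("ObjectProperty", ext(src, local)))
            axioms.append(AnnotationAssertion(ext(src, local), RDFS_LABEL,
                                              term_label(local)))
    return Ontology(iri=EXT_DOC[src], axioms=axioms)


# ---------------------------------------------------------------------------
# Built-in annotation table (the spreadsheet workflow fixture)
# ---------------------------------------------------------------------------

ANNOTATION_HEADERS = ("assay id", "assay design method",
                      "physical detection method", "assay format",
                      "endpoint", "mode of action", "signal direction")

ANNOTATION_ROWS = (
    ("A-LRG-1", "luciferase gene expression measurement method",
     "chemiluminescence", "cell based format", "percent activation",
     "activation", "signal increase"),
    ("A-CVA-2", "ATP quantitation using luciferase", "chemiluminescence",
     "cell based format", "percent inhibition", "inhibition",
     "signal decrease"),
    ("A-CYP-3", "luciferin coupled enzyme activity measurement method",
     "chemiluminescence", "biochemical format", "IC50", "inhibition",
     "signal decrease"),
    ("A-KIN-4", "ATP coupled enzyme activity measurement method",
     "chemiluminescence", "biochemical format", "IC50", "inhibition",
     "signal decrease"),
    ("A-LEA-5", "luciferase enzyme activity measurement method",
     "chemiluminescence", "biochemical format", "percent inhibition",
     "inhibition", "signal decrease"),
)

ANNOTATION_HEADER_MAPPING = {
    "assay design method": (b("has_assay_design_method"), "class"),
    "physical detection method": (b("has_physical_detection_method"),
                                  "class"),
    "assay format": (b("has_assay_format"), "class"),
    "endpoint": (b("has_endpoint"), "class"),
    "mode of action": (b("has_mode_of_action"), "class"),
    "signal direction": (b("has_signal_direction"), "class"),
}


def write_annotation_table(path, delimiter: str = ",") -> Path:
    import csv
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(ANNOTATION_HEADERS)
        w.writerows(ANNOTATION_ROWS)
    return path


# ---------------------------------------------------------------------------
# The whole catalog
# ---------------------------------------------------------------------------

CORE_IRI = DOC + "modules/bao_core"
BIOASSAY_AXIOMS_IRI = DOC + "axioms/bioassay_axioms"
LUCIFERASE_AXIOMS_IRI = DOC + "axioms/luciferase_axioms"
COMBINATOR_IRI = DOC + "combinators/external_mappings"
ABOX_IRI = DOC + "abox/luciferase_annotations"
CORE_PERSPECTIVE_IRI = DOC + "perspectives/core"
COMPLETE_PERSPECTIVE_IRI = DOC + "perspectives/complete"


def generate_bao_mini(out_dir, with_abox: bool = False,
                      panel: Optional[Tuple[int, int]] = None
                      ) -> ImportCatalog:
    """Emit the full layered catalog under ``out_dir``.

    Six component vocabularies + a property vocabulary, the core gluing
    module, two axiom files, eleven external stubs, one combinator file and
    two perspectives (core-only and complete).  Optionally an annotation
    ABox file and a panel axiom file are added to the complete perspective.
    Generation is deterministic — no randomness anywhere.
    """
    out_dir = Path(out_dir)
    entries: Dict[str, CatalogEntry] = {}

    def emit(onto: Ontology, rel: str, kind: str) -> None:
        write_ontology_file(onto, out_dir / rel, FIXTURE_POLICY)
        entries[onto.iri] = CatalogEntry(iri=onto.iri, path=Path(rel),
                                         kind=kind)

    for name in _COMPONENT_VOCABS:
        emit(component_vocabulary(name), f"vocab/{name}.ofn", "vocabulary")
    emit(properties_vocabulary(), "vocab/properties.ofn", "vocabulary")

    core = Ontology(iri=CORE_IRI, direct_imports=[
        DOC + "vocab/" + name for name in _COMPONENT_VOCABS
    ] + [DOC + "vocab/properties"])
    emit(core, "modules/bao_core.ofn", "module")

    emit(Ontology(iri=BIOASSAY_AXIOMS_IRI,
                  axioms=generate_measure_group_axioms()),
         "axioms/bioassay_axioms.ofn", "axiomfile")
    emit(Ontology(iri=LUCIFERASE_AXIOMS_IRI, axioms=_luciferase_axioms()),
         "axioms/luciferase_axioms.ofn", "axiomfile")

    for src in EXTERNAL_SOURCES:
        emit(external_stub(src), f"external/{src}.ofn", "external_stub")

    from .modules import make_combinator
    combinator = make_combinator(COMBINATOR_MAPPINGS, iri=COMBINATOR_IRI)
    emit(combinator, "combinators/external_mappings.ofn", "combinator")

    core_perspective = Ontology(iri=CORE_PERSPECTIVE_IRI, direct_imports=[
        CORE_IRI, BIOASSAY_AXIOMS_IRI, LUCIFERASE_AXIOMS_IRI])
    emit(core_perspective, "perspectives/core.ofn", "perspective")

    complete_imports = [CORE_PERSPECTIVE_IRI, COMBINATOR_IRI] + \
        [EXT_DOC[src] for src in EXTERNAL_SOURCES]

    if with_abox:
        from .annotations import AnnotationTable, HeaderMapping, \
            table_to_triples
        table = AnnotationTable(columns=list(ANNOTATION_HEADERS),
                                rows=[dict(zip(ANNOTATION_HEADERS, r))
                                      for r in ANNOTATION_ROWS])
        mapping = HeaderMapping(dict(ANNOTATION_HEADER_MAPPING))
        kb = Ontology(iri="urn:tmp")
        for name in _COMPONENT_VOCABS:
            kb.merge(component_vocabulary(name))
        kb.merge(properties_vocabulary())
        assertions = table_to_triples(table, mapping, kb)
        emit(Ontology(iri=ABOX_IRI, axioms=assertions),
             "abox/luciferase_annotations.ofn", "axiomfile")
        complete_imports.append(ABOX_IRI)

    if panel is not None:
        spec = PanelSpec(m=panel[0], n=panel[1])
        panel_onto = generate_panel_assay(spec)
        emit(panel_onto, "examples/panel.ofn", "module")
        complete_imports.append(panel_onto.iri)

    complete = Ontology(iri=COMPLETE_PERSPECTIVE_IRI,
                        direct_imports=complete_imports)
    emit(complete, "perspectives/complete.ofn", "perspective")

    catalog = ImportCatalog(
        entries=entries,
        roots=[COMPLETE_PERSPECTIVE_IRI, CORE_PERSPECTIVE_IRI],
        base_dir=out_dir)
    catalog.dump(out_dir / "catalog.yaml")
    return catalog


def component_vocabulary_count(catalog: ImportCatalog) -> int:
    """Vocabulary files that declare classes (the component count)."""
    from .ofn import read_ontology_file
    count = 0
    for iri, entry in catalog.entries.items():
        if entry.kind != "vocabulary":
            continue
        onto = read_ontology_file(catalog.resolve_path(iri)).ontology
        if any(d.kind == "Class" for d in onto.declarations):
            count += 1
    return count


def external_stub_count(catalog: ImportCatalog) -> int:
    return sum(1 for e in catalog.entries.values()
               if e.kind == "external_stub")


# ---------------------------------------------------------------------------
# Random small TBoxes for the soundness suite
# ---------------------------------------------------------------------------

RAND_NS = "http://example.org/rand#"


def random_ontology(rng: random.Random, max_axioms: int = 6,
                    n_classes: int = 4, n_roles: int = 2,
                    max_depth: int = 3) -> Set[Axiom]:
    """A random small TBox in the supported fragment (seeded, TBox-only)."""
    classes = [Atomic(RAND_NS + f"C{i}") for i in range(n_classes)]
    roles = [RoleRef(RAND_NS + f"R{i}") for i in range(n_roles)]

    def expr(depth: int) -> ConceptExpr:
        choices = ["atomic"] * 4
        if depth > 0:
            choices += ["not", "and", "or", "exists", "forall"] * 2
        kind = rng.choice(choices)
        if kind == "atomic":
            return rng.choice(classes + [classes[0]])
        if kind == "not":
            return Not(expr(depth - 1))
        if kind in {"and", "or"}:
            parts = [expr(depth - 1) for _ in range(rng.randint(2, 3))]
            return And(*parts) if kind == "and" else Or(*parts)
        role = rng.choice(roles)
        filler = expr(depth - 1)
        return Exists(role, filler) if kind == "exists" \
            else Forall(role, filler)

    axioms: Set[Axiom] = set()
    for _ in range(rng.randint(1, max_axioms)):
        kind = rng.choices(["sub", "equiv", "disjoint"],
                           weights=[6, 2, 2])[0]
        if kind == "sub":
            axioms.add(SubClassOf(expr(max_depth), expr(max_depth)))
        elif kind == "equiv":
            a, bx = expr(max_depth - 1), expr(max_depth - 1)
            if a != bx:
                axioms.add(EquivalentClasses(a, bx))
        else:
            a, bx = expr(max_depth - 1), expr(max_depth - 1)
            if a != bx:
                axioms.add(DisjointClasses(a, bx))
    if not axioms:
        axioms.add(SubClassOf(classes[0], classes[0]))
    return axioms
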