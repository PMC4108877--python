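"""Class-expression data model: canonical forms, parsing, NNF, signatures."""

import pytest
from hypothesis import given, settings, strategies as st

from ontoassay.dl import (
    TOP, BOTTOM, And, Atomic, EquivalentClasses, Exists, Forall, MinCard,
    Nominal, Not, Or, RoleRef, SelfRestriction, Signature, SubClassOf,
    UnknownNameError, UnsupportedConstructError, internalize,
    parse_class_expression, signature_of, to_nnf,
)
from ontoassay.reasoner import concept_extension, Interpretation

A, B, C = Atomic("urn:A"), Atomic("urn:B"), Atomic("urn:C")
R, S = RoleRef("urn:R"), RoleRef("urn:S")


class TestCanonicalForm:
    def test_and_or_argument_order_is_irrelevant(self):
        assert And(A, B) == And(B, A)
        assert Or(A, B, C) == Or(C, B, A)
        assert hash(And(A, B)) == hash(And(B, A))

    def test_nested_same_kind_nodes_flatten(self):
        assert And(A, And(B, C)) == And(A, B, C)
        assert Or(Or(A, B), Or(B, C)) == Or(A, B, C)

    def test_duplicates_collapse(self):
        assert And(A, A) == A
        assert Or(A, A, B) == Or(A, B)

    def test_neutral_and_absorbing_elements(self):
        assert And(A, TOP) == A
        assert And(A, BOTTOM) is BOTTOM
        assert Or(A, BOTTOM) == A
        assert Or(A, TOP) is TOP


# -- surface parser ---------------------------------------------------------

@pytest.fixture
def sig():
    return Signature(
        classes={"urn:bioassay", "urn:assay_design_method",
                 "urn:luciferin_4_monooxygenase", "urn:A", "urn:B"},
        roles={"urn:has_assay_method", "urn:has_participant", "urn:R"},
        individuals={"urn:a1"},
    )


class TestParser:
    def test_quoted_label_nesting(self, sig):
        text = ("bioassay and ('has assay method' some "
                "('assay design method' and "
                "('has participant' some 'Luciferin 4-monooxygenase')))")
        expr = parse_class_expression(text, sig)
        expected = And(
            Atomic("urn:bioassay"),
            Exists(RoleRef("urn:has_assay_method"),
                   And(Atomic("urn:assay_design_method"),
                       Exists(RoleRef("urn:has_participant"),
                              Atomic("urn:luciferin_4_monooxygenase")))))
        assert expr == expected

    def test_top_and_bottom_keywords(self, sig):
        assert parse_class_expression("owl:Thing", sig) is TOP
        assert parse_class_expression("owl:Nothing", sig) is BOTTOM

    def test_negation_structure_is_preserved(self, sig):
        expr = parse_class_expression("not (A and B)", sig)
        assert expr == Not(And(Atomic("urn:A"), Atomic("urn:B")))

    def test_unknown_name_is_an_error_not_a_creation(self, sig):
        with pytest.raises(UnknownNameError):
            parse_class_expression("no_such_class", sig)

    def test_precedence_not_binds_tighter_than_and_than_or(self, sig):
        expr = parse_class_expression("not A and B or A", sig)
        assert expr == Or(And(Not(Atomic("urn:A")), Atomic("urn:B")),
                          Atomic("urn:A"))

    def test_cardinality_nominal_and_self_parse(self, sig):
        expr = parse_class_expression("R min 2 A", sig)
        assert isinstance(expr, MinCard) and expr.n == 2
        assert parse_class_expression("{a1}", sig) == Nominal("urn:a1")
        assert parse_class_expression("R self", sig) == \
            SelfRestriction(RoleRef("urn:R"))

    def test_syntax_error_carries_position(self, sig):
        from ontoassay.dl import ExpressionSyntaxError
        with pytest.raises(ExpressionSyntaxError):
            parse_class_expression("A and (B", sig)


# -- NNF --------------------------------------------------------------------

def _expr_strategy():
    atoms = st.sampled_from([A, B, C, TOP, BOTTOM])
    roles = st.sampled_from([R, S])
    return st.recursive(
        atoms,
        lambda inner: st.one_of(
            inner.map(Not),
            st.tuples(inner, inner).map(lambda t: And(*t)),
            st.tuples(inner, inner).map(lambda t: Or(*t)),
            st.tuples(roles, inner).map(lambda t: Exists(*t)),
            st.tuples(roles, inner).map(lambda t: Forall(*t)),
        ),
        max_leaves=8,
    )


def _random_interpretations():
    domain = [0, 1, 2]
    subsets = st.frozensets(st.sampled_from(domain))
    pairs = st.frozensets(
        st.tuples(st.sampled_from(domain), st.sampled_from(domain)))
    return st.builds(
        lambda ea, eb, ec, er, es: Interpretation(
            frozenset(domain),
            {"urn:A": ea, "urn:B": eb, "urn:C": ec},
            {"urn:R": er, "urn:S": es}),
        subsets, subsets, subsets, pairs, pairs)


class TestNNF:
    @pytest.mark.parametrize("before,after", [
        (Not(And(A, B)), Or(Not(A), Not(B))),
        (Not(Exists(R, A)), Forall(R, Not(A))),
        (Not(Forall(R, A)), Exists(R, Not(A))),
        (Not(Not(A)), A),
        (Not(TOP), BOTTOM),
    ])
    def test_rewrites(self, before, after):
        assert to_nnf(before) == after

    @given(_expr_strategy())
    @settings(max_examples=150, deadline=None)
    def test_idempotent(self, expr):
        once = to_nnf(expr)
        assert to_nnf(once) == once

    @given(_expr_strategy())
    @settings(max_examples=150, deadline=None)
    def test_nnf_never_invents_names(self, expr):
        # constant folding (⊤/⊥ absorption) may drop names, never add them
        assert signature_of([SubClassOf(to_nnf(expr), TOP)]).all_iris() <= \
            signature_of([SubClassOf(expr, TOP)]).all_iris()

    def test_signature_preserved_without_constants(self):
        expr = Not(And(A, Or(Not(B), Exists(R, Forall(S, C)))))
        assert signature_of([SubClassOf(to_nnf(expr), TOP)]).all_iris() == \
            signature_of([SubClassOf(expr, TOP)]).all_iris()

    @given(_expr_strategy(), _random_interpretations())
    @settings(max_examples=200, deadline=None)
    def test_semantics_preserved_on_finite_structures(self, expr, interp):
        assert concept_extension(expr, interp) == \
            concept_extension(to_nnf(expr), interp)

    @pytest.mark.parametrize("expr", [
        Nominal("urn:a1"),
        SelfRestriction(R),
        MinCard(1, R, A),
    ])
    def test_unsupported_variants_error(self, expr):
        with pytest.raises(UnsupportedConstructError):
            to_nnf(Not(expr))


# -- signatures and internalization ----------------------------------------

class TestSignature:
    def test_partitioned_exactly(self):
        sig = signature_of([SubClassOf(A, Exists(R, B))])
        assert sig.classes == {"urn:A", "urn:B"}
        assert sig.roles == {"urn:R"}
        assert not sig.individuals

    def test_empty(self):
        sig = signature_of([])
        assert not sig.all_iris()

    def test_monotone_under_axiom_addition(self):
        small = signature_of([SubClassOf(A, B)])
        big = signature_of([SubClassOf(A, B), SubClassOf(B, Exists(R, C))])
        assert small.all_iris() <= big.all_iris()

    def test_luciferase_suite_contains_the_printed_names(self):
        from ontoassay import fixtures as fx
        suite = fx.generate_luciferase_suite()
        sig = signature_of(suite.all_axioms())
        for name in fx.LUCIFERASE_ASSAYS:
            assert fx.b(name) in sig.classes
        assert fx.b("luciferin_4_monooxygenase") in sig.classes


class TestInternalize:
    def test_single_gci(self):
        assert internalize([SubClassOf(A, B)]) == Or(Not(A), B)

    def test_equivalence_becomes_two_gcis(self):
        got = internalize([EquivalentClasses(A, B)])
        assert got == And(Or(Not(A), B), Or(Not(B), A))

    def test_empty_tbox_is_top(self):
        assert internalize([]) is TOP
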