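"""Derivation of the bipartite Boolean model: rule structure and
semantic properties (latch, decay, determinism, symbol closure)."""

import pytest

from bibool import (
    Atom,
    and_,
    build_bipartite,
    default_init,
    flatten_effector,
    not_,
    or_,
    reaction_rule,
    run_sync,
    state_rule,
)
from bibool.core import Effector, ModelError, RxnconModel
from bibool.fixtures import random_model, simplified_hog
from bibool.parse import parse_quick


class TestWorkedRules:
    """The four reference update equations of the derivation scheme."""

    def test_required_state_enters_with_and(self, hog_model):
        r = hog_model.reaction_by_id("Hog1_P+_Hot1")
        assert reaction_rule(hog_model, r) == and_(
            Atom("Hog1"), Atom("Hot1"), Atom("Hog1-{P}")
        )

    def test_inhibiting_state_enters_negated(self, hog_model):
        r = hog_model.reaction_by_id("Ssk1_ppi_Ssk2")
        assert reaction_rule(hog_model, r) == and_(
            Atom("Ssk1"), Atom("Ssk2"), not_(Atom("Ssk1-{P}"))
        )

    def test_irreversibly_produced_state_latches_until_consumed(self, hog_model):
        (state,) = [s for s in hog_model.states() if s.id == "Sln1-{P}"]
        rule = state_rule(hog_model, state, conjoin_components=False)
        assert rule == or_(
            Atom("Sln1_AP_Sln1"),
            and_(Atom("Sln1-{P}"), not_(Atom("Sln1_PT_Ypd1"))),
        )

    def test_reversibly_produced_state_tracks_its_producer(self, hog_model):
        (state,) = [s for s in hog_model.states() if s.id == "Ssk1--Ssk2"]
        assert state_rule(hog_model, state, conjoin_components=False) == Atom("Ssk1_ppi_Ssk2")

    def test_component_conjunct_flag(self, hog_model):
        (state,) = [s for s in hog_model.states() if s.id == "Ssk1--Ssk2"]
        assert state_rule(hog_model, state, conjoin_components=True) == and_(
            Atom("Ssk1"), Atom("Ssk2"), Atom("Ssk1_ppi_Ssk2")
        )


class TestReactionRule:
    def test_no_contingencies_requires_only_components(self):
        m = parse_quick("A_ppi_B")
        assert reaction_rule(m, m.reactions[0]) == and_(Atom("A"), Atom("B"))

    def test_autoreaction_has_single_component_conjunct(self):
        m = parse_quick("Sln1_AP_Sln1")
        assert reaction_rule(m, m.reactions[0]) == Atom("Sln1")

    def test_quantitative_policy_strict_vs_neutral(self):
        m = parse_quick("A_ppi_B\nC_P+_A\nA_P+_D; K+ A-{P}")
        r = m.reaction_by_id("A_P+_D")
        strict = reaction_rule(m, r, policy="strict")
        neutral = reaction_rule(m, r, policy="neutral")
        assert strict == and_(Atom("A"), Atom("D"), Atom("A-{P}"))
        assert neutral == and_(Atom("A"), Atom("D"))
        # the two policies differ by exactly the quantitative conjunct
        assert set(strict.atoms()) - set(neutral.atoms()) == {"A-{P}"}

    def test_neutral_signs_are_ignored(self):
        m = parse_quick("A_ppi_B\nC_P+_A\nA_P+_D; 0 A-{P}; ? A--B")
        r = m.reaction_by_id("A_P+_D")
        assert reaction_rule(m, r) == and_(Atom("A"), Atom("D"))


class TestStateRule:
    def test_mixed_producers_and_consumer(self):
        # irreversible production overrides consumption; reversible
        # maintenance is gated by the consumer
        m = parse_quick("A_P+_B\nA_PT_B\nC_P-_B")
        (state,) = [s for s in m.states() if s.id == "B-{P}"]
        rule = state_rule(m, state, conjoin_components=False)
        assert rule == or_(
            or_(Atom("A_P+_B"), Atom("A_PT_B")),
            and_(Atom("B-{P}"), not_(Atom("C_P-_B"))),
        )

    def test_contingency_only_state_is_frozen(self):
        m = parse_quick("A_ppi_B; ! X-{P}")
        (state,) = [s for s in m.states() if s.id == "X-{P}"]
        assert state_rule(m, state, conjoin_components=False) == Atom("X-{P}")

    def test_consumer_only_state_decays(self):
        m = parse_quick("A_P-_B")
        (state,) = [s for s in m.states() if s.id == "B-{P}"]
        rule = state_rule(m, state, conjoin_components=False)
        assert rule == and_(Atom("B-{P}"), not_(Atom("A_P-_B")))


class TestFlatten:
    def test_atomic_effectors(self):
        m = RxnconModel()
        from bibool.parse import parse_effector_text

        assert flatten_effector(m, parse_effector_text("Hog1-{P}", m)) == Atom("Hog1-{P}")
        assert flatten_effector(m, parse_effector_text("[Turgor]", m)) == Atom("[Turgor]")

    def test_three_level_nesting_equals_manual_expansion(self):
        m = parse_quick(
            "A_ppi_B\nC_P+_A\nC_P+_B\n"
            "INNER = OR(A-{P}, B-{P})\n"
            "MID = AND(A--B, INNER)\n"
            "TOP = OR(MID, NOT([S]))\n"
            "A_P+_D; ! TOP"
        )

        # independent recursive expansion over the node table
        def expand(eff):
            if eff.kind == "state":
                return Atom(eff.state.id)
            if eff.kind == "input":
                return Atom(eff.name)
            node = m.boolean_nodes[eff.name]
            parts = [expand(c) for c in node.children]
            if node.operator == "AND":
                return and_(parts)
            if node.operator == "OR":
                return or_(parts)
            return not_(parts[0])

        eff = m.contingencies_on("A_P+_D")[0].effector
        expected = expand(eff)
        assert flatten_effector(m, eff) == expected
        # no node names survive the flattening
        assert set(expected.atoms()) <= {"A-{P}", "B-{P}", "A--B", "[S]"}

    def test_cyclic_node_reference_is_an_error(self):
        m = parse_quick("A_ppi_B\nC_P+_A")
        from bibool.core import BooleanNodeDef

        m.add_boolean_node(BooleanNodeDef("P", "AND", (Effector.of_node("Q"), Effector.of_node("Q"))))
        m.add_boolean_node(BooleanNodeDef("Q", "OR", (Effector.of_node("P"), Effector.of_node("P"))))
        with pytest.raises(ModelError, match="cycl"):
            flatten_effector(m, Effector.of_node("P"))


class TestBuild:
    def test_repeated_builds_are_structurally_equal(self, hog_model):
        assert build_bipartite(hog_model) == build_bipartite(hog_model)

    def test_one_variable_per_node_class(self, hog_bipartite):
        roles = hog_bipartite.roles
        by_role = {}
        for v, role in roles.items():
            by_role.setdefault(role, []).append(v)
        # 11 reactions + 1 output pseudo-reaction
        assert len(by_role["reaction"]) == 12
        assert sorted(by_role["state"]) == [
            "Hog1-{P}", "Hot1-{P}", "Pbs2-{P}", "Sln1-{P}",
            "Ssk1--Ssk2", "Ssk1-{P}", "Ypd1-{P}",
        ]
        assert by_role["output"] == ["[Turgor]"]
        assert len(by_role["component"]) == 8  # incl. ukPPase

    def test_components_and_inputs_are_constant(self, crosstalk_bipartite):
        bm = crosstalk_bipartite
        for v in bm.variables:
            if bm.roles[v] in ("component", "input"):
                assert bm.rules[v] == Atom(v)

    def test_symbol_audit_all_atoms_declared(self, hog_bipartite, crosstalk_bipartite):
        for bm in (hog_bipartite, crosstalk_bipartite):
            bm.check_closed()  # raises on violation

    def test_every_contingency_effector_lands_in_its_target_rule(self, crosstalk_model):
        bm = build_bipartite(crosstalk_model)
        from bibool.bipartite import output_pseudo_reaction_id

        for c in crosstalk_model.contingencies:
            var = c.target if not c.target.startswith("[") else output_pseudo_reaction_id(c.target)
            assert c.effector.text in set(bm.rules[var].atoms())

    def test_empty_model_builds_empty(self):
        bm = build_bipartite(RxnconModel())
        assert bm.variables == []

    def test_latch_property_monotone_when_consumers_false(self, crosstalk_bipartite):
        # Ste11-{P} has only the irreversible producer Ste20_P+_Ste11 and
        # no consumers: along any trajectory it never switches back off
        bm = crosstalk_bipartite
        traj = run_sync(bm, default_init(bm, inputs_true=["[Pher]"]), max_steps=50)
        values = [a["Ste11-{P}"] for a in traj.assignments]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_decay_property_reversible_state_is_delayed_producer(self, crosstalk_bipartite):
        # Ste11--Ste5 (bond ids are partner-ordered): sole reversible
        # producer, no consumers; with components constant-true the
        # state equals the producer one step back
        bm = crosstalk_bipartite
        traj = run_sync(bm, default_init(bm, inputs_true=["[Pher]"]), max_steps=50)
        for prev, cur in zip(traj.assignments, traj.assignments[1:]):
            assert cur["Ste11--Ste5"] == prev["Ste5_ppi_Ste11"]

    def test_random_models_build_closed(self):
        for seed in range(10):
            bm = build_bipartite(random_model(5, 10, seed=seed))
            bm.check_closed()
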