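"""Synchronous and asynchronous simulation semantics."""

import itertools

import numpy as np
import pytest

from bibool import (
    Atom,
    PerturbationEvent,
    PerturbationSchedule,
    TRUE,
    and_,
    build_bipartite,
    default_init,
    not_,
    run_async,
    run_sync,
    sync_step,
)
from bibool.bipartite import BooleanModel
from bibool.expr import And, BoolExpr, Const, Not, Or
from bibool.fixtures import negative_feedback_toggle, random_model


def _toggle2() -> BooleanModel:
    bm = BooleanModel()
    bm.add("A", "state", not_(Atom("B")))
    bm.add("B", "state", Atom("A"))
    return bm


class TestSyncStep:
    def test_unregulated_reactions_fire_from_all_false(self, crosstalk_bipartite):
        bm = crosstalk_bipartite
        a = default_init(bm)  # components true, everything else false
        nxt = sync_step(bm, a)
        assert nxt["Ste20_P+_Ste11"] is True  # no contingencies
        assert nxt["Ste5_ppi_Ste11"] is False  # requires [Pher]

    def test_fixed_point_maps_to_itself(self):
        bm = _toggle2()
        a = {"A": True, "B": False}
        # not a fixed point of the toggle; build one explicitly
        bm2 = BooleanModel()
        bm2.add("X", "state", TRUE)
        bm2.add("Y", "state", Atom("X"))
        fp = {"X": True, "Y": True}
        assert sync_step(bm2, fp) == fp
        assert sync_step(bm, a) != a

    def test_two_steps_equal_symbolic_composition(self):
        # independent oracle: substitute every atom by its rule to get
        # the two-step rule symbolically, then evaluate once
        def substitute(e: BoolExpr, rules) -> BoolExpr:
            if isinstance(e, Atom):
                return rules[e.name]
            if isinstance(e, Const):
                return e
            if isinstance(e, Not):
                return Not(substitute(e.child, rules))
            if isinstance(e, And):
                return And(tuple(substitute(c, rules) for c in e.children))
            return Or(tuple(substitute(c, rules) for c in e.children))

        bm = build_bipartite(random_model(3, 5, contingency_density=0.5, seed=11))
        composed = {v: substitute(bm.rules[v], bm.rules) for v in bm.variables}
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = {v: bool(rng.integers(2)) for v in bm.variables}
            two_steps = sync_step(bm, sync_step(bm, a))
            oracle = {v: composed[v].evaluate(a) for v in bm.variables}
            assert two_steps == oracle

    def test_clamped_variable_keeps_clamp_value(self):
        bm = _toggle2()
        nxt = sync_step(bm, {"A": False, "B": False}, clamps={"A": False})
        assert nxt["A"] is False  # rule would say True


class TestRunSync:
    def test_same_init_and_schedule_give_identical_trajectories(self, hog_bipartite):
        sched = PerturbationSchedule([PerturbationEvent(5, "[Turgor]", False, clamp=True)])
        init = default_init(hog_bipartite, inputs_true=["[Turgor]"])
        t1 = run_sync(hog_bipartite, init, sched, max_steps=60)
        t2 = run_sync(hog_bipartite, init, sched, max_steps=60)
        assert t1.assignments == t2.assignments and t1.attractor == t2.attractor

    def test_point_attractor_on_constant_model(self):
        bm = BooleanModel()
        bm.add("X", "state", TRUE)
        bm.add("Y", "state", Const(False))
        traj = run_sync(bm, {"X": False, "Y": True}, max_steps=10)
        assert traj.attractor is not None and traj.attractor[0] == "point"
        assert traj.attractor[1] <= 2
        assert traj.assignments[-1] == traj.assignments[-2]

    def test_cycle_period_is_minimal(self):
        traj = run_sync(negative_feedback_toggle(),
                        {"A": False, "a": False, "B": False, "b": False}, max_steps=50)
        kind, i, p = traj.attractor
        assert kind == "cycle" and p == 4
        for q in range(1, p):
            if p % q == 0:
                assert traj.assignments[i] != traj.assignments[i + q]

    def test_unconverged_flag_when_budget_too_small(self, hog_bipartite):
        traj = run_sync(hog_bipartite, default_init(hog_bipartite), max_steps=3)
        assert not traj.converged

    def test_clamp_contract_holds_over_whole_window(self, hog_bipartite):
        sched = PerturbationSchedule([
            PerturbationEvent(0, "[Turgor]", True, clamp=True),
            PerturbationEvent(20, "[Turgor]", False, clamp=True),
        ])
        traj = run_sync(hog_bipartite, default_init(hog_bipartite), sched, max_steps=80)
        for t, a in enumerate(traj.assignments):
            if t < 20:
                assert a["[Turgor]"] is True
            else:
                assert a["[Turgor]"] is False

    def test_one_shot_set_may_recover_clamp_does_not(self):
        bm = BooleanModel()
        bm.add("X", "state", TRUE)
        init = {"X": True}
        one_shot = run_sync(bm, init,
                            PerturbationSchedule([PerturbationEvent(3, "X", False)]),
                            max_steps=10)
        clamped = run_sync(bm, init,
                           PerturbationSchedule([PerturbationEvent(3, "X", False, clamp=True)]),
                           max_steps=10)
        assert one_shot.assignments[3]["X"] is False
        assert one_shot.assignments[4]["X"] is True
        assert all(a["X"] is False for a in clamped.assignments[3:])

    def test_detection_window_restarts_after_events(self, hog_bipartite):
        # the model reaches its turgor-on steady state, is perturbed at
        # t=27, and must then be re-classified rather than reuse the
        # pre-perturbation visit table
        sched = PerturbationSchedule([
            PerturbationEvent(0, "[Turgor]", True, clamp=True),
            PerturbationEvent(27, "[Turgor]", False, clamp=True),
        ])
        traj = run_sync(hog_bipartite, default_init(hog_bipartite), sched, max_steps=100)
        assert traj.converged and traj.attractor[1] > 27
        assert traj.value_at_attractor("Hog1_P+_Hot1") == {True}

    def test_schedule_rejects_unknown_variable(self, hog_bipartite):
        sched = PerturbationSchedule([PerturbationEvent(0, "NOPE", True)])
        with pytest.raises(KeyError):
            run_sync(hog_bipartite, default_init(hog_bipartite), sched)


class TestRunAsync:
    def test_seed_reproducibility_bitwise(self):
        bm = negative_feedback_toggle()
        init = {v: False for v in bm.variables}
        m1 = run_async(bm, init, n_runs=20, n_steps=10, seed=42)
        m2 = run_async(bm, init, n_runs=20, n_steps=10, seed=42)
        assert (m1.to_numpy() == m2.to_numpy()).all()

    def test_single_run_entries_are_binary(self):
        bm = negative_feedback_toggle()
        init = {v: False for v in bm.variables}
        m = run_async(bm, init, n_runs=1, n_steps=5, seed=0)
        assert set(np.unique(m.to_numpy())) <= {0.0, 1.0}

    def test_deterministic_cascade_converges_to_binary_activity(self, crosstalk_bipartite):
        bm = crosstalk_bipartite
        init = default_init(bm, inputs_true=["[Pher]"])
        m = run_async(bm, init, n_runs=30, n_steps=30, seed=7)
        final = m.iloc[:, -1].to_numpy()
        assert set(np.unique(final)) <= {0.0, 1.0}
        assert m.loc["[MATING]"].iloc[-1] == 1.0
        assert m.loc["[TURGOR]"].iloc[-1] == 0.0

    def test_toggle_means_match_exhaustive_order_enumeration(self):
        # oracle: enumerate all per-step update orders of the 2-variable
        # negative loop A* = NOT B, B* = A and average exactly
        bm = _toggle2()
        n_steps = 4
        totals = np.zeros((2, n_steps + 1))
        orders = list(itertools.product([("A", "B"), ("B", "A")], repeat=n_steps))
        for seq in orders:
            state = {"A": False, "B": False}
            totals[:, 0] += [state["A"], state["B"]]
            for step, order in enumerate(seq, start=1):
                for var in order:
                    state[var] = bm.rules[var].evaluate(state)
                totals[:, step] += [state["A"], state["B"]]
        exact = totals / len(orders)

        sim = run_async(bm, {"A": False, "B": False}, n_runs=3000, n_steps=n_steps, seed=123)
        assert np.abs(sim.to_numpy() - exact).max() < 0.05
        # the loop has no fixed point: long-run averages sit strictly inside (0, 1)
        assert 0.0 < exact[0, -1] < 1.0

    def test_negative_feedback_cycle_settles_to_one_arm_per_run(self):
        bm = negative_feedback_toggle()
        init = {v: False for v in bm.variables}
        arm1 = {"A": 1.0, "a": 1.0, "B": 0.0, "b": 0.0}
        arm2 = {"A": 0.0, "a": 0.0, "B": 1.0, "b": 1.0}
        for seed in range(8):
            m = run_async(bm, init, n_runs=1, n_steps=20, seed=seed)
            final = m.iloc[:, -1].to_dict()
            assert final in (arm1, arm2)

    def test_clamps_respected(self):
        bm = _toggle2()
        m = run_async(bm, {"A": False, "B": False}, n_runs=5, n_steps=5, seed=1,
                      clamps={"A": False})
        assert (m.loc["A"] == 0.0).all()
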