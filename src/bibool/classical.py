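"""Component-level ("classical") Boolean export.

Built from the reaction-graph topology only: one variable per
component, input and output; activation flows from the source of a
reaction to its target, bonds activate both partners symmetrically, and
contingency context is reduced to the components and inputs involved.
This construction deliberately discards which *state* of a component
carries a signal, so crosstalk through shared components leaks — it
exists to contrast with the bipartite export, which keeps the signals
separate.  The derivation is a documented heuristic (such models are
traditionally written by hand), chosen to reproduce the expected
topology on the crosstalk fixture; it makes no claim of correctness for
arbitrary networks.
"""

from __future__ import annotations

from .bipartite import BooleanModel
from .core import Diagnostic, ElementalReaction, RxnconModel, skeleton
from .expr import Atom, and_, not_, or_

__all__ = ["build_classical"]


def _reaction_targets(r: ElementalReaction) -> list[str]:
    # bonds activate both partners; directed reactions act on B
    if not r.rtype.directed:
        return [c.name for c in r.components]
    return [r.component_b.name]


def _is_inhibitory(r: ElementalReaction) -> bool:
    # consuming-type reactions (dephosphorylation, degradation, ...)
    # deactivate their target
    produced, consumed = skeleton(r)
    return bool(consumed) and not produced


def build_classical(model: RxnconModel) -> tuple[BooleanModel, list[Diagnostic]]:
    """Derive the component-level Boolean model from reaction topology.

    For each component/output T:

    * activators: source components of non-inhibitory reactions
      targeting T whose net contingency context (+1 per ``!``/``K+``,
      -1 per ``x``/``K-``) is non-negative, plus the components of
      positive state effectors and positive input effectors of those
      reactions' contingencies;
    * inhibitors: sources of inhibitory (consuming-type) reactions and
      components/inputs of negative effectors;
    * rule(T) = OR(activators) AND NOT OR(inhibitors).

    Components with no incoming reaction keep their own value (constant)
    and are reported in the returned diagnostics.  Inputs are constant;
    outputs get activators from their contingencies.  No state or
    reaction variables are introduced.
    """
    activators: dict[str, set[str]] = {}
    inhibitors: dict[str, set[str]] = {}

    def _context(target_contingencies):
        """(net sign, positive contributors, negative contributors)"""
        net = 0
        pos: set[str] = set()
        neg: set[str] = set()
        for c in target_contingencies:
            sign = {"K+": "!", "K-": "x"}.get(c.sign, c.sign)
            if sign not in ("!", "x"):
                continue
            bucket = pos if sign == "!" else neg
            net += 1 if sign == "!" else -1
            for name in _effector_components(model, c.effector):
                bucket.add(name)
        return net, pos, neg

    for r in model.reactions:
        net, pos, neg = _context(model.contingencies_on(r.id))
        for target in _reaction_targets(r):
            sources = {c.name for c in r.components if c.name != target}
            if _is_inhibitory(r):
                inhibitors.setdefault(target, set()).update(sources | pos)
            elif net >= 0:
                activators.setdefault(target, set()).update(sources | pos)
            inhibitors.setdefault(target, set()).update(neg)

    for out in model.outputs:
        _, pos, neg = _context(model.contingencies_on(out))
        activators.setdefault(out, set()).update(pos)
        inhibitors.setdefault(out, set()).update(neg)

    bm = BooleanModel(kind="classical")
    diagnostics: list[Diagnostic] = []
    pure_inputs = sorted(model.inputs - model.outputs)

    def _rule_for(name: str):
        acts = sorted(activators.get(name, ()))
        inhs = sorted(inhibitors.get(name, ()))
        if not acts:
            diagnostics.append(
                Diagnostic("no-activators", f"{name} has no incoming activation; kept constant", name)
            )
            return Atom(name)
        rule = or_([Atom(a) for a in acts])
        if inhs:
            rule = and_(rule, not_(or_([Atom(i) for i in inhs])))
        return rule

    comps = dict(model.components)
    for s in model.states():  # contingency-only states may carry new components
        for c in s.components:
            comps.setdefault(c.name, c)
    for comp in comps.values():
        bm.add(comp.name, "component", _rule_for(comp.name))
    for inp in pure_inputs:
        bm.add(inp, "input")  # constant
    for out in sorted(model.outputs):
        bm.add(out, "output", _rule_for(out))
    bm.check_closed()
    return bm, diagnostics


def _effector_components(model: RxnconModel, effector) -> set[str]:
    """Components/inputs a (possibly nested) effector refers to."""
    if effector.kind == "state":
        return {c.name for c in effector.state.components}
    if effector.kind == "input":
        return {effector.name}
    node = model.boolean_nodes.get(effector.name)
    if node is None:
        return set()
    out: set[str] = set()
    for child in node.children:
        out |= _effector_components(model, child)
    return out
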