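"""Automatic derivation of the bipartite Boolean model.

One Boolean variable is created per elemental reaction, per elemental
state, per component, per input and per output.  The two node classes
get distinct update rules:

* a **reaction** is true when its two components are present and its
  contingencies are satisfied — required effectors (``!``, and ``K+``
  under the strict-qualitative policy) enter with AND, inhibiting
  effectors (``x`` / ``K-``) enter negated;

* a **state** follows the reactions that produce and consume it.
  Irreversible producers latch the state on; reversible producers must
  stay on to maintain it (the state decays when they switch off);
  consumers switch it off unless an irreversible producer overrides.

Components and inputs are constant under update (rule = own value);
outputs are treated exactly like states, produced by a pseudo-reaction
that carries the output's contingencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

from .core import (
    Effector,
    ElementalReaction,
    ElementalState,
    ModelError,
    RxnconModel,
    skeleton,
)
from .expr import Atom, BoolExpr, FALSE, and_, not_, or_

__all__ = [
    "BooleanModel",
    "Role",
    "flatten_effector",
    "reaction_rule",
    "state_rule",
    "build_bipartite",
    "output_pseudo_reaction_id",
]

Role = Literal["reaction", "state", "component", "input", "output"]

#: Contingency policies: how quantitative signs are mapped before export.
#: ``strict`` (default) treats K+ as ! and K- as x; ``neutral`` drops both.
POLICIES = ("strict", "neutral")


@dataclass
class BooleanModel:
    """An executable Boolean network: ordered variables + update rules."""

    variables: list[str] = field(default_factory=list)
    rules: dict[str, BoolExpr] = field(default_factory=dict)
    roles: dict[str, Role] = field(default_factory=dict)
    kind: str = "bipartite"

    def add(self, var: str, role: Role, rule: Optional[BoolExpr] = None) -> None:
        if var in self.roles:
            raise ModelError(f"duplicate Boolean variable {var!r}")
        self.variables.append(var)
        self.roles[var] = role
        self.rules[var] = rule if rule is not None else Atom(var)

    def by_role(self, role: Role) -> list[str]:
        return [v for v in self.variables if self.roles[v] == role]

    def check_closed(self) -> None:
        """Every atom of every rule must be a declared variable."""
        declared = set(self.variables)
        for var, rule in self.rules.items():
            for atom in rule.atoms():
                if atom not in declared:
                    raise ModelError(f"rule for {var!r} references undeclared variable {atom!r}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BooleanModel):
            return NotImplemented
        return (
            self.variables == other.variables
            and self.rules == other.rules
            and self.roles == other.roles
            and self.kind == other.kind
        )


def output_pseudo_reaction_id(output: str) -> str:
    """Variable id of the pseudo-reaction producing a given output."""
    return f"{output}_gen"


def flatten_effector(model: RxnconModel, e: Effector) -> BoolExpr:
    """Expand an effector to an expression over state/input atoms only.

    Boolean node references are flattened recursively; a cyclic node
    reference raises naming the cycle.
    """
    return _flatten(model, e, stack=[])


def _flatten(model: RxnconModel, e: Effector, stack: list[str]) -> BoolExpr:
    if e.kind == "state":
        return Atom(e.state.id)
    if e.kind == "input":
        return Atom(e.name)
    node = model.boolean_nodes.get(e.name)
    if node is None:
        raise ModelError(f"undefined Boolean node {e.name!r}")
    if e.name in stack:
        cycle = " -> ".join(stack[stack.index(e.name):] + [e.name])
        raise ModelError(f"cyclic Boolean node reference: {cycle}")
    stack.append(e.name)
    try:
        children = [_flatten(model, c, stack) for c in node.children]
    finally:
        stack.pop()
    if node.operator == "AND":
        return and_(children)
    if node.operator == "OR":
        return or_(children)
    return not_(children[0])


def _split_contingencies(model: RxnconModel, target: str, policy: str):
    if policy not in POLICIES:
        raise ModelError(f"unknown contingency policy {policy!r}; choose from {POLICIES}")
    positive: list[BoolExpr] = []
    negative: list[BoolExpr] = []
    for c in model.contingencies_on(target):
        sign = c.sign
        if sign in ("0", "?"):
            continue
        if sign in ("K+", "K-"):
            if policy == "neutral":
                continue
            sign = "!" if sign == "K+" else "x"
        expr = flatten_effector(model, c.effector)
        (positive if sign == "!" else negative).append(expr)
    return positive, negative


def reaction_rule(model: RxnconModel, r: ElementalReaction, policy: str = "strict") -> BoolExpr:
    """Update rule for a reaction variable.

    AND of the reaction's components, its required effectors and the
    negations of its inhibiting effectors; ``0``/``?`` are ignored.
    """
    positive, negative = _split_contingencies(model, r.id, policy)
    conjuncts: list[BoolExpr] = [Atom(c.name) for c in r.components]
    conjuncts.extend(positive)
    conjuncts.extend(not_(n) for n in negative)
    return and_(conjuncts)


def state_rule(
    model: RxnconModel,
    s: ElementalState,
    conjoin_components: bool = True,
    producers: Optional[list[ElementalReaction]] = None,
    consumers: Optional[list[ElementalReaction]] = None,
) -> BoolExpr:
    """Update rule for a state variable.

    With irreversible producers ``P_irr``, reversible producers
    ``P_rev`` and consumers ``C``::

        maintenance = OR(P_rev)            if P_rev else  the state itself
        rule        = comps AND ( OR(P_irr)  OR  (maintenance AND NOT OR(C)) )

    Empty disjunctions drop out; a state with no producers and no
    consumers is frozen at its own value (flagged by the validator).
    The irreversible-producer branch latches the state on and overrides
    consumption; the reversible branch makes the state track its
    producer and decay with it.  ``conjoin_components=False`` omits the
    component conjuncts (components are constant-true by default, so
    this changes only the printed form, not the dynamics).
    """
    if producers is None or consumers is None:
        all_prod, all_cons = model.producers_consumers()
        producers = all_prod.get(s.id, [])
        consumers = all_cons.get(s.id, [])
    # a reaction both producing and consuming the same state: production wins
    prod_ids = {p.id for p in producers}
    consumers = [c for c in consumers if c.id not in prod_ids]

    p_irr = [Atom(p.id) for p in producers if not p.rtype.reversible]
    p_rev = [Atom(p.id) for p in producers if p.rtype.reversible]
    cons = [Atom(c.id) for c in consumers]

    maintenance = or_(p_rev) if p_rev else Atom(s.id)
    keep = and_(maintenance, not_(or_(cons))) if cons else maintenance
    core = or_(or_(p_irr) if p_irr else FALSE, keep)
    if not producers and not consumers:
        core = Atom(s.id)
    if conjoin_components:
        return and_([Atom(c.name) for c in s.components] + [core])
    return core


def build_bipartite(
    model: RxnconModel,
    policy: str = "strict",
    conjoin_components: bool = True,
) -> BooleanModel:
    """Derive the bipartite Boolean model; pure and deterministic.

    Variable order: components, reactions, states, output
    pseudo-reactions, inputs, outputs — each in model declaration order.
    """
    bm = BooleanModel(kind="bipartite")
    comps = dict(model.components)
    for s in model.states():  # contingency-only states may carry new components
        for c in s.components:
            comps.setdefault(c.name, c)
    for comp in comps.values():
        bm.add(comp.name, "component")  # constant: rule = own atom
    for r in model.reactions:
        bm.add(r.id, "reaction", reaction_rule(model, r, policy))
    producers, consumers = model.producers_consumers()
    for s in model.states():
        bm.add(
            s.id,
            "state",
            state_rule(
                model,
                s,
                conjoin_components=conjoin_components,
                producers=producers.get(s.id, []),
                consumers=consumers.get(s.id, []),
            ),
        )
    for out in sorted(model.outputs):
        positive, negative = _split_contingencies(model, out, policy)
        gen_rule = and_(list(positive) + [not_(n) for n in negative])
        gen = output_pseudo_reaction_id(out)
        bm.add(gen, "reaction", gen_rule)
        # the pseudo-reaction is reversible: the output tracks it like a
        # reversible-producer state with no consumers
        bm.add(out, "output", Atom(gen))
    for inp in sorted(model.inputs):
        if inp in model.outputs:
            continue  # a fed-back node already has its output rule
        bm.add(inp, "input")
    bm.check_closed()
    return bm
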