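"""Domain model for reaction-contingency networks.

A network is defined by *elemental reactions* between pairs of
components (binding, phosphorylation, phosphotransfer, ...) and the
*elemental states* those reactions produce or consume (bonds ``A--B``
and modifications ``A-{P}``), plus *contingencies*: contextual
constraints saying how states, inputs or Boolean combinations thereof
switch reactions on or off.  This module holds the domain types, the
reaction-type registry mapping each reaction symbol to its state
templates and reversibility, and model-level validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

__all__ = [
    "Component",
    "StateTemplate",
    "ReactionTypeDef",
    "ElementalReaction",
    "ElementalState",
    "CONTINGENCY_SIGNS",
    "Effector",
    "BooleanNodeDef",
    "Contingency",
    "RxnconModel",
    "Diagnostic",
    "RegistryError",
    "ModelError",
    "default_registry",
    "skeleton",
    "validate_model",
    "parse_registry_config",
]

#: Admissible contingency signs: required, inhibiting, quantitative
#: positive/negative, no effect, unknown.
CONTINGENCY_SIGNS = ("!", "x", "K+", "K-", "0", "?")

_RESERVED = set("_-{}[]; \t")


class RegistryError(KeyError):
    """Unknown or ill-formed reaction type."""


class ModelError(ValueError):
    """Ill-formed model content."""


@dataclass(frozen=True)
class Component:
    """A network component (protein, gene...), e.g. ``Hog1``."""

    name: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ModelError("component name must be non-empty")
        bad = _RESERVED.intersection(self.name)
        if bad:
            raise ModelError(
                f"component name {self.name!r} contains reserved characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class StateTemplate:
    """Template for a state over the two reaction slots A and B.

    ``kind='bond'`` uses both slots; ``kind='mod'`` uses ``slot`` and a
    modification ``label`` (e.g. P, Ub, GTP, present).
    """

    kind: Literal["bond", "mod"]
    slot: str = "B"  # for mod templates: which slot carries the modification
    label: str = "P"

    def __post_init__(self) -> None:
        if self.kind not in ("bond", "mod"):
            raise ModelError(f"unknown template kind {self.kind!r}")
        if self.slot not in ("A", "B"):
            raise ModelError(f"template slot must be A or B, got {self.slot!r}")

    def instantiate(self, a: Component, b: Component) -> "ElementalState":
        if self.kind == "bond":
            return ElementalState.bond(a, b)
        return ElementalState.modification(a if self.slot == "A" else b, self.label)


@dataclass(frozen=True)
class ReactionTypeDef:
    """Semantics of one reaction symbol (e.g. ``ppi``, ``P+``, ``PT``)."""

    symbol: str
    reversible: bool
    produced_templates: tuple[StateTemplate, ...] = ()
    consumed_templates: tuple[StateTemplate, ...] = ()
    directed: bool = True

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ModelError("reaction type symbol must be non-empty")
        if self.reversible and not self.produced_templates:
            raise ModelError(
                f"reversible reaction type {self.symbol!r} needs a produced state "
                "(its decay semantics need a product)"
            )


@dataclass(frozen=True)
class ElementalReaction:
    """A single reaction event ``A_<symbol>_B`` between two components."""

    component_a: Component
    component_b: Component
    rtype: ReactionTypeDef

    @property
    def id(self) -> str:
        return f"{self.component_a.name}_{self.rtype.symbol}_{self.component_b.name}"

    @property
    def components(self) -> tuple[Component, ...]:
        if self.component_a == self.component_b:
            return (self.component_a,)
        return (self.component_a, self.component_b)


@dataclass(frozen=True)
class ElementalState:
    """A bond ``A--B`` or modification ``A-{M}`` state.

    Bond states are order-normalised so that ``A--B`` and ``B--A`` are
    the same state.
    """

    components: tuple[Component, ...]
    kind: Literal["bond", "mod"]
    label: str = ""

    @staticmethod
    def bond(a: Component, b: Component) -> "ElementalState":
        first, second = sorted((a, b), key=lambda c: c.name)
        return ElementalState(components=(first, second), kind="bond")

    @staticmethod
    def modification(c: Component, label: str) -> "ElementalState":
        return ElementalState(components=(c,), kind="mod", label=label)

    @property
    def id(self) -> str:
        if self.kind == "bond":
            return f"{self.components[0].name}--{self.components[1].name}"
        return f"{self.components[0].name}-{{{self.label}}}"

    def __post_init__(self) -> None:
        if self.kind == "bond" and len(self.components) != 2:
            raise ModelError("bond state needs exactly two components")
        if self.kind == "mod" and len(self.components) != 1:
            raise ModelError("modification state needs exactly one component")


@dataclass(frozen=True)
class Effector:
    """Right-hand side of a contingency: a state, an input or a Boolean node."""

    kind: Literal["state", "input", "node"]
    state: Optional[ElementalState] = None
    name: str = ""  # input name (with brackets) or node name

    @staticmethod
    def of_state(state: ElementalState) -> "Effector":
        return Effector(kind="state", state=state)

    @staticmethod
    def of_input(name: str) -> "Effector":
        if not (name.startswith("[") and name.endswith("]")):
            raise ModelError(f"input name must be bracketed, got {name!r}")
        return Effector(kind="input", name=name)

    @staticmethod
    def of_node(name: str) -> "Effector":
        return Effector(kind="node", name=name)

    @property
    def text(self) -> str:
        return self.state.id if self.kind == "state" else self.name


@dataclass(frozen=True)
class BooleanNodeDef:
    """Named AND/OR/NOT combination of effectors, usable as an effector."""

    name: str
    operator: Literal["AND", "OR", "NOT"]
    children: tuple[Effector, ...]

    def __post_init__(self) -> None:
        if self.operator == "NOT" and len(self.children) != 1:
            raise ModelError(f"NOT node {self.name!r} must have exactly one child")
        if self.operator in ("AND", "OR") and len(self.children) < 2:
            raise ModelError(f"{self.operator} node {self.name!r} needs >= 2 children")


@dataclass(frozen=True)
class Contingency:
    """``target`` (reaction id or bracketed output) constrained by ``effector``."""

    target: str
    sign: str
    effector: Effector

    def __post_init__(self) -> None:
        if self.sign not in CONTINGENCY_SIGNS:
            raise ModelError(
                f"contingency sign {self.sign!r} not in {CONTINGENCY_SIGNS}"
            )


@dataclass
class RxnconModel:
    """A reaction-contingency network definition."""

    registry: dict[str, ReactionTypeDef] = field(default_factory=lambda: default_registry())
    components: dict[str, Component] = field(default_factory=dict)
    reactions: list[ElementalReaction] = field(default_factory=list)
    contingencies: list[Contingency] = field(default_factory=list)
    boolean_nodes: dict[str, BooleanNodeDef] = field(default_factory=dict)
    inputs: set[str] = field(default_factory=set)
    outputs: set[str] = field(default_factory=set)

    # -- construction helpers -------------------------------------------------
    def add_component(self, name: str) -> Component:
        comp = self.components.get(name)
        if comp is None:
            comp = Component(name)
            self.components[name] = comp
        return comp

    def add_reaction(self, a: str, symbol: str, b: str) -> ElementalReaction:
        """Add (or return the existing) reaction ``a_symbol_b``."""
        rtype = self.registry.get(symbol)
        if rtype is None:
            raise RegistryError(f"unknown reaction type symbol {symbol!r}")
        rxn = ElementalReaction(self.add_component(a), self.add_component(b), rtype)
        existing = self.reaction_by_id(rxn.id)
        if existing is not None:
            return existing
        self.reactions.append(rxn)
        return rxn

    def add_contingency(self, target: str, sign: str, effector: Effector) -> Contingency:
        if effector.kind == "input":
            self.inputs.add(effector.name)
        cont = Contingency(target=target, sign=sign, effector=effector)
        self.contingencies.append(cont)
        return cont

    def add_output(self, name: str) -> str:
        if not (name.startswith("[") and name.endswith("]")):
            raise ModelError(f"output name must be bracketed, got {name!r}")
        self.outputs.add(name)
        return name

    def add_boolean_node(self, node: BooleanNodeDef) -> BooleanNodeDef:
        self.boolean_nodes[node.name] = node
        return node

    # -- queries --------------------------------------------------------------
    def reaction_by_id(self, rid: str) -> Optional[ElementalReaction]:
        for r in self.reactions:
            if r.id == rid:
                return r
        return None

    def states(self) -> list[ElementalState]:
        """All elemental states: skeleton products/consumptions plus
        states referenced only by contingencies, in first-seen order."""
        seen: dict[str, ElementalState] = {}
        for r in self.reactions:
            produced, consumed = skeleton(r)
            for s in (*produced, *consumed):
                seen.setdefault(s.id, s)
        for eff in self._all_effectors():
            if eff.kind == "state":
                seen.setdefault(eff.state.id, eff.state)
        return list(seen.values())

    def _all_effectors(self) -> Iterable[Effector]:
        for c in self.contingencies:
            yield c.effector
        for node in self.boolean_nodes.values():
            yield from node.children

    def producers_consumers(self) -> tuple[dict[str, list[ElementalReaction]], dict[str, list[ElementalReaction]]]:
        """Maps state id -> producing / consuming reactions."""
        producers: dict[str, list[ElementalReaction]] = {}
        consumers: dict[str, list[ElementalReaction]] = {}
        for r in self.reactions:
            produced, consumed = skeleton(r)
            for s in produced:
                producers.setdefault(s.id, []).append(r)
            for s in consumed:
                consumers.setdefault(s.id, []).append(r)
        return producers, consumers

    def contingencies_on(self, target: str) -> list[Contingency]:
        return [c for c in self.contingencies if c.target == target]


@dataclass(frozen=True)
class Diagnostic:
    """Non-fatal finding from :func:`validate_model`."""

    code: str
    message: str
    subject: str = ""

    def __str__(self) -> str:  # pragma: no cover
        return f"[{self.code}] {self.message}"


def default_registry() -> dict[str, ReactionTypeDef]:
    """The built-in reaction-type registry.

    Reconstructed from the standard reaction vocabulary of the
    reaction-contingency format: reversible interactions produce a bond,
    phosphorylation-class reactions irreversibly produce (or consume) a
    modification, phosphotransfer moves a phosphate from the catalyst to
    the substrate.  Extensible via :func:`parse_registry_config`.
    """
    mod = lambda slot, label: StateTemplate("mod", slot, label)  # noqa: E731
    bond = StateTemplate("bond")
    defs = [
        ReactionTypeDef("ppi", reversible=True, produced_templates=(bond,), directed=False),
        ReactionTypeDef("i", reversible=True, produced_templates=(bond,), directed=False),
        ReactionTypeDef("P+", reversible=False, produced_templates=(mod("B", "P"),)),
        ReactionTypeDef("P-", reversible=False, consumed_templates=(mod("B", "P"),)),
        ReactionTypeDef("AP", reversible=False, produced_templates=(mod("A", "P"),)),
        ReactionTypeDef(
            "PT",
            reversible=False,
            produced_templates=(mod("B", "P"),),
            consumed_templates=(mod("A", "P"),),
        ),
        ReactionTypeDef("Ub+", reversible=False, produced_templates=(mod("B", "Ub"),)),
        ReactionTypeDef("Ub-", reversible=False, consumed_templates=(mod("B", "Ub"),)),
        ReactionTypeDef("GEF", reversible=False, produced_templates=(mod("B", "GTP"),)),
        ReactionTypeDef("GAP", reversible=False, consumed_templates=(mod("B", "GTP"),)),
        ReactionTypeDef("TRSC", reversible=False, produced_templates=(mod("B", "mRNA"),)),
        ReactionTypeDef("deg", reversible=False, consumed_templates=(mod("B", "present"),)),
    ]
    return {d.symbol: d for d in defs}


def skeleton(reaction: ElementalReaction) -> tuple[list[ElementalState], list[ElementalState]]:
    """Instantiate the reaction type's templates for one reaction.

    Returns ``(produced, consumed)`` elemental states; bond states are
    canonically ordered, so ``A_ppi_B`` and ``B_ppi_A`` yield the same
    state id.
    """
    a, b = reaction.component_a, reaction.component_b
    produced = [t.instantiate(a, b) for t in reaction.rtype.produced_templates]
    consumed = [t.instantiate(a, b) for t in reaction.rtype.consumed_templates]
    return produced, consumed


def validate_model(model: RxnconModel) -> list[Diagnostic]:
    """Structural validation; returns diagnostics, never raises.

    Flags: contingency targets that do not resolve, effector states no
    reaction produces, modification states with irreversible producers
    and no consuming reaction (candidate gaps fixable by
    :func:`bibool.fixtures.add_reverse_reactions`), dangling Boolean
    node references, inputs used as targets, outputs without
    contingencies, duplicate reaction ids, and self-consuming reactions.
    """
    diags: list[Diagnostic] = []
    producers, consumers = model.producers_consumers()
    reaction_ids = [r.id for r in model.reactions]

    seen_ids: set[str] = set()
    for rid in reaction_ids:
        if rid in seen_ids:
            diags.append(Diagnostic("duplicate-reaction", f"duplicate reaction id {rid}", rid))
        seen_ids.add(rid)

    for r in model.reactions:
        produced, consumed = skeleton(r)
        overlap = {s.id for s in produced} & {s.id for s in consumed}
        for sid in overlap:
            diags.append(
                Diagnostic(
                    "self-consuming",
                    f"reaction {r.id} both produces and consumes {sid}; production wins",
                    r.id,
                )
            )

    # states with irreversible-only production and no consumer
    for sid, prods in producers.items():
        if sid in consumers:
            continue
        if all(not p.rtype.reversible for p in prods):
            diags.append(
                Diagnostic(
                    "irreversible-only",
                    f"state {sid} is produced irreversibly and never consumed (latches on)",
                    sid,
                )
            )

    # contingency resolution
    known_nodes = set(model.boolean_nodes)
    for c in model.contingencies:
        if c.target.startswith("["):
            if c.target in model.inputs and c.target not in model.outputs:
                diags.append(
                    Diagnostic("input-as-target", f"input {c.target} used as contingency target", c.target)
                )
            elif c.target not in model.outputs:
                diags.append(
                    Diagnostic("unresolved-target", f"unknown output target {c.target}", c.target)
                )
        elif c.target not in seen_ids:
            diags.append(
                Diagnostic("unresolved-target", f"contingency targets unknown reaction {c.target}", c.target)
            )
        _check_effector(c.effector, producers, known_nodes, diags)

    for node in model.boolean_nodes.values():
        for child in node.children:
            _check_effector(child, producers, known_nodes, diags)

    # unused boolean nodes
    referenced = {
        e.name
        for e in model._all_effectors()
        if e.kind == "node"
    }
    for name in known_nodes - referenced:
        diags.append(Diagnostic("dangling-node", f"Boolean node {name} is never referenced", name))

    for out in model.outputs:
        if not model.contingencies_on(out):
            diags.append(Diagnostic("unregulated-output", f"output {out} has no contingencies", out))

    return diags


def _check_effector(
    eff: Effector,
    producers: dict[str, list[ElementalReaction]],
    known_nodes: set[str],
    diags: list[Diagnostic],
) -> None:
    if eff.kind == "state" and eff.state.id not in producers:
        diags.append(
            Diagnostic(
                "unproduced-effector",
                f"effector state {eff.state.id} is produced by no reaction",
                eff.state.id,
            )
        )
    elif eff.kind == "node" and eff.name not in known_nodes:
        diags.append(
            Diagnostic("dangling-node", f"reference to undefined Boolean node {eff.name}", eff.name)
        )


def parse_registry_config(text: str, base: Optional[dict[str, ReactionTypeDef]] = None) -> dict[str, ReactionTypeDef]:
    """Parse a plain-text registry override/extension.

    One reaction type per line::

        symbol  rev|irr  [directed|undirected]  [produce=TPL,...]  [consume=TPL,...]

    where each template TPL is ``A--B`` (bond) or ``A-{M}`` / ``B-{M}``
    (modification of the named slot).  Lines starting with ``#`` are
    comments.  Entries replace same-symbol entries of ``base``.
    """
    registry = dict(base) if base else {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        if len(tokens) < 2:
            raise ModelError(f"registry config line {lineno}: need at least symbol and rev/irr")
        symbol, revtok = tokens[0], tokens[1].lower()
        if revtok not in ("rev", "irr", "reversible", "irreversible"):
            raise ModelError(f"registry config line {lineno}: bad reversibility {tokens[1]!r}")
        reversible = revtok.startswith("rev")
        directed = True
        produced: list[StateTemplate] = []
        consumed: list[StateTemplate] = []
        for tok in tokens[2:]:
            low = tok.lower()
            if low in ("directed", "undirected"):
                directed = low == "directed"
            elif low.startswith("produce="):
                produced.extend(_parse_template(t, lineno) for t in tok[8:].split(",") if t)
            elif low.startswith("consume="):
                consumed.extend(_parse_template(t, lineno) for t in tok[8:].split(",") if t)
            else:
                raise ModelError(f"registry config line {lineno}: unknown token {tok!r}")
        registry[symbol] = ReactionTypeDef(
            symbol, reversible, tuple(produced), tuple(consumed), directed
        )
    return registry


def _parse_template(text: str, lineno: int) -> StateTemplate:
    if text == "A--B":
        return StateTemplate("bond")
    for slot in ("A", "B"):
        prefix = f"{slot}-{{"
        if text.startswith(prefix) and text.endswith("}"):
            return StateTemplate("mod", slot, text[len(prefix):-1])
    raise ModelError(f"registry config line {lineno}: bad state template {text!r}")
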