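"""Boolean expression trees used by all update rules.

Expressions are immutable and compared structurally.  The smart
constructors :func:`and_`, :func:`or_` and :func:`not_` perform the
light normalisation that the rule-derivation layer relies on: constant
folding, dropping of neutral elements and collapsing of single-child
conjunctions/disjunctions.  Operator precedence in rendered and parsed
rules is NOT > AND > OR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

__all__ = [
    "BoolExpr",
    "Atom",
    "Const",
    "Not",
    "And",
    "Or",
    "TRUE",
    "FALSE",
    "and_",
    "or_",
    "not_",
]


class BoolExpr:
    """Base class for Boolean expression nodes."""

    def evaluate(self, assignment: Mapping[str, bool]) -> bool:
        raise NotImplementedError

    def atoms(self) -> Iterator[str]:
        """Yield the variable names referenced by this expression."""
        raise NotImplementedError

    def render(self, *, and_op: str = " & ", or_op: str = " | ", not_op: str = "!") -> str:
        """Render with precedence NOT > AND > OR, parenthesising as needed."""
        return _render(self, and_op, or_op, not_op)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


@dataclass(frozen=True)
class Atom(BoolExpr):
    name: str

    def evaluate(self, assignment: Mapping[str, bool]) -> bool:
        return bool(assignment[self.name])

    def atoms(self) -> Iterator[str]:
        yield self.name


@dataclass(frozen=True)
class Const(BoolExpr):
    value: bool

    def evaluate(self, assignment: Mapping[str, bool]) -> bool:
        return self.value

    def atoms(self) -> Iterator[str]:
        return iter(())


TRUE = Const(True)
FALSE = Const(False)


@dataclass(frozen=True)
class Not(BoolExpr):
    child: BoolExpr

    def evaluate(self, assignment: Mapping[str, bool]) -> bool:
        return not self.child.evaluate(assignment)

    def atoms(self) -> Iterator[str]:
        return self.child.atoms()


@dataclass(frozen=True)
class And(BoolExpr):
    children: tuple[BoolExpr, ...]

    def evaluate(self, assignment: Mapping[str, bool]) -> bool:
        return all(c.evaluate(assignment) for c in self.children)

    def atoms(self) -> Iterator[str]:
        for c in self.children:
            yield from c.atoms()


@dataclass(frozen=True)
class Or(BoolExpr):
    children: tuple[BoolExpr, ...]

    def evaluate(self, assignment: Mapping[str, bool]) -> bool:
        return any(c.evaluate(assignment) for c in self.children)

    def atoms(self) -> Iterator[str]:
        for c in self.children:
            yield from c.atoms()


def and_(*children: BoolExpr | Iterable[BoolExpr]) -> BoolExpr:
    """Conjunction; empty conjunction is TRUE."""
    items = _collect(children)
    out: list[BoolExpr] = []
    for c in items:
        if c == TRUE:
            continue
        if c == FALSE:
            return FALSE
        if isinstance(c, And):
            out.extend(c.children)
        else:
            out.append(c)
    if not out:
        return TRUE
    if len(out) == 1:
        return out[0]
    return And(tuple(out))


def or_(*children: BoolExpr | Iterable[BoolExpr]) -> BoolExpr:
    """Disjunction; empty disjunction is FALSE."""
    items = _collect(children)
    out: list[BoolExpr] = []
    for c in items:
        if c == FALSE:
            continue
        if c == TRUE:
            return TRUE
        if isinstance(c, Or):
            out.extend(c.children)
        else:
            out.append(c)
    if not out:
        return FALSE
    if len(out) == 1:
        return out[0]
    return Or(tuple(out))


def not_(child: BoolExpr) -> BoolExpr:
    if isinstance(child, Const):
        return Const(not child.value)
    if isinstance(child, Not):
        return child.child
    return Not(child)


def _collect(children) -> list[BoolExpr]:
    items: list[BoolExpr] = []
    for c in children:
        if isinstance(c, BoolExpr):
            items.append(c)
        else:
            items.extend(c)
    return items


# precedence levels: atoms/const/not = 3, and = 2, or = 1
def _prec(e: BoolExpr) -> int:
    if isinstance(e, Or):
        return 1
    if isinstance(e, And):
        return 2
    return 3


def _render(e: BoolExpr, and_op: str, or_op: str, not_op: str) -> str:
    if isinstance(e, Atom):
        return e.name
    if isinstance(e, Const):
        return "1" if e.value else "0"
    if isinstance(e, Not):
        inner = _render(e.child, and_op, or_op, not_op)
        if _prec(e.child) < 3:
            inner = f"({inner})"
        return f"{not_op}{inner}"
    if isinstance(e, And):
        parts = [
            f"({_render(c, and_op, or_op, not_op)})" if _prec(c) < 2 else _render(c, and_op, or_op, not_op)
            for c in e.children
        ]
        return and_op.join(parts)
    if isinstance(e, Or):
        parts = [_render(c, and_op, or_op, not_op) for c in e.children]
        return or_op.join(parts)
    raise TypeError(f"not a BoolExpr: {e!r}")
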