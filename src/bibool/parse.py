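"""Readers and writers for network definitions.

Two input styles are supported:

* the *quick* text format — one reaction per line, with contingency
  clauses appended after semicolons::

      Ssk1_ppi_Ssk2; x Ssk1-{P}
      Sln1_AP_Sln1; ! [Turgor]
      [MATING]; ! Fus3-{P}          # output-producing line
      GATE = AND(Ste5--Ste11, Ste11-{P})   # Boolean node definition

* tabular reaction/contingency lists (TSV/CSV or spreadsheet),
  mirroring the two-sheet layout: a reaction list defining topology and
  a contingency list with target / contingency-sign / modifier columns.

Both produce the same :class:`~bibool.core.RxnconModel`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .core import (
    BooleanNodeDef,
    CONTINGENCY_SIGNS,
    Effector,
    ElementalReaction,
    ElementalState,
    Component,
    ModelError,
    RegistryError,
    RxnconModel,
    default_registry,
)

__all__ = [
    "QuickSyntaxError",
    "parse_reaction_id",
    "parse_effector_text",
    "parse_quick",
    "serialize_quick",
    "load_tabular",
    "load_quick_file",
    "load_tabular_files",
    "load_excel",
]

_MOD_STATE_RE = re.compile(r"^([^\s_\-{}\[\];]+)-\{([^{}\s]+)\}$")
_NODE_CALL_RE = re.compile(r"^(AND|OR|NOT)\s*\((.*)\)$", re.IGNORECASE | re.DOTALL)
_SIGN_ALIASES = {s.lower(): s for s in CONTINGENCY_SIGNS}


class QuickSyntaxError(ValueError):
    """Aggregated per-line syntax errors with line numbers."""

    def __init__(self, errors: list[tuple[int, str]]):
        self.errors = errors
        msg = "; ".join(f"line {n}: {m}" for n, m in errors)
        super().__init__(msg)


def parse_reaction_id(text: str, model: Optional[RxnconModel] = None) -> ElementalReaction:
    """Parse ``A_<symbol>_B`` into an elemental reaction.

    The middle part (joined back with underscores if the symbol itself
    contains none of the component characters) must be a registered
    reaction-type symbol; symbols may contain ``+`` and ``-``.
    If ``model`` is given the reaction is added to it (idempotently).
    """
    text = text.strip()
    if not text:
        raise QuickSyntaxError([(0, "empty reaction text")])
    parts = text.split("_")
    if len(parts) < 3:
        raise QuickSyntaxError([(0, f"reaction {text!r} does not match A_<type>_B")])
    a, b = parts[0], parts[-1]
    symbol = "_".join(parts[1:-1])
    if not a or not b:
        raise QuickSyntaxError([(0, f"reaction {text!r} has an empty component")])
    if not symbol:
        raise QuickSyntaxError(
            [(0, f"reaction {text!r} has an empty type (position {len(a) + 1})")]
        )
    scratch = model if model is not None else RxnconModel()
    if symbol not in scratch.registry:
        raise RegistryError(f"unknown reaction type symbol {symbol!r} in {text!r}")
    return scratch.add_reaction(a, symbol, b)


def parse_effector_text(tok: str, model: RxnconModel) -> Effector:
    """Parse an effector token: state id, bracketed input, or node name."""
    tok = tok.strip()
    if not tok:
        raise ModelError("empty effector")
    if tok.startswith("[") and tok.endswith("]"):
        model.inputs.add(tok)
        return Effector.of_input(tok)
    if "--" in tok:
        left, sep, right = tok.partition("--")
        if not left or not right or "--" in right:
            raise ModelError(f"bad bond state {tok!r}")
        state = ElementalState.bond(model.add_component(left), model.add_component(right))
        return Effector.of_state(state)
    m = _MOD_STATE_RE.match(tok)
    if m:
        state = ElementalState.modification(model.add_component(m.group(1)), m.group(2))
        return Effector.of_state(state)
    # anything else is a Boolean node reference; <angle brackets> optional
    return Effector.of_node(tok.strip("<>"))


def parse_quick(text: str, registry=None) -> RxnconModel:
    """Parse the quick text format into a model.

    Per-line syntax errors are collected and raised together as
    :class:`QuickSyntaxError` with line numbers.
    """
    model = RxnconModel(registry=dict(registry) if registry else default_registry())
    errors: list[tuple[int, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            _parse_quick_line(line, model)
        except (ModelError, RegistryError, QuickSyntaxError) as exc:
            errors.append((lineno, str(exc)))
    if errors:
        raise QuickSyntaxError(errors)
    return model


def _parse_quick_line(line: str, model: RxnconModel) -> None:
    if "=" in line and not line.split("=", 1)[0].strip().startswith("["):
        # Boolean node definition:  NAME = AND(e1, e2, ...)
        name, _, body = line.partition("=")
        _parse_node_def(name.strip().strip("<>"), body.strip(), model)
        return
    head, *clauses = [part.strip() for part in line.split(";")]
    if head.startswith("[") and head.endswith("]"):
        target = model.add_output(head)
    else:
        target = parse_reaction_id(head, model).id
    for clause in clauses:
        if not clause:
            continue
        sign_tok, _, eff_text = clause.partition(" ")
        sign = _SIGN_ALIASES.get(sign_tok.strip().lower())
        if sign is None:
            raise ModelError(f"unknown contingency sign {sign_tok!r}")
        if not eff_text.strip():
            raise ModelError(f"contingency {clause!r} is missing an effector")
        model.add_contingency(target, sign, parse_effector_text(eff_text, model))


def _parse_node_def(name: str, body: str, model: RxnconModel) -> BooleanNodeDef:
    m = _NODE_CALL_RE.match(body)
    if not m:
        raise ModelError(f"Boolean node body {body!r} must be AND(...)/OR(...)/NOT(...)")
    operator = m.group(1).upper()
    children: list[Effector] = []
    for i, arg in enumerate(_split_args(m.group(2))):
        if _NODE_CALL_RE.match(arg):
            # nested combination: define an auxiliary node
            child = _parse_node_def(f"{name}.{i + 1}", arg, model)
            children.append(Effector.of_node(child.name))
        else:
            children.append(parse_effector_text(arg, model))
    node = BooleanNodeDef(name=name, operator=operator, children=tuple(children))
    return model.add_boolean_node(node)


def _split_args(text: str) -> list[str]:
    args, depth, cur = [], 0, []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "," and depth == 0:
            args.append("".join(cur).strip())
            cur = []
        else:
            cur.append(ch)
    tail = "".join(cur).strip()
    if tail:
        args.append(tail)
    return args


def serialize_quick(model: RxnconModel) -> str:
    """Render a model back to quick text (round-trips through
    :func:`parse_quick` to an id-identical model)."""
    lines: list[str] = []
    for node in model.boolean_nodes.values():
        if "." in node.name:
            continue  # auxiliary nodes are re-created from the nesting
        lines.append(f"{node.name} = {_render_node(node, model)}")
    for r in model.reactions:
        lines.append(_line_for_target(r.id, model))
    for out in sorted(model.outputs):
        lines.append(_line_for_target(out, model))
    return "\n".join(lines) + ("\n" if lines else "")


def _line_for_target(target: str, model: RxnconModel) -> str:
    parts = [target]
    for c in model.contingencies_on(target):
        parts.append(f"{c.sign} {c.effector.text}")
    return "; ".join(parts)


def _render_node(node: BooleanNodeDef, model: RxnconModel) -> str:
    rendered = []
    for child in node.children:
        if child.kind == "node" and child.name in model.boolean_nodes and "." in child.name:
            rendered.append(_render_node(model.boolean_nodes[child.name], model))
        else:
            rendered.append(child.text)
    return f"{node.operator}({', '.join(rendered)})"


# ---------------------------------------------------------------------------
# tabular input
# ---------------------------------------------------------------------------

@dataclass
class TableColumns:
    """Configurable column roles for the tabular input.

    The reaction list is read either from a full-id column or from the
    component/type triple; the contingency list needs target, sign and
    modifier columns.  Matching is case-insensitive.
    """

    reaction_id: tuple[str, ...] = ("Reaction", "ReactionID", "Reaction ID", "B")
    component_a: tuple[str, ...] = ("ComponentA", "Component A", "SourceComponent")
    reaction_type: tuple[str, ...] = ("ReactionType", "Reaction type", "Reaction")
    component_b: tuple[str, ...] = ("ComponentB", "Component B", "TargetComponent")
    target: tuple[str, ...] = ("Target", "TargetReaction", "B")
    sign: tuple[str, ...] = ("Contingency", "Sign", "C")
    modifier: tuple[str, ...] = ("Modifier", "Effector", "D")


def load_tabular(
    reaction_rows: pd.DataFrame,
    contingency_rows: Optional[pd.DataFrame] = None,
    registry=None,
    columns: Optional[TableColumns] = None,
) -> RxnconModel:
    """Build a model from reaction-list and contingency-list tables.

    Equivalent content yields the same model as :func:`parse_quick`.
    Boolean nodes are defined by contingency rows whose target is an
    ``<angle-bracketed>`` node name, with AND/OR/NOT in the sign column.
    """
    cols = columns or TableColumns()
    model = RxnconModel(registry=dict(registry) if registry else default_registry())

    id_col = _find_col(reaction_rows, cols.reaction_id)
    if id_col is not None:
        for raw in reaction_rows[id_col]:
            if _blank(raw):
                continue
            parse_reaction_id(str(raw).strip(), model)
    else:
        a_col = _find_col(reaction_rows, cols.component_a)
        t_col = _find_col(reaction_rows, cols.reaction_type)
        b_col = _find_col(reaction_rows, cols.component_b)
        if not (a_col and t_col and b_col):
            raise ModelError(
                "reaction table needs a reaction-id column or the "
                f"component/type triple; found {list(reaction_rows.columns)}"
            )
        for _, row in reaction_rows.iterrows():
            if _blank(row[a_col]):
                continue
            model.add_reaction(str(row[a_col]).strip(), str(row[t_col]).strip(), str(row[b_col]).strip())

    if contingency_rows is not None and len(contingency_rows):
        t_col = _find_col(contingency_rows, cols.target)
        s_col = _find_col(contingency_rows, cols.sign)
        m_col = _find_col(contingency_rows, cols.modifier)
        if not (t_col and s_col and m_col):
            raise ModelError(
                "contingency table needs target/sign/modifier columns; "
                f"found {list(contingency_rows.columns)}"
            )
        node_children: dict[str, tuple[str, list[Effector]]] = {}
        pending: list[tuple[str, str, str]] = []
        for _, row in contingency_rows.iterrows():
            if _blank(row[t_col]):
                continue
            target = str(row[t_col]).strip()
            sign_raw = str(row[s_col]).strip()
            modifier = str(row[m_col]).strip()
            if target.startswith("<"):
                op = sign_raw.upper()
                if op not in ("AND", "OR", "NOT"):
                    raise ModelError(f"Boolean node {target} row needs AND/OR/NOT, got {sign_raw!r}")
                name = target.strip("<>")
                entry = node_children.setdefault(name, (op, []))
                if entry[0] != op:
                    raise ModelError(f"Boolean node {name} mixes operators {entry[0]} and {op}")
                entry[1].append(parse_effector_text(modifier, model))
            else:
                pending.append((target, sign_raw, modifier))
        for name, (op, children) in node_children.items():
            model.add_boolean_node(BooleanNodeDef(name, op, tuple(children)))
        for target, sign_raw, modifier in pending:
            sign = _SIGN_ALIASES.get(sign_raw.lower())
            if sign is None:
                raise ModelError(f"unknown contingency sign {sign_raw!r} for target {target}")
            if target.startswith("["):
                model.add_output(target)
            elif model.reaction_by_id(target) is None:
                candidates = ", ".join(r.id for r in model.reactions) or "none"
                raise ModelError(
                    f"contingency target {target!r} matches no reaction (candidates: {candidates})"
                )
            eff = parse_effector_text(modifier, model)
            if eff.kind == "node" and eff.name not in model.boolean_nodes:
                candidates = ", ".join(sorted(model.boolean_nodes)) or "none"
                raise ModelError(
                    f"modifier {modifier!r} resolves to no state, input or Boolean node "
                    f"(known nodes: {candidates})"
                )
            model.add_contingency(target, sign, eff)
    return model


def _find_col(df: pd.DataFrame, candidates: tuple[str, ...]) -> Optional[str]:
    lowered = {str(c).strip().lower(): c for c in df.columns}
    for cand in candidates:
        hit = lowered.get(cand.lower())
        if hit is not None:
            return hit
    return None


def _blank(value) -> bool:
    return value is None or (isinstance(value, float) and pd.isna(value)) or str(value).strip() == ""


# ---------------------------------------------------------------------------
# file-level loaders
# ---------------------------------------------------------------------------

def load_quick_file(path: str | Path, registry=None) -> RxnconModel:
    return parse_quick(Path(path).read_text(encoding="utf-8"), registry=registry)


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, dtype=str)


def load_tabular_files(
    reactions_path: str | Path,
    contingencies_path: Optional[str | Path] = None,
    registry=None,
    columns: Optional[TableColumns] = None,
) -> RxnconModel:
    reactions = _read_table(Path(reactions_path))
    contingencies = _read_table(Path(contingencies_path)) if contingencies_path else None
    return load_tabular(reactions, contingencies, registry=registry, columns=columns)


def load_excel(
    path: str | Path,
    reaction_sheet: str = "(I) Reaction list",
    contingency_sheet: Optional[str] = None,
    registry=None,
    columns: Optional[TableColumns] = None,
) -> RxnconModel:
    """Read the two-sheet spreadsheet layout (reaction + contingency list)."""
    book = pd.read_excel(path, sheet_name=None, dtype=str)
    if reaction_sheet not in book:
        raise ModelError(f"sheet {reaction_sheet!r} not found in {path}; sheets: {list(book)}")
    contingencies = None
    if contingency_sheet is not None:
        contingencies = book[contingency_sheet]
    else:  # first sheet with a recognisable contingency header
        cols = columns or TableColumns()
        for name, df in book.items():
            if name == reaction_sheet:
                continue
            if _find_col(df, cols.sign) is not None and _find_col(df, cols.modifier) is not None:
                contingencies = df
                break
    return load_tabular(book[reaction_sheet], contingencies, registry=registry, columns=columns)
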