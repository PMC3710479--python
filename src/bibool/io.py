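"""Exporters: rule text, BoolNet ``.bnet``, regulatory graphs, CSV
matrices and the clustered time-course heat map.

All text output is UTF-8 with LF line endings.  Identifiers in the
native formats contain ``-``, ``{}``, ``[]`` and ``+``, which many
downstream Boolean tools reject; the ``.bnet`` writer therefore
sanitises identifiers and emits an alias table alongside.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .bipartite import BooleanModel
from .core import RxnconModel, skeleton
from .sim import PerturbationSchedule, Trajectory

__all__ = [
    "rules_text",
    "sanitise_ids",
    "to_bnet",
    "write_bnet",
    "export_regulatory_graph",
    "write_graphml",
    "write_dot",
    "trajectory_heatmap",
    "save_schedule",
    "load_schedule",
]


def rules_text(bm: BooleanModel) -> str:
    """Human-readable update rules, one ``<var>* = <expr>`` per line."""
    return "\n".join(f"{v}* = {bm.rules[v].render()}" for v in bm.variables) + "\n"


def sanitise_ids(bm: BooleanModel) -> dict[str, str]:
    """Map each variable id to a BoolNet-safe alias (unique, [A-Za-z0-9_])."""
    aliases: dict[str, str] = {}
    used: set[str] = set()
    for var in bm.variables:
        alias = (
            var.replace("+", "_p")
            .replace("-", "_d_")
            .replace("{", "")
            .replace("}", "")
            .replace("[", "")
            .replace("]", "")
        )
        alias = "".join(ch if (ch.isalnum() or ch == "_") else "_" for ch in alias)
        if not alias or alias[0].isdigit():
            alias = f"v_{alias}"
        base, k = alias, 2
        while alias in used:
            alias = f"{base}_{k}"
            k += 1
        used.add(alias)
        aliases[var] = alias
    return aliases


def to_bnet(bm: BooleanModel) -> tuple[str, dict[str, str]]:
    """Render as a BoolNet ``targets, factors`` file plus the alias table."""
    aliases = sanitise_ids(bm)
    lines = ["targets, factors"]
    for var in bm.variables:
        rendered = _alias_expr(bm.rules[var], aliases).render()
        lines.append(f"{aliases[var]}, {rendered}")
    return "\n".join(lines) + "\n", aliases


def _alias_expr(expr, aliases):
    from .expr import And, Atom, Not, Or

    if isinstance(expr, Atom):
        return Atom(aliases[expr.name])
    if isinstance(expr, Not):
        return Not(_alias_expr(expr.child, aliases))
    if isinstance(expr, And):
        return And(tuple(_alias_expr(c, aliases) for c in expr.children))
    if isinstance(expr, Or):
        return Or(tuple(_alias_expr(c, aliases) for c in expr.children))
    return expr


def write_bnet(bm: BooleanModel, path: str | Path) -> Path:
    """Write ``.bnet`` and an ``<stem>.aliases.csv`` table next to it."""
    path = Path(path)
    text, aliases = to_bnet(bm)
    path.write_text(text, encoding="utf-8")
    alias_path = path.with_suffix(".aliases.csv")
    pd.DataFrame(
        {"id": list(aliases), "alias": list(aliases.values())}
    ).to_csv(alias_path, index=False)
    return alias_path


_EDGE_COLOURS = {
    "produce": "blue",
    "consume": "purple",
    "activate": "green",
    "inhibit": "red",
    "neutral": "grey",
    "member": "black",
}

_SIGN_CLASS = {"!": "activate", "K+": "activate", "x": "inhibit", "K-": "inhibit",
               "0": "neutral", "?": "neutral"}


def export_regulatory_graph(model: RxnconModel) -> nx.DiGraph:
    """The bipartite regulatory graph.

    Reaction and state nodes; reaction->state edges classed
    ``produce``/``consume``, contingency edges state->reaction classed
    ``activate``/``inhibit`` (``0``/``?`` as ``neutral``), with colour
    attributes matching the conventional legend.  Inputs, outputs and
    Boolean combination nodes appear as their own node types; every
    contingency contributes exactly one effector->target edge.
    """
    g = nx.DiGraph()
    for r in model.reactions:
        g.add_node(r.id, node_type="reaction")
        produced, consumed = skeleton(r)
        for s in produced:
            g.add_node(s.id, node_type="state")
            g.add_edge(r.id, s.id, edge_class="produce", color=_EDGE_COLOURS["produce"])
        for s in consumed:
            g.add_node(s.id, node_type="state")
            g.add_edge(r.id, s.id, edge_class="consume", color=_EDGE_COLOURS["consume"])
    for name, node in model.boolean_nodes.items():
        g.add_node(name, node_type="boolean", operator=node.operator)
        for child in node.children:
            _ensure_effector_node(g, model, child)
            g.add_edge(child.text if child.kind != "node" else child.name, name,
                       edge_class="member", color=_EDGE_COLOURS["member"])
    for c in model.contingencies:
        _ensure_effector_node(g, model, c.effector)
        if c.target.startswith("["):
            g.add_node(c.target, node_type="output")
        cls = _SIGN_CLASS[c.sign]
        source = c.effector.text if c.effector.kind != "node" else c.effector.name
        g.add_edge(source, c.target, edge_class=cls, color=_EDGE_COLOURS[cls], sign=c.sign)
    return g


def _ensure_effector_node(g: nx.DiGraph, model: RxnconModel, eff) -> None:
    if eff.kind == "state":
        g.add_node(eff.state.id, node_type="state")
    elif eff.kind == "input":
        node_type = "output" if eff.name in model.outputs else "input"
        g.add_node(eff.name, node_type=node_type)
    else:
        node = model.boolean_nodes.get(eff.name)
        g.add_node(eff.name, node_type="boolean",
                   operator=node.operator if node else "?")


def write_graphml(g: nx.DiGraph, path: str | Path) -> None:
    nx.write_graphml(g, str(path))


def write_dot(g: nx.DiGraph, path: str | Path) -> None:
    """Minimal DOT writer (node/edge attributes as plain strings)."""
    def q(s: str) -> str:
        return '"' + str(s).replace('"', r"\"") + '"'

    lines = ["digraph G {"]
    for n, data in g.nodes(data=True):
        attrs = ", ".join(f"{k}={q(v)}" for k, v in sorted(data.items()))
        lines.append(f"  {q(n)}" + (f" [{attrs}]" if attrs else "") + ";")
    for u, v, data in g.edges(data=True):
        attrs = ", ".join(f"{k}={q(val)}" for k, val in sorted(data.items()))
        lines.append(f"  {q(u)} -> {q(v)}" + (f" [{attrs}]" if attrs else "") + ";")
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def trajectory_heatmap(
    traj: Trajectory | pd.DataFrame,
    cluster: bool = True,
    drop_constant: bool = True,
    image_path: Optional[str | Path] = None,
    metric: str = "hamming",
    linkage_method: str = "average",
) -> pd.DataFrame:
    """Time-course matrix ordered for heat-map display.

    Rows are variables, columns time steps.  Variables that never change
    are dropped; the remaining rows are ordered by hierarchical
    clustering of their 0/1 profiles (Hamming distance, average linkage
    by default), so entities with similar state evolution sit together.
    Optionally renders the matrix to an image file.
    """
    frame = traj.to_frame() if isinstance(traj, Trajectory) else traj.copy()
    if drop_constant:
        changing = frame.index[frame.nunique(axis=1) > 1]
        frame = frame.loc[changing]
    if cluster and len(frame) >= 2:
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import pdist

        distances = pdist(frame.to_numpy(dtype=float), metric=metric)
        order = hierarchy.leaves_list(hierarchy.linkage(distances, method=linkage_method))
        frame = frame.iloc[order]
    if image_path is not None and len(frame):
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(max(4.0, 0.25 * frame.shape[1]), max(2.0, 0.25 * frame.shape[0]))
        )
        ax.imshow(frame.to_numpy(dtype=float), aspect="auto", cmap="cividis",
                  interpolation="nearest")
        ax.set_yticks(np.arange(len(frame)), labels=list(frame.index), fontsize=6)
        ax.set_xlabel("time step")
        fig.tight_layout()
        fig.savefig(image_path, dpi=150)
        plt.close(fig)
    return frame


def save_schedule(schedule: PerturbationSchedule, path: str | Path) -> None:
    Path(path).write_text(json.dumps(schedule.to_json_obj(), indent=2) + "\n", encoding="utf-8")


def load_schedule(path: str | Path) -> PerturbationSchedule:
    return PerturbationSchedule.from_json_obj(json.loads(Path(path).read_text(encoding="utf-8")))
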