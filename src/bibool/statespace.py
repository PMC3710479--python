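"""State-transition graphs and attractor classification.

Under synchronous update the global state space is a functional graph
(out-degree exactly one), so every state reaches exactly one attractor:
a fixed point or a minimal-period cycle, the graph's terminal cycles.
The complete space can be enumerated only for small models; larger
models are explored as the closure reachable from given start states.
Constants (components, inputs) are excluded from the free variables by
default and held fixed, shrinking the enumerable space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .bipartite import BooleanModel
from .sim import TruthAssignment, sync_step

__all__ = ["Attractor", "TransitionGraph", "enumerate_full", "reachable"]

StateKey = tuple[bool, ...]


@dataclass(frozen=True)
class Attractor:
    kind: str  # "point" | "cycle"
    states: tuple[StateKey, ...]

    @property
    def period(self) -> int:
        return len(self.states)


@dataclass
class TransitionGraph:
    """Deduplicated global states with their synchronous successor map."""

    free_vars: list[str]
    fixed: TruthAssignment
    successor: dict[StateKey, StateKey]
    attractors: list[Attractor] = field(default_factory=list)
    basin_sizes: dict[int, int] = field(default_factory=dict)
    attractor_of: dict[StateKey, int] = field(default_factory=dict)

    @property
    def nodes(self) -> list[StateKey]:
        return list(self.successor)

    def assignment(self, key: StateKey) -> TruthAssignment:
        a = dict(self.fixed)
        a.update(zip(self.free_vars, key))
        return a

    def key_of(self, a: Mapping[str, bool]) -> StateKey:
        return tuple(bool(a[v]) for v in self.free_vars)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for key, nxt in self.successor.items():
            label = _hex_label(key)
            aid = self.attractor_of.get(key, -1)
            g.add_node(
                label,
                attractor=aid,
                in_attractor=bool(
                    aid >= 0 and key in set(self.attractors[aid].states)
                ),
            )
        for key, nxt in self.successor.items():
            g.add_edge(_hex_label(key), _hex_label(nxt))
        return g


def _hex_label(key: StateKey) -> str:
    value = 0
    for bit in key:
        value = (value << 1) | int(bit)
    width = max(1, (len(key) + 3) // 4)
    return f"{value:0{width}x}"


def default_free_vars(bm: BooleanModel) -> list[str]:
    """All variables except the constant components and inputs."""
    return [v for v in bm.variables if bm.roles[v] not in ("component", "input")]


def _fixed_for(bm: BooleanModel, free: Sequence[str], fixed: Optional[Mapping[str, bool]]) -> TruthAssignment:
    free_set = set(free)
    out: TruthAssignment = {}
    for v in bm.variables:
        if v in free_set:
            continue
        if fixed is not None and v in fixed:
            out[v] = bool(fixed[v])
        elif bm.roles[v] == "component" and bm.kind != "classical":
            out[v] = True
        else:
            out[v] = False
    missing = [v for v in bm.variables if v not in free_set and v not in out]
    if missing:
        raise KeyError(f"fixed assignment does not cover {missing}")
    return out


def enumerate_full(
    bm: BooleanModel,
    free_vars: Optional[Sequence[str]] = None,
    fixed: Optional[Mapping[str, bool]] = None,
    cap: int = 20,
) -> TransitionGraph:
    """Expand all ``2^|free_vars|`` states and classify attractors.

    ``fixed`` covers the remaining variables (defaulting to the standard
    constants: components true, inputs false).  Refuses above ``cap``
    free variables — use :func:`reachable` for larger models.
    """
    free = list(free_vars) if free_vars is not None else default_free_vars(bm)
    if len(free) > cap:
        raise ValueError(
            f"{len(free)} free variables exceeds the enumeration cap ({cap}); "
            "use reachable() from chosen start states instead"
        )
    fixed_assignment = _fixed_for(bm, free, fixed)
    succ: dict[StateKey, StateKey] = {}
    n = len(free)
    for idx in range(2 ** n):
        key = tuple(bool((idx >> (n - 1 - j)) & 1) for j in range(n))
        succ[key] = _successor(bm, free, fixed_assignment, key)
    graph = TransitionGraph(free, fixed_assignment, succ)
    _classify(graph)
    return graph


def reachable(
    bm: BooleanModel,
    starts: Iterable[TruthAssignment],
    free_vars: Optional[Sequence[str]] = None,
    max_nodes: int = 2 ** 20,
) -> TransitionGraph:
    """Breadth-first closure of the successor relation from ``starts``.

    All starts must agree on the non-free (fixed) variables.  Attractor
    classification is performed on the closure, which is closed under
    the successor map and therefore contains its terminal cycles.
    """
    starts = list(starts)
    if not starts:
        raise ValueError("need at least one start state")
    free = list(free_vars) if free_vars is not None else default_free_vars(bm)
    free_set = set(free)
    fixed_assignment = {v: bool(starts[0][v]) for v in bm.variables if v not in free_set}
    for a in starts[1:]:
        for v, val in fixed_assignment.items():
            if bool(a[v]) != val:
                raise ValueError(f"start states disagree on fixed variable {v!r}")

    succ: dict[StateKey, StateKey] = {}
    frontier = [tuple(bool(a[v]) for v in free) for a in starts]
    while frontier:
        nxt_frontier = []
        for key in frontier:
            if key in succ:
                continue
            nxt = _successor(bm, free, fixed_assignment, key)
            succ[key] = nxt
            if len(succ) > max_nodes:
                raise RuntimeError(f"reachable closure exceeded {max_nodes} states")
            if nxt not in succ:
                nxt_frontier.append(nxt)
        frontier = nxt_frontier
    graph = TransitionGraph(free, fixed_assignment, succ)
    _classify(graph)
    return graph


def _successor(
    bm: BooleanModel, free: Sequence[str], fixed: TruthAssignment, key: StateKey
) -> StateKey:
    a = dict(fixed)
    a.update(zip(free, key))
    nxt = sync_step(bm, a, clamps=fixed)
    return tuple(bool(nxt[v]) for v in free)


def _classify(graph: TransitionGraph) -> None:
    """Find terminal cycles and basins by pointer-chasing with colouring."""
    succ = graph.successor
    attractor_of: dict[StateKey, int] = {}
    attractors: list[Attractor] = []

    for start in succ:
        if start in attractor_of:
            continue
        path: list[StateKey] = []
        on_path: dict[StateKey, int] = {}
        node = start
        while node not in attractor_of and node not in on_path:
            on_path[node] = len(path)
            path.append(node)
            node = succ[node]
        if node in on_path:  # new cycle discovered
            i = on_path[node]
            cycle = tuple(path[i:])
            kind = "point" if len(cycle) == 1 else "cycle"
            aid = len(attractors)
            attractors.append(Attractor(kind, cycle))
        else:
            aid = attractor_of[node]
        for n in path:
            attractor_of[n] = aid

    graph.attractors = attractors
    graph.attractor_of = attractor_of
    basins: dict[int, int] = {i: 0 for i in range(len(attractors))}
    for node, aid in attractor_of.items():
        basins[aid] += 1
    graph.basin_sizes = basins
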