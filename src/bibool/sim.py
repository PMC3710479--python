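"""Execution of Boolean models.

Synchronous simulation updates every variable simultaneously from the
previous step and is deterministic; revisited global states are detected
by hashing, labelling the trajectory with a point or (minimal-period)
cyclic attractor.  Perturbation schedules set or clamp variables at
given time steps; a clamped variable ignores its rule until released.

Asynchronous simulation performs, per time step, one full pass over the
variables in a fresh uniformly random order, and averages variable
activity over an ensemble of runs (reproducible for a fixed seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .bipartite import BooleanModel

__all__ = [
    "PerturbationEvent",
    "PerturbationSchedule",
    "Trajectory",
    "default_init",
    "sync_step",
    "run_sync",
    "run_async",
]

TruthAssignment = dict[str, bool]


@dataclass(frozen=True)
class PerturbationEvent:
    """Set ``var`` to ``value`` at time ``t``; ``clamp`` holds it there.

    A clamped variable is excluded from rule updates until a later event
    on the same variable releases it (an unclamped event releases and
    performs a one-shot set; a clamped event moves the clamp).
    """

    t: int
    var: str
    value: bool
    clamp: bool = False

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("event time must be non-negative")


@dataclass
class PerturbationSchedule:
    events: list[PerturbationEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.t)

    def at(self, t: int) -> list[PerturbationEvent]:
        return [e for e in self.events if e.t == t]

    def validate(self, bm: BooleanModel) -> None:
        for e in self.events:
            if e.var not in bm.roles:
                raise KeyError(f"schedule event targets unknown variable {e.var!r}")

    @staticmethod
    def from_json_obj(obj: Iterable[Mapping]) -> "PerturbationSchedule":
        """Build from a list of ``{"t":..,"var":..,"value":..,"clamp":..}``."""
        return PerturbationSchedule(
            [
                PerturbationEvent(
                    int(d["t"]), str(d["var"]), bool(d["value"]), bool(d.get("clamp", False))
                )
                for d in obj
            ]
        )

    def to_json_obj(self) -> list[dict]:
        return [
            {"t": e.t, "var": e.var, "value": e.value, "clamp": e.clamp} for e in self.events
        ]


@dataclass
class Trajectory:
    """A synchronous simulation result.

    ``attractor`` is ``None`` (unconverged within the step budget),
    ``("point", i)`` — the assignment at index ``i`` maps to itself —
    or ``("cycle", i, p)`` — the orbit repeats from index ``i`` with
    minimal period ``p``.
    """

    variables: list[str]
    assignments: list[TruthAssignment]
    attractor: Optional[tuple] = None
    events: list[PerturbationEvent] = field(default_factory=list)

    @property
    def n_steps(self) -> int:
        return len(self.assignments) - 1

    @property
    def converged(self) -> bool:
        return self.attractor is not None

    def attractor_states(self) -> list[TruthAssignment]:
        if self.attractor is None:
            return []
        if self.attractor[0] == "point":
            return [self.assignments[self.attractor[1]]]
        _, i, p = self.attractor
        return self.assignments[i:i + p]

    def value_at_attractor(self, var: str) -> set[bool]:
        """Values ``var`` takes over the attractor (a singleton if stable)."""
        return {a[var] for a in self.attractor_states()}

    def to_frame(self) -> pd.DataFrame:
        """Variables x time matrix of 0/1 values."""
        data = {
            t: [int(a[v]) for v in self.variables] for t, a in enumerate(self.assignments)
        }
        return pd.DataFrame(data, index=self.variables)


def default_init(
    bm: BooleanModel,
    inputs_true: Sequence[str] = (),
    overrides: Optional[Mapping[str, bool]] = None,
) -> TruthAssignment:
    """Standard initial condition.

    Bipartite models: components present (true), reactions, states and
    outputs false, inputs per ``inputs_true``; component-presence states
    (label ``present``) start true so degradation has something to act
    on.  Classical models: components start false.  ``overrides`` wins.
    """
    a: TruthAssignment = {}
    component_default = bm.kind != "classical"
    for var in bm.variables:
        role = bm.roles[var]
        if role == "component":
            a[var] = component_default
        elif role == "input":
            a[var] = var in inputs_true
        else:
            a[var] = False
    for var in bm.variables:
        if bm.roles[var] == "state" and var.endswith("-{present}"):
            a[var] = True
    for var in inputs_true:  # inputs that double as outputs
        if var in a:
            a[var] = True
    if overrides:
        for var, val in overrides.items():
            if var not in a:
                raise KeyError(f"override for unknown variable {var!r}")
            a[var] = bool(val)
    return a


def sync_step(
    bm: BooleanModel,
    a: TruthAssignment,
    clamps: Optional[Mapping[str, bool]] = None,
) -> TruthAssignment:
    """One synchronous update: all non-clamped variables simultaneously."""
    clamps = clamps or {}
    nxt = {var: bm.rules[var].evaluate(a) for var in bm.variables}
    for var, val in clamps.items():
        nxt[var] = val
    return nxt


def run_sync(
    bm: BooleanModel,
    init: TruthAssignment,
    schedule: Optional[PerturbationSchedule] = None,
    max_steps: int = 200,
) -> Trajectory:
    """Iterate synchronous steps until an attractor or ``max_steps``.

    Revisited assignments are detected by hashing the full assignment;
    the detection window restarts after every perturbation event (events
    break the determinism of the orbit).  If ``max_steps`` is reached
    without a revisit the trajectory is returned unconverged.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    schedule = schedule or PerturbationSchedule()
    schedule.validate(bm)
    clamps: dict[str, bool] = {}

    a = dict(init)
    assignments: list[TruthAssignment] = []
    seen: dict[tuple, int] = {}
    attractor = None
    last_event_t = max((e.t for e in schedule.events), default=-1)

    for t in range(max_steps + 1):
        events = schedule.at(t)
        if events:
            for e in events:
                if e.clamp:
                    clamps[e.var] = e.value
                else:
                    clamps.pop(e.var, None)
                a[e.var] = e.value
            seen = {}
        assignments.append(a)
        key = _key(bm, a)
        if key in seen and t > last_event_t:
            i = seen[key]
            p = t - i
            attractor = ("point", i) if p == 1 else ("cycle", i, p)
            break
        seen[key] = t
        if t == max_steps:
            break
        a = sync_step(bm, a, clamps)

    return Trajectory(
        variables=list(bm.variables),
        assignments=assignments,
        attractor=attractor,
        events=list(schedule.events),
    )


def _key(bm: BooleanModel, a: TruthAssignment) -> tuple:
    return tuple(a[v] for v in bm.variables)


def run_async(
    bm: BooleanModel,
    init: TruthAssignment,
    n_runs: int,
    n_steps: int,
    seed: int,
    clamps: Optional[Mapping[str, bool]] = None,
) -> pd.DataFrame:
    """Ensemble of asynchronous simulations; mean activity per variable.

    Each run performs ``n_steps`` full passes; within a pass the
    variables are updated sequentially in a fresh uniformly random
    permutation.  Returns a variables x (n_steps+1) DataFrame whose
    entries are the fraction of runs in which the variable was true at
    that step (column 0 is the initial condition).  Bitwise reproducible
    for a fixed seed.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    clamps = dict(clamps or {})
    rng = np.random.default_rng(seed)
    variables = list(bm.variables)
    n_vars = len(variables)
    counts = np.zeros((n_vars, n_steps + 1), dtype=np.int64)

    for _ in range(n_runs):
        a = dict(init)
        a.update(clamps)
        counts[:, 0] += [a[v] for v in variables]
        for step in range(1, n_steps + 1):
            for idx in rng.permutation(n_vars):
                var = variables[idx]
                if var in clamps:
                    continue
                a[var] = bm.rules[var].evaluate(a)
            counts[:, step] += [a[v] for v in variables]

    return pd.DataFrame(counts / n_runs, index=variables, columns=range(n_steps + 1))
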