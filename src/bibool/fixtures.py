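"""Built-in example networks and generators.

The two small networks are reconstructions of well-known yeast
signalling motifs, pinned here as the package's reference fixtures:

* :func:`simplified_hog` — a two-module sketch of the high-osmolarity
  glycerol (HOG) pathway: a turgor-sensing phosphorelay
  (Sln1 -> Ypd1 -> Ssk1) whose phosphorylated Ssk1 keeps the downstream
  MAP kinase module (Ssk2 -> Pbs2 -> Hog1 -> Hot1) switched off, with
  the MAPK output feeding back to restore turgor.  Dephosphorylation of
  the kinase-module phospho-states is catalysed by a synthetic
  "unknown phosphatase" (ukPPase) so the states can decay, and the
  phosphotransfer steps require their donor state — both choices are
  needed for the relay to drain when turgor is lost.

* :func:`toy_crosstalk` — the mating (MAT) and HOG pathways sharing
  the kinases Ste20 and Ste11, with pheromone-gated scaffold binding
  (Ste5) and osmostress-gated membrane recruitment (Sho1) separating
  the two signals.  Used to demonstrate that the bipartite export keeps
  the signals specific while the component-level export does not.
"""

from __future__ import annotations

import copy
from pathlib import Path

import numpy as np

from .bipartite import BooleanModel
from .core import Component, ElementalReaction, ElementalState, RxnconModel, default_registry, skeleton
from .expr import Atom, not_
from .parse import load_excel, load_quick_file, load_tabular_files, parse_effector_text

__all__ = [
    "SIMPLIFIED_HOG_QUICK",
    "TOY_CROSSTALK_QUICK",
    "MAPK_DEFAULTS",
    "simplified_hog",
    "toy_crosstalk",
    "negative_feedback_toggle",
    "random_model",
    "add_reverse_reactions",
    "load_mapk",
]

SIMPLIFIED_HOG_QUICK = """\
Sln1_AP_Sln1; ! [Turgor]
Sln1_PT_Ypd1; ! Sln1-{P}
Ypd1_PT_Ssk1; ! Ypd1-{P}
Ssk1_ppi_Ssk2; x Ssk1-{P}
Ssk2_P+_Pbs2; ! Ssk1--Ssk2
Pbs2_P+_Hog1; ! Pbs2-{P}
Hog1_P+_Hot1; ! Hog1-{P}
ukPPase_P-_Ssk1
ukPPase_P-_Pbs2
ukPPase_P-_Hog1
ukPPase_P-_Hot1
[Turgor]; ! Hot1-{P}
"""

TOY_CROSSTALK_QUICK = """\
Ste20_P+_Ste11
Ste5_ppi_Ste11; ! [Pher]
Sho1_ppi_Ste11; ! [Osmo]
Ste11_P+_Ste7; ! Ste11-{P}; ! Ste5--Ste11
Ste11_P+_Pbs2; ! Ste11-{P}; ! Sho1--Ste11
Ste7_P+_Fus3; ! Ste7-{P}
Pbs2_P+_Hog1; ! Pbs2-{P}
[MATING]; ! Fus3-{P}
[TURGOR]; ! Hog1-{P}
"""

#: Recommended initial condition for the full MAPK case study:
#: turgor present, no alpha-factor, the alpha-cell receptor Ste3 absent,
#: the Tec1 transcription factor present.
MAPK_DEFAULTS: dict[str, bool] = {
    "[Turgor]": True,
    "[MFalpha]": False,
    "Ste3": False,
    "Tec1": True,
}


def _cont(model: RxnconModel, target: str, sign: str, effector_text: str) -> None:
    model.add_contingency(target, sign, parse_effector_text(effector_text, model))


def simplified_hog() -> RxnconModel:
    """Programmatic build of the simplified HOG network (see module doc)."""
    m = RxnconModel()
    m.add_reaction("Sln1", "AP", "Sln1")
    _cont(m, "Sln1_AP_Sln1", "!", "[Turgor]")
    m.add_reaction("Sln1", "PT", "Ypd1")
    _cont(m, "Sln1_PT_Ypd1", "!", "Sln1-{P}")
    m.add_reaction("Ypd1", "PT", "Ssk1")
    _cont(m, "Ypd1_PT_Ssk1", "!", "Ypd1-{P}")
    m.add_reaction("Ssk1", "ppi", "Ssk2")
    _cont(m, "Ssk1_ppi_Ssk2", "x", "Ssk1-{P}")
    m.add_reaction("Ssk2", "P+", "Pbs2")
    _cont(m, "Ssk2_P+_Pbs2", "!", "Ssk1--Ssk2")
    m.add_reaction("Pbs2", "P+", "Hog1")
    _cont(m, "Pbs2_P+_Hog1", "!", "Pbs2-{P}")
    m.add_reaction("Hog1", "P+", "Hot1")
    _cont(m, "Hog1_P+_Hot1", "!", "Hog1-{P}")
    for substrate in ("Ssk1", "Pbs2", "Hog1", "Hot1"):
        m.add_reaction("ukPPase", "P-", substrate)
    m.add_output("[Turgor]")
    _cont(m, "[Turgor]", "!", "Hot1-{P}")
    return m


def toy_crosstalk() -> RxnconModel:
    """Programmatic build of the MAT/HOG crosstalk toy (see module doc)."""
    m = RxnconModel()
    m.add_reaction("Ste20", "P+", "Ste11")
    m.add_reaction("Ste5", "ppi", "Ste11")
    _cont(m, "Ste5_ppi_Ste11", "!", "[Pher]")
    m.add_reaction("Sho1", "ppi", "Ste11")
    _cont(m, "Sho1_ppi_Ste11", "!", "[Osmo]")
    m.add_reaction("Ste11", "P+", "Ste7")
    _cont(m, "Ste11_P+_Ste7", "!", "Ste11-{P}")
    _cont(m, "Ste11_P+_Ste7", "!", "Ste5--Ste11")
    m.add_reaction("Ste11", "P+", "Pbs2")
    _cont(m, "Ste11_P+_Pbs2", "!", "Ste11-{P}")
    _cont(m, "Ste11_P+_Pbs2", "!", "Sho1--Ste11")
    m.add_reaction("Ste7", "P+", "Fus3")
    _cont(m, "Ste7_P+_Fus3", "!", "Ste7-{P}")
    m.add_reaction("Pbs2", "P+", "Hog1")
    _cont(m, "Pbs2_P+_Hog1", "!", "Pbs2-{P}")
    m.add_output("[MATING]")
    _cont(m, "[MATING]", "!", "Fus3-{P}")
    m.add_output("[TURGOR]")
    _cont(m, "[TURGOR]", "!", "Hog1-{P}")
    return m


def negative_feedback_toggle() -> BooleanModel:
    """Four-variable negative-feedback cycle, built directly as a
    Boolean model.

    Two mutually inhibiting two-variable arms (A -> a -| B -> b -| A).
    Under synchronous update the all-false state sits on a length-4
    cyclic attractor; under asynchronous update each run settles into
    one of the two point attractors with one arm on and the other off.
    """
    bm = BooleanModel(kind="bipartite")
    bm.add("A", "state", not_(Atom("b")))
    bm.add("a", "state", Atom("A"))
    bm.add("B", "state", not_(Atom("a")))
    bm.add("b", "state", Atom("B"))
    bm.check_closed()
    return bm


_RANDOM_TYPES = ("ppi", "P+", "P-", "AP", "PT", "Ub+")


def random_model(
    n_components: int,
    n_reactions: int,
    contingency_density: float = 0.3,
    seed: int = 0,
) -> RxnconModel:
    """Seeded random reaction-contingency network for property tests.

    Draws reaction types from a safe subset of the default registry and
    only uses producible states as contingency effectors, so generated
    models validate cleanly apart from (possibly) the irreversible-only
    diagnostic.  Reproducible per seed.
    """
    if n_components < 1:
        raise ValueError("need at least one component")
    rng = np.random.default_rng(seed)
    m = RxnconModel()
    # component pool; only components actually drawn into reactions are
    # registered, so the model serialises losslessly to quick text
    names = [f"C{i + 1}" for i in range(n_components)]

    attempts = 0
    while len(m.reactions) < n_reactions and attempts < 50 * max(1, n_reactions):
        attempts += 1
        symbol = _RANDOM_TYPES[rng.integers(len(_RANDOM_TYPES))]
        a = names[rng.integers(n_components)]
        b = a if symbol == "AP" else names[rng.integers(n_components)]
        if symbol in ("ppi",) and a == b:
            continue
        # reject candidates that would consume their own product
        # (e.g. a transfer autoreaction), which never validate cleanly
        candidate = ElementalReaction(Component(a), Component(b), m.registry[symbol])
        produced, consumed = skeleton(candidate)
        if {s.id for s in produced} & {s.id for s in consumed}:
            continue
        m.add_reaction(a, symbol, b)

    producers, _ = m.producers_consumers()
    producible = sorted(producers)
    if producible:
        for r in list(m.reactions):
            if rng.random() < contingency_density:
                sid = producible[rng.integers(len(producible))]
                sign = "!" if rng.random() < 0.5 else "x"
                _cont(m, r.id, sign, sid)
    return m


def add_reverse_reactions(
    model: RxnconModel, catalyst: str = "ukPPase"
) -> tuple[RxnconModel, list[ElementalReaction]]:
    """Make irreversibly produced modification states consumable.

    For every modification state that has producing reactions (all
    irreversible) but no consuming reaction, add a hypothetical
    consuming reaction catalysed by a synthetic component (``ukPPase``
    for phosphorylations, ``uk<label>ase`` otherwise), with no
    contingencies.  Returns a new model plus the added reactions;
    idempotent — a second application adds nothing.
    """
    m = copy.deepcopy(model)
    producers, consumers = m.producers_consumers()
    reverse_types = {}
    for t in m.registry.values():
        if not t.produced_templates and len(t.consumed_templates) == 1:
            tpl = t.consumed_templates[0]
            if tpl.kind == "mod" and tpl.slot == "B":
                reverse_types.setdefault(tpl.label, t.symbol)

    added: list[ElementalReaction] = []
    for sid in sorted(producers):
        if sid in consumers:
            continue
        state = _state_by_id(m, sid)
        if state is None or state.kind != "mod" or state.label == "present":
            continue
        if any(p.rtype.reversible for p in producers[sid]):
            continue
        symbol = reverse_types.get(state.label)
        if symbol is None:
            continue
        name = catalyst if state.label == "P" else f"uk{state.label}ase"
        added.append(m.add_reaction(name, symbol, state.components[0].name))
    return m, added


def _state_by_id(model: RxnconModel, sid: str) -> ElementalState | None:
    for s in model.states():
        if s.id == sid:
            return s
    return None


def load_mapk(
    path: str | Path,
    contingencies_path: str | Path | None = None,
    registry=None,
) -> RxnconModel:
    """Load the full yeast MAPK network from a user-supplied file.

    Accepts the spreadsheet layout (``.xlsx``), a reaction/contingency
    table pair (``.csv``/``.tsv``), or quick text.  The file is not
    distributed with this package and is never downloaded; obtain the
    published model table and pass its path here.  Recommended initial
    conditions are in :data:`MAPK_DEFAULTS`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found. The full MAPK model table is not bundled with "
            "bibool; download the published model table (spreadsheet or "
            "reaction/contingency lists) and pass its path to load_mapk()."
        )
    registry = registry or default_registry()
    suffix = path.suffix.lower()
    if suffix in (".xlsx", ".xls"):
        return load_excel(path, registry=registry)
    if suffix in (".csv", ".tsv", ".tab"):
        return load_tabular_files(path, contingencies_path, registry=registry)
    return load_quick_file(path, registry=registry)
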