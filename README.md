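# bibool — bipartite Boolean modelling of reaction–contingency networks

`bibool` turns a reaction–contingency description of a cellular signal
transduction network into an executable Boolean model, uniquely and
without manual curation.

A network is written as a list of **elemental reactions** (single
biochemical events between at most two components, such as a binding
`Ssk1_ppi_Ssk2` or a phosphorylation `Pbs2_P+_Hog1`) and
**contingencies** — contextual constraints saying which **elemental
states** (a bond `Ssk1--Ssk2`, a modification `Pbs2-{P}`) a reaction
requires (`!`), is inhibited by (`x`), or is quantitatively modulated
by (`K+`/`K-`). From this the package derives a **bipartite Boolean
network** with one variable per reaction *and* one per state:

- a reaction variable is true when its components are present, all its
  required effectors hold and no inhibiting effector holds;
- a state variable is true when an irreversible producing reaction just
  fired, or when it was already true, is maintained (by a reversible
  producer, or trivially for irreversibly produced states) and no
  consuming reaction fired.

Because reactions and states are kept apart, the model preserves the
*context* of every event: two pathways sharing a kinase stay insulated
when their downstream reactions require different states of that
kinase — the component-level ("classical") Boolean projection, which
`bibool` can also build for comparison, loses exactly this information
and shows spurious crosstalk.

## Features

- Parsers for a compact one-line-per-reaction text format, tabular
  (CSV/TSV) network + contingency lists, and spreadsheets.
- Rule generation for the bipartite model (with a switchable component
  conjunct on state rules) and the component-level comparison model.
- An extensible reaction-type registry (`ppi`, `P+`, `P-`,
  phosphotransfer, autophosphorylation, ubiquitination, GEF/GAP,
  transcription, degradation, …) configurable from plain text.
- Deterministic synchronous simulation with point/cyclic attractor
  detection, perturbation schedules (one-shot sets and clamps).
- Random-order asynchronous ensemble simulation, bitwise reproducible
  per seed.
- State-space enumeration (full, or as a reachable closure) with
  attractor classification and basin sizes.
- Structural validation with actionable diagnostics and an automatic
  repair step that adds hypothetical reverse reactions for
  irreversibly produced modification states.
- Exports: rule text, BoolNet `.bnet` (with a sanitised-alias table),
  regulatory graphs as GraphML/DOT, clustered time-course heat maps.
- A thin `bibool` command-line interface over all of the above.

## Worked example

```python
from bibool import build_bipartite, default_init, run_sync
from bibool.fixtures import simplified_hog
from bibool.io import rules_text

model = simplified_hog()           # osmotic-stress (HOG) pathway sketch
bm = build_bipartite(model)
print(rules_text(bm))
```

Selected generated rules (the component conjunct on state rules is
switched off here, `conjoin_components=False`, to show the minimal
form):

```text
Hog1_P+_Hot1*  = Hog1 & Hot1 & Hog1-{P}
Ssk1_ppi_Ssk2* = Ssk1 & Ssk2 & !Ssk1-{P}
Sln1-{P}*      = Sln1_AP_Sln1 | Sln1-{P} & !Sln1_PT_Ypd1
Ssk1--Ssk2*    = Ssk1_ppi_Ssk2
```

Simulating with turgor clamped present gives a point attractor with
the MAP kinase module off; clamping turgor absent activates the
cascade (`Hog1_P+_Hot1` true at the attractor); free-running with the
feedback closed, the synchronous dynamics settle into a sustained
oscillation of period 32:

```python
traj = run_sync(bm, default_init(bm), max_steps=200)
print(traj.attractor)              # ('cycle', 1, 32)
```

The `examples/` directory contains five narrated scripts covering
model building, the stress/recovery simulation protocol, the
signal-specificity contrast with the component-level model, state-space
enumeration, and asynchronous ensembles.

## Command line

```sh
bibool validate network.rxncon
bibool export network.rxncon bipartite
bibool export network.rxncon bnet --out model.bnet
bibool simulate network.rxncon sync --clamp '[Turgor]=1' --steps 50
bibool simulate network.rxncon async --runs 1000 --seed 0 --input '[Osmo]'
bibool statespace network.rxncon reachable --out ts.graphml
bibool repair network.rxncon        # add hypothetical reverse reactions
bibool fixtures hog                 # print a built-in network
```

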