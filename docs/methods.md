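# Methods

This note records the precise semantics the package implements and the
design decisions behind them.

## 1. Network definition

A model consists of:

- **Components** — molecules, with plain-word names (the characters
  `_ - { } [ ]` and whitespace are reserved by the id grammar and
  rejected in component names).
- **Elemental reactions** `A_<type>_B` — single events between at most
  two components. Each reaction type is described by a registry entry
  stating whether it is reversible, whether it is directed, and which
  state templates it produces and consumes. The default registry
  covers `ppi` and `i` (reversible bonds), `P+`, `P-`, `AP`
  (autophosphorylation), `PT` (phosphotransfer: consumes `A-{P}`,
  produces `B-{P}`), `Ub+`, `Ub-`, `GEF`/`GAP`, `TRSC` and `deg`.
  Users can extend or override the registry from a plain-text
  configuration (one `symbol rev|irr [directed|undirected]
  [produce=…] [consume=…]` per line).
- **Elemental states** — the direct outcomes of reactions: bonds
  `A--B` (partner-ordered, so `A_ppi_B` and `B_ppi_A` yield the same
  state id) and modifications `A-{label}`. States of the same component
  are not mutually exclusive.
- **Contingencies** — `(target, sign, effector)` triples. Targets are
  reactions or bracketed outputs; effectors are states, bracketed
  inputs, or named Boolean combinations (`AND`/`OR`/`NOT` nodes, which
  may nest). Signs: `!` required, `x` inhibiting, `K+`/`K-`
  quantitative positive/negative, `0` no effect, `?` unknown.

## 2. Rule generation (bipartite model)

One Boolean variable per component, reaction, state, input and output.
Components and inputs have the identity rule (they are constants of the
dynamics, set by the initial condition or clamped).

**Reaction rule.** The conjunction of: the reaction's components; every
effector with a positive sign; the negation of every effector with a
negative sign. Under the default *strict* policy the quantitative signs
are conservatively binarised (`K+` → `!`, `K-` → `x`); under the
*neutral* policy they are dropped. `0` and `?` are always ignored.
Boolean-combination effectors are flattened recursively (cyclic node
definitions are reported as errors).

**State rule.** With `P_irr` the irreversible producing reactions,
`P_rev` the reversible ones and `C` the consuming reactions of state
`s`:

```
maintenance(s) = OR(P_rev)    if P_rev is non-empty
               = s            otherwise
s* = components(s) AND ( OR(P_irr)  OR  ( maintenance(s) AND NOT OR(C) ) )
```

with the conventions: an empty `OR` is false, and the `NOT OR(C)` term
is dropped when there are no consumers. The reading: a state switches
on when an irreversible producer fires, and stays on while it is
maintained — by a still-firing reversible producer (a released bond
decays when its binding reaction stops), or trivially for irreversibly
produced states — and not consumed. If a single reaction both produces
and consumes a state, production wins and a diagnostic is emitted.

The `conjoin_components` flag controls whether the component conjunct
appears on *state* rules. Reaction rules always include their
components. With the flag off the state rules take their minimal
textbook form (e.g. `Ssk1--Ssk2* = Ssk1_ppi_Ssk2`); with it on
(default) states decay when their components are removed, which is the
safer behaviour in models with synthesis and degradation.

**Outputs.** A bracketed output `[X]` gets a pseudo-reaction variable
`[X]_gen` whose rule is built from the output's contingencies exactly
like a reaction rule (without a component conjunct), and the output
itself follows it with reversible-producer semantics: `[X]* = [X]_gen`.
An output may double as an input elsewhere in the network (the turgor
feedback in the built-in osmotic-pathway fixture does this); such a
variable is classed as an output and is clamped during experiments that
control it.

**Variable order** is deterministic: components (in first-use order),
reactions (in definition order), states (in first-production order),
output pseudo-reactions and outputs (sorted), then inputs (sorted).

## 3. Component-level ("classical") comparison model

One variable per component, input and output. For a target `T`:
activators are the source components of non-consuming reactions
targeting `T` whose net contingency context is non-negative (bond
reactions contribute each partner as an activator of the other), plus
components of positive state effectors; inhibitors are sources of
consuming-type reactions and components of negative effectors. The
rule is `OR(activators) AND NOT OR(inhibitors)`. A target with no
activators keeps its own value and is reported (`no-activators`).
This projection deliberately discards state context; its purpose is
the specificity contrast shown in `examples/03_crosstalk_specificity.py`.

## 4. Simulation semantics

**Synchronous.** All variables update simultaneously. The trajectory
is deterministic, so a revisited global state (detected by hashing the
full assignment) identifies the attractor: a point (period 1) or a
cycle whose period is automatically minimal for a deterministic orbit.
Perturbation events either set a variable once (it may immediately
recover) or **clamp** it (it is excluded from updates until a later
event on the same variable); the revisit-detection window restarts
after every event, since events break determinism.

**Asynchronous.** Per time step, one full pass over the variables in a
fresh uniformly random permutation (`numpy.random.default_rng(seed)`),
updating sequentially within the pass; the ensemble mean activity per
variable and step is returned. Results are bitwise reproducible for a
fixed seed. This scheme was chosen over single-variable-per-step
updating so that one "step" is comparable in work to one synchronous
step; the exactness of the implementation is tested against a complete
enumeration of all update orders on a two-variable model.

**Initial condition.** `default_init`: components present (true),
inputs as requested, everything else false; component-presence states
(label `present`) start true so degradation has a substrate. For the
component-level model, components start false (they represent
activity, not presence).

## 5. State space

Under synchronous update the global state space is a functional graph
(out-degree one), so attractors are its terminal cycles and every state
belongs to exactly one basin; classification is by pointer-chasing with
colouring. Components and inputs are excluded from the free variables
by default and held fixed. Full enumeration refuses beyond a cap
(default 20 free variables) and points to the reachable-closure mode,
which explores the successor relation breadth-first from given start
states; the closure is successor-closed, hence contains its terminal
cycles and supports the same classification.

## 6. Validation and repair

`validate_model` flags: duplicate reactions, self-consuming reactions,
contingency targets that do not resolve, inputs used as targets,
effector states never produced, dangling Boolean-node references,
unregulated outputs, and — the most consequential class — modification
states with only irreversible producers and no consumer. Such states
latch on forever; `add_reverse_reactions` repairs them by adding an
unregulated consuming reaction catalysed by a synthetic component
(`ukPPase` for phosphorylations), mirroring how such gaps are closed in
practice. The repair is idempotent and never mutates its input.

## 7. Built-in fixtures

`simplified_hog` is a reconstruction of the two-module
osmotic-stress pathway: a turgor-sensing phosphorelay
(Sln1 → Ypd1 → Ssk1) whose phosphorylated Ssk1 blocks formation of the
Ssk1–Ssk2 complex, a MAP kinase cascade (Ssk2 → Pbs2 → Hog1 → Hot1),
and the transcriptional output restoring turgor. Two modelling choices
are load-bearing and were verified dynamically: the phosphotransfer
steps carry a `!` contingency on their donor state (so the relay
drains when its source dries up), and the four kinase-module
phospho-states get `ukPPase` dephosphorylation reactions (so the
cascade can switch off again). Without either, states latch and the
stress response never terminates or never recovers.

`toy_crosstalk` is a minimal mating/osmostress crosstalk motif sharing
Ste20 and Ste11, with scaffold binding (Ste5, pheromone-gated) and
membrane recruitment (Sho1, osmostress-gated) as the insulating states.
Its phospho-states are deliberately left without consumers — the
`irreversible-only` diagnostics are part of the fixture's test surface.

`negative_feedback_toggle` is a four-variable negative-feedback cycle
built directly as a Boolean model: a synchronous length-4 cyclic
attractor that, under asynchronous updates, resolves into one of two
stable arms per run.

`random_model` draws seeded random networks from a safe subset of the
registry (rejecting candidates that would consume their own product)
and only uses producible states as effectors, so generated models
validate cleanly apart from possible `irreversible-only` diagnostics.

## 8. Exports

Identifiers contain `-`, `{}`, `[]` and `+`, which many downstream
Boolean tools reject. The BoolNet `.bnet` writer sanitises ids
(`+` → `_p`, `-` → `_d_`, braces and brackets dropped, uniqueness
enforced by numeric suffixes) and emits an `id,alias` CSV alongside.
The regulatory graph export has reaction→state edges classed
`produce`/`consume` and effector→target contingency edges classed
`activate`/`inhibit`/`neutral` (one edge per contingency), with a
conventional colour attribute per class; it is written as GraphML via
`networkx` or as DOT by a minimal built-in writer. Time courses are
rendered as heat maps after dropping constant rows and ordering the
remaining variables by hierarchical clustering of their 0/1 profiles
(Hamming distance, average linkage).

## 9. Limitations

- Quantitative contingencies (`K+`/`K-`) are binarised or dropped;
  there is no quantitative semantics.
- The component-level builder is a deliberately simple topological
  projection for comparison purposes, not a faithful reimplementation
  of any particular curation heuristic.
- Full state-space enumeration is exponential and capped; large models
  must use the reachable closure or simulation.
- The asynchronous scheme is random-order-per-pass; other asynchronous
  regimes (single random variable per step, priority classes) are not
  implemented.
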