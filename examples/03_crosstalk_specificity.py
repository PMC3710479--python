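"""Signal specificity: bipartite versus component-level Boolean models.

Two pathways (mating and osmostress) share two kinases.  The bipartite
model keeps track of *which state* of the shared kinase each downstream
reaction requires (scaffold-bound vs membrane-recruited), so each
stimulus activates only its own output.  The component-level projection
of the same network only knows that the kinase is "active", and both
outputs fire under either stimulus.
"""

from bibool import build_bipartite, build_classical, default_init, run_sync
from bibool.fixtures import toy_crosstalk

model = toy_crosstalk()
bipartite = build_bipartite(model)
classical, diagnostics = build_classical(model)
for d in diagnostics:
    print("note:", d)


def outputs(bm, inputs):
    traj = run_sync(bm, default_init(bm, inputs_true=inputs), max_steps=100)
    return {out: traj.value_at_attractor(out) == {True}
            for out in ("[MATING]", "[TURGOR]")}


print(f"\n{'stimulus':16s}  {'bipartite':42s}  component-level")
for inputs in ([], ["[Pher]"], ["[Osmo]"], ["[Pher]", "[Osmo]"]):
    name = "+".join(inputs) or "(none)"
    print(f"{name:16s}  {str(outputs(bipartite, inputs)):42s}  {outputs(classical, inputs)}")
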