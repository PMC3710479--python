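"""Enumerate a model's synchronous state space and classify attractors.

Under synchronous update every global state has exactly one successor,
so the state space is a functional graph whose terminal cycles are the
attractors; every state belongs to exactly one basin.  Full enumeration
is feasible for small models; larger ones are explored as the closure
reachable from chosen start states.
"""

from bibool import build_bipartite, default_init, enumerate_full, reachable
from bibool.fixtures import negative_feedback_toggle, simplified_hog

# full enumeration of a 4-variable negative-feedback cycle
toggle = negative_feedback_toggle()
graph = enumerate_full(toggle)
print(f"toggle: {len(graph.nodes)} states, {len(graph.attractors)} attractors")
for i, att in enumerate(graph.attractors):
    print(f"  attractor {i}: {att.kind}, period {att.period}, "
          f"basin {graph.basin_sizes[i]}")

# the HOG model has too many free variables for full enumeration;
# explore the closure reachable from a chosen start instead.  Nothing
# is clamped here, so the turgor feedback loop is closed and the
# pathway settles into its sustained oscillation
bm = build_bipartite(simplified_hog())
closure = reachable(bm, [default_init(bm, inputs_true=["[Turgor]"])])
print(f"\nHOG (started with turgor present): {len(closure.nodes)} reachable "
      f"states, {len(closure.attractors)} attractor(s)")
for att in closure.attractors:
    print(f"  {att.kind}, period {att.period}")

# export for graph tools
closure.to_networkx()  # -> networkx DiGraph, see bibool.io.write_graphml
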