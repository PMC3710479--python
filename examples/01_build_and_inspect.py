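"""Define a small reaction-contingency network and inspect the rules.

A network is a list of elemental reactions plus contingencies —
contextual constraints saying which elemental states a reaction
requires (!) or is inhibited by (x).  From that one description the
package derives a bipartite Boolean model: one variable per reaction
and one per state, each with its own update rule.
"""

from bibool import build_bipartite, validate_model
from bibool.io import rules_text
from bibool.parse import parse_quick

TEXT = """\
# a kinase that needs its scaffold bond to act
Scaffold_ppi_Kinase
Kinase_P+_Substrate; ! Scaffold--Kinase
Phosphatase_P-_Substrate
[Response]; ! Substrate-{P}
"""

model = parse_quick(TEXT)
print(f"{len(model.reactions)} reactions, {len(model.contingencies)} contingencies")

for diag in validate_model(model):
    print("diagnostic:", diag)

bm = build_bipartite(model)
print("\nUpdate rules:")
print(rules_text(bm))

# the same model without the component conjunct on state rules —
# the minimal textbook form of the state equations
minimal = build_bipartite(model, conjoin_components=False)
print("Minimal state rule for the bond:")
print("Scaffold--Kinase* =", minimal.rules["Kinase--Scaffold"].render())
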