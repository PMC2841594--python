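"""Track resolution of bivalent imprinted genes from ESCs into NPCs and MEFs.

For every imprinted gene bivalent (K4+K27) in the pluripotent state, the
state in each differentiated cell type is classified as resolved to K4,
resolved to K27, resolved to none, or retained bivalent, coupled to the
expression outcome (activated / still repressed / ...). The class counts
are the synthetic analogue of the published cross-cell-type dynamics table.
"""

import pandas as pd

from _common import RESULTS, default_bundle
from imprintmarks.signatures import bivalency_state, classify_transition
from imprintmarks.synthetic import K4, K27

config, bundle, _ = default_bundle()
state = bundle.state_table()
esc = state[state.cell_type == "ESC"].set_index("gene_id")

rows = []
for ct in [c for c in bundle.cell_types() if c != "ESC"]:
    target = state[state.cell_type == ct].set_index("gene_id")
    for gid, row in esc.iterrows():
        if not (row[K4] and row[K27]):
            continue
        rec = classify_transition(
            gid, "ESC", ct,
            "bivalent",
            bivalency_state(bool(target.loc[gid, K4]), bool(target.loc[gid, K27])),
            row["expression"], target.loc[gid, "expression"],
        )
        rows.append(
            {
                "gene_id": gid,
                "to_cell_type": ct,
                "to_state": rec.to_state,
                "transition_class": rec.transition_class,
                "expression_outcome": rec.expression_outcome,
            }
        )

table = pd.DataFrame(rows)
RESULTS.mkdir(exist_ok=True)
table.to_csv(RESULTS / "transitions.tsv", sep="\t", index=False)

print(f"{len(esc[esc[K4] & esc[K27]])} imprinted genes bivalent in ESCs")
summary = table.groupby(["to_cell_type", "transition_class"]).size()
print(summary.to_string())
outcomes = table.groupby(["transition_class", "expression_outcome"]).size()
print("\nby expression outcome:")
print(outcomes.to_string())
print(f"\ntable written to {RESULTS / 'transitions.tsv'}")
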