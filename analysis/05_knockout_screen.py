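"""Knock out every ON node from each cell state's steady state, score the
shifts as z-normalized Hamming distances to the four reference states,
and classify each post-knockout steady state."""

import pandas as pd
from common import STUDY_DIR, run_study

manifest = run_study("koscreen")
m = manifest["metrics"]["koscreen"]
print(f"simulations: {m['n_simulations']} (converged: {m['n_converged']})")
table = pd.read_csv(STUDY_DIR / "ko_screen.tsv", sep="\t")
moved = table[table["classified_state"] != table["start_state"]]
switches = moved[["start_state", "ko_node", "classified_state"]].drop_duplicates()
print(f"knockouts that switched the cell state: {len(switches)}")
if len(switches):
    print(switches.to_string(index=False))
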