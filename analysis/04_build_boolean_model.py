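"""Synthesize per-node gate rules so every cell state is a fixed point of
the Boolean model, then simulate each state to steady state and compare
the four steady states by similarity score."""

import pandas as pd
from common import STUDY_DIR, run_study

manifest = run_study("boolnet")
m = manifest["metrics"]["boolnet"]
print(f"network: {m['nodes']} nodes, {m['edges']} edges; "
      f"unsatisfiable nodes: {m['unsatisfiable_nodes']}")
sim = pd.read_csv(STUDY_DIR / "state_similarity.tsv", sep="\t", index_col="state")
print("steady-state similarity (%):")
print(sim.round(1).to_string())
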