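"""Generate the synthetic study: a 20-node signed network whose logic has
four planted cell-state attractors, a single-cell reference plus a
100-sample bulk cohort with known state proportions, noisy activity
profiles per state, and paired phospho/RNA tables."""

from common import STUDY_DIR, run_study

manifest = run_study("synthetic")
stage = manifest["stages"]["synthetic"]
print(f"synthetic study written to {STUDY_DIR}")
print("outputs:", ", ".join(sorted(stage["outputs"])))
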