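"""Train the boosted-tree classifier on the knockout screen, predict the
dominant state of booleanized activity profiles, and explain a paired
primary/recurrent example through TreeSHAP attribution shifts."""

import json
from common import STUDY_DIR, run_study

manifest = run_study("predict")
m = manifest["metrics"]["predict"]
print("per-class balanced accuracy on noisy activity profiles:")
for cls, ba in sorted(m["per_class_balanced_accuracy"].items()):
    print(f"  {cls}: {ba:.3f}")
print(f"attribution additivity max error: {m['attribution_additivity_error']:.2e}")
transitions = json.loads((STUDY_DIR / "paired_transitions.json").read_text())
sid, t = next(iter(transitions.items()))
print(f"example pair {sid}: {t['state_before']} -> {t['state_after']}; "
      f"top supporting features: {[f for f, _ in t['top_supporting'][:3]]}")
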