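"""Impute phospho-level activity from RNA-level activity through the
per-entity reference ratio, and booleanize the per-state activity
profiles into the classifier's test format."""

from common import run_study

manifest = run_study("activity")
m = manifest["metrics"]["activity"]
print(f"imputation Pearson r vs. hidden truth: {m['imputation_pearson_r']:.3f}")
print(f"entities falling back to RNA activity (|ref RNA| < 1e-6): {m['imputation_fallbacks']}")
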