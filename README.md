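# statefate

Boolean-network modeling of tumor cell-state transitions.

Glioblastoma tumors mix four malignant cell programs — mesenchymal-like
(MES), astrocyte-like (AC), neural-progenitor-like (NPC) and
oligodendrocyte-progenitor-like (OPC) — and most tumors are dominated by
one of them. `statefate` implements, as a tested and reusable pipeline,
the analysis chain that (i) assigns each bulk sample a dominant cell
state by reference-based deconvolution, (ii) infers TF/kinase activity
from regulon footprints, (iii) converts a signed protein-interaction
network with per-state up/down annotations into a Boolean model whose
fixed points are the four cell states, (iv) runs in-silico knockout
screens to propose state-transition drivers, and (v) trains classifiers
on the simulation output to predict the dominant state of booleanized
activity profiles, with additive (TreeSHAP) per-feature explanations.

Because the real cohorts behind such studies are controlled-access, the
package ships a first-class synthetic-data module that generates every
input with known ground truth: signed networks with *planted*
attractors, single-cell references and bulk mixtures with known
proportions, noisy activity profiles, and paired phospho/RNA tables.
Every downstream stage is validated against that truth.

## The core models

**Boolean model.** Each node is ON (1) or OFF (0). A node with
activators *A* and inhibitors *I* updates through a gate descriptor:
activators combine by OR/AND into *a*, inhibitors by OR/AND into *i*,
and dominance resolves them as `a AND NOT i` (inhibitor wins) or
`a OR NOT i` (activator wins) — eight descriptors per node. Rule
synthesis picks, per node, a descriptor under which all four annotated
cell states are fixed points of the synchronous update; input nodes
(no regulators) are clamped to their per-state values. Dynamics are
continuous-time asynchronous: every node whose rule output disagrees
with its value flips at unit rate (Gillespie simulation); steady states
are absorbing states.

**Knockout screen.** From each state's steady state, each ON node is
permanently clamped OFF and the model re-run to steady state. Outcomes
are scored by Hamming distance to the four reference states,
z-normalized per reference column within each start-state block, and
classified to the most similar state
(`similarity = 100 · #matching / #nodes`).

**Activity scores.** A regulator's WMEAN activity over its regulon is
`sum(x_i · w_i) / sum(|w_i|)`; the normalized variant compares the score
to a gene-label permutation null (z and empirical p). Phospho activity
missing in a test cohort is imputed entity-wise as
`test_phos = test_rna · ref_phos / ref_rna`, and signed activities are
booleanized (positive → 1).

**Prediction.** Classifiers (multinomial elastic net, KNN, random
forest, depth-1 boosted trees) are trained on the screen's binary
steady-state vectors labeled with the resulting state; performance is
one-vs-rest balanced accuracy, `(sensitivity + specificity) / 2`, per
state. TreeSHAP contributions satisfy
`base + Σ φ_j = margin` per sample and class.

## Worked example

```
$ statefate demo --outdir demo_run
{
 "activity": { "imputation_fallbacks": 0, "imputation_pearson_r": 0.990 },
 "assign": { "dominant_state_accuracy": 0.94, "proportion_rmse": 0.0199 },
 "boolnet": { "edges": 44, "nodes": 20, "unsatisfiable_nodes": 0 },
 "koscreen": { "n_converged": 38, "n_simulations": 38 },
 "predict": {
  "attribution_additivity_error": 6.8e-07,
  "per_class_balanced_accuracy":
   { "AC": 0.963, "MES": 0.913, "NPC": 1.0, "OPC": 0.910 }
 }
}
```

Reading the numbers: the 20-node planted network admits gate rules that
make all four cell states exact fixed points (`unsatisfiable_nodes: 0`);
deconvolution recovers the bulk mixing proportions to RMSE ≈ 0.02 and
the dominant state for 94% of samples (misses sit on near-tied
compositions); all 38 knockout simulations reach a new steady state; and
the boosted-tree classifier trained on those simulations recovers the
dominant state of noisy booleanized activity profiles at 0.91–1.00
balanced accuracy per class, with attribution additivity exact to
float32 resolution.

The same study can be replayed stage by stage with the narrative
drivers `analysis/01_generate_synthetic_study.py` …
`analysis/06_predict_and_attribute.py`, which write their tables under
`results/study/`. Library use starts at
`statefate.synthetic.generate_network_with_attractors` and follows the
stage functions re-exported from the top-level package.

## Layout

- `src/statefate/` — the library: `synthetic`, `assign`, `activity`,
  `boolnet`, `koscreen`, `predictor`, `pipeline`, `cli`, `io`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property (hypothesis) and stage-level acceptance tests.
- `docs/methods.md` — the modeling and design notes.
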