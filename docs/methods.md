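# Methods and design notes

## Scope and model

`statefate` models a tumor as a mixture of four malignant cell states
(MES-, AC-, NPC-, OPC-like) and asks which single-protein inhibitions
could move a tumor from one state to another. The object at the center
is a Boolean network over a signed, directed protein-interaction graph
in which every node carries a per-state up/down annotation. The
pipeline's stages are deliberately modular: each consumes files a
practitioner could produce with standard tools (SIF networks, GMT gene
sets, TSV count matrices and regulons) and each is testable in
isolation against synthetic ground truth.

## Boolean semantics

Gate descriptors, not arbitrary truth tables. A node's rule is one of
eight descriptors: activators aggregated by OR or AND, inhibitors by OR
or AND, and a dominance flag choosing `act AND NOT inh` or
`act OR NOT inh`. Restricting to this family keeps synthesis
identifiable (eight candidates per node, exhaustively scored) and the
resulting rules human-readable; arbitrary-DNF synthesis is a documented
extension point, not implemented. Nodes with only activators use `act`,
only inhibitors `NOT inh`; regulator-free nodes are inputs and are
clamped to their per-state value for the whole simulation.

Rule synthesis scores each descriptor by the number of target states it
reproduces when the node's regulators take their target values; the
first descriptor (canonical order: dominance, then activator gate, then
inhibitor gate) achieving the maximum is kept, ties flagged. Because
all other nodes are pinned to target values, the per-node search is
exact and independent across nodes. Nodes whose best descriptor misses
some targets are reported as unsatisfiable, never silently patched.

Dynamics are continuous-time asynchronous with unit flip rates: among
nodes whose rule output disagrees with their value, one flips uniformly
at random and time advances exponentially (Gillespie). This reproduces
the standard stochastic-Boolean steady-state semantics without
committing to any particular rate calibration, for which no data
exist here. A deterministic synchronous step (`apply_update`) and two
exhaustive oracles (`find_fixed_points`, vectorized over the full state
space; `find_attractors_bruteforce`, synchronous cycles or asynchronous
terminal SCCs) support testing. Exhaustive enumeration is guarded at 20
free nodes (2^20 states); fixed points are shared by both update
schemes, so the oracles are valid references for the stochastic runs.

Steady "state" of a stochastic run: per-node marginals over trajectory
endpoints thresholded at 0.5; an exact 0.5 retains the initial value
and is flagged. `converged` means every trajectory reached an absorbing
state within `max_time` (default 50–100 time units; with unit rates a
20-node network typically absorbs in < 20 units when a fixed point is
reachable). Non-convergence (cyclic attractors) is reported, not hidden.

## Knockout screen

A knockout is a permanent clamp to OFF — the model of sustained
pharmacological inhibition — applied to each ON node of each state's
steady state, one at a time. The Hamming distance of the new steady
state to each of the four references is z-normalized with population
standard deviation per reference column *within each start-state
block* (matching the one-heatmap-per-start-state layout); pooled
normalization across all simulations is available via `z_mode`.
Constant columns z-score to zero and are flagged. The knocked-out node
itself is included in the distance; this is configurable in principle
but is the default because no exclusion rule is forced by the screen's
definition. Classification of an outcome is the similarity argmax over
the references, ties resolved by the fixed state order MES > NPC > AC >
OPC. Per-simulation RNG streams are derived from the screen seed and
the (start state, node) names via CRC32, so results are invariant to
file and node ordering.

## State assignment

Cluster labeling uses the inclusive upper-tail hypergeometric
over-representation test, P(X ≥ k) with N = |universe|, K = |module|,
n = |markers|, k = |overlap|; scores are −log10 p capped at 300; an
empty module scores p = 1 by convention. The gene universe is supplied
by the caller (all background genes by default) since marker detection
itself is upstream of this package.

Deconvolution is intentionally a linear reference-based stand-in for
heavier transform-based estimators: counts are CPM-normalized, the
signature matrix is the per-state mean CPM over reference cells, and
each bulk sample is solved by non-negative least squares and
renormalized to the simplex. CPM makes the estimate invariant to bulk
library size; a rank-deficient signature matrix is an error naming the
collinear states. Downstream stages only consume the dominant state
(row argmax, same tie order as above), which is far more robust than
the full composition.

## Activity inference

WMEAN: `sum(x_i w_i) / sum(|w_i|)` over the regulon targets present in
the statistics; missing targets are dropped, and a regulator with no
retained target is an error. The normalized variant permutes the
statistic values over gene labels (default 1000 permutations) and
reports `z = (score − mean(null)) / sd(null)` plus a two-sided
empirical p centered on the null mean with +1 smoothing. A
zero-variance null defines z = 0 with a warning. Differential
statistics are inputs, not computed here — low-count and low-prevalence
filtering belong to the upstream differential-analysis step.

Phospho imputation: `test_phos[e] = test_rna[e] · ref_phos[e] /
ref_rna[e]` for entities shared by all three tables, with a floor of
1e-6 on |ref_rna| below which the entity falls back to its RNA
activity and is flagged (the ratio is undefined at zero and no
principled substitute exists). Booleanization maps positive activity to
1 and non-positive (including exactly zero) to 0.

## Prediction and attribution

Training rows are the knockout outcomes' binary steady-state vectors,
labeled with the state each outcome was *classified into* (the resulting
phenotype, not the start state). The four unperturbed steady states are
appended as baseline rows by default so that every class is represented
even when few knockouts escape their basin.

Model defaults follow widely used settings for this problem class:
boosted trees with 100 depth-1 stumps, learning rate 0.1, subsample
0.1; random forest with 1000 trees and 35 features per split; KNN with
13 neighbors; multinomial elastic net with L1 ratio 0.14 and penalty
strength by internal 10-fold cross-validation. The subsample fraction
and neighbor count implicitly assume a training set of roughly 146
simulations; `scaled_hyperparams` preserves the *absolute* rows per
tree (~15) and the neighbor fraction when the screen is smaller, which
is what the synthetic study uses. Test profiles are reindexed to the
training feature order; nodes absent from a sample are filled with the
training-set majority value and samples missing more than 25% of
features are flagged but still predicted.

The evaluation metric is one-vs-rest balanced accuracy per state —
robust to the heavy class imbalance that dominant-state cohorts show.
Attributions come from the TreeSHAP algorithm as implemented inside
xgboost (`pred_contribs`), returned per sample and class with the
additivity identity `base + Σ φ = margin` checked to 1e-6 (float32
model output). For depth-1 ensembles each stump contributes only
through its split feature, which yields a closed-form oracle (leaf
value minus cover-weighted mean leaf) used in the tests. Paired
primary/recurrent comparison ranks the features whose input value
changed *and* whose attribution toward the recurrent predicted state
moved positively; value changes with negligible attribution shift are
reported separately.

## Synthetic ground truth

The generator plants attractors by sampling logic first: non-input
nodes receive 1 + Poisson(mean_in_degree − 1) regulators (70%
activating) and a random descriptor, and a candidate model is kept only
if exhaustive enumeration finds at least four fixed points that are
pairwise distinct *on the non-input nodes* (states differing only in
clamped inputs would be phenotypically identical). Resampling uses
incremented sub-seeds, so generation is a pure function of its
arguments. This guarantees the planted states are self-consistent with
the engine's own semantics rather than constructed ad hoc.

Study scale: a 20-node network with 2 inputs and mean in-degree 2.5 —
the largest exhaustive enumeration admits — yielding ~40 knockout
simulations; a 100-sample bulk cohort with flat Dirichlet(1,1,1,1)
proportions; negative-binomial counts with variance mean + mean²/10
(dispersion 10, a typical bulk RNA-seq value; a Poisson flag covers the
infinite-dispersion limit); disjoint 30-gene marker blocks per state at
10× background mean, which makes deconvolution identifiable so failures
are attributable to the algorithm; 50–100 activity profiles per state
built as ±1 plus Gaussian noise (sd 0.3) with per-entry sign flips; 200
paired phospho/RNA entities with |reference RNA| ≥ 0.1 and observation
noise sd 0.1.

What the generator deliberately does not emulate: real expression
distributions, batch effects, shared markers between states,
microenvironment and immune cells, or dependence between noise and
state. Passing tests therefore demonstrate the *algorithms* recover a
known truth under their stated noise models — not that the biology of
any real cohort is captured.

## Numerical choices and degenerate inputs

- Hypergeometric p is clamped to (0, 1]; −log10 p capped at 300.
- z-normalization uses population (ddof = 0) standard deviation;
  constant columns are zeroed and flagged; a single row is an error.
- NNLS solutions with total mass 0 fall back to the uniform composition.
- All tie-breaks are deterministic and flagged: lexicographic module
  order, the fixed state order, canonical descriptor order.
- Every stochastic function takes an explicit seed; the pipeline uses
  one seed per stage, never a shared global RNG, and its manifest
  records output checksums so reruns are verifiable.

## Known limitations

- The gate family cannot express mixed-gate rules (e.g. one activator
  AND-ed with another OR-group); unsatisfiable annotation sets are
  reported rather than approximated.
- Exhaustive attractor oracles stop at 20 free nodes; larger networks
  can be simulated but not exhaustively verified.
- The asynchronous simulator is exact but pure-Python per trajectory;
  screens over hundreds of nodes would want a vectorized or compiled
  path.
- Balanced-accuracy comparisons across noise levels are Monte-Carlo
  estimates; the tests allow three standard errors of slack.
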