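"""Synthetic study generator with known ground truth.

Produces every input the pipeline consumes: signed networks whose logic
has at least four distinct fixed points (the planted cell states), a
single-cell reference and bulk mixtures with known state proportions and
negative-binomial count noise, per-state signed activity profiles with
Gaussian and sign-flip noise, and paired phospho/RNA activity tables for
the imputation ratio.  All generators are pure functions of their
arguments including the seed.

The planting strategy samples random gate logic first and keeps a
network only if exhaustive enumeration finds >= 4 distinct fixed points,
so every planted state is self-consistent with the engine's own update
semantics rather than constructed ad hoc.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .boolnet import (
    STATE_ORDER,
    BooleanState,
    DESCRIPTORS,
    GateRule,
    LogicModel,
    SignedNetwork,
    apply_update,
    find_fixed_points,
)

__all__ = [
    "SyntheticTruth",
    "generate_network_with_attractors",
    "generate_reference_and_bulk",
    "generate_activity_profiles",
    "generate_paired_omics",
]

_MAX_RESAMPLES = 1000
_PLANT_NODE_LIMIT = 20  # exhaustive fixed-point enumeration guard


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic study.

    ``cell_states`` maps the four state names to verified fixed points of
    ``logic``; ``proportions``/``labels`` are filled in by
    :func:`generate_reference_and_bulk` for the bulk cohort.
    """

    network: SignedNetwork
    logic: LogicModel
    cell_states: dict[str, BooleanState]
    proportions: dict[str, dict[str, float]] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if len(self.cell_states) != 4:
            raise ValueError("exactly four cell states required")
        seen = set()
        inputs = self.logic.inputs
        for name, state in self.cell_states.items():
            clamp = {n: state[n] for n in inputs}
            if apply_update(self.logic, state, clamp) != state:
                raise ValueError(f"cell state {name!r} is not a fixed point")
            if state in seen:
                raise ValueError("cell states must be pairwise distinct")
            seen.add(state)
        for sample, row in self.proportions.items():
            vals = np.array(list(row.values()))
            if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(f"proportions for {sample!r} are not on the simplex")
            best = max(row, key=lambda s: (row[s], -list(self.cell_states).index(s)))
            if self.labels.get(sample) != best:
                raise ValueError(f"label for {sample!r} is not the proportion argmax")

    def to_manifest(self) -> dict:
        return {
            "seed": self.seed,
            "n_nodes": len(self.network.nodes),
            "n_edges": len(self.network.edges),
            "inputs": self.logic.inputs,
            "cell_states": {k: v.as_dict() for k, v in self.cell_states.items()},
            "proportions": self.proportions,
            "labels": self.labels,
        }

    def write_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_manifest(), fh, indent=1, sort_keys=True)


def _spread_four(fixed: list[BooleanState], internal: list[str]) -> list[BooleanState] | None:
    """Pick four fixed points, greedily maximizing Hamming spread.

    The chosen states must also be pairwise distinct on the internal
    (non-input) nodes: four cell states that differ only in their clamped
    inputs would be phenotypically identical.  Returns None when no such
    quadruple exists among ``fixed``.
    """
    by_internal: dict[tuple, BooleanState] = {}
    for st in fixed:
        key = tuple(st[n] for n in internal)
        by_internal.setdefault(key, st)
    fixed = list(by_internal.values())
    if len(fixed) < 4:
        return None

    def ham(a, b):
        return sum(1 for n in a if a[n] != b[n])

    if len(fixed) == 4:
        return fixed

    best_pair, best_d = (0, 1), -1
    for i, j in itertools.combinations(range(len(fixed)), 2):
        d = ham(fixed[i], fixed[j])
        if d > best_d:
            best_pair, best_d = (i, j), d
    chosen = [fixed[best_pair[0]], fixed[best_pair[1]]]
    remaining = [s for k, s in enumerate(fixed) if k not in best_pair]
    while len(chosen) < 4:
        scores = [min(ham(c, s) for c in chosen) for s in remaining]
        pick = int(np.argmax(scores))
        chosen.append(remaining.pop(pick))
    return chosen


def generate_network_with_attractors(
    n_nodes: int,
    n_inputs: int,
    mean_in_degree: float = 2.0,
    seed: int = 0,
    max_resamples: int = _MAX_RESAMPLES,
) -> SyntheticTruth:
    """Random signed network + gate logic with >= 4 distinct fixed points.

    Non-input nodes receive 1 + Poisson(mean_in_degree − 1) regulators
    (70% activating) and a random gate descriptor.  Candidate models are
    resampled with incremented sub-seeds until exhaustive enumeration
    finds at least four distinct fixed points; four are designated the
    cell states (MES/NPC/AC/OPC), chosen for maximal pairwise spread, and
    the per-state node signs are derived from them.
    """
    if not (4 <= n_nodes <= _PLANT_NODE_LIMIT):
        raise ValueError(
            f"n_nodes must be in [4, {_PLANT_NODE_LIMIT}] (exhaustive enumeration guard)"
        )
    if not (1 <= n_inputs < n_nodes):
        raise ValueError("need 1 <= n_inputs < n_nodes")
    if mean_in_degree <= 0:
        raise ValueError("mean_in_degree must be positive")

    names = [f"N{i:02d}" for i in range(n_nodes)]
    input_names = names[:n_inputs]
    regulated = names[n_inputs:]

    for attempt in range(max_resamples):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        edges: list[tuple[str, str, int]] = []
        rules: dict[str, GateRule] = {}
        for node in regulated:
            k = 1 + rng.poisson(max(mean_in_degree - 1.0, 0.0))
            k = min(k, n_nodes - 1)
            pool = [n for n in names if n != node]
            regs = list(rng.choice(pool, size=k, replace=False))
            signs = rng.choice([1, -1], size=k, p=[0.7, 0.3])
            for reg, sign in zip(regs, signs):
                edges.append((reg, node, int(sign)))
            rules[node] = DESCRIPTORS[rng.integers(len(DESCRIPTORS))]
        network = SignedNetwork(nodes=list(names), edges=edges)
        if set(network.input_nodes) != set(input_names):
            continue  # an intended input gained an edge target collision; resample
        logic = LogicModel(network=network, rules=rules)
        fixed = find_fixed_points(logic)
        if len(fixed) < 4:
            continue
        states = _spread_four(fixed, regulated)
        if states is None:
            continue
        cell_states = dict(zip(STATE_ORDER, states))
        network.node_signs = {
            name: {n: (1 if st[n] else -1) for n in names}
            for name, st in cell_states.items()
        }
        truth = SyntheticTruth(
            network=network, logic=logic, cell_states=cell_states, seed=seed
        )
        truth.validate()
        return truth
    raise RuntimeError(
        f"no network with >= 4 fixed points found in {max_resamples} resamples "
        f"(n_nodes={n_nodes}, n_inputs={n_inputs}, mean_in_degree={mean_in_degree}, seed={seed})"
    )


def generate_reference_and_bulk(
    truth: SyntheticTruth,
    genes_per_state: int = 30,
    n_cells_per_state: int = 50,
    n_samples: int = 100,
    dirichlet_alpha: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
    nb_dispersion: float = 10.0,
    seed: int = 0,
    poisson: bool = False,
    marker_mean: float = 100.0,
    background_mean: float = 10.0,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, pd.DataFrame]:
    """Single-cell reference + bulk mixtures with known proportions.

    Each state owns a disjoint block of ``genes_per_state`` marker genes
    with elevated mean ``marker_mean`` (background ``background_mean``).
    Reference cells and bulk samples draw counts from a negative binomial
    with variance mean + mean²/dispersion (or Poisson when
    ``poisson=True``); bulk means are the proportion-weighted mixture of
    the state signatures, with proportions ~ Dirichlet(alpha).

    Returns (reference counts genes × cells, cell labels, bulk counts
    genes × samples, true proportions samples × states).  The truth's
    ``proportions``/``labels`` are filled in.
    """
    if genes_per_state < 5:
        raise ValueError("genes_per_state must be >= 5")
    if not poisson and nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be positive")
    alpha = np.asarray(dirichlet_alpha, dtype=float)
    if alpha.shape != (4,) or (alpha <= 0).any():
        raise ValueError("dirichlet_alpha must be 4 positive reals")

    rng = np.random.default_rng(seed)
    states = list(truth.cell_states)
    genes = [f"G_{s}_{i:03d}" for s in states for i in range(genes_per_state)]
    n_genes = len(genes)

    # signature matrix: genes × states, disjoint elevated marker blocks
    sig = np.full((n_genes, 4), background_mean, dtype=float)
    for j in range(4):
        block = slice(j * genes_per_state, (j + 1) * genes_per_state)
        sig[block, j] = marker_mean

    def draw(mean):
        mean = np.clip(mean, 1e-9, None)
        if poisson:
            return rng.poisson(mean)
        # NB(mean, dispersion): n = dispersion, p = n / (n + mean)
        p = nb_dispersion / (nb_dispersion + mean)
        return rng.negative_binomial(nb_dispersion, p)

    cells, cell_labels = [], []
    for j, s in enumerate(states):
        for c in range(n_cells_per_state):
            cells.append(draw(sig[:, j]))
            cell_labels.append(s)
    cell_ids = [f"cell_{i:04d}" for i in range(len(cells))]
    ref = pd.DataFrame(np.column_stack(cells), index=genes, columns=cell_ids)
    labels = pd.Series(cell_labels, index=cell_ids, name="state")

    props = rng.dirichlet(alpha, size=n_samples)
    sample_ids = [f"sample_{i:03d}" for i in range(n_samples)]
    bulk = np.column_stack([draw(sig @ props[i]) for i in range(n_samples)])
    bulk_df = pd.DataFrame(bulk, index=genes, columns=sample_ids)
    prop_df = pd.DataFrame(props, index=sample_ids, columns=states)

    order = {s: i for i, s in enumerate(states)}
    truth.proportions = {
        s: {st: float(prop_df.loc[s, st]) for st in states} for s in sample_ids
    }
    truth.labels = {
        s: max(states, key=lambda st: (prop_df.loc[s, st], -order[st])) for s in sample_ids
    }
    return ref, labels, bulk_df, prop_df


def generate_activity_profiles(
    truth: SyntheticTruth,
    n_per_state: int = 50,
    flip_prob: float = 0.0,
    gauss_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Noisy continuous activity profiles around each cell state.

    Each profile starts at ±1 (2·bit − 1 per node), adds Gaussian noise
    with sd ``gauss_sd``, then sign-flips each entry independently with
    probability ``flip_prob``.  Returns (profiles samples × nodes, state
    labels).
    """
    if not (0.0 <= flip_prob <= 0.5):
        raise ValueError("flip_prob must be in [0, 0.5]")
    if gauss_sd < 0:
        raise ValueError("gauss_sd must be non-negative")
    rng = np.random.default_rng(seed)
    nodes = truth.network.nodes
    rows, labels, ids = [], [], []
    for state_name, state in truth.cell_states.items():
        base = np.array([2 * state[n] - 1 for n in nodes], dtype=float)
        for i in range(n_per_state):
            x = base + rng.normal(0.0, gauss_sd, size=len(nodes))
            flips = rng.random(len(nodes)) < flip_prob
            x[flips] *= -1.0
            rows.append(x)
            labels.append(state_name)
            ids.append(f"{state_name}_{i:03d}")
    profiles = pd.DataFrame(rows, index=ids, columns=nodes)
    return profiles, pd.Series(labels, index=ids, name="state")


def generate_paired_omics(
    n_entities: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.Series, pd.Series, pd.Series, pd.Series]:
    """Paired reference/test activity tables for the imputation ratio.

    Reference RNA activities are bounded away from zero (|value| >= 0.1);
    the noiseless truth satisfies ``true_test_phos = test_rna * ref_phos
    / ref_rna`` exactly, and Gaussian noise with sd ``noise_sd`` is added
    to the observed test RNA only, so the imputed value degrades smoothly
    with noise.  Returns (ref_phos, ref_rna, test_rna, true_test_phos).
    """
    if n_entities < 1:
        raise ValueError("n_entities must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    entities = [f"E{i:04d}" for i in range(n_entities)]
    sign = rng.choice([1.0, -1.0], size=n_entities)
    ref_rna = sign * (0.1 + np.abs(rng.normal(1.0, 0.5, size=n_entities)))
    ref_phos = rng.normal(0.0, 1.0, size=n_entities)
    test_rna_clean = rng.normal(0.0, 1.0, size=n_entities)
    true_test_phos = test_rna_clean * ref_phos / ref_rna
    test_rna = test_rna_clean + rng.normal(0.0, noise_sd, size=n_entities)
    return (
        pd.Series(ref_phos, index=entities, name="ref_phos"),
        pd.Series(ref_rna, index=entities, name="ref_rna"),
        pd.Series(test_rna, index=entities, name="test_rna"),
        pd.Series(true_test_phos, index=entities, name="true_test_phos"),
    )
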