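"""In-silico knockout screen over a Boolean cell-state model.

Starting from each cell state's steady state, every ON node is clamped
OFF (a permanent knockout emulating sustained pharmacological
inhibition) and the model is simulated to a new steady state.  Each
outcome is scored by its Hamming distance to the four reference steady
states; distances are z-normalized per reference-state column within
each start-state block (the heatmap layout), and every outcome is
classified into the nearest cell state by similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .boolnet import (
    BooleanState,
    LogicModel,
    SteadyStateResult,
    apply_update,
    similarity_score,
    simulate_to_steady_state,
    stable_hash,
)

__all__ = [
    "SimConfig",
    "KOScreenResult",
    "hamming_distance",
    "z_normalize",
    "classify_steady_state",
    "run_knockout_screen",
]


def hamming_distance(a: BooleanState, b: BooleanState) -> int:
    """Number of nodes whose ON/OFF state differs between ``a`` and ``b``."""
    if set(a) != set(b):
        raise ValueError("hamming_distance requires identical node sets")
    return sum(1 for node in a if a[node] != b[node])


def z_normalize(matrix: pd.DataFrame, axis: int = 0) -> tuple[pd.DataFrame, list]:
    """Column-wise (axis=0) or row-wise (axis=1) z-scores with population sd.

    Constant slices become all-zero and are returned in the flag list.
    Requires at least two entries along the normalization axis.
    """
    if axis not in (0, 1):
        raise ValueError("axis must be 0 (columns) or 1 (rows)")
    work = matrix.T if axis == 1 else matrix
    if work.shape[0] < 2:
        raise ValueError("z_normalize requires >= 2 rows along the normalization axis")
    mean = work.mean(axis=0)
    sd = work.std(axis=0, ddof=0)
    constant = sd[sd == 0].index.tolist()
    safe_sd = sd.replace(0, 1.0)
    z = (work - mean) / safe_sd
    z[constant] = 0.0
    return (z.T if axis == 1 else z), constant


def classify_steady_state(
    outcome: BooleanState,
    references: Mapping[str, BooleanState],
) -> tuple[str, bool]:
    """Nearest reference cell state by similarity; returns (state, tie_flag).

    Ties go to the first state in the mapping's (fixed) order.
    """
    best_state, best_sim, tie = None, -1.0, False
    for state, ref in references.items():
        sim = similarity_score(outcome, ref)
        if sim > best_sim:
            best_state, best_sim, tie = state, sim, False
        elif sim == best_sim:
            tie = True
    return best_state, tie


@dataclass
class SimConfig:
    """Simulation settings shared by all knockouts in one screen.

    ``z_mode`` selects the normalization block: ``per_start`` (one block
    per start-state heatmap, the default) or ``pooled`` (all simulations
    in one block).
    """

    n_traj: int = 200
    max_time: float = 50.0
    seed: int = 0
    z_mode: str = "per_start"

    def __post_init__(self):
        if self.z_mode not in ("per_start", "pooled"):
            raise ValueError(f"bad z_mode {self.z_mode!r}")


@dataclass
class KOScreenResult:
    """Knockout × reference-state distance matrices plus classifications.

    ``raw_distance`` and ``z_distance`` are indexed by (start_state,
    ko_node); ``classified`` maps the same keys to the nearest state;
    ``outcome_states`` holds the post-knockout steady states (the ML
    training features); ``n_simulations`` is the summed ON-node count of
    the start states.
    """

    raw_distance: pd.DataFrame
    z_distance: pd.DataFrame
    classified: dict[tuple[str, str], str]
    n_simulations: int
    outcome_states: dict[tuple[str, str], BooleanState]
    converged: dict[tuple[str, str], bool]
    classification_ties: dict[tuple[str, str], bool] = field(default_factory=dict)
    constant_columns: list = field(default_factory=list)

    def long_table(self) -> pd.DataFrame:
        rows = []
        for (start, ko) in self.raw_distance.index:
            for ref in self.raw_distance.columns:
                rows.append(
                    {
                        "start_state": start,
                        "ko_node": ko,
                        "reference_state": ref,
                        "raw_distance": int(self.raw_distance.loc[(start, ko), ref]),
                        "z_distance": float(self.z_distance.loc[(start, ko), ref]),
                        "classified_state": self.classified[(start, ko)],
                        "converged": bool(self.converged[(start, ko)]),
                    }
                )
        return pd.DataFrame(rows)

    def display_scores(self) -> pd.DataFrame:
        """Heatmap orientation: positive = shifted toward that state."""
        return -self.z_distance


def plot_heatmaps(screen: KOScreenResult, path) -> None:
    """Write one shift heatmap per start state (red = toward that state)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    starts = list(screen.z_distance.index.get_level_values(0).unique())
    fig, axes = plt.subplots(1, len(starts), figsize=(4 * len(starts), 5), squeeze=False)
    scores = screen.display_scores()
    for ax, start in zip(axes[0], starts):
        block = scores.loc[[start]]
        im = ax.imshow(block.to_numpy(), cmap="RdBu_r", vmin=-2.5, vmax=2.5,
                       aspect="auto")
        ax.set_xticks(range(block.shape[1]), block.columns, rotation=90)
        ax.set_yticks(range(block.shape[0]), [ko for _, ko in block.index], fontsize=6)
        ax.set_title(f"start: {start}")
    fig.colorbar(im, ax=axes[0], shrink=0.6, label="shift toward state (−z)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def run_knockout_screen(
    logic: LogicModel,
    steady_states: Mapping[str, BooleanState],
    sim_config: SimConfig | None = None,
) -> KOScreenResult:
    """Single-node knockout screen from each cell state's steady state.

    For every start state, input nodes are clamped to their state values;
    each ON node in turn is additionally clamped OFF and the model run to
    steady state.  Per-simulation RNG streams are derived from the config
    seed and the (start state, knocked-out node) names, so results do not
    depend on node or file ordering.
    """
    cfg = sim_config or SimConfig()
    inputs = logic.inputs
    for state_name, state in steady_states.items():
        clamp = {n: state[n] for n in inputs}
        if apply_update(logic, state, clamp) != state:
            raise ValueError(f"steady_states[{state_name!r}] is not a fixed point of the model")

    ref_names = list(steady_states)
    rows = []
    raw = {}
    classified: dict[tuple[str, str], str] = {}
    ties: dict[tuple[str, str], bool] = {}
    outcomes: dict[tuple[str, str], BooleanState] = {}
    converged: dict[tuple[str, str], bool] = {}
    n_simulations = 0
    for start_name, start_state in steady_states.items():
        clamp_base = {n: start_state[n] for n in inputs}
        for ko_node in start_state.on_nodes():
            n_simulations += 1
            clamp = dict(clamp_base)
            clamp[ko_node] = 0
            initial = start_state.replace(**{ko_node: 0})
            sim_seed = stable_hash(str(cfg.seed), start_name, ko_node)
            res: SteadyStateResult = simulate_to_steady_state(
                logic,
                initial,
                clamped=clamp,
                n_traj=cfg.n_traj,
                max_time=cfg.max_time,
                seed=sim_seed,
            )
            key = (start_name, ko_node)
            outcomes[key] = res.state
            converged[key] = res.converged
            raw[key] = [hamming_distance(res.state, steady_states[r]) for r in ref_names]
            cls, tie = classify_steady_state(res.state, steady_states)
            classified[key] = cls
            ties[key] = tie
            rows.append(key)

    index = pd.MultiIndex.from_tuples(rows, names=["start_state", "ko_node"])
    raw_df = pd.DataFrame([raw[k] for k in rows], index=index, columns=ref_names)

    constant_cols: list = []
    if cfg.z_mode == "pooled":
        z_df, constant_cols = z_normalize(raw_df.astype(float), axis=0)
    else:
        blocks = []
        for start_name in steady_states:
            if start_name not in raw_df.index.get_level_values(0):
                continue  # start state with no ON nodes contributes no simulations
            block = raw_df.loc[[start_name]].astype(float)
            if block.shape[0] < 2:
                zb = block * 0.0
                constant_cols.extend((start_name, c) for c in block.columns)
            else:
                zb, const = z_normalize(block, axis=0)
                constant_cols.extend((start_name, c) for c in const)
            blocks.append(zb)
        z_df = pd.concat(blocks)

    return KOScreenResult(
        raw_distance=raw_df,
        z_distance=z_df,
        classified=classified,
        n_simulations=n_simulations,
        outcome_states=outcomes,
        converged=converged,
        classification_ties=ties,
        constant_columns=constant_cols,
    )
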