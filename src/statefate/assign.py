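"""Cell-state assignment: cluster labeling, deconvolution, dominant state.

Clusters of single cells are labeled with the most over-represented
gene module (upper-tail hypergeometric test); bulk samples are
deconvolved against per-state mean-CPM signatures by non-negative least
squares and renormalized to the simplex; each sample's dominant state is
the composition argmax.  Also counts how many network nodes fall in each
hallmark-style pathway gene set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .boolnet import STATE_ORDER

__all__ = [
    "GeneModuleSet",
    "EnrichmentTable",
    "CompositionEstimate",
    "hypergeometric_enrichment",
    "label_clusters",
    "estimate_compositions",
    "classify_dominant_state",
    "count_pathway_membership",
]

NEG_LOG10_CAP = 300.0


@dataclass
class GeneModuleSet:
    """Named gene modules over a gene universe (GMT-style)."""

    modules: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self):
        if not self.universe:
            raise ValueError("gene universe must be non-empty")
        for name, genes in self.modules.items():
            extra = genes - self.universe
            if extra:
                raise ValueError(
                    f"module {name!r} has genes outside the universe: {sorted(extra)[:5]}"
                )

    @classmethod
    def from_gmt(cls, path, universe: Iterable[str] | None = None) -> "GeneModuleSet":
        """Read GMT (name, description, genes...); universe defaults to the union."""
        modules: dict[str, set[str]] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or not parts[0]:
                    continue
                if parts[0] in modules:
                    raise ValueError(f"duplicate module name {parts[0]!r} in GMT")
                modules[parts[0]] = {g for g in parts[2:] if g}
        uni = set(universe) if universe is not None else set().union(*modules.values())
        return cls(modules=modules, universe=uni)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.modules):
                genes = "\t".join(sorted(self.modules[name]))
                fh.write(f"{name}\tna\t{genes}\n")


@dataclass
class EnrichmentTable:
    """Per-cluster module enrichment: −log10 p matrix plus winning module."""

    scores: pd.DataFrame  # cluster × module, −log10 p
    winner: dict[str, str]
    ties: dict[str, bool] = field(default_factory=dict)


@dataclass
class CompositionEstimate:
    """Per-sample cell-state proportions on the simplex plus dominant state."""

    proportions: pd.DataFrame  # sample × state
    dominant: dict[str, str] = field(default_factory=dict)
    ties: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        p = self.proportions
        if (p.values < -1e-12).any():
            raise ValueError("proportions must be non-negative")
        bad = np.abs(p.sum(axis=1) - 1.0) > 1e-6
        if bad.any():
            raise ValueError(f"proportion rows must sum to 1: {list(p.index[bad])[:5]}")


def hypergeometric_enrichment(
    cluster_markers: set[str],
    module: set[str],
    universe: set[str],
) -> float:
    """Upper-tail over-representation p-value P(X >= k).

    X ~ Hypergeom(N=|universe|, K=|module|, n=|cluster_markers|) and
    k = |overlap|.  An empty module returns 1 by convention.
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not cluster_markers <= universe or not module <= universe:
        raise ValueError("markers and module must be subsets of the universe")
    if not module:
        return 1.0
    N, K, n = len(universe), len(module), len(cluster_markers)
    k = len(cluster_markers & module)
    # sf(k-1) = P(X >= k), inclusive upper tail
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, np.nextafter(0, 1)), 1.0)


def label_clusters(
    markers_by_cluster: Mapping[str, Iterable[str]],
    modules: GeneModuleSet,
) -> EnrichmentTable:
    """Label each cluster with its most enriched module.

    Scores are −log10 p capped at 300; the winner is the score argmax with
    ties broken by lexicographic module order (tie flag recorded).  Marker
    genes outside the universe are dropped with a warning.
    """
    module_names = sorted(modules.modules)
    scores = {}
    winner, ties = {}, {}
    for cluster, markers in markers_by_cluster.items():
        marker_set = set(markers)
        if not marker_set:
            raise ValueError(f"cluster {cluster!r} has no marker genes")
        stray = marker_set - modules.universe
        if stray:
            warnings.warn(
                f"cluster {cluster!r}: dropping {len(stray)} marker(s) outside the universe"
            )
            marker_set -= stray
        row = {}
        for name in module_names:
            p = hypergeometric_enrichment(marker_set, modules.modules[name], modules.universe)
            row[name] = min(-np.log10(p), NEG_LOG10_CAP)
        scores[cluster] = row
        best = max(row.values())
        winners = [m for m in module_names if row[m] == best]
        winner[cluster] = winners[0]
        ties[cluster] = len(winners) > 1
    table = pd.DataFrame.from_dict(scores, orient="index")[module_names]
    return EnrichmentTable(scores=table, winner=winner, ties=ties)


def _cpm(counts: pd.DataFrame) -> pd.DataFrame:
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("every sample/cell must have positive total counts")
    return counts / totals * 1e6


def estimate_compositions(
    bulk_counts: pd.DataFrame,
    reference_counts: pd.DataFrame,
    reference_labels: Mapping[str, str] | pd.Series,
) -> CompositionEstimate:
    """Reference-based linear deconvolution of bulk samples.

    Both matrices are genes × samples/cells of raw counts.  Counts are
    CPM-normalized; the signature matrix is the mean CPM per state over
    the reference cells; each bulk sample's CPM vector is regressed on
    the signatures by NNLS and the solution renormalized to the simplex.
    CPM makes the result invariant to rescaling any bulk sample.
    """
    labels = pd.Series(reference_labels)
    if labels.nunique() < 2:
        raise ValueError("need at least 2 cell states in the reference labels")
    missing = set(labels.index) - set(reference_counts.columns)
    if missing:
        raise ValueError(f"labels refer to unknown reference cells: {sorted(missing)[:5]}")
    shared = bulk_counts.index.intersection(reference_counts.index)
    if len(shared) < 10:
        raise ValueError(f"bulk and reference share only {len(shared)} genes (< 10)")

    bulk_cpm = _cpm(bulk_counts.loc[shared])
    ref_cpm = _cpm(reference_counts)
    states = list(pd.unique(labels))
    sig = pd.DataFrame(
        {s: ref_cpm.loc[shared, labels.index[labels == s]].mean(axis=1) for s in states}
    )
    rank = np.linalg.matrix_rank(sig.values)
    if rank < len(states):
        corr = np.corrcoef(sig.values.T)
        collinear = sorted(
            {states[i] for i in range(len(states)) for j in range(len(states))
             if i != j and abs(corr[i, j]) > 0.9999}
        )
        raise ValueError(
            "state signature matrix is rank-deficient"
            + (f"; collinear states: {collinear}" if collinear else "")
        )

    props = {}
    for sample in bulk_cpm.columns:
        x, _ = nnls(sig.values, bulk_cpm[sample].values)
        total = x.sum()
        props[sample] = x / total if total > 0 else np.full(len(states), 1.0 / len(states))
    prop_df = pd.DataFrame.from_dict(props, orient="index", columns=states)
    comp = CompositionEstimate(proportions=prop_df)
    comp.dominant, comp.ties = _row_argmax(prop_df)
    return comp


def _state_tie_order(columns: Iterable[str]) -> list[str]:
    cols = list(columns)
    ordered = [s for s in STATE_ORDER if s in cols]
    ordered += sorted(c for c in cols if c not in STATE_ORDER)
    return ordered


def _row_argmax(prop_df: pd.DataFrame) -> tuple[dict[str, str], dict[str, bool]]:
    order = _state_tie_order(prop_df.columns)
    dominant, ties = {}, {}
    for sample, row in prop_df.iterrows():
        best = row.max()
        winners = [s for s in order if row[s] == best]
        dominant[sample] = winners[0]
        ties[sample] = len(winners) > 1
    return dominant, ties


def classify_dominant_state(comp: CompositionEstimate) -> dict[str, str]:
    """Row argmax of the composition; ties fall back to MES > NPC > AC > OPC."""
    dominant, ties = _row_argmax(comp.proportions)
    comp.dominant, comp.ties = dominant, ties
    return dominant


def count_pathway_membership(
    network_nodes: set[str],
    pathways: GeneModuleSet,
) -> dict[str, int]:
    """|nodes ∩ pathway| per pathway, ordered by descending count."""
    counts = {name: len(network_nodes & genes) for name, genes in pathways.modules.items()}
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
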