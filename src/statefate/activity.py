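"""Footprint-based TF/kinase activity scoring and booleanization.

A regulator's activity is inferred from the differential statistics of
its regulon targets with a weighted mean (WMEAN) score, optionally
normalized against a gene-label permutation null.  Phospho-level
activity absent from a test cohort is imputed from RNA-level activity
through a per-entity reference ratio, and signed activities are
booleanized (positive -> ON).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Regulon",
    "ActivityProfile",
    "BooleanProfile",
    "WmeanResult",
    "wmean_score",
    "normalized_wmean",
    "impute_phospho_activity",
    "booleanize_profile",
]

IMPUTATION_FLOOR = 1e-6


@dataclass
class Regulon:
    """Weighted regulator→target edges (signed, nonzero weights)."""

    edges: pd.DataFrame  # columns: source, target, weight

    def __post_init__(self):
        df = pd.DataFrame(self.edges, columns=["source", "target", "weight"]).copy()
        df["weight"] = df["weight"].astype(float)
        if not np.isfinite(df["weight"]).all():
            raise ValueError("regulon weights must be finite")
        if (df["weight"] == 0).any():
            raise ValueError("regulon weights must be nonzero")
        if df.duplicated(subset=["source", "target"]).any():
            dup = df[df.duplicated(subset=["source", "target"])].iloc[0]
            raise ValueError(f"duplicate regulon edge {dup['source']!r}->{dup['target']!r}")
        self.edges = df

    @classmethod
    def from_tsv(cls, path) -> "Regulon":
        return cls(pd.read_csv(path, sep="\t"))

    def targets_of(self, regulator: str) -> pd.DataFrame:
        return self.edges[self.edges["source"] == regulator]

    @property
    def regulators(self) -> list[str]:
        return list(pd.unique(self.edges["source"]))


@dataclass
class ActivityProfile:
    """Signed activity per entity for one sample at one molecular level."""

    values: dict[str, float]
    sample_id: str = ""
    level: str = "rna"  # or "phospho"

    def __post_init__(self):
        if self.level not in ("rna", "phospho"):
            raise ValueError(f"bad level {self.level!r}")
        vals = {str(k): float(v) for k, v in dict(self.values).items()}
        bad = [k for k, v in vals.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite activity for entities {bad[:5]}")
        self.values = vals

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, dtype=float)


@dataclass
class BooleanProfile:
    """ON/OFF activity per entity."""

    values: dict[str, int]

    def __post_init__(self):
        vals = {str(k): int(v) for k, v in dict(self.values).items()}
        bad = [k for k, v in vals.items() if v not in (0, 1)]
        if bad:
            raise ValueError(f"non-binary entries for entities {bad[:5]}")
        self.values = vals

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, dtype=int)


def _retained(molecular_stats: Mapping[str, float], regulon: Regulon, regulator: str):
    sub = regulon.targets_of(regulator)
    mask = sub["target"].isin(molecular_stats.keys())
    sub = sub[mask]
    if sub.empty:
        raise ValueError(f"regulator {regulator!r} has no targets present in the stats")
    x = np.array([float(molecular_stats[t]) for t in sub["target"]])
    w = sub["weight"].to_numpy()
    return x, w


def wmean_score(
    molecular_stats: Mapping[str, float],
    regulon: Regulon,
    regulator: str,
) -> float:
    """Weighted-mean enrichment: sum(x_i w_i) / sum(|w_i|) over retained targets.

    Targets absent from the stats are dropped; dropping every target is an
    error naming the regulator.
    """
    x, w = _retained(molecular_stats, regulon, regulator)
    return float(np.dot(x, w) / np.abs(w).sum())


@dataclass
class WmeanResult:
    score: float
    z: float
    empirical_p: float
    degenerate_null: bool = False


def normalized_wmean(
    molecular_stats: Mapping[str, float],
    regulon: Regulon,
    regulator: str,
    n_perm: int = 1000,
    seed: int = 0,
) -> WmeanResult:
    """WMEAN score with a gene-label permutation null.

    The null permutes the stats values over gene labels ``n_perm`` times
    and rescores; z = (score − mean(null)) / sd(null), and the empirical
    p-value is two-sided around the null mean with +1 smoothing.  A
    zero-variance null yields z = 0 with a warning.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    stats_series = pd.Series(molecular_stats, dtype=float)
    genes = list(stats_series.index)
    sub = regulon.targets_of(regulator)
    sub = sub[sub["target"].isin(genes)]
    if sub.empty:
        raise ValueError(f"regulator {regulator!r} has no targets present in the stats")
    w = sub["weight"].to_numpy()
    gene_pos = {g: i for i, g in enumerate(genes)}
    idx = np.array([gene_pos[t] for t in sub["target"]])
    values = stats_series.to_numpy()
    score = float(values[idx] @ w / np.abs(w).sum())

    rng = np.random.default_rng(seed)
    perm = np.tile(values, (n_perm, 1))
    perm = rng.permuted(perm, axis=1)
    null = perm[:, idx] @ w / np.abs(w).sum()
    mu, sd = float(null.mean()), float(null.std(ddof=0))
    if sd == 0:
        warnings.warn(f"degenerate permutation null for {regulator!r}; z set to 0")
        z = 0.0
        degenerate = True
    else:
        z = (score - mu) / sd
        degenerate = False
    exceed = int(np.sum(np.abs(null - mu) >= abs(score - mu)))
    p = (1 + exceed) / (n_perm + 1)
    return WmeanResult(score=score, z=z, empirical_p=p, degenerate_null=degenerate)


def impute_phospho_activity(
    ref_phos: ActivityProfile,
    ref_rna: ActivityProfile,
    test_rna: ActivityProfile,
    floor: float = IMPUTATION_FLOOR,
) -> tuple[ActivityProfile, list[str]]:
    """Impute test phospho activity via the reference phospho/RNA ratio.

    ``out[e] = test_rna[e] * ref_phos[e] / ref_rna[e]`` for every entity
    shared by the three profiles with ``|ref_rna[e]| >= floor``; entities
    below the floor fall back to their RNA activity and are returned in
    the flag list.
    """
    shared = set(ref_phos.values) & set(ref_rna.values) & set(test_rna.values)
    if not shared:
        raise ValueError("no shared entities across reference and test profiles")
    out: dict[str, float] = {}
    fallback: list[str] = []
    for e in sorted(shared):
        denom = ref_rna.values[e]
        if abs(denom) < floor:
            out[e] = test_rna.values[e]
            fallback.append(e)
        else:
            out[e] = test_rna.values[e] * ref_phos.values[e] / denom
    profile = ActivityProfile(values=out, sample_id=test_rna.sample_id, level="phospho")
    return profile, fallback


def booleanize_profile(profile: ActivityProfile) -> BooleanProfile:
    """Positive activity -> 1, non-positive -> 0; NaN is an error."""
    out = {}
    for e, v in profile.values.items():
        if not np.isfinite(v):
            raise ValueError(f"non-finite activity for entity {e!r}")
        out[e] = 1 if v > 0 else 0
    return BooleanProfile(values=out)
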