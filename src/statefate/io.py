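"""File-format helpers: SIF networks, node-sign tables, activity TSVs."""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .boolnet import BooleanState, SignedNetwork

__all__ = [
    "read_sif",
    "write_sif",
    "read_node_signs",
    "write_node_signs",
    "read_activity_tsv",
    "write_activity_tsv",
    "read_count_matrix",
    "write_count_matrix",
]


def write_sif(network: SignedNetwork, path) -> None:
    """Write ``source<TAB>sign<TAB>target`` lines (sign in {1, -1}).

    Isolated nodes are preserved as ``node<TAB>0<TAB>node`` self-marker
    lines so the node set round-trips.
    """
    touched = {s for s, _, _ in network.edges} | {t for _, t, _ in network.edges}
    with open(path, "w") as fh:
        for s, t, sign in network.edges:
            fh.write(f"{s}\t{sign}\t{t}\n")
        for n in network.nodes:
            if n not in touched:
                fh.write(f"{n}\t0\t{n}\n")


def read_sif(path) -> SignedNetwork:
    nodes: list[str] = []
    seen = set()
    edges = []

    def add_node(n):
        if n not in seen:
            seen.add(n)
            nodes.append(n)

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            s, sign, t = line.split("\t")
            add_node(s)
            add_node(t)
            if int(sign) != 0:
                edges.append((s, t, int(sign)))
    return SignedNetwork(nodes=nodes, edges=edges)


def write_node_signs(network: SignedNetwork, path) -> None:
    rows = [
        {"node": n, "state": state, "sign": sign}
        for state, signs in network.node_signs.items()
        for n, sign in signs.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_node_signs(path) -> dict[str, dict[str, int]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, int]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["state"]), {})[str(row["node"])] = int(row["sign"])
    return out


def write_activity_tsv(profiles: pd.DataFrame, path) -> None:
    """Long-format (entity, sample, value) activity table."""
    long = profiles.stack().rename("value").reset_index()
    long.columns = ["sample", "entity", "value"]
    long[["entity", "sample", "value"]].to_csv(path, sep="\t", index=False)


def read_activity_tsv(path) -> pd.DataFrame:
    long = pd.read_csv(path, sep="\t")
    return long.pivot(index="sample", columns="entity", values="value")


def write_count_matrix(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_count_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def states_to_frame(states: Mapping[str, BooleanState]) -> pd.DataFrame:
    return pd.DataFrame({k: pd.Series(v.as_dict()) for k, v in states.items()}).T
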