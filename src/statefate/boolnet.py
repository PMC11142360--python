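"""Boolean network engine: signed networks, logic synthesis, and dynamics.

A signed directed protein-interaction network (activating ``+1`` /
inhibiting ``-1`` edges, with per-cell-state up/down node annotations) is
turned into a Boolean model by choosing, for every regulated node, a gate
descriptor from a small human-readable family such that each annotated
cell state is a fixed point of the synchronous update.  Dynamics are
simulated either synchronously (used by the exhaustive oracles) or as a
continuous-time asynchronous Markov process with unit flip rates, in which
a node whose rule output disagrees with its current value flips after an
exponential waiting time.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "STATE_ORDER",
    "BooleanState",
    "SignedNetwork",
    "GateRule",
    "DESCRIPTORS",
    "LogicModel",
    "SynthesisReport",
    "SteadyStateResult",
    "merge_networks",
    "synthesize_rules",
    "apply_update",
    "find_fixed_points",
    "find_attractors_bruteforce",
    "simulate_to_steady_state",
    "similarity_score",
]

#: Fixed tie-break order for the four tumor cell states (most to least
#: aggressive by convention): mesenchymal-like, neural-progenitor-like,
#: astrocyte-like, oligodendrocyte-progenitor-like.
STATE_ORDER = ("MES", "NPC", "AC", "OPC")

_BRUTE_FORCE_LIMIT = 20  # free nodes; 2**20 states is the enumeration guard


class BooleanState(Mapping):
    """An ON/OFF assignment over a fixed set of named nodes.

    Behaves as an immutable mapping ``node -> {0, 1}``.  Equality and
    hashing are value-based, so states can be dict keys and compared
    across modules.
    """

    __slots__ = ("_bits",)

    def __init__(self, bits: Mapping[str, int]):
        clean = {}
        for node, value in bits.items():
            iv = int(value)
            if iv not in (0, 1):
                raise ValueError(f"bit for node {node!r} must be 0 or 1, got {value!r}")
            clean[str(node)] = iv
        self._bits = clean

    def __getitem__(self, node: str) -> int:
        return self._bits[node]

    def __iter__(self):
        return iter(self._bits)

    def __len__(self) -> int:
        return len(self._bits)

    def __eq__(self, other) -> bool:
        if isinstance(other, BooleanState):
            return self._bits == other._bits
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._bits.items()))

    def __repr__(self) -> str:
        on = [n for n, b in self._bits.items() if b]
        return f"BooleanState(on={on!r}, n={len(self._bits)})"

    def replace(self, **bits: int) -> "BooleanState":
        new = dict(self._bits)
        for node, value in bits.items():
            if node not in new:
                raise KeyError(node)
            new[node] = int(value)
        return BooleanState(new)

    def complement(self) -> "BooleanState":
        return BooleanState({n: 1 - b for n, b in self._bits.items()})

    def on_nodes(self) -> list[str]:
        return [n for n, b in self._bits.items() if b == 1]

    def as_dict(self) -> dict[str, int]:
        return dict(self._bits)


@dataclass
class SignedNetwork:
    """Directed graph with signed edges and per-state node regulation signs.

    ``edges`` holds ``(source, target, sign)`` triples with sign ``+1``
    (activating) or ``-1`` (inhibiting).  ``node_signs`` maps a cell-state
    name to a full ``node -> {+1, -1}`` annotation (up-/down-regulated in
    that state).  ``sign_conflicts`` records (source, target) pairs that
    carry both signs after a merge; both edges are kept as separate
    regulator slots.
    """

    nodes: list[str]
    edges: list[tuple[str, str, int]]
    node_signs: dict[str, dict[str, int]] = field(default_factory=dict)
    sign_conflicts: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.nodes = [str(n) for n in self.nodes]
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node names")
        seen = set()
        clean_edges = []
        for s, t, sign in self.edges:
            if sign not in (1, -1):
                raise ValueError(f"edge ({s},{t}) has sign {sign}; must be +1 or -1")
            if s not in node_set or t not in node_set:
                raise ValueError(f"edge ({s},{t}) references undeclared node")
            key = (s, t, sign)
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)
            clean_edges.append((str(s), str(t), int(sign)))
        self.edges = clean_edges
        for state, signs in self.node_signs.items():
            missing = node_set - set(signs)
            if missing:
                raise ValueError(f"node_signs for state {state!r} missing {sorted(missing)}")
            bad = {n: v for n, v in signs.items() if v not in (1, -1)}
            if bad:
                raise ValueError(f"node_signs for state {state!r} has non-±1 values {bad}")

    def regulators(self, node: str) -> tuple[list[str], list[str]]:
        """Return (activators, inhibitors) of ``node``, in edge order."""
        acts = [s for s, t, sign in self.edges if t == node and sign == 1]
        inhs = [s for s, t, sign in self.edges if t == node and sign == -1]
        return acts, inhs

    @property
    def input_nodes(self) -> list[str]:
        targets = {t for _, t, _ in self.edges}
        return [n for n in self.nodes if n not in targets]

    def target_states(self) -> dict[str, BooleanState]:
        """Per-state Boolean targets: up-regulated (+1) -> ON, down (-1) -> OFF."""
        return {
            state: BooleanState({n: 1 if v == 1 else 0 for n, v in signs.items()})
            for state, signs in self.node_signs.items()
        }

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for s, t, sign in self.edges:
            g.add_edge(s, t, sign=sign)
        return g


def merge_networks(networks: Sequence[SignedNetwork]) -> SignedNetwork:
    """Union of nodes and of unique (source, target, sign) edges.

    A (source, target) pair appearing with both signs across the inputs is
    kept as two parallel regulator slots (one activating, one inhibiting)
    and recorded in ``sign_conflicts``.  Node-sign annotations are merged
    per state; a later network's annotation for the same state wins only
    where states do not overlap (overlapping annotations must agree).
    """
    if not networks:
        raise ValueError("merge_networks requires at least one network")
    nodes: list[str] = []
    seen_nodes: set[str] = set()
    edges: list[tuple[str, str, int]] = []
    seen_edges: set[tuple[str, str, int]] = set()
    node_signs: dict[str, dict[str, int]] = {}
    for net in networks:
        for n in net.nodes:
            if n not in seen_nodes:
                seen_nodes.add(n)
                nodes.append(n)
        for e in net.edges:
            if e not in seen_edges:
                seen_edges.add(e)
                edges.append(e)
        for state, signs in net.node_signs.items():
            node_signs.setdefault(state, {}).update(signs)
    pair_signs: dict[tuple[str, str], set[int]] = {}
    for s, t, sign in edges:
        pair_signs.setdefault((s, t), set()).add(sign)
    conflicts = sorted(pair for pair, signs in pair_signs.items() if len(signs) == 2)
    # merged node_signs may not cover all nodes per state; fill missing as down
    for state, signs in node_signs.items():
        for n in nodes:
            signs.setdefault(n, -1)
    return SignedNetwork(nodes=nodes, edges=edges, node_signs=node_signs, sign_conflicts=conflicts)


@dataclass(frozen=True)
class GateRule:
    """Gate descriptor for one node's update rule.

    Activators are combined with ``activator_gate`` (OR = any activator
    suffices, AND = all required), inhibitors with ``inhibitor_gate``;
    ``dominance`` resolves the combination: ``inhibitor_wins`` gives
    ``act AND NOT inh``, ``activator_wins`` gives ``act OR NOT inh``.
    Nodes with only activators use ``act``; only inhibitors, ``NOT inh``.
    """

    activator_gate: str = "OR"
    inhibitor_gate: str = "OR"
    dominance: str = "inhibitor_wins"

    def __post_init__(self):
        if self.activator_gate not in ("OR", "AND"):
            raise ValueError(f"bad activator_gate {self.activator_gate!r}")
        if self.inhibitor_gate not in ("OR", "AND"):
            raise ValueError(f"bad inhibitor_gate {self.inhibitor_gate!r}")
        if self.dominance not in ("inhibitor_wins", "activator_wins"):
            raise ValueError(f"bad dominance {self.dominance!r}")

    def to_dict(self) -> dict[str, str]:
        return {
            "activator_gate": self.activator_gate,
            "inhibitor_gate": self.inhibitor_gate,
            "dominance": self.dominance,
        }


#: Canonical descriptor order used for synthesis tie-breaks.
DESCRIPTORS: tuple[GateRule, ...] = tuple(
    GateRule(ag, ig, dom)
    for dom in ("inhibitor_wins", "activator_wins")
    for ag in ("OR", "AND")
    for ig in ("OR", "AND")
)


def _eval_gate(rule: GateRule, act_vals: Sequence[int], inh_vals: Sequence[int],
               current: int) -> int:
    if not act_vals and not inh_vals:
        return current  # input node holds its value unless clamped
    act = None
    if act_vals:
        act = max(act_vals) if rule.activator_gate == "OR" else min(act_vals)
    inh = None
    if inh_vals:
        inh = max(inh_vals) if rule.inhibitor_gate == "OR" else min(inh_vals)
    if inh is None:
        return act
    if act is None:
        return 1 - inh
    if rule.dominance == "inhibitor_wins":
        return act & (1 - inh)
    return act | (1 - inh)


@dataclass
class LogicModel:
    """Per-node gate rules over a signed network.

    ``rules`` covers every regulated node; input nodes (no regulators)
    have no rule and are clamped during simulation.
    """

    network: SignedNetwork
    rules: dict[str, GateRule]

    _regs: dict[str, tuple[list[str], list[str]]] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self._regs = {n: self.network.regulators(n) for n in self.network.nodes}
        for node, (acts, inhs) in self._regs.items():
            if (acts or inhs) and node not in self.rules:
                raise ValueError(f"regulated node {node!r} has no rule")

    @property
    def inputs(self) -> list[str]:
        return self.network.input_nodes

    def regulators(self, node: str) -> tuple[list[str], list[str]]:
        return self._regs[node]

    def evaluate_node(self, node: str, state: Mapping[str, int]) -> int:
        acts, inhs = self._regs[node]
        rule = self.rules.get(node, GateRule())
        return _eval_gate(rule, [state[a] for a in acts], [state[i] for i in inhs], state[node])

    def to_dict(self) -> dict:
        return {
            "nodes": self.network.nodes,
            "edges": [list(e) for e in self.network.edges],
            "rules": {n: r.to_dict() for n, r in self.rules.items()},
            "inputs": self.inputs,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, payload: Mapping) -> "LogicModel":
        net = SignedNetwork(
            nodes=list(payload["nodes"]),
            edges=[tuple(e) for e in payload["edges"]],
        )
        rules = {n: GateRule(**r) for n, r in payload["rules"].items()}
        return cls(network=net, rules=rules)

    def to_boolnet_text(self) -> str:
        """Export rules as BoolNet-style ``targets, factors`` lines."""
        lines = ["targets, factors"]
        for node in self.network.nodes:
            acts, inhs = self._regs[node]
            rule = self.rules.get(node)
            if not acts and not inhs:
                lines.append(f"{node}, {node}")
                continue
            a_op = " | " if rule.activator_gate == "OR" else " & "
            i_op = " | " if rule.inhibitor_gate == "OR" else " & "
            act_expr = "(" + a_op.join(acts) + ")" if acts else ""
            inh_expr = "(" + i_op.join(inhs) + ")" if inhs else ""
            if acts and inhs:
                if rule.dominance == "inhibitor_wins":
                    expr = f"{act_expr} & !{inh_expr}"
                else:
                    expr = f"{act_expr} | !{inh_expr}"
            elif acts:
                expr = act_expr
            else:
                expr = f"!{inh_expr}"
            lines.append(f"{node}, {expr}")
        return "\n".join(lines) + "\n"


@dataclass
class SynthesisReport:
    """Outcome of gate-descriptor synthesis per node.

    ``satisfied`` maps node -> (n_targets_matched, n_targets); nodes in
    ``unsatisfiable`` could not match every target with any descriptor
    (their chosen rule maximizes the match count, canonical order breaking
    ties).  ``tied`` flags nodes where several descriptors achieved the
    best count.  ``clamped_inputs`` lists regulator-free nodes, which are
    clamped rather than ruled.
    """

    satisfied: dict[str, tuple[int, int]]
    unsatisfiable: list[str]
    tied: dict[str, bool]
    clamped_inputs: list[str]

    @property
    def all_satisfied(self) -> bool:
        return not self.unsatisfiable


def synthesize_rules(
    network: SignedNetwork,
    targets: Mapping[str, BooleanState],
) -> tuple[LogicModel, SynthesisReport]:
    """Choose a gate descriptor per regulated node matching the target states.

    For each node the eight descriptors are scored by how many target
    states the node's update reproduces when its regulators take their
    target values; the first descriptor (canonical order) with the best
    score is kept.  Node-local search is exact because, with every other
    node pinned to its target value, descriptor choices are independent.
    """
    if not targets:
        raise ValueError("at least one target state required")
    node_set = set(network.nodes)
    for state, tgt in targets.items():
        if set(tgt) != node_set:
            raise ValueError(f"target {state!r} does not cover the network's nodes")
    rules: dict[str, GateRule] = {}
    satisfied: dict[str, tuple[int, int]] = {}
    unsat: list[str] = []
    tied: dict[str, bool] = {}
    inputs = []
    n_targets = len(targets)
    for node in network.nodes:
        acts, inhs = network.regulators(node)
        if not acts and not inhs:
            inputs.append(node)
            continue
        best_rule, best_score, best_tied = None, -1, False
        for rule in DESCRIPTORS:
            score = 0
            for tgt in targets.values():
                out = _eval_gate(rule, [tgt[a] for a in acts], [tgt[i] for i in inhs], tgt[node])
                if out == tgt[node]:
                    score += 1
            if score > best_score:
                best_rule, best_score, best_tied = rule, score, False
            elif score == best_score:
                best_tied = True
        rules[node] = best_rule
        satisfied[node] = (best_score, n_targets)
        tied[node] = best_tied
        if best_score < n_targets:
            unsat.append(node)
    model = LogicModel(network=network, rules=rules)
    report = SynthesisReport(
        satisfied=satisfied, unsatisfiable=unsat, tied=tied, clamped_inputs=inputs
    )
    return model, report


def apply_update(
    logic: LogicModel,
    state: BooleanState,
    clamped: Mapping[str, int] | None = None,
) -> BooleanState:
    """One synchronous step: every non-clamped node takes its rule output."""
    clamped = dict(clamped or {})
    unknown = set(clamped) - set(logic.network.nodes)
    if unknown:
        raise ValueError(f"clamped nodes not in network: {sorted(unknown)}")
    out = {}
    for node in logic.network.nodes:
        if node in clamped:
            out[node] = int(clamped[node])
        else:
            out[node] = logic.evaluate_node(node, state)
    return BooleanState(out)


def _free_nodes(logic: LogicModel, clamped: Mapping[str, int]) -> list[str]:
    return [n for n in logic.network.nodes if n not in clamped]


def _vectorized_step(logic, free, clamped, bits):
    """Next-value boolean arrays for all enumerated states.

    ``bits`` maps node -> bool array over the enumerated state block.
    """
    nxt = {}
    for node in logic.network.nodes:
        if node in clamped:
            nxt[node] = bits[node]
            continue
        acts, inhs = logic.regulators(node)
        rule = logic.rules.get(node, GateRule())
        if not acts and not inhs:
            nxt[node] = bits[node]
            continue
        act = None
        if acts:
            stack = [bits[a] for a in acts]
            act = np.logical_or.reduce(stack) if rule.activator_gate == "OR" else np.logical_and.reduce(stack)
        inh = None
        if inhs:
            stack = [bits[i] for i in inhs]
            inh = np.logical_or.reduce(stack) if rule.inhibitor_gate == "OR" else np.logical_and.reduce(stack)
        if inh is None:
            nxt[node] = act
        elif act is None:
            nxt[node] = ~inh
        elif rule.dominance == "inhibitor_wins":
            nxt[node] = act & ~inh
        else:
            nxt[node] = act | ~inh
    return nxt


def _enumerate_bits(logic, clamped):
    free = _free_nodes(logic, clamped)
    if len(free) > _BRUTE_FORCE_LIMIT:
        raise ValueError(
            f"exhaustive enumeration limited to {_BRUTE_FORCE_LIMIT} free nodes; got {len(free)}"
        )
    n = len(free)
    idx = np.arange(1 << n, dtype=np.int64)
    bits = {}
    for j, node in enumerate(free):
        bits[node] = ((idx >> j) & 1).astype(bool)
    ones = np.ones(1 << n, dtype=bool)
    for node, val in clamped.items():
        bits[node] = ones if val else ~ones
    return free, idx, bits


def find_fixed_points(
    logic: LogicModel,
    clamped: Mapping[str, int] | None = None,
) -> list[BooleanState]:
    """All synchronous fixed points, by vectorized exhaustive enumeration.

    Unclamped input nodes hold their value, so each of their settings
    yields its own clamped subsystem implicitly.
    """
    clamped = dict(clamped or {})
    free, idx, bits = _enumerate_bits(logic, clamped)
    nxt = _vectorized_step(logic, free, clamped, bits)
    stable = np.ones(len(idx), dtype=bool)
    for node in free:
        stable &= nxt[node] == bits[node]
    fixed = []
    for i in np.nonzero(stable)[0]:
        st = {node: int(bits[node][i]) for node in logic.network.nodes}
        fixed.append(BooleanState(st))
    return fixed


@dataclass
class Attractor:
    states: list[BooleanState]
    is_fixed_point: bool

    def __contains__(self, state: BooleanState) -> bool:
        return state in self.states


def find_attractors_bruteforce(
    logic: LogicModel,
    clamped: Mapping[str, int] | None = None,
    mode: str = "synchronous",
) -> list[Attractor]:
    """Exhaustive attractor search over the full state space.

    ``synchronous`` mode follows the deterministic one-step map and
    returns its cycles (fixed points flagged).  ``asynchronous`` mode
    builds the nondeterministic single-flip transition graph and returns
    its terminal strongly connected components — the attractors of the
    continuous-time dynamics.  Refuses more than 20 free nodes.
    """
    clamped = dict(clamped or {})
    free, idx, bits = _enumerate_bits(logic, clamped)
    n = len(free)
    size = 1 << n
    nxt = _vectorized_step(logic, free, clamped, bits)

    if mode == "synchronous":
        succ = np.zeros(size, dtype=np.int64)
        for j, node in enumerate(free):
            succ += nxt[node].astype(np.int64) << j
        color = np.zeros(size, dtype=np.int64)  # 0 unvisited, else run id
        attractors = []
        run = 0
        for start in range(size):
            if color[start]:
                continue
            run += 1
            path = []
            s = start
            while color[s] == 0:
                color[s] = run
                path.append(s)
                s = succ[s]
            if color[s] == run:  # new cycle found in this run
                cyc_start = path.index(s)
                cycle = path[cyc_start:]
                attractors.append(cycle)
        result = []
        for cycle in attractors:
            states = [_index_to_state(i, free, clamped, logic) for i in cycle]
            result.append(Attractor(states=states, is_fixed_point=len(cycle) == 1))
        return result

    if mode == "asynchronous":
        from scipy import sparse
        from scipy.sparse.csgraph import connected_components

        rows, cols = [], []
        for j, node in enumerate(free):
            unstable = np.nonzero(nxt[node] != bits[node])[0]
            rows.append(unstable)
            cols.append(unstable ^ (1 << j))
        rows = np.concatenate(rows) if rows else np.array([], dtype=np.int64)
        cols = np.concatenate(cols) if cols else np.array([], dtype=np.int64)
        data = np.ones(len(rows), dtype=np.int8)
        graph = sparse.coo_matrix((data, (rows, cols)), shape=(size, size)).tocsr()
        n_comp, labels = connected_components(graph, directed=True, connection="strong")
        # terminal SCC: no edge leaves the component
        leaves = np.zeros(n_comp, dtype=bool)
        src_labels = labels[rows]
        dst_labels = labels[cols]
        leaves[src_labels[src_labels != dst_labels]] = True
        result = []
        for comp in range(n_comp):
            if leaves[comp]:
                continue
            members = np.nonzero(labels == comp)[0]
            states = [_index_to_state(i, free, clamped, logic) for i in members]
            result.append(Attractor(states=states, is_fixed_point=len(members) == 1))
        return result

    raise ValueError(f"unknown mode {mode!r}")


def _index_to_state(i: int, free: list[str], clamped: Mapping[str, int], logic: LogicModel) -> BooleanState:
    st = {node: (i >> j) & 1 for j, node in enumerate(free)}
    st.update({n: int(v) for n, v in clamped.items()})
    return BooleanState({n: st[n] for n in logic.network.nodes})


@dataclass
class SteadyStateResult:
    """Endpoint summary of a stochastic run.

    ``marginals`` are per-node ON frequencies over trajectory endpoints;
    ``state`` thresholds them at 0.5 (exact 0.5 retains the initial value
    and is listed in ``half_ties``).  ``endpoint_counts`` maps each
    distinct endpoint state to its trajectory count.
    """

    marginals: dict[str, float]
    state: BooleanState
    converged: bool
    trajectory_count: int
    endpoint_counts: dict[BooleanState, int] = field(default_factory=dict)
    half_ties: list[str] = field(default_factory=list)


def stable_hash(*parts: str) -> int:
    """Deterministic 32-bit hash of strings (independent of PYTHONHASHSEED)."""
    h = 0
    for p in parts:
        h = zlib.crc32(str(p).encode("utf8"), h)
    return h & 0x7FFFFFFF


def simulate_to_steady_state(
    logic: LogicModel,
    initial: BooleanState,
    clamped: Mapping[str, int] | None = None,
    n_traj: int = 1000,
    max_time: float = 100.0,
    seed: int = 0,
) -> SteadyStateResult:
    """Continuous-time asynchronous simulation with unit flip rates.

    Each trajectory is a Gillespie walk: among nodes whose rule output
    differs from their current value, one flips uniformly at random and
    time advances by an Exp(1/k) increment.  A state with no unstable
    node is absorbing; ``converged`` is True when every trajectory
    reached one within ``max_time``.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    clamped = dict(clamped or {})
    nodes = logic.network.nodes
    if set(initial) != set(nodes):
        raise ValueError("initial state does not cover the network's nodes")
    rng = np.random.default_rng(seed)
    start = {n: (int(clamped[n]) if n in clamped else initial[n]) for n in nodes}
    free = [n for n in nodes if n not in clamped]

    endpoint_counts: dict[BooleanState, int] = {}
    all_absorbed = True
    for _ in range(n_traj):
        state = dict(start)
        t = 0.0
        while True:
            unstable = [n for n in free if logic.evaluate_node(n, state) != state[n]]
            if not unstable:
                break
            t += rng.exponential(1.0 / len(unstable))
            if t > max_time:
                all_absorbed = False
                break
            pick = unstable[rng.integers(len(unstable))]
            state[pick] = 1 - state[pick]
        endpoint = BooleanState(state)
        endpoint_counts[endpoint] = endpoint_counts.get(endpoint, 0) + 1

    marginals = {n: 0.0 for n in nodes}
    for st, cnt in endpoint_counts.items():
        for n in nodes:
            marginals[n] += st[n] * cnt
    marginals = {n: v / n_traj for n, v in marginals.items()}
    half_ties = []
    bits = {}
    for n in nodes:
        if marginals[n] > 0.5:
            bits[n] = 1
        elif marginals[n] < 0.5:
            bits[n] = 0
        else:
            bits[n] = start[n]
            half_ties.append(n)
    return SteadyStateResult(
        marginals=marginals,
        state=BooleanState(bits),
        converged=all_absorbed,
        trajectory_count=n_traj,
        endpoint_counts=endpoint_counts,
        half_ties=half_ties,
    )


def similarity_score(a: BooleanState, b: BooleanState) -> float:
    """Percentage of nodes in the same ON/OFF state in ``a`` and ``b``."""
    if set(a) != set(b):
        raise ValueError("similarity_score requires identical node sets")
    n = len(a)
    matching = sum(1 for node in a if a[node] == b[node])
    return 100.0 * matching / n
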