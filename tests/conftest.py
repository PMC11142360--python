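"""Shared fixtures: toy Boolean models and a session-wide synthetic study."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import statefate as sf
from statefate.koscreen import SimConfig, run_knockout_screen
from statefate.predictor import training_set_from_screen


@pytest.fixture()
def identity_logic():
    """B := A over an activating edge; A is a clamped input."""
    net = sf.SignedNetwork(nodes=["A", "B"], edges=[("A", "B", 1)])
    logic, _ = sf.synthesize_rules(
        net,
        {
            "on": sf.BooleanState({"A": 1, "B": 1}),
            "off": sf.BooleanState({"A": 0, "B": 0}),
        },
    )
    return logic


@pytest.fixture()
def bistable_logic():
    """Mutual activation A := B, B := A: fixed points all-ON and all-OFF."""
    net = sf.SignedNetwork(nodes=["A", "B"], edges=[("A", "B", 1), ("B", "A", 1)])
    rules = {"A": sf.GateRule(), "B": sf.GateRule()}
    return sf.LogicModel(network=net, rules=rules)


@pytest.fixture()
def negative_feedback_logic():
    """A := NOT B, B := A: no fixed point, one 4-cycle."""
    net = sf.SignedNetwork(nodes=["A", "B"], edges=[("B", "A", -1), ("A", "B", 1)])
    rules = {"A": sf.GateRule(), "B": sf.GateRule()}
    return sf.LogicModel(network=net, rules=rules)


@pytest.fixture(scope="session")
def study():
    """One full synthetic study shared by the downstream-stage tests.

    20 nodes (2 clamped inputs), mean in-degree 2.5: the planted model,
    its synthesized logic, per-state steady states, the knockout screen
    and the derived training set.
    """
    truth = sf.generate_network_with_attractors(
        n_nodes=20, n_inputs=2, mean_in_degree=2.5, seed=11
    )
    targets = truth.network.target_states()
    logic, report = sf.synthesize_rules(truth.network, targets)
    steady = {}
    for name, tgt in targets.items():
        clamp = {n: tgt[n] for n in logic.inputs}
        res = sf.simulate_to_steady_state(
            logic, tgt, clamped=clamp, n_traj=50, max_time=50.0, seed=23
        )
        steady[name] = res.state
    screen = run_knockout_screen(logic, steady, SimConfig(n_traj=100, seed=23))
    train = training_set_from_screen(screen, steady)
    return {
        "truth": truth,
        "logic": logic,
        "report": report,
        "steady": steady,
        "screen": screen,
        "train": train,
    }


@pytest.fixture(scope="session")
def attractor_test_samples(study):
    """Noiseless test set: each steady state as one Boolean profile."""
    steady = study["steady"]
    nodes = study["truth"].network.nodes
    features = pd.DataFrame({n: {s: steady[s][n] for s in steady} for n in nodes})
    labels = pd.Series(features.index, index=features.index, name="state")
    return features, labels


def random_state(nodes, rng) -> sf.BooleanState:
    return sf.BooleanState({n: int(b) for n, b in zip(nodes, rng.integers(0, 2, len(nodes)))})
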