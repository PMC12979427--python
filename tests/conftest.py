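"""Shared fixtures: hand-built toy graphs and fast synthetic worlds."""

import numpy as np
import pytest

from msat.graph import HeteroGraph
from msat.network import ModelConfig
from msat.synthetic import SynthConfig, generate
from msat.training import TrainConfig


@pytest.fixture
def tiny_graph():
    """Hand-built graph with exactly known structure.

    cmm: C0, C1; compound: M0, M1; target: T0, T1, T2; adr: A0, A1.
    Meta-paths (cmm->compound->target->adr):
      C0 -> M0 -> T0 -> A0  and  C0 -> M0 -> T1 -> A0  => mp(C0, A0) = 2
      C1 -> M1 -> T2 -> A1                             => mp(C1, A1) = 1
    """
    import pandas as pd

    node_ids = {
        "cmm": ["C0", "C1"],
        "compound": ["M0", "M1"],
        "target": ["T0", "T1", "T2"],
        "adr": ["A0", "A1"],
    }
    edges = {
        "cmm-compound": np.array([[0, 0], [1, 1]]),
        "compound-target": np.array([[0, 0], [0, 1], [1, 2]]),
        "cmm-target": np.array([[0, 2]]),
        "target-target": np.array([[0, 1]]),
        "target-adr": np.array([[0, 0], [1, 0], [2, 1]]),
        "cmm-adr": np.array([[0, 0], [1, 1]]),
    }
    attrs = pd.DataFrame({"report_count": [5, 0],
                          "provenance": ["faers", "literature"]})
    rng = np.random.default_rng(0)
    feats = {t: rng.normal(size=(len(ids), 4))
             for t, ids in node_ids.items()}
    return HeteroGraph(node_ids=node_ids, edges=edges,
                       edge_attrs={"cmm-adr": attrs}, node_features=feats)


@pytest.fixture(scope="session")
def small_world():
    """A small but trainable synthetic world (shared, treat as read-only)."""
    return generate(SynthConfig(n_cmm=15, n_compound=30, n_target=50,
                                n_adr=20, seed=7))


@pytest.fixture
def small_model_config():
    return ModelConfig(heads=2, head_dim=4, layers=1, dropout=0.0,
                       gate_hidden=8, hci_hidden=16)


@pytest.fixture
def fast_train_config():
    return TrainConfig(learning_rate=3e-3, batch_size=128, max_epochs=8,
                       early_stop_patience=8, scheduler_patience=4, seed=0)
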