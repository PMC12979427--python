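"""Equation oracles for the encoder: ESA-Gate, biased attention, HSP."""

import numpy as np
import pytest

from msat import autodiff as ad
from msat.autodiff import Tensor
from msat.graph import HeteroGraph
from msat.network import (ModelConfig, biased_attention, build_graph_batch,
                          edge_biases, encode_graph, esa_gate_bias,
                          hsp_transform, init_params, project_inputs)


def _gate_params(layer=0, theta=0.0, mlp_out=2.0, ws_row=4.0 / 6.0, heads=1):
    """ESA-Gate params with constant-output branches.

    MLP branch: W1 = 0, b1 = 0 (ReLU(0) = 0), W2 anything, b2 = mlp_out, so
    MLP(e) = mlp_out for every e. Shortcut: Ws with all entries ws_row, so
    Ws e = ws_row * sum(e).
    """
    pre = f"L{layer}"
    return {
        f"{pre}.theta": Tensor(theta),
        f"{pre}.gate.W1": Tensor(np.zeros((6, 8))),
        f"{pre}.gate.b1": Tensor(np.zeros(8)),
        f"{pre}.gate.W2": Tensor(np.ones((8, heads))),
        f"{pre}.gate.b2": Tensor(np.full(heads, mlp_out)),
        f"{pre}.Ws": Tensor(np.full((6, heads), ws_row)),
    }


CFG1 = ModelConfig(heads=1, head_dim=2, layers=1, dropout=0.0, gate_hidden=8)


def test_esa_gate_scalar_hand_arithmetic():
    # e = ones(6): MLP(e) = 2, Ws e = 4; theta = 0 -> g = 0.5
    # beta = 0.5 * 2 + 0.5 * 4 = 3
    params = _gate_params(theta=0.0)
    e = Tensor(np.ones((1, 6)))
    beta = esa_gate_bias(e, params, 0, CFG1)
    np.testing.assert_allclose(beta.data, [[3.0]])


@pytest.mark.parametrize("theta,expected", [(30.0, 2.0), (-30.0, 4.0)])
def test_esa_gate_saturation_limits(theta, expected):
    # g = sigmoid(+-30) ~ 1 / 0: pure MLP branch (2) or pure shortcut (4)
    params = _gate_params(theta=theta)
    beta = esa_gate_bias(Tensor(np.ones((1, 6))), params, 0, CFG1)
    np.testing.assert_allclose(beta.data, [[expected]], atol=1e-10)


def test_esa_gate_rejects_wrong_evidence_dim():
    with pytest.raises(ValueError, match="length 6"):
        esa_gate_bias(Tensor(np.ones((1, 5))), _gate_params(), 0, CFG1)


def _attention_graph():
    """C0 -> A0 (supervised) and T0 -> A0 (mechanistic) into one ADR node."""
    return HeteroGraph(
        node_ids={"cmm": ["C0"], "compound": [], "target": ["T0"],
                  "adr": ["A0"]},
        edges={"cmm-adr": np.array([[0, 0]]),
               "target-adr": np.array([[0, 0]])})


def test_biased_attention_closed_form_weights():
    # Wq = 0 kills the content term; the cmm-adr edge carries an ESA bias of
    # ln 3 (theta = 30 saturates the gate onto the constant MLP branch) and
    # the target-adr edge a zero learned bias, so the softmax over A0's two
    # incoming edges is (3/4, 1/4) and the message is 0.75 v_C0 + 0.25 v_T0.
    g = _attention_graph()
    batch = build_graph_batch(g)
    params = _gate_params(theta=30.0, mlp_out=np.log(3.0))
    params.update({
        "L0.Wq": Tensor(np.zeros((2, 2))),
        "L0.Wk": Tensor(np.eye(2)),
        "L0.Wv": Tensor(np.eye(2)),
        "L0.bias.target-adr.fwd": Tensor(np.zeros(1)),
        "L0.bias.target-adr.rev": Tensor(np.zeros(1)),
    })
    h = Tensor(np.array([[1.0, 0.0],    # C0 (global row 0)
                         [0.0, 1.0],    # T0 (global row 1)
                         [5.0, 5.0]]))  # A0 (global row 2)
    ev = Tensor(np.ones((1, 6)))
    bias = edge_biases(batch, ev, params, 0, CFG1)
    out = biased_attention(h, bias, batch, params, 0, CFG1)
    np.testing.assert_allclose(out.data[2], [0.75, 0.25], atol=1e-10)


def test_attention_weights_sum_to_one_per_destination(small_world,
                                                      small_model_config):
    from msat.evidence import (build_evidence_vectors, evidence_matrix,
                               fit_evidence_scaler)
    g = small_world.graph
    cfg = small_model_config
    rng = np.random.default_rng(0)
    feature_dims = {t: g.node_features[t].shape[1] for t in g.node_features}
    params = init_params(cfg, feature_dims, rng)
    batch = build_graph_batch(g)
    ev = evidence_matrix(build_evidence_vectors(g, fit_evidence_scaler(g)))
    h = project_inputs(g.node_features, cfg, params)
    bias = edge_biases(batch, Tensor(ev), params, 0, cfg)
    # reproduce the attention weights explicitly
    import math
    q = (h.data @ params["L0.Wq"].data)[batch.dst].reshape(
        -1, cfg.heads, cfg.head_dim)
    k = (h.data @ params["L0.Wk"].data)[batch.src].reshape(
        -1, cfg.heads, cfg.head_dim)
    logits = (q * k).sum(axis=2) / math.sqrt(cfg.head_dim) + bias.data
    alpha = ad.segment_softmax(Tensor(logits), batch.dst, batch.n_nodes).data
    for node in np.unique(batch.dst):
        np.testing.assert_allclose(alpha[batch.dst == node].sum(axis=0),
                                   np.ones(cfg.heads), atol=1e-12)


def test_hsp_traverses_expand_compress_widths():
    cfg = ModelConfig()  # full-scale defaults: d_h = 8 * 72 = 576
    rng = np.random.default_rng(0)
    params = init_params(cfg, {t: 4 for t in
                               ("cmm", "compound", "target", "adr")}, rng)
    assert cfg.hidden_dim == 576
    assert params["L0.hsp.W1"].shape == (576, 1152)
    assert params["L0.hsp.W2"].shape == (1152, 1728)
    assert params["L0.hsp.W3"].shape == (1728, 576)


def test_hsp_matches_direct_three_matrix_evaluation():
    cfg = CFG1  # d_h = 2
    rng = np.random.default_rng(4)
    w1, b1 = rng.normal(size=(2, 4)), rng.normal(size=4)
    w2, b2 = rng.normal(size=(4, 6)), rng.normal(size=6)
    w3, b3 = rng.normal(size=(6, 2)), rng.normal(size=2)
    params = {"L0.hsp.W1": Tensor(w1), "L0.hsp.b1": Tensor(b1),
              "L0.hsp.W2": Tensor(w2), "L0.hsp.b2": Tensor(b2),
              "L0.hsp.W3": Tensor(w3), "L0.hsp.b3": Tensor(b3)}
    x = rng.normal(size=(5, 2))
    out = hsp_transform(Tensor(x), params, 0, cfg)
    direct = np.maximum(np.maximum(x @ w1 + b1, 0) @ w2 + b2, 0) @ w3 + b3
    np.testing.assert_allclose(out.data, direct)


def test_hsp_rejects_wrong_width():
    with pytest.raises(ValueError, match="width"):
        hsp_transform(Tensor(np.zeros((3, 5))), {}, 0, CFG1)


def test_encode_graph_is_deterministic_in_eval_mode(small_world,
                                                    small_model_config):
    from msat.evidence import (build_evidence_vectors, evidence_matrix,
                               fit_evidence_scaler)
    g = small_world.graph
    cfg = small_model_config
    rng = np.random.default_rng(0)
    feature_dims = {t: g.node_features[t].shape[1] for t in g.node_features}
    params = init_params(cfg, feature_dims, rng)
    batch = build_graph_batch(g)
    ev = evidence_matrix(build_evidence_vectors(g, fit_evidence_scaler(g)))
    h1 = encode_graph(batch, g.node_features, ev, params, cfg, training=False)
    h2 = encode_graph(batch, g.node_features, ev, params, cfg, training=False)
    np.testing.assert_array_equal(h1.data, h2.data)
    assert h1.shape == (g.n_nodes(), cfg.hidden_dim)


def test_cmm_adr_mask_hides_edges_but_keeps_evidence_rows(small_world):
    g = small_world.graph
    n_ca = g.n_edges("cmm-adr")
    mask = np.ones(n_ca, dtype=bool)
    mask[:3] = False
    full = build_graph_batch(g)
    masked = build_graph_batch(g, cmm_adr_mask=mask)
    assert masked.src.size == full.src.size - 2 * 3  # fwd + rev
    # surviving evidence rows still index the *full* evidence table
    ca_segments = [i for i, (suffix, s, e) in enumerate(masked.segments)
                   if suffix is None]
    for seg in ca_segments:
        np.testing.assert_array_equal(masked.evidence_rows[seg],
                                      np.arange(3, n_ca))
    with pytest.raises(ValueError, match="mask length"):
        build_graph_batch(g, cmm_adr_mask=mask[:-1])


def test_model_config_json_round_trip_and_validation():
    cfg = ModelConfig(heads=4, head_dim=16, layers=2)
    assert ModelConfig.from_json(cfg.to_json()) == cfg
    with pytest.raises(ValueError):
        ModelConfig(layers=0)
    with pytest.raises(ValueError):
        ModelConfig(dropout=1.0)


def test_cmm_adr_edges_without_evidence_is_error(tiny_graph,
                                                 small_model_config):
    batch = build_graph_batch(tiny_graph)
    rng = np.random.default_rng(0)
    params = init_params(small_model_config,
                         {t: 4 for t in tiny_graph.node_ids}, rng)
    with pytest.raises(ValueError, match="evidence"):
        edge_biases(batch, None, params, 0, small_model_config)
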