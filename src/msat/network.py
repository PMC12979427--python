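"""Multi-Scale Attention encoder for evidence-rich heterogeneous graphs.

Each layer combines three pieces:

* an evidence-semantic adaptive gate (ESA-Gate) that turns the 6-dimensional
  evidence vector of a supervised CMM-ADR edge into one additive attention
  bias per head, as a learnable convex combination of an MLP branch and a
  linear shortcut: ``beta = g * MLP(e) + (1 - g) * Ws e`` with
  ``g = sigmoid(theta)``;
* biased multi-head attention over the union of all incoming edges at each
  destination node, ``alpha = softmax(Q_i K_j^T / sqrt(d_k) + beta_ij)``,
  where mechanistic relations (which carry no evidence vector) contribute a
  learnable per-relation, per-head bias instead;
* a hierarchical signal propagation (HSP) transform, an expand-and-compress
  feed-forward block traversing widths d_h -> 2 d_h -> 3 d_h -> d_h, followed
  by a residual connection and layer normalisation.

Message passing runs over canonical plus materialised reverse relations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .graph import CMM_ADR, NODE_TYPES, RELATIONS, HeteroGraph


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the full-scale configuration (8 heads of width 72, three
    layers, dropout 0.18); desk-scale runs pass a smaller config explicitly.
    """

    heads: int = 8
    head_dim: int = 72
    layers: int = 3
    dropout: float = 0.18
    evidence_dim: int = 6
    gate_hidden: int = 32
    hci_hidden: int = 256

    def __post_init__(self):
        if self.layers < 1:
            raise ValueError("layers must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def hidden_dim(self) -> int:
        return self.heads * self.head_dim

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        return cls(**json.loads(text))


#: directed relations used in message passing: canonical + reverse
def directed_relations() -> list[tuple[str, str]]:
    out = []
    for rel in RELATIONS:
        out.append((rel, "fwd"))
        out.append((rel, "rev"))
    return out


def init_params(config: ModelConfig, feature_dims: dict[str, int],
                rng: np.random.Generator) -> dict[str, Tensor]:
    """Fresh parameters: Xavier-uniform matrices, zero biases, theta = 0."""
    dh = config.hidden_dim
    H = config.heads
    gh = config.gate_hidden
    p: dict[str, Tensor] = {}

    def mat(name, shape):
        p[name] = ad.parameter(ad.xavier_uniform(rng, shape))

    def vec(name, n):
        p[name] = ad.parameter(np.zeros(n))

    for t in NODE_TYPES:
        if t not in feature_dims:
            raise ValueError(f"missing feature dimension for node type {t!r}")
        mat(f"in.{t}.W", (feature_dims[t], dh))
        vec(f"in.{t}.b", dh)

    for l in range(config.layers):
        pre = f"L{l}"
        p[f"{pre}.theta"] = ad.parameter(0.0)  # gate g = sigmoid(0) = 0.5
        mat(f"{pre}.gate.W1", (config.evidence_dim, gh))
        vec(f"{pre}.gate.b1", gh)
        mat(f"{pre}.gate.W2", (gh, H))
        vec(f"{pre}.gate.b2", H)
        mat(f"{pre}.Ws", (config.evidence_dim, H))
        mat(f"{pre}.Wq", (dh, dh))
        mat(f"{pre}.Wk", (dh, dh))
        mat(f"{pre}.Wv", (dh, dh))
        for rel, direction in directed_relations():
            if rel != CMM_ADR:
                vec(f"{pre}.bias.{rel}.{direction}", H)
        mat(f"{pre}.hsp.W1", (dh, 2 * dh))
        vec(f"{pre}.hsp.b1", 2 * dh)
        mat(f"{pre}.hsp.W2", (2 * dh, 3 * dh))
        vec(f"{pre}.hsp.b2", 3 * dh)
        mat(f"{pre}.hsp.W3", (3 * dh, dh))
        vec(f"{pre}.hsp.b3", dh)
        p[f"{pre}.ln.g"] = ad.parameter(np.ones(dh))
        vec(f"{pre}.ln.b", dh)
    return p


# -- static per-fold message-passing structure -------------------------------

@dataclass
class GraphBatch:
    """Edge arrays with global node indices, grouped by directed relation.

    ``segments`` lists (param_suffix_or_None, start, end); a None suffix marks
    a CMM-ADR segment whose bias comes from ESA-Gate via ``evidence_rows``.
    """

    n_nodes: int
    offsets: dict[str, int]
    src: np.ndarray
    dst: np.ndarray
    segments: list[tuple[str | None, int, int]]
    evidence_rows: dict[int, np.ndarray] = field(default_factory=dict)

    def type_slice(self, ntype: str, n_of_type: int) -> slice:
        off = self.offsets[ntype]
        return slice(off, off + n_of_type)


def build_graph_batch(graph: HeteroGraph,
                      cmm_adr_mask: np.ndarray | None = None) -> GraphBatch:
    """Flatten the graph into global-index edge arrays (canonical + reverse).

    CMM-ADR evidence rows are assumed aligned with the stored edge order, as
    produced by :func:`msat.evidence.build_evidence_vectors`. An optional
    boolean ``cmm_adr_mask`` hides a subset of supervised edges from message
    passing (used to exclude a mini-batch's own target edges at train time)
    while keeping evidence-row indices aligned with the full evidence table.
    """
    offsets: dict[str, int] = {}
    off = 0
    for t in NODE_TYPES:
        offsets[t] = off
        off += graph.n_nodes(t)
    n_total = off

    srcs: list[np.ndarray] = []
    dsts: list[np.ndarray] = []
    segments: list[tuple[str | None, int, int]] = []
    evidence_rows: dict[int, np.ndarray] = {}
    pos = 0
    for seg_idx, (rel, direction) in enumerate(directed_relations()):
        st, dt = RELATIONS[rel]
        e = graph.edges[rel]
        if rel == CMM_ADR and cmm_adr_mask is not None:
            if cmm_adr_mask.shape[0] != e.shape[0]:
                raise ValueError("cmm_adr_mask length must equal the number "
                                 "of cmm-adr edges")
            kept = np.nonzero(cmm_adr_mask)[0]
            e = e[kept]
        if direction == "fwd":
            s = e[:, 0] + offsets[st]
            d = e[:, 1] + offsets[dt]
        else:
            s = e[:, 1] + offsets[dt]
            d = e[:, 0] + offsets[st]
        srcs.append(s)
        dsts.append(d)
        n = e.shape[0]
        if rel == CMM_ADR:
            segments.append((None, pos, pos + n))
            if cmm_adr_mask is not None:
                evidence_rows[len(segments) - 1] = kept
            else:
                evidence_rows[len(segments) - 1] = np.arange(n)
        else:
            segments.append((f"bias.{rel}.{direction}", pos, pos + n))
        pos += n
    src = (np.concatenate(srcs) if srcs else np.zeros(0, dtype=np.int64))
    dst = (np.concatenate(dsts) if dsts else np.zeros(0, dtype=np.int64))
    return GraphBatch(n_nodes=n_total, offsets=offsets,
                      src=src.astype(np.int64), dst=dst.astype(np.int64),
                      segments=segments, evidence_rows=evidence_rows)


# -- operations ---------------------------------------------------------------

def project_inputs(node_features: dict[str, np.ndarray],
                   config: ModelConfig, params: dict[str, Tensor]) -> Tensor:
    """Type-specific linear projection of raw features to width d_h,
    stacked over node types in canonical order."""
    parts = []
    for t in NODE_TYPES:
        feats = node_features.get(t)
        if feats is None:
            raise ValueError(f"missing features for node type {t!r}")
        if feats.shape[0] == 0:
            continue
        x = Tensor(feats)
        parts.append(ad.add(ad.matmul(x, params[f"in.{t}.W"]),
                            params[f"in.{t}.b"]))
    if not parts:
        raise ValueError("graph has no nodes")
    return ad.concat(parts, axis=0) if len(parts) > 1 else parts[0]


def esa_gate_bias(evidence: Tensor, params: dict[str, Tensor],
                  layer: int, config: ModelConfig) -> Tensor:
    """Per-edge, per-head attention bias from the 6-dim evidence vector."""
    if evidence.shape[-1] != config.evidence_dim:
        raise ValueError(
            f"evidence vectors must have length {config.evidence_dim}, "
            f"got {evidence.shape[-1]}")
    pre = f"L{layer}"
    g = ad.sigmoid(params[f"{pre}.theta"])  # scalar gate shared across heads
    hidden = ad.relu(ad.add(ad.matmul(evidence, params[f"{pre}.gate.W1"]),
                            params[f"{pre}.gate.b1"]))
    mlp = ad.add(ad.matmul(hidden, params[f"{pre}.gate.W2"]),
                 params[f"{pre}.gate.b2"])
    shortcut = ad.matmul(evidence, params[f"{pre}.Ws"])
    one_minus_g = ad.sub(Tensor(1.0), g)
    return ad.add(ad.mul(g, mlp), ad.mul(one_minus_g, shortcut))


def edge_biases(batch: GraphBatch, evidence: Tensor | None,
                params: dict[str, Tensor], layer: int,
                config: ModelConfig) -> Tensor:
    """Assemble the (E, H) bias matrix over all directed edges."""
    pre = f"L{layer}"
    esa = None
    parts = []
    for seg_idx, (suffix, start, end) in enumerate(batch.segments):
        n = end - start
        if n == 0:
            continue
        if suffix is None:
            if evidence is None:
                raise ValueError("CMM-ADR edges present but no evidence table")
            if esa is None:
                esa = esa_gate_bias(evidence, params, layer, config)
            parts.append(ad.rows(esa, batch.evidence_rows[seg_idx]))
        else:
            zeros = Tensor(np.zeros((n, config.heads)))
            parts.append(ad.add(zeros, params[f"{pre}.{suffix}"]))
    if not parts:
        return Tensor(np.zeros((0, config.heads)))
    return ad.concat(parts, axis=0) if len(parts) > 1 else parts[0]


def biased_attention(h: Tensor, bias: Tensor, batch: GraphBatch,
                     params: dict[str, Tensor], layer: int,
                     config: ModelConfig,
                     rng: np.random.Generator | None = None,
                     training: bool = False) -> Tensor:
    """Multi-head attention over incoming edges with additive logit biases.

    Per head and destination node the attention weights over the union of
    incoming edges sum to 1; a node with no incoming edges receives the zero
    message.
    """
    pre = f"L{layer}"
    H, d = config.heads, config.head_dim
    n = batch.n_nodes
    q = ad.matmul(h, params[f"{pre}.Wq"])
    k = ad.matmul(h, params[f"{pre}.Wk"])
    v = ad.matmul(h, params[f"{pre}.Wv"])
    if batch.src.size == 0:
        return Tensor(np.zeros((n, H * d)))
    qd = ad.reshape(ad.rows(q, batch.dst), (-1, H, d))
    ks = ad.reshape(ad.rows(k, batch.src), (-1, H, d))
    vs = ad.reshape(ad.rows(v, batch.src), (-1, H, d))
    logits = ad.mul(ad.sum_(ad.mul(qd, ks), axis=2), Tensor(1.0 / math.sqrt(d)))
    logits = ad.add(logits, bias)  # (E, H)
    alpha = ad.segment_softmax(logits, batch.dst, n)
    alpha = ad.dropout(alpha, config.dropout, rng, training)
    weighted = ad.mul(ad.reshape(alpha, (-1, H, 1)), vs)
    msg = ad.segment_sum(weighted, batch.dst, n)
    return ad.reshape(msg, (n, H * d))


def hsp_transform(m: Tensor, params: dict[str, Tensor], layer: int,
                  config: ModelConfig) -> Tensor:
    """Expand-and-compress transform d_h -> 2 d_h -> 3 d_h -> d_h (ReLU)."""
    dh = config.hidden_dim
    if m.shape[-1] != dh:
        raise ValueError(f"expected width {dh}, got {m.shape[-1]}")
    pre = f"L{layer}.hsp"
    x = ad.relu(ad.add(ad.matmul(m, params[f"{pre}.W1"]), params[f"{pre}.b1"]))
    x = ad.relu(ad.add(ad.matmul(x, params[f"{pre}.W2"]), params[f"{pre}.b2"]))
    return ad.add(ad.matmul(x, params[f"{pre}.W3"]), params[f"{pre}.b3"])


def msat_layer(h: Tensor, batch: GraphBatch, evidence: Tensor | None,
               params: dict[str, Tensor], layer: int, config: ModelConfig,
               rng: np.random.Generator | None = None,
               training: bool = False) -> Tensor:
    """One encoder layer: h <- LayerNorm(HSP(Attention(h)) + h)."""
    bias = edge_biases(batch, evidence, params, layer, config)
    attn = biased_attention(h, bias, batch, params, layer, config,
                            rng=rng, training=training)
    out = hsp_transform(attn, params, layer, config)
    out = ad.dropout(out, config.dropout, rng, training)
    pre = f"L{layer}"
    return ad.layer_norm(ad.add(out, h),
                         params[f"{pre}.ln.g"], params[f"{pre}.ln.b"])


def encode_graph(batch: GraphBatch, node_features: dict[str, np.ndarray],
                 evidence: np.ndarray | None, params: dict[str, Tensor],
                 config: ModelConfig, rng: np.random.Generator | None = None,
                 training: bool = False) -> Tensor:
    """Project inputs and apply the layer stack; returns (N_total, d_h)."""
    ev = Tensor(evidence) if evidence is not None and len(evidence) else None
    h = project_inputs(node_features, config, params)
    for l in range(config.layers):
        h = msat_layer(h, batch, ev, params, l, config, rng=rng,
                       training=training)
    return h


def embeddings_by_type(h: Tensor | np.ndarray, batch: GraphBatch,
                       graph: HeteroGraph) -> dict[str, np.ndarray]:
    data = h.data if isinstance(h, Tensor) else np.asarray(h)
    return {t: data[batch.type_slice(t, graph.n_nodes(t))]
            for t in NODE_TYPES}
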