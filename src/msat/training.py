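"""Per-fold optimisation loop for the encoder + scorer.

Binary cross-entropy on sampled (pair, label) mini-batches with full-graph
encoding per step, AdamW with decoupled weight decay, global gradient-norm
clipping, a reduce-on-plateau learning-rate schedule keyed to validation
AUROC, early stopping, and best-validation checkpointing. All randomness is
driven by a single integer seed, so runs are reproducible on one CPU thread.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score

from . import autodiff as ad
from .autodiff import Tensor
from .evidence import (EvidenceScaler, build_evidence_vectors,
                       evidence_matrix, fit_evidence_scaler)
from .graph import HeteroGraph
from .network import (GraphBatch, ModelConfig, build_graph_batch,
                      encode_graph, init_params)
from .scoring import DegreeStandardizer, hci_logit, init_scorer_params


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 4e-4
    weight_decay: float = 1e-5
    batch_size: int = 512
    max_epochs: int = 1000
    early_stop_patience: int = 100
    clip_norm: float = 1.0
    scheduler_factor: float = 0.6
    scheduler_patience: int = 15
    # hide each mini-batch's own supervised edges from message passing so the
    # scorer cannot shortcut to "the edge is present" (train positives are
    # edges of the training graph; evaluation pairs never are)
    exclude_target_edges: bool = True
    seed: int = 42

    def __post_init__(self):
        for name in ("learning_rate", "weight_decay", "batch_size",
                     "max_epochs", "early_stop_patience", "clip_norm",
                     "scheduler_factor", "scheduler_patience"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class Checkpoint:
    """Best-validation parameter snapshot plus everything needed to score."""

    params: dict[str, np.ndarray]
    model_config: ModelConfig
    scaler_json: str
    deg_stats: dict
    epoch: int
    val_auroc: float

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez(out / "params.npz", **self.params)
        meta = {"model_config": json.loads(self.model_config.to_json()),
                "scaler": json.loads(self.scaler_json),
                "deg_stats": self.deg_stats,
                "epoch": self.epoch, "val_auroc": self.val_auroc}
        (out / "checkpoint.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, in_dir) -> "Checkpoint":
        d = Path(in_dir)
        meta = json.loads((d / "checkpoint.json").read_text())
        with np.load(d / "params.npz") as npz:
            params = {k: npz[k].copy() for k in npz.files}
        return cls(params=params,
                   model_config=ModelConfig(**meta["model_config"]),
                   scaler_json=json.dumps(meta["scaler"]),
                   deg_stats=meta["deg_stats"], epoch=meta["epoch"],
                   val_auroc=meta["val_auroc"])


@dataclass
class PairArrays:
    """Global embedding rows and standardised degree features per pair."""

    cmm_rows: np.ndarray
    adr_rows: np.ndarray
    deg_c: np.ndarray  # (B, 1)
    deg_a: np.ndarray  # (B, 1)
    labels: np.ndarray


def _pair_arrays(graph: HeteroGraph, batch: GraphBatch,
                 pairs: list[tuple[str, str]], labels: np.ndarray,
                 deg_std: DegreeStandardizer) -> PairArrays:
    ci = np.array([graph.index("cmm", c) for c, _ in pairs], dtype=np.int64)
    ai = np.array([graph.index("adr", a) for _, a in pairs], dtype=np.int64)
    deg_c_all = graph.degree_vector("cmm", scope="all")
    deg_a_all = graph.degree_vector("adr", scope="all")
    return PairArrays(
        cmm_rows=ci + batch.offsets["cmm"],
        adr_rows=ai + batch.offsets["adr"],
        deg_c=deg_std.transform_cmm(deg_c_all[ci]).reshape(-1, 1),
        deg_a=deg_std.transform_adr(deg_a_all[ai]).reshape(-1, 1),
        labels=np.asarray(labels, dtype=np.float64),
    )


def _score_pairs(h: Tensor, pa: PairArrays, idx: np.ndarray,
                 params: dict[str, Tensor], config: ModelConfig,
                 rng=None, training=False) -> Tensor:
    z_c = ad.rows(h, pa.cmm_rows[idx])
    z_a = ad.rows(h, pa.adr_rows[idx])
    return hci_logit(z_c, z_a, Tensor(pa.deg_c[idx]), Tensor(pa.deg_a[idx]),
                     params, config, rng=rng, training=training)


def train_fold(graph: HeteroGraph,
               train_pos: list[tuple[str, str]],
               train_neg: list[tuple[str, str]],
               val_pos: list[tuple[str, str]],
               val_neg: list[tuple[str, str]],
               model_config: ModelConfig,
               train_config: TrainConfig,
               ) -> tuple[Checkpoint, list[dict]]:
    """Train on one fold's training graph (test edges already removed).

    Returns the best-validation checkpoint and a per-epoch log of train loss,
    validation AUROC, and learning rate.
    """
    if not train_pos or not val_pos or not train_neg or not val_neg:
        raise ValueError("empty train/validation split")

    rng = np.random.default_rng(train_config.seed)
    scaler = fit_evidence_scaler(graph)
    ev_table = build_evidence_vectors(graph, scaler)
    ev = evidence_matrix(ev_table)
    batch = build_graph_batch(graph)
    deg_std = DegreeStandardizer.fit(graph)
    features = {t: graph.node_features[t] for t in graph.node_features}

    feature_dims = {t: (f.shape[1] if f is not None else 0)
                    for t, f in features.items()}
    params = init_params(model_config, feature_dims, rng)
    params.update(init_scorer_params(model_config, rng))
    opt = ad.AdamW(params, lr=train_config.learning_rate,
                   weight_decay=train_config.weight_decay)

    train_pairs = list(train_pos) + list(train_neg)
    train_labels = np.r_[np.ones(len(train_pos)), np.zeros(len(train_neg))]
    val_pairs = list(val_pos) + list(val_neg)
    val_labels = np.r_[np.ones(len(val_pos)), np.zeros(len(val_neg))]
    tr = _pair_arrays(graph, batch, train_pairs, train_labels, deg_std)
    va = _pair_arrays(graph, batch, val_pairs, val_labels, deg_std)

    # map each training pair to its cmm-adr edge row (or -1 for negatives)
    ca = graph.edges["cmm-adr"]
    edge_row = {(int(s), int(d)): r for r, (s, d) in enumerate(ca)}
    tr_edge_rows = np.array(
        [edge_row.get((graph.index("cmm", c), graph.index("adr", a)), -1)
         for c, a in train_pairs], dtype=np.int64)

    best_auroc = -np.inf
    best_epoch = -1
    best_params: dict[str, np.ndarray] = {}
    bad_epochs = 0
    sched_bad = 0
    log: list[dict] = []
    n_train = len(train_pairs)

    for epoch in range(train_config.max_epochs):
        perm = rng.permutation(n_train)
        losses = []
        for start in range(0, n_train, train_config.batch_size):
            idx = perm[start:start + train_config.batch_size]
            if train_config.exclude_target_edges:
                mask = np.ones(ca.shape[0], dtype=bool)
                rows = tr_edge_rows[idx]
                mask[rows[rows >= 0]] = False
                step_batch = build_graph_batch(graph, cmm_adr_mask=mask)
            else:
                step_batch = batch
            h = encode_graph(step_batch, features, ev, params, model_config,
                             rng=rng, training=True)
            logits = _score_pairs(h, tr, idx, params, model_config,
                                  rng=rng, training=True)
            loss = ad.bce_with_logits(logits, tr.labels[idx].reshape(-1, 1))
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    "check learning rate / feature scaling")
            opt.zero_grad()
            loss.backward()
            ad.clip_grad_norm(params, train_config.clip_norm)
            opt.step()
            losses.append(float(loss.data))

        h = encode_graph(batch, features, ev, params, model_config,
                         training=False)
        val_logits = _score_pairs(h, va, np.arange(len(val_pairs)),
                                  params, model_config, training=False)
        val_scores = 1.0 / (1.0 + np.exp(-val_logits.data.ravel()))
        val_auroc = float(roc_auc_score(va.labels, val_scores))
        log.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                    "val_auroc": val_auroc, "lr": opt.lr})

        if val_auroc > best_auroc:
            best_auroc = val_auroc
            best_epoch = epoch
            best_params = {k: p.data.copy() for k, p in params.items()}
            bad_epochs = 0
            sched_bad = 0
        else:
            bad_epochs += 1
            sched_bad += 1
            if sched_bad >= train_config.scheduler_patience:
                opt.lr *= train_config.scheduler_factor
                sched_bad = 0
            if bad_epochs >= train_config.early_stop_patience:
                break

    ckpt = Checkpoint(params=best_params, model_config=model_config,
                      scaler_json=scaler.to_json(),
                      deg_stats=deg_std.to_dict(),
                      epoch=best_epoch, val_auroc=best_auroc)
    return ckpt, log


def predict_pairs(checkpoint: Checkpoint, graph: HeteroGraph,
                  pairs: list[tuple[str, str]]) -> np.ndarray:
    """Probabilities for (cmm_id, adr_id) pairs; deterministic in eval mode."""
    for c, a in pairs:
        graph.index("cmm", c)
        graph.index("adr", a)
    config = checkpoint.model_config
    params = {k: Tensor(v) for k, v in checkpoint.params.items()}
    scaler = EvidenceScaler.from_json(checkpoint.scaler_json)
    ev = evidence_matrix(build_evidence_vectors(graph, scaler))
    batch = build_graph_batch(graph)
    deg_std = DegreeStandardizer.from_dict(checkpoint.deg_stats)
    features = {t: graph.node_features[t] for t in graph.node_features}
    h = encode_graph(batch, features, ev, params, config, training=False)
    pa = _pair_arrays(graph, batch, pairs, np.zeros(len(pairs)), deg_std)
    logits = _score_pairs(h, pa, np.arange(len(pairs)), params, config,
                          training=False)
    return 1.0 / (1.0 + np.exp(-logits.data.ravel()))
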