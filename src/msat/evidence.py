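"""Six-dimensional evidence vectors for CMM-ADR edges.

Each supervised CMM-ADR edge carries, in order:

1. ``sem_sim``     cosine similarity of the CMM and ADR node feature vectors
2. ``log_reports`` log1p of the pair's report count, min-max scaled on the
                   training fold (0 for literature-only pairs before scaling)
3. ``provenance``  1 if report-derived, 0 if literature-only
4. ``cmm_deg``     log1p CMM degree (all incident relations), min-max scaled
5. ``adr_deg``     log1p ADR degree, min-max scaled
6. ``metapath``    log1p count of mechanistic CMM->compound->target->ADR
                   paths between the pair, min-max scaled

The scaler is fitted on the training fold's edges only and clamps held-out
values into [0, 1]. Degrees and meta-path counts are computed from the
training graph (test edges already removed), which keeps the vector free of
held-out topology.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .graph import CMM_ADR, HeteroGraph

EVIDENCE_DIM = 6
FEATURE_NAMES = ("sem_sim", "log_reports", "provenance",
                 "cmm_deg", "adr_deg", "metapath")
#: features that are min-max scaled on the training fold
SCALED_FEATURES = ("log_reports", "cmm_deg", "adr_deg", "metapath")


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """u.v / (|u||v|); 0 if either vector has zero norm."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def _biadjacency(graph: HeteroGraph, rel: str) -> sp.csr_matrix:
    from .graph import RELATIONS
    st, dt = RELATIONS[rel]
    e = graph.edges[rel]
    return sp.csr_matrix(
        (np.ones(e.shape[0]), (e[:, 0], e[:, 1])),
        shape=(graph.n_nodes(st), graph.n_nodes(dt)))


def metapath_matrix(graph: HeteroGraph) -> sp.csr_matrix:
    """Counts of CMM->compound->target->ADR paths for every (CMM, ADR) pair,
    as the chained biadjacency product A_cm @ A_mt @ A_ta."""
    a_cm = _biadjacency(graph, "cmm-compound")
    a_mt = _biadjacency(graph, "compound-target")
    a_ta = _biadjacency(graph, "target-adr")
    return (a_cm @ a_mt @ a_ta).tocsr()


def metapath_count(graph: HeteroGraph, cmm_id: str, adr_id: str) -> int:
    """Number of distinct mechanistic (compound, target) chains linking a pair."""
    i = graph.index("cmm", cmm_id)
    j = graph.index("adr", adr_id)
    return int(metapath_matrix(graph)[i, j])


class EvidenceScaler:
    """Per-feature min-max scaler fitted on training-fold edge features."""

    def __init__(self):
        self.mins: dict[str, float] | None = None
        self.maxs: dict[str, float] | None = None

    @property
    def fitted(self) -> bool:
        return self.mins is not None

    def fit(self, raw: pd.DataFrame) -> "EvidenceScaler":
        self.mins = {c: float(raw[c].min()) for c in SCALED_FEATURES}
        self.maxs = {c: float(raw[c].max()) for c in SCALED_FEATURES}
        return self

    def transform(self, raw: pd.DataFrame) -> pd.DataFrame:
        if not self.fitted:
            raise RuntimeError("EvidenceScaler.transform called before fit")
        out = raw.copy()
        for c in SCALED_FEATURES:
            lo, hi = self.mins[c], self.maxs[c]
            span = hi - lo
            if span <= 0:
                out[c] = 0.0
            else:
                out[c] = np.clip((raw[c] - lo) / span, 0.0, 1.0)
        return out

    def to_json(self) -> str:
        return json.dumps({"mins": self.mins, "maxs": self.maxs})

    @classmethod
    def from_json(cls, text: str) -> "EvidenceScaler":
        obj = json.loads(text)
        sc = cls()
        sc.mins = obj["mins"]
        sc.maxs = obj["maxs"]
        return sc


def raw_evidence_frame(graph: HeteroGraph,
                       pairs: list[tuple[str, str]] | None = None,
                       report_counts: dict[tuple[str, str], int] | None = None,
                       provenance: dict[tuple[str, str], str] | None = None,
                       ) -> pd.DataFrame:
    """Unscaled evidence features for CMM-ADR pairs.

    By default the pairs, counts and provenance come from the graph's stored
    CMM-ADR edges and their attribute rows (columns ``report_count`` and
    ``provenance``); explicit arguments override for held-out pairs.
    """
    if pairs is None:
        pairs = graph.cmm_adr_pairs()
        attrs = graph.edge_attrs.get(CMM_ADR)
        if attrs is not None and report_counts is None:
            report_counts = {p: int(c) for p, c in
                             zip(pairs, attrs["report_count"])}
        if attrs is not None and provenance is None:
            provenance = {p: str(v) for p, v in zip(pairs, attrs["provenance"])}
    report_counts = report_counts or {}
    provenance = provenance or {}

    mp = metapath_matrix(graph)
    deg_c = graph.degree_vector("cmm", scope="all")
    deg_a = graph.degree_vector("adr", scope="all")
    feats_c = graph.node_features.get("cmm")
    feats_a = graph.node_features.get("adr")

    rows = []
    for cmm_id, adr_id in pairs:
        i = graph.index("cmm", cmm_id)
        j = graph.index("adr", adr_id)
        if feats_c is not None and feats_a is not None \
                and feats_c.shape[1] == feats_a.shape[1]:
            sem = cosine_similarity(feats_c[i], feats_a[j])
        else:
            sem = 0.0
        prov = provenance.get((cmm_id, adr_id), "faers")
        count = report_counts.get((cmm_id, adr_id), 0)
        if prov != "faers":
            count = 0  # literature-only pairs carry no report-count evidence
        rows.append({
            "cmm_id": cmm_id, "adr_id": adr_id,
            "sem_sim": sem,
            "log_reports": float(np.log1p(count)),
            "provenance": 1.0 if prov == "faers" else 0.0,
            "cmm_deg": float(np.log1p(deg_c[i])),
            "adr_deg": float(np.log1p(deg_a[j])),
            "metapath": float(np.log1p(mp[i, j])),
        })
    cols = ["cmm_id", "adr_id", *FEATURE_NAMES]
    return pd.DataFrame(rows, columns=cols)


def build_evidence_vectors(graph: HeteroGraph,
                           scaler: EvidenceScaler) -> pd.DataFrame:
    """Scaled 6-vectors for every stored (training) CMM-ADR edge.

    The scaler must already be fitted (on the training fold's raw features);
    an unfitted scaler is an error, which guards against fitting on held-out
    edges by accident.
    """
    if not scaler.fitted:
        raise RuntimeError("scaler must be fitted on training edges first")
    raw = raw_evidence_frame(graph)
    return scaler.transform(raw)


def fit_evidence_scaler(graph: HeteroGraph) -> EvidenceScaler:
    """Fit a min-max scaler on the graph's stored (training) CMM-ADR edges."""
    return EvidenceScaler().fit(raw_evidence_frame(graph))


def evidence_matrix(table: pd.DataFrame) -> np.ndarray:
    """The (E, 6) numeric matrix in canonical feature order."""
    return table.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=np.float64)
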