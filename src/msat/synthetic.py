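"""Seeded generator of synthetic pharmacovigilance graphs with planted signal.

The generator emulates the statistical structure the model assumes, at desk
scale and with full determinism per seed:

* a four-type heterogeneous graph (CMM, compound, target, ADR) whose
  mechanistic relations are sampled independently at configurable densities;
* node features drawn as shared latent-cluster centroids plus Gaussian noise,
  so the CMM-ADR feature cosine is informative for true pairs;
* planted CMM-ADR positives whose log-odds increase with the mechanistic
  meta-path count and with the pair's feature cosine:
  ``P(pos) = logistic(a0 + b * metapath + c * cosine)`` where ``a0`` is the
  logit of the configured baseline positive rate;
* a provenance mix: each positive is literature-only with the configured
  probability, otherwise report-derived with an overdispersed
  (negative-binomial) report count whose mean grows with the meta-path count.

It does not emulate reporting-bias mechanisms of real spontaneous-report data
(stimulated reporting, channeling, co-medication confounding).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph import HeteroGraph, RELATIONS

_DENSITY_FIELDS = ("density_cmm_compound", "density_compound_target",
                   "density_cmm_target", "density_target_target",
                   "density_target_adr")


@dataclass(frozen=True)
class SynthConfig:
    n_cmm: int = 60
    n_compound: int = 150
    n_target: int = 300
    n_adr: int = 120
    density_cmm_compound: float = 0.03
    density_compound_target: float = 0.010
    density_cmm_target: float = 0.004
    density_target_target: float = 0.004
    density_target_adr: float = 0.012
    positive_rate: float = 0.01      # baseline P(positive) at zero signal
    signal_metapath: float = 2.0     # log-odds per mechanistic meta-path
    signal_cosine: float = 8.0       # log-odds per unit feature cosine
    report_mean: float = 6.0         # baseline negative-binomial mean
    report_dispersion: float = 1.5   # negative-binomial shape (smaller = wider)
    literature_fraction: float = 0.12
    feature_dim: int = 32
    n_latent_clusters: int = 6
    noise_sd: float = 0.05
    seed: int = 42

    def __post_init__(self):
        if min(self.n_cmm, self.n_compound, self.n_target, self.n_adr) <= 0:
            raise ValueError("node counts must be positive")
        for f in _DENSITY_FIELDS:
            d = getattr(self, f)
            if not 0.0 < d <= 1.0:
                raise ValueError(f"{f} must be in (0, 1]")
        if not 0.0 < self.positive_rate < 1.0:
            raise ValueError("positive_rate must be in (0, 1)")
        if not 0.0 <= self.literature_fraction <= 1.0:
            raise ValueError("literature_fraction must be in [0, 1]")


@dataclass
class SynthData:
    """Everything a test or experiment needs from one generated world."""

    graph: HeteroGraph
    pair_table: pd.DataFrame          # cmm_id, pt, report_count, provenance
    labels: np.ndarray                # (n_cmm, n_adr) 0/1 ground truth
    probs: np.ndarray                 # (n_cmm, n_adr) planted probabilities
    metapath_counts: np.ndarray       # (n_cmm, n_adr) mechanistic path counts
    config: SynthConfig = field(repr=False, default=None)

    @property
    def positives(self) -> list[tuple[str, str]]:
        cmm_ids = self.graph.node_ids["cmm"]
        adr_ids = self.graph.node_ids["adr"]
        ii, jj = np.nonzero(self.labels)
        return [(cmm_ids[i], adr_ids[j]) for i, j in zip(ii, jj)]


def _bernoulli_edges(rng, n_src, n_dst, density, no_self=False) -> np.ndarray:
    mask = rng.random((n_src, n_dst)) < density
    if no_self:
        np.fill_diagonal(mask, False)
    s, d = np.nonzero(mask)
    return np.stack([s, d], axis=1).astype(np.int64)


def generate(config: SynthConfig) -> SynthData:
    """Sample one synthetic world; bit-identical for a fixed config."""
    rng = np.random.default_rng(config.seed)
    n_c, n_m, n_t, n_a = (config.n_cmm, config.n_compound,
                          config.n_target, config.n_adr)
    node_ids = {
        "cmm": [f"CMM_{i:04d}" for i in range(n_c)],
        "compound": [f"CPD_{i:04d}" for i in range(n_m)],
        "target": [f"TGT_{i:04d}" for i in range(n_t)],
        "adr": [f"ADR_{i:04d}" for i in range(n_a)],
    }

    # shared latent clusters -> informative CMM/ADR feature cosine
    centroids = rng.normal(size=(config.n_latent_clusters, config.feature_dim))
    centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
    clusters = {t: rng.integers(config.n_latent_clusters, size=n)
                for t, n in (("cmm", n_c), ("compound", n_m),
                             ("target", n_t), ("adr", n_a))}
    node_features = {
        t: centroids[clusters[t]]
        + config.noise_sd * rng.normal(size=(len(clusters[t]),
                                             config.feature_dim))
        for t in clusters
    }

    edges = {
        "cmm-compound": _bernoulli_edges(rng, n_c, n_m,
                                         config.density_cmm_compound),
        "compound-target": _bernoulli_edges(rng, n_m, n_t,
                                            config.density_compound_target),
        "cmm-target": _bernoulli_edges(rng, n_c, n_t,
                                       config.density_cmm_target),
        "target-target": _bernoulli_edges(rng, n_t, n_t,
                                          config.density_target_target,
                                          no_self=True),
        "target-adr": _bernoulli_edges(rng, n_t, n_a,
                                       config.density_target_adr),
    }

    # mechanistic meta-path counts via dense biadjacency products
    def adj(rel, n_src, n_dst):
        a = np.zeros((n_src, n_dst))
        e = edges[rel]
        if e.size:
            a[e[:, 0], e[:, 1]] = 1.0
        return a

    mp = (adj("cmm-compound", n_c, n_m)
          @ adj("compound-target", n_m, n_t)
          @ adj("target-adr", n_t, n_a))

    feats_c = node_features["cmm"]
    feats_a = node_features["adr"]
    norms_c = np.linalg.norm(feats_c, axis=1, keepdims=True)
    norms_a = np.linalg.norm(feats_a, axis=1, keepdims=True)
    cos = (feats_c / norms_c) @ (feats_a / norms_a).T

    a0 = np.log(config.positive_rate / (1.0 - config.positive_rate))
    logits = a0 + config.signal_metapath * mp + config.signal_cosine * cos
    probs = 1.0 / (1.0 + np.exp(-logits))
    labels = (rng.random((n_c, n_a)) < probs).astype(np.int64)

    # provenance and overdispersed report counts for positives
    ii, jj = np.nonzero(labels)
    is_lit = rng.random(ii.size) < config.literature_fraction
    k = config.report_dispersion
    means = config.report_mean * (1.0 + mp[ii, jj])
    counts = 1 + rng.negative_binomial(k, k / (k + means))
    counts[is_lit] = 0

    pair_rows = []
    for e, (i, j) in enumerate(zip(ii, jj)):
        pair_rows.append({
            "cmm_id": node_ids["cmm"][i],
            "pt": node_ids["adr"][j],
            "report_count": int(counts[e]),
            "provenance": "literature" if is_lit[e] else "faers",
        })
    pair_table = pd.DataFrame(
        pair_rows, columns=["cmm_id", "pt", "report_count", "provenance"])

    edges["cmm-adr"] = np.stack([ii, jj], axis=1).astype(np.int64)
    edge_attrs = {rel: None for rel in RELATIONS}
    edge_attrs["cmm-adr"] = pair_table[["report_count", "provenance"]].copy()

    graph = HeteroGraph(node_ids=node_ids, edges=edges,
                        edge_attrs=edge_attrs, node_features=node_features)
    return SynthData(graph=graph, pair_table=pair_table, labels=labels,
                     probs=probs, metapath_counts=mp, config=config)


def generate_report_records(pair_table: pd.DataFrame, seed: int,
                            version_duplicate_rate: float = 0.0,
                            contamination_pts: list[str] | None = None,
                            contamination_rate: float = 0.0,
                            multi_drug_rate: float = 0.0) -> pd.DataFrame:
    """Expand report-derived pairs into report-reaction records.

    Each report-derived pair yields ``report_count`` distinct cases; a
    configurable fraction of cases additionally appears at a superseded lower
    version, a configurable fraction of extra records carries a blacklisted
    (non-ADR) PT, and a fraction of reports lists more than one drug. With all
    dials at zero, curating the records reproduces the pair table exactly.
    """
    rng = np.random.default_rng(seed)
    rows = []
    case_no = 0
    for r in pair_table.itertuples(index=False):
        if r.provenance != "faers":
            continue
        for _ in range(int(r.report_count)):
            case_no += 1
            case_id = f"case{case_no:07d}"
            n_drugs = (int(rng.integers(2, 6))
                       if rng.random() < multi_drug_rate else 1)
            if rng.random() < version_duplicate_rate:
                rows.append((case_id, 1, r.cmm_id, r.pt, n_drugs))
                rows.append((case_id, 2, r.cmm_id, r.pt, n_drugs))
            else:
                rows.append((case_id, 1, r.cmm_id, r.pt, n_drugs))
    if contamination_pts and contamination_rate > 0:
        cmms = pair_table["cmm_id"].unique()
        n_extra = int(round(contamination_rate * len(rows)))
        for _ in range(n_extra):
            case_no += 1
            rows.append((f"case{case_no:07d}", 1,
                         str(rng.choice(cmms)),
                         str(rng.choice(contamination_pts)), 1))
    return pd.DataFrame(rows, columns=["case_id", "case_version", "cmm_id",
                                       "pt", "n_drugs_in_report"])
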