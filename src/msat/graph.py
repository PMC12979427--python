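"""Typed heterogeneous graph container with TSV IO and leakage-safe removal.

The pharmacological space is a graph over four node types (CMM, compound,
protein target, ADR) and six canonical relations. Edges are stored in their
canonical direction only; the encoder materialises reverse relations for
message passing, so removing a CMM-ADR pair from the canonical list removes
it from both message-passing directions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

NODE_TYPES = ("cmm", "compound", "target", "adr")

#: canonical relation name -> (source node type, destination node type)
RELATIONS: dict[str, tuple[str, str]] = {
    "cmm-compound": ("cmm", "compound"),
    "compound-target": ("compound", "target"),
    "cmm-target": ("cmm", "target"),
    "target-target": ("target", "target"),
    "target-adr": ("target", "adr"),
    "cmm-adr": ("cmm", "adr"),
}

CMM_ADR = "cmm-adr"

#: relations incident to a CMM node (the CMM-centered subgraph)
CMM_CENTERED_RELATIONS = ("cmm-compound", "cmm-target", "cmm-adr")

DEGREE_SCOPES = ("all", "cmm-adr", "cmm-centered")


class GraphError(ValueError):
    pass


@dataclass
class HeteroGraph:
    """Typed node registry plus typed, attribute-bearing edge lists.

    ``edges[rel]`` is an (E, 2) int array of (src_index, dst_index) into the
    per-type ``node_ids`` lists. ``edge_attrs[rel]``, when present, is a
    DataFrame row-aligned with ``edges[rel]``.
    """

    node_ids: dict[str, list[str]]
    edges: dict[str, np.ndarray]
    edge_attrs: dict[str, pd.DataFrame | None] = field(default_factory=dict)
    node_features: dict[str, np.ndarray | None] = field(default_factory=dict)

    def __post_init__(self):
        for t in NODE_TYPES:
            self.node_ids.setdefault(t, [])
        for rel in RELATIONS:
            if rel not in self.edges:
                self.edges[rel] = np.zeros((0, 2), dtype=np.int64)
            self.edges[rel] = np.asarray(self.edges[rel], dtype=np.int64).reshape(-1, 2)
            self.edge_attrs.setdefault(rel, None)
        self._index: dict[str, dict[str, int]] = {
            t: {nid: i for i, nid in enumerate(ids)}
            for t, ids in self.node_ids.items()
        }
        self.validate()

    # -- queries -----------------------------------------------------------
    def n_nodes(self, ntype: str | None = None) -> int:
        if ntype is None:
            return sum(len(v) for v in self.node_ids.values())
        return len(self.node_ids[ntype])

    def n_edges(self, rel: str | None = None) -> int:
        if rel is None:
            return sum(e.shape[0] for e in self.edges.values())
        return self.edges[rel].shape[0]

    def index(self, ntype: str, node_id: str) -> int:
        try:
            return self._index[ntype][node_id]
        except KeyError:
            raise GraphError(f"unknown {ntype} node {node_id!r}") from None

    def has_node(self, ntype: str, node_id: str) -> bool:
        return node_id in self._index[ntype]

    def validate(self) -> None:
        for rel, (st, dt) in RELATIONS.items():
            e = self.edges[rel]
            if e.shape[0] == 0:
                continue
            if e[:, 0].min() < 0 or e[:, 0].max() >= len(self.node_ids[st]):
                raise GraphError(f"relation {rel}: src index out of range")
            if e[:, 1].min() < 0 or e[:, 1].max() >= len(self.node_ids[dt]):
                raise GraphError(f"relation {rel}: dst index out of range")
            keys = {(int(s), int(d)) for s, d in e}
            if len(keys) != e.shape[0]:
                raise GraphError(f"relation {rel}: duplicate (src, dst) edges")
            attrs = self.edge_attrs.get(rel)
            if attrs is not None and len(attrs) != e.shape[0]:
                raise GraphError(
                    f"relation {rel}: {len(attrs)} attribute rows for "
                    f"{e.shape[0]} edges")
        for t, feats in self.node_features.items():
            if feats is not None and feats.shape[0] != len(self.node_ids[t]):
                raise GraphError(
                    f"node type {t}: {feats.shape[0]} feature rows for "
                    f"{len(self.node_ids[t])} nodes")

    def copy(self) -> "HeteroGraph":
        return HeteroGraph(
            node_ids={t: list(v) for t, v in self.node_ids.items()},
            edges={r: e.copy() for r, e in self.edges.items()},
            edge_attrs={r: (a.copy() if a is not None else None)
                        for r, a in self.edge_attrs.items()},
            node_features={t: (f.copy() if f is not None else None)
                           for t, f in self.node_features.items()},
        )

    # -- degrees ------------------------------------------------------------
    def degree(self, ntype: str, node_id: str, scope: str = "all") -> int:
        """Undirected incidence count of a node within the given scope."""
        if scope not in DEGREE_SCOPES:
            raise GraphError(f"unknown degree scope {scope!r}; "
                             f"expected one of {DEGREE_SCOPES}")
        i = self.index(ntype, node_id)
        if scope == "cmm-adr":
            rels = (CMM_ADR,)
        elif scope == "cmm-centered":
            rels = CMM_CENTERED_RELATIONS
        else:
            rels = tuple(RELATIONS)
        deg = 0
        for rel in rels:
            st, dt = RELATIONS[rel]
            e = self.edges[rel]
            if st == ntype:
                deg += int(np.count_nonzero(e[:, 0] == i))
            if dt == ntype:
                deg += int(np.count_nonzero(e[:, 1] == i))
        return deg

    def degree_vector(self, ntype: str, scope: str = "all") -> np.ndarray:
        """Degrees of every node of a type, in node_ids order."""
        if scope not in DEGREE_SCOPES:
            raise GraphError(f"unknown degree scope {scope!r}")
        n = len(self.node_ids[ntype])
        deg = np.zeros(n, dtype=np.int64)
        if scope == "cmm-adr":
            rels = (CMM_ADR,)
        elif scope == "cmm-centered":
            rels = CMM_CENTERED_RELATIONS
        else:
            rels = tuple(RELATIONS)
        for rel in rels:
            st, dt = RELATIONS[rel]
            e = self.edges[rel]
            if st == ntype:
                np.add.at(deg, e[:, 0], 1)
            if dt == ntype:
                np.add.at(deg, e[:, 1], 1)
        return deg

    # -- leakage-safe edge removal -------------------------------------------
    def remove_pair_edges(self, pairs: list[tuple[str, str]]) -> "HeteroGraph":
        """Return a copy with the given CMM-ADR pairs removed.

        Removal covers both message-passing directions (edges are stored
        canonically and reversed only at encode time) and drops the aligned
        attribute rows synchronously. Absent pairs are a no-op.
        """
        pair_idx = {(self.index("cmm", c), self.index("adr", a))
                    for c, a in pairs}
        g = self.copy()
        e = g.edges[CMM_ADR]
        keep = np.array([(int(s), int(d)) not in pair_idx for s, d in e],
                        dtype=bool)
        g.edges[CMM_ADR] = e[keep]
        attrs = g.edge_attrs.get(CMM_ADR)
        if attrs is not None:
            g.edge_attrs[CMM_ADR] = attrs.loc[keep].reset_index(drop=True)
        return g

    def pair_occurrences(self, pairs: list[tuple[str, str]]) -> int:
        """Count occurrences of the given CMM-ADR pairs across all relations,
        scanning every relation in both orientations (leakage audit)."""
        wanted = set(pairs)
        count = 0
        for rel, (st, dt) in RELATIONS.items():
            e = self.edges[rel]
            for s, d in e:
                sid = self.node_ids[st][int(s)]
                did = self.node_ids[dt][int(d)]
                if (st, dt) == ("cmm", "adr") and (sid, did) in wanted:
                    count += 1
                if (dt, st) == ("cmm", "adr") and (did, sid) in wanted:
                    count += 1
        return count

    def cmm_adr_pairs(self) -> list[tuple[str, str]]:
        """The stored CMM-ADR edges as (cmm_id, adr_id) string pairs."""
        return [(self.node_ids["cmm"][int(s)], self.node_ids["adr"][int(d)])
                for s, d in self.edges[CMM_ADR]]


# -- IO -------------------------------------------------------------------


def load_graph(node_file, edge_files: dict[str, object],
               feature_files: dict[str, object] | None = None) -> HeteroGraph:
    """Load a graph from TSV files.

    ``node_file``: columns node_id, node_type. ``edge_files``: relation name
    -> TSV with columns src_id, dst_id plus optional attribute columns.
    ``feature_files``: node type -> TSV with node_id plus numeric columns,
    row-aligned to the node file after reindexing by node_id.
    """
    nodes = pd.read_csv(node_file, sep="\t", dtype=str)
    if not {"node_id", "node_type"} <= set(nodes.columns):
        raise GraphError("node file must have columns node_id, node_type")
    bad = set(nodes["node_type"]) - set(NODE_TYPES)
    if bad:
        raise GraphError(f"unknown node types in node file: {sorted(bad)}")
    node_ids = {t: nodes.loc[nodes["node_type"] == t, "node_id"].tolist()
                for t in NODE_TYPES}
    index = {t: {nid: i for i, nid in enumerate(ids)}
             for t, ids in node_ids.items()}

    edges: dict[str, np.ndarray] = {}
    edge_attrs: dict[str, pd.DataFrame | None] = {}
    for rel, path in edge_files.items():
        if rel not in RELATIONS:
            raise GraphError(f"unknown relation {rel!r}")
        st, dt = RELATIONS[rel]
        df = pd.read_csv(path, sep="\t", dtype={"src_id": str, "dst_id": str})
        if not {"src_id", "dst_id"} <= set(df.columns):
            raise GraphError(f"edge file for {rel} must have src_id, dst_id")
        rows = []
        for rownum, r in enumerate(df.itertuples(index=False)):
            if r.src_id not in index[st]:
                raise GraphError(
                    f"relation {rel}, row {rownum}: unknown {st} node "
                    f"{r.src_id!r}")
            if r.dst_id not in index[dt]:
                raise GraphError(
                    f"relation {rel}, row {rownum}: unknown {dt} node "
                    f"{r.dst_id!r}")
            rows.append((index[st][r.src_id], index[dt][r.dst_id]))
        arr = np.array(rows, dtype=np.int64).reshape(-1, 2)
        # collapse duplicated edge rows (keep first occurrence and its attrs)
        _, first = np.unique(arr, axis=0, return_index=True)
        if len(first) < arr.shape[0]:
            warnings.warn(
                f"relation {rel}: collapsed {arr.shape[0] - len(first)} "
                "duplicate edge row(s)", stacklevel=2)
        keep = np.sort(first)
        edges[rel] = arr[keep]
        extra_cols = [c for c in df.columns if c not in ("src_id", "dst_id")]
        edge_attrs[rel] = (df.iloc[keep][extra_cols].reset_index(drop=True)
                           if extra_cols else None)

    node_features: dict[str, np.ndarray | None] = {t: None for t in NODE_TYPES}
    for t, path in (feature_files or {}).items():
        df = pd.read_csv(path, sep="\t", dtype={"node_id": str})
        df = df.set_index("node_id")
        missing = [nid for nid in node_ids[t] if nid not in df.index]
        if missing or len(df) != len(node_ids[t]):
            raise GraphError(
                f"feature file for {t}: row mismatch with node file "
                f"({len(df)} rows for {len(node_ids[t])} nodes)")
        node_features[t] = df.loc[node_ids[t]].to_numpy(dtype=np.float64)

    return HeteroGraph(node_ids=node_ids, edges=edges,
                       edge_attrs=edge_attrs, node_features=node_features)


def save_graph(graph: HeteroGraph, out_dir) -> None:
    """Write the graph back to the TSV layout read by :func:`load_graph`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [(nid, t) for t in NODE_TYPES for nid in graph.node_ids[t]]
    pd.DataFrame(rows, columns=["node_id", "node_type"]).to_csv(
        out / "nodes.tsv", sep="\t", index=False)
    for rel, (st, dt) in RELATIONS.items():
        e = graph.edges[rel]
        df = pd.DataFrame({
            "src_id": [graph.node_ids[st][int(s)] for s in e[:, 0]],
            "dst_id": [graph.node_ids[dt][int(d)] for d in e[:, 1]],
        })
        attrs = graph.edge_attrs.get(rel)
        if attrs is not None:
            df = pd.concat([df, attrs.reset_index(drop=True)], axis=1)
        df.to_csv(out / f"edges_{rel}.tsv", sep="\t", index=False)
    for t in NODE_TYPES:
        feats = graph.node_features.get(t)
        if feats is not None:
            df = pd.DataFrame(feats,
                              columns=[f"f{j}" for j in range(feats.shape[1])])
            df.insert(0, "node_id", graph.node_ids[t])
            df.to_csv(out / f"features_{t}.tsv", sep="\t", index=False)


def load_graph_dir(in_dir) -> HeteroGraph:
    """Load a graph from a directory written by :func:`save_graph`."""
    d = Path(in_dir)
    edge_files = {rel: d / f"edges_{rel}.tsv" for rel in RELATIONS
                  if (d / f"edges_{rel}.tsv").exists()}
    feature_files = {t: d / f"features_{t}.tsv" for t in NODE_TYPES
                     if (d / f"features_{t}.tsv").exists()}
    return load_graph(d / "nodes.tsv", edge_files, feature_files)
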