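"""Tree-ensemble gene-regulatory-network inference and network comparison.

For every target gene, an ensemble of regression trees predicts the target's
(unit-variance standardised) expression from the candidate regulators; the
weight of edge regulator -> target is the regulator's total variance-reduction
importance summed over the ensemble and divided by the number of trees.  This
is the standard random-forest GRN recipe: ceil(sqrt(p)) candidate features
per split, fully grown trees, importance = impurity (variance) reduction.

Networks are weighted directed graphs with per-node modality labels and
per-edge membership across up to four simultaneous inferences, supporting
hop-limited neighbourhood extraction around focus genes and UpSet-style
subset counting between networks.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .matrixio import ExpressionMatrix, MatrixIOError

__all__ = [
    "Network",
    "NetworkComparison",
    "infer_grn",
    "extract_neighbourhood",
    "compare_networks",
    "MAX_NETWORKS",
    "MAX_HOPS",
]

#: at most four inferences may be compared simultaneously
MAX_NETWORKS = 4
#: neighbourhood extraction is limited to three indirect hops for robustness
MAX_HOPS = 3


@dataclass
class Network:
    """Weighted directed regulator -> target graph.

    Node attributes: ``modality`` (assay label), ``is_focus`` (flag),
    ``annotation_source`` (None for inferred nodes; the external source label
    for nodes attached by cis/custom integration).  Edge attributes:
    ``weight`` (>= 0; 0 for annotation edges), ``kind`` ("inferred" or
    "annotation"), ``relation`` (cis annotation: upstream/downstream/
    overlapping) and ``membership`` (tuple of network indices after
    comparison).  Self-loops are forbidden.
    """

    g: nx.DiGraph = field(default_factory=nx.DiGraph)

    def add_node(self, node_id: str, modality: str = "mRNA", is_focus: bool = False,
                 annotation_source: str | None = None) -> None:
        if node_id in self.g:
            # keep strongest claims on re-add
            attrs = self.g.nodes[node_id]
            attrs["is_focus"] = attrs.get("is_focus", False) or is_focus
            return
        self.g.add_node(node_id, modality=modality, is_focus=is_focus,
                        annotation_source=annotation_source)

    def add_edge(self, regulator: str, target: str, weight: float = 0.0,
                 kind: str = "inferred", relation: str | None = None) -> None:
        if regulator == target:
            raise MatrixIOError(f"self-loop edge on {regulator!r} is not allowed")
        if weight < 0:
            raise MatrixIOError("edge weights must be >= 0")
        self.g.add_edge(regulator, target, weight=float(weight), kind=kind, relation=relation)

    # -- views -------------------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return list(self.g.nodes)

    def edge_set(self, inferred_only: bool = True) -> set[tuple[str, str]]:
        return {
            (u, v)
            for u, v, d in self.g.edges(data=True)
            if not inferred_only or d.get("kind", "inferred") == "inferred"
        }

    def edge_weight(self, regulator: str, target: str) -> float:
        return float(self.g.edges[regulator, target]["weight"])

    def edges_table(self) -> pd.DataFrame:
        rows = [
            (u, v, d.get("weight", 0.0), d.get("kind", "inferred"), d.get("relation"))
            for u, v, d in self.g.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=["regulator", "target", "weight", "kind", "relation"])
        return df.sort_values(["regulator", "target"], kind="mergesort").reset_index(drop=True)

    def copy(self) -> "Network":
        return Network(self.g.copy())

    def write_graphml(self, path) -> None:
        g = self.g.copy()
        for _, d in g.nodes(data=True):
            for k, v in list(d.items()):
                if v is None:
                    d[k] = ""
        for _, _, d in g.edges(data=True):
            for k, v in list(d.items()):
                if v is None:
                    d[k] = ""
                elif isinstance(v, (tuple, list)):
                    d[k] = ",".join(map(str, v))
        nx.write_graphml(g, path)


@dataclass
class NetworkComparison:
    """UpSet-style exclusive subset counts over edge identity (reg, tgt)."""

    n_networks: int
    subset_counts: dict[tuple[int, ...], int]   # sorted index tuples -> count
    shared_edges: list[tuple[str, str]]         # edges in >= 2 networks
    membership: dict[tuple[str, str], tuple[int, ...]]

    @property
    def union_size(self) -> int:
        return sum(self.subset_counts.values())

    def counts_table(self) -> pd.DataFrame:
        rows = [
            ("+".join(str(i + 1) for i in subset), len(subset), count)
            for subset, count in sorted(self.subset_counts.items())
        ]
        return pd.DataFrame(rows, columns=["networks", "degree", "edge_count"])


def _target_seed(seed: int, target: str, regulators: list[str]) -> int:
    """Deterministic per-target seed, independent of regulator input order."""
    payload = f"{seed}|{target}|{'|'.join(sorted(regulators))}".encode()
    return zlib.crc32(payload) % (2**31 - 1)


def infer_grn(
    m: ExpressionMatrix,
    sample_subset: list[str] | None = None,
    targets: list[str] | None = None,
    regulators: list[str] | None = None,
    n_trees: int = 1000,
    seed: int = 0,
) -> Network:
    """Random-forest GRN inference over a sample subset.

    Per target, a forest of ``n_trees`` regression trees predicts the
    standardised target expression from all candidate regulators (excluding
    the target itself); the edge weight is the summed variance-reduction
    importance divided by ``n_trees``.  Targets and regulators must be
    non-constant over the subset.  Fully deterministic for a fixed ``seed``
    (the per-target seed hashes the sorted regulator ids, so regulator input
    order is irrelevant).
    """
    if n_trees < 1:
        raise MatrixIOError("n_trees must be positive")
    if sample_subset is None:
        sample_subset = m.sample_ids
    missing = [s for s in sample_subset if s not in m.data.columns]
    if missing:
        raise MatrixIOError(f"unknown sample(s): {missing}")
    if len(sample_subset) < 3:
        raise MatrixIOError("GRN inference needs at least 3 samples")

    sub = m.data[sample_subset]
    sd = sub.std(axis=1, ddof=0)
    nonconstant = set(sub.index[sd > 0])
    if targets is None:
        targets = sorted(nonconstant)
    if regulators is None:
        regulators = sorted(nonconstant)
    for name, ids in (("target", targets), ("regulator", regulators)):
        unknown = [f for f in ids if f not in sub.index]
        if unknown:
            raise MatrixIOError(f"unknown {name} feature(s): {unknown}")
        constant = sorted(set(ids) - nonconstant)
        if constant:
            raise MatrixIOError(f"constant {name} feature(s) over the subset: {constant}")

    net = Network()
    for fid in sorted(set(targets) | set(regulators)):
        net.add_node(fid, modality=m.feature_modality(fid))

    reg_sorted = sorted(set(regulators))
    for t in sorted(set(targets)):
        preds = [r for r in reg_sorted if r != t]
        if not preds:
            continue
        X = sub.loc[preds].to_numpy(dtype=float).T
        yv = sub.loc[t].to_numpy(dtype=float)
        yv = (yv - yv.mean()) / yv.std()
        p = len(preds)
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=min(p, int(np.ceil(np.sqrt(p)))),
            random_state=_target_seed(seed, t, preds),
            n_jobs=1,
        )
        forest.fit(X, yv)
        importances = np.zeros(p)
        for tree in forest.estimators_:
            importances += tree.tree_.compute_feature_importances(normalize=False)
        importances /= n_trees
        for r, w in zip(preds, importances):
            if w > 0:
                net.add_edge(r, t, weight=float(w))
    return net


def extract_neighbourhood(
    net: Network,
    focus: list[str],
    top_n: int = 7,
    max_hops: int = 2,
) -> Network:
    """Hop-limited neighbourhood of the focus genes.

    Starting from the focus set, each hop keeps the ``top_n`` highest-weight
    incident edges (in either direction) per frontier node, ties broken by
    (regulator, target) lexicographic order, and advances the frontier to the
    new endpoints; at most ``max_hops`` in [1, 3] hops.  The result is the
    subnetwork induced by the kept edges, with focus flags set.
    """
    if top_n < 1:
        raise MatrixIOError("top_n must be >= 1")
    if not (1 <= max_hops <= MAX_HOPS):
        raise MatrixIOError(f"max_hops must lie in [1, {MAX_HOPS}]")
    missing = [f for f in focus if f not in net.g]
    if missing:
        raise MatrixIOError(f"focus node(s) not in network: {missing}")

    kept_edges: set[tuple[str, str]] = set()
    visited: set[str] = set(focus)
    frontier: set[str] = set(focus)
    for _ in range(max_hops):
        next_frontier: set[str] = set()
        for node in sorted(frontier):
            incident = [
                (u, v, net.g.edges[u, v].get("weight", 0.0))
                for u, v in list(net.g.in_edges(node)) + list(net.g.out_edges(node))
            ]
            incident.sort(key=lambda e: (-e[2], e[0], e[1]))
            for u, v, _w in incident[:top_n]:
                kept_edges.add((u, v))
                for endpoint in (u, v):
                    if endpoint not in visited:
                        next_frontier.add(endpoint)
        visited |= next_frontier
        frontier = next_frontier
        if not frontier:
            break

    out = Network()
    for f in focus:
        d = net.g.nodes[f]
        out.add_node(f, modality=d.get("modality", "mRNA"), is_focus=True,
                     annotation_source=d.get("annotation_source"))
    for u, v in sorted(kept_edges):
        for n_id in (u, v):
            d = net.g.nodes[n_id]
            out.add_node(n_id, modality=d.get("modality", "mRNA"),
                         is_focus=n_id in focus,
                         annotation_source=d.get("annotation_source"))
        d = net.g.edges[u, v]
        out.add_edge(u, v, weight=d.get("weight", 0.0), kind=d.get("kind", "inferred"),
                     relation=d.get("relation"))
    return out


def compare_networks(nets: list[Network]) -> NetworkComparison:
    """Exclusive subset counts over edge identity across 2-4 networks.

    Edge identity is the (regulator, target) pair; weights are ignored and
    annotation edges are excluded.  Edges present in two or more networks are
    flagged as shared (for highlighting).
    """
    if not (2 <= len(nets) <= MAX_NETWORKS):
        raise MatrixIOError(f"can compare between 2 and {MAX_NETWORKS} networks, got {len(nets)}")
    membership: dict[tuple[str, str], tuple[int, ...]] = {}
    edge_sets = [n.edge_set(inferred_only=True) for n in nets]
    union = set().union(*edge_sets)
    subset_counts: dict[tuple[int, ...], int] = {}
    for e in union:
        subset = tuple(i for i, es in enumerate(edge_sets) if e in es)
        membership[e] = subset
        subset_counts[subset] = subset_counts.get(subset, 0) + 1
    shared = sorted(e for e, s in membership.items() if len(s) >= 2)
    return NetworkComparison(
        n_networks=len(nets),
        subset_counts=subset_counts,
        shared_edges=shared,
        membership=membership,
    )
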