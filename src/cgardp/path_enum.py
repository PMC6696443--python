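"""Drug-to-disease path enumeration over the heterogeneous network.

Edges are derived from the network matrices: an intra-layer edge joins two
drugs (or two diseases) whose similarity reaches ``sim_threshold``, and an
inter-layer edge joins each known drug-disease association.  Paths from a
drug to a disease are simple node sequences over these edges; each path is
weighted by the product of its edge weights (the similarity value for
intra-layer edges, 1 for association edges), so every weight lies in
(0, 1].  When more than ``cap`` paths exist the highest-weight ones are
kept, with ties broken by lexicographic node sequence for determinism.

The path being predicted must not serve as its own evidence: with
``exclude_direct`` the two-node path consisting of the direct ``i - j``
association edge is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .netio import HeteroNetwork

__all__ = [
    "DRUG",
    "DISEASE",
    "EdgeSets",
    "PathSet",
    "build_graph_edges",
    "enumerate_paths",
    "node_feature",
    "DEFAULT_SIM_THRESHOLD",
    "DEFAULT_MAX_LEN",
    "DEFAULT_CAP",
]

DRUG = "drug"
DISEASE = "disease"

DEFAULT_SIM_THRESHOLD = 0.5
DEFAULT_MAX_LEN = 3
DEFAULT_CAP = 8

Node = tuple[str, int]


@dataclass
class EdgeSets:
    """Weighted adjacency of the thresholded heterogeneous graph.

    ``adjacency`` maps each node to a list of ``(neighbor, edge_weight)``
    pairs, sorted by neighbor for deterministic traversal.
    """

    n_drugs: int
    n_diseases: int
    sim_threshold: float
    adjacency: dict[Node, list[tuple[Node, float]]] = field(default_factory=dict)

    def neighbors(self, node: Node) -> list[tuple[Node, float]]:
        return self.adjacency.get(node, [])

    def n_edges(self) -> dict[str, int]:
        counts = {"drug-drug": 0, "disease-disease": 0, "drug-disease": 0}
        for (layer, _), nbrs in self.adjacency.items():
            for (nlayer, _), _w in nbrs:
                key = (
                    "drug-disease"
                    if layer != nlayer
                    else ("drug-drug" if layer == DRUG else "disease-disease")
                )
                counts[key] += 1
        # every edge was seen from both endpoints
        return {k: v // 2 for k, v in counts.items()}


def build_graph_edges(
    net: HeteroNetwork, sim_threshold: float = DEFAULT_SIM_THRESHOLD
) -> EdgeSets:
    """Derive the weighted edge sets from R, D (thresholded) and A."""
    if not 0.0 <= sim_threshold <= 1.0:
        raise ValueError("sim_threshold must be in [0, 1]")
    adj: dict[Node, list[tuple[Node, float]]] = {}

    def add(u: Node, v: Node, w: float) -> None:
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))

    nr, nd = net.n_drugs, net.n_diseases
    for i in range(nr):
        for k in range(i + 1, nr):
            if net.R[i, k] >= sim_threshold:
                add((DRUG, i), (DRUG, k), float(net.R[i, k]))
    for j in range(nd):
        for l in range(j + 1, nd):
            if net.D[j, l] >= sim_threshold:
                add((DISEASE, j), (DISEASE, l), float(net.D[j, l]))
    for i, j in zip(*np.nonzero(net.A)):
        add((DRUG, int(i)), (DISEASE, int(j)), 1.0)
    for nbrs in adj.values():
        nbrs.sort(key=lambda t: t[0])
    return EdgeSets(nr, nd, sim_threshold, adj)


@dataclass
class PathSet:
    """Ordered drug-to-disease paths with per-node features and weights."""

    drug_index: int
    disease_index: int
    paths: list[list[Node]]
    node_features: list[np.ndarray]  # per path: (path_len, Nr+Nd)
    weights: list[float]

    def __len__(self) -> int:
        return len(self.paths)


def enumerate_paths(
    edges: EdgeSets,
    i: int,
    j: int,
    max_len: int = DEFAULT_MAX_LEN,
    cap: int | None = DEFAULT_CAP,
    exclude_direct: bool = True,
    net: HeteroNetwork | None = None,
) -> PathSet:
    """All simple paths from drug ``i`` to disease ``j``, capped and sorted.

    ``max_len`` bounds the node count (>= 3 intermediate evidence requires
    at least a 3-node path; 2-node direct paths are still enumerated when
    ``exclude_direct`` is off).  ``cap=None`` means unbounded.  Node
    features are attached when ``net`` is given.
    """
    if max_len < 3:
        raise ValueError("max_len must be >= 3 (node count including endpoints)")
    start: Node = (DRUG, i)
    target: Node = (DISEASE, j)
    found: list[tuple[float, list[Node]]] = []
    path: list[Node] = [start]
    on_path = {start}

    def dfs(node: Node, weight: float) -> None:
        for nbr, w in edges.neighbors(node):
            if nbr == target:
                if not (exclude_direct and len(path) == 1):
                    found.append((weight * w, path + [target]))
                continue
            if nbr in on_path or len(path) >= max_len - 1:
                continue
            path.append(nbr)
            on_path.add(nbr)
            dfs(nbr, weight * w)
            path.pop()
            on_path.remove(nbr)

    dfs(start, 1.0)
    found.sort(key=lambda t: (-t[0], t[1]))
    if cap is not None:
        found = found[:cap]
    paths = [p for _, p in found]
    weights = [w for w, _ in found]
    feats = (
        [np.stack([node_feature(net, n) for n in p]) for p in paths]
        if net is not None
        else []
    )
    return PathSet(i, j, paths, feats, weights)


def node_feature(net: HeteroNetwork, node: Node) -> np.ndarray:
    """The (Nr+Nd)-vector a path node feeds into the sequence encoder.

    Drug k -> ``[R[k, :] || A[k, :]]``; disease l -> ``[A[:, l]^T || D[l, :]]``
    (the same row conventions as the per-pair feature matrix X).
    """
    layer, idx = node
    if layer == DRUG:
        return np.concatenate([net.R[idx, :], net.A[idx, :]])
    if layer == DISEASE:
        return np.concatenate([net.A[:, idx], net.D[idx, :]])
    raise ValueError(f"unknown layer tag {layer!r}")
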