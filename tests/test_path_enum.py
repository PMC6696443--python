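"""Path enumeration against an exhaustive networkx oracle."""

import networkx as nx
import numpy as np
import pytest

from cgardp import SynthConfig, generate
from cgardp.netio import HeteroNetwork
from cgardp.path_enum import (
    DISEASE,
    DRUG,
    build_graph_edges,
    enumerate_paths,
    node_feature,
)


def nx_graph(net, threshold):
    """Independent reconstruction of the thresholded graph."""
    g = nx.Graph()
    nr, nd = net.n_drugs, net.n_diseases
    for i in range(nr):
        g.add_node((DRUG, i))
    for j in range(nd):
        g.add_node((DISEASE, j))
    for i in range(nr):
        for k in range(i + 1, nr):
            if net.R[i, k] >= threshold:
                g.add_edge((DRUG, i), (DRUG, k), weight=net.R[i, k])
    for j in range(nd):
        for l in range(j + 1, nd):
            if net.D[j, l] >= threshold:
                g.add_edge((DISEASE, j), (DISEASE, l), weight=net.D[j, l])
    for i, j in zip(*np.nonzero(net.A)):
        g.add_edge((DRUG, int(i)), (DISEASE, int(j)), weight=1.0)
    return g


def oracle_paths(net, threshold, i, j, max_len, exclude_direct):
    """Brute-force simple paths via networkx, with product weights."""
    g = nx_graph(net, threshold)
    out = []
    src, dst = (DRUG, i), (DISEASE, j)
    if src not in g or dst not in g:
        return out
    for p in nx.all_simple_paths(g, src, dst, cutoff=max_len - 1):
        if exclude_direct and len(p) == 2:
            continue
        w = 1.0
        for u, v in zip(p[:-1], p[1:]):
            w *= g[u][v]["weight"]
        out.append((w, p))
    return out


class TestBuildGraphEdges:
    def test_vacuous_threshold_gives_no_intralayer_edges(self, tiny_net):
        edges = build_graph_edges(tiny_net, 1.0)
        counts = edges.n_edges()
        assert counts["drug-drug"] == 0 and counts["disease-disease"] == 0

    def test_worked_example_drug_neighborhood(self, worked_example):
        edges = build_graph_edges(worked_example, 0.5)
        nbrs = [n for n, _ in edges.neighbors((DRUG, 0)) if n[0] == DRUG]
        assert sorted(i for _, i in nbrs) == [1, 2, 5]  # r2, r3, r6

    def test_complete_bipartite_association_edges(self):
        net = HeteroNetwork(["r1", "r2"], ["d1", "d2"], np.eye(2), np.eye(2), np.ones((2, 2)))
        assert build_graph_edges(net, 1.0).n_edges()["drug-disease"] == 4


class TestEnumeratePaths:
    def test_worked_example_has_exactly_four_paths(self, worked_example):
        edges = build_graph_edges(worked_example, 0.5)
        ps = enumerate_paths(edges, 0, 2, max_len=3, cap=None)
        expected = {
            ((DRUG, 0), (DRUG, 1), (DISEASE, 2)),       # r1 -> r2 -> d3
            ((DRUG, 0), (DRUG, 5), (DISEASE, 2)),       # r1 -> r6 -> d3
            ((DRUG, 0), (DISEASE, 0), (DISEASE, 2)),    # r1 -> d1 -> d3
            ((DRUG, 0), (DISEASE, 1), (DISEASE, 2)),    # r1 -> d2 -> d3
        }
        assert {tuple(p) for p in ps.paths} == expected

    def test_direct_only_pair_yields_empty_set(self):
        A = np.zeros((3, 2))
        A[0, 0] = 1.0
        net = HeteroNetwork(["r1", "r2", "r3"], ["d1", "d2"], np.eye(3), np.eye(2), A)
        ps = enumerate_paths(build_graph_edges(net, 0.5), 0, 0, exclude_direct=True)
        assert len(ps) == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("max_len", [3, 4])
    def test_matches_exhaustive_oracle(self, seed, max_len):
        net = generate(
            SynthConfig(n_drugs=8, n_diseases=6, n_blocks=2,
                        assoc_density_matched=0.5, assoc_density_unmatched=0.1,
                        seed=seed)
        )
        edges = build_graph_edges(net, 0.5)
        for i in range(net.n_drugs):
            for j in range(net.n_diseases):
                got = enumerate_paths(edges, i, j, max_len=max_len, cap=None)
                want = oracle_paths(net, 0.5, i, j, max_len, exclude_direct=True)
                assert {tuple(p) for p in got.paths} == {tuple(p) for _, p in want}
                got_w = {tuple(p): w for p, w in zip(got.paths, got.weights)}
                for w, p in want:
                    assert got_w[tuple(p)] == pytest.approx(w)

    def test_cap_keeps_highest_weights_in_order(self):
        net = generate(SynthConfig(n_drugs=10, n_diseases=8, n_blocks=2,
                                   assoc_density_matched=0.6,
                                   assoc_density_unmatched=0.2, seed=4))
        edges = build_graph_edges(net, 0.4)
        full = enumerate_paths(edges, 0, 0, max_len=4, cap=None)
        capped = enumerate_paths(edges, 0, 0, max_len=4, cap=3)
        assert len(full) > 3
        assert capped.weights == sorted(full.weights, reverse=True)[:3]
        assert capped.weights == sorted(capped.weights, reverse=True)

    def test_weights_in_unit_interval(self, tiny_net):
        edges = build_graph_edges(tiny_net, 0.3)
        for i in range(tiny_net.n_drugs):
            ps = enumerate_paths(edges, i, 0, max_len=4, cap=None)
            for w in ps.weights:
                assert 0.0 < w <= 1.0

    def test_invariant_to_node_relabeling(self, tiny_net):
        """Permuting drug order (with matrices permuted consistently) permutes paths."""
        perm = np.random.default_rng(0).permutation(tiny_net.n_drugs)
        net2 = HeteroNetwork(
            [tiny_net.drug_ids[p] for p in perm],
            tiny_net.disease_ids,
            tiny_net.R[np.ix_(perm, perm)],
            tiny_net.D,
            tiny_net.A[perm],
        )
        inv = np.argsort(perm)
        e1 = build_graph_edges(tiny_net, 0.5)
        e2 = build_graph_edges(net2, 0.5)
        for i in range(tiny_net.n_drugs):
            for j in range(tiny_net.n_diseases):
                p1 = enumerate_paths(e1, i, j, cap=None)
                p2 = enumerate_paths(e2, int(inv[i]), j, cap=None)
                translate = {
                    tuple((l, int(perm[k]) if l == DRUG else k) for l, k in p)
                    for p in p2.paths
                }
                assert translate == {tuple(p) for p in p1.paths}

    def test_max_len_below_three_rejected(self, worked_example):
        edges = build_graph_edges(worked_example, 0.5)
        with pytest.raises(ValueError):
            enumerate_paths(edges, 0, 0, max_len=2)


class TestNodeFeature:
    def test_drug_feature_matches_pair_matrix_row(self, tiny_net):
        from cgardp.pair_features import build_pair_matrix

        for i in (0, 5):
            vec = node_feature(tiny_net, (DRUG, i))
            pfm = build_pair_matrix(tiny_net, i, 0, mask_known=False)
            np.testing.assert_array_equal(vec, pfm.X[0])

    def test_disease_feature_blocks(self, tiny_net):
        nr = tiny_net.n_drugs
        vec = node_feature(tiny_net, (DISEASE, 3))
        np.testing.assert_array_equal(vec[:nr], tiny_net.A[:, 3])
        np.testing.assert_array_equal(vec[nr:], tiny_net.D[3, :])

    def test_identity_network_gives_onehot(self):
        net = HeteroNetwork(["r1", "r2"], ["d1"], np.eye(2), np.eye(1), np.zeros((2, 1)))
        np.testing.assert_array_equal(node_feature(net, (DRUG, 1)), [0, 1, 0])

    def test_bad_layer_tag(self, tiny_net):
        with pytest.raises(ValueError):
            node_feature(tiny_net, ("gene", 0))
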