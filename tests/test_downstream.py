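"""Clustering, purity, relevance networks, assortativity, modularity and
consensus networks."""

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from rhoshrink.associate import shrinkage_correlation
from rhoshrink.data import DataError, TaxonomyTable
from rhoshrink.downstream import (
    TaxonNetwork,
    assortativity_categorical,
    cluster_purity,
    consensus_network,
    hierarchical_cluster,
    modularity_communities,
    relevance_network,
    spectral_affinity,
    spectral_cluster,
)
from rhoshrink.normalize import clr
from rhoshrink.synthdata import block_spec, make_taxonomy, simulate_counts


def _block_R(sizes, within, between=0.0):
    p = sum(sizes)
    R = np.full((p, p), between)
    start = 0
    for b in sizes:
        R[start:start + b, start:start + b] = within
        start += b
    np.fill_diagonal(R, 1.0)
    return R


def _net_from_edges(edges, nodes=None):
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return TaxonNetwork(g, sorted(g.nodes))


class TestAffinity:
    def test_endpoint_map(self):
        R = np.array([[1.0, 1.0], [1.0, 1.0]])
        aff = 1 - np.sqrt((1 - R) / 2)
        assert aff[0, 1] == 1.0
        R2 = np.array([[1.0, -1.0], [-1.0, 1.0]])
        assert (1 - np.sqrt((1 - R2) / 2))[0, 1] == 0.0
        assert 1 - np.sqrt(0.5) == pytest.approx(0.29289, abs=1e-5)

    def test_block_diagonal_keeps_no_cross_edges(self):
        R = _block_R([4, 4], within=0.8, between=0.0)
        aff = spectral_affinity(R, knn=2)
        assert np.all(aff[:4, 4:] == 0)
        assert np.any(aff[:4, :4] > 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            spectral_affinity(np.array([[1.0, 1.5], [1.5, 1.0]]))


class TestSpectralCluster:
    def test_two_cliques_bipartition(self):
        R = _block_R([5, 5], within=0.9)
        aff = spectral_affinity(R, knn=2)
        ca = spectral_cluster(aff)
        labels = ca.labels.to_numpy()
        assert ca.k == 2
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_auto_k_equals_components(self):
        R = _block_R([3, 4, 5], within=0.9)
        aff = spectral_affinity(R, knn=2)
        ca = spectral_cluster(aff)
        assert ca.diagnostics["n_components"] == 3
        assert ca.k == 3

    def test_noisy_blocks_recovered_across_seeds(self):
        truth = np.repeat([0, 1, 2], 10)
        for s in range(10):
            spec = block_spec(p=30, n=600, n_blocks=3, within=0.6, seed=700 + s,
                              base_spread=1.5)
            sim = simulate_counts(spec)
            R = shrinkage_correlation(clr(sim.counts))
            ca = spectral_cluster(spectral_affinity(R), taxon_ids=R.taxon_ids,
                                  seed=s)
            assert adjusted_rand_score(truth, ca.labels.to_numpy()) == 1.0

    def test_taxon_order_invariance(self, rng):
        R = _block_R([6, 6], within=0.8)
        aff = spectral_affinity(R)
        base = spectral_cluster(aff).labels.to_numpy()
        perm = rng.permutation(12)
        permuted = spectral_cluster(spectral_affinity(R[np.ix_(perm, perm)]))
        assert adjusted_rand_score(base[perm], permuted.labels.to_numpy()) == 1.0


class TestHierarchical:
    def test_two_blocks_recovered(self):
        R = _block_R([4, 6], within=0.8)
        ca = hierarchical_cluster(R, k=2)
        labels = ca.labels.to_numpy()
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[5]

    def test_merge_heights_monotone(self, rng):
        a = rng.normal(size=(30, 8))
        R = np.corrcoef(a, rowvar=False)
        ca = hierarchical_cluster(R, k=3)
        heights = ca.diagnostics["linkage"][:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_k_exceeding_p_errors(self):
        with pytest.raises(DataError):
            hierarchical_cluster(np.eye(3), k=5)


class TestPurity:
    def _assign(self, members):
        labels = pd.concat([pd.Series(c, index=t) for c, t in members.items()])
        from rhoshrink.downstream import ClusterAssignment
        return ClusterAssignment(labels, "manual", len(members))

    def _tax(self, fam_of):
        return TaxonomyTable(pd.DataFrame(
            {"family": pd.Series(fam_of)}).rename_axis("taxon_id"))

    def test_single_family_cluster(self):
        assign = self._assign({0: ["a", "b", "c"]})
        _, mean_p = cluster_purity(assign, self._tax({t: "F1" for t in "abc"}))
        assert mean_p == pytest.approx(1.0)

    def test_uniform_two_families(self):
        assign = self._assign({0: list("abcd")})
        tax = self._tax({"a": "F1", "b": "F1", "c": "F2", "d": "F2"})
        per, _ = cluster_purity(assign, tax)
        assert per[0] == pytest.approx(1.0)

    def test_nine_to_one_split(self):
        taxa = [f"t{i}" for i in range(10)]
        assign = self._assign({0: taxa})
        fam = {t: "F1" for t in taxa[:9]} | {taxa[9]: "F2"}
        per, _ = cluster_purity(assign, self._tax(fam))
        H = -(0.9 * np.log(0.9) + 0.1 * np.log(0.1))
        assert per[0] == pytest.approx(np.exp(H) / 2, abs=1e-6)
        assert per[0] == pytest.approx(0.6921, abs=1e-4)


class TestRelevanceNetwork:
    def test_single_strongest_pair(self):
        R = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, -0.5], [0.1, -0.5, 1.0]])
        net = relevance_network(R, top_k=1)
        assert net.edges == {("T0", "T1")}

    def test_complete_graph(self):
        R = np.eye(4) + 0.1
        np.fill_diagonal(R, 1.0)
        net = relevance_network(R, top_k=6)
        assert net.graph.number_of_edges() == 6

    def test_tie_break_deterministic(self):
        R = np.eye(4)
        R[0, 1] = R[1, 0] = 0.5
        R[2, 3] = R[3, 2] = 0.5
        R[0, 2] = R[2, 0] = -0.5
        net = relevance_network(R, top_k=2)
        assert net.edges == {("T0", "T1"), ("T0", "T2")}

    def test_monotone_in_top_k(self, rng):
        a = rng.normal(size=(20, 8))
        R = np.corrcoef(a, rowvar=False)
        for k1, k2 in [(3, 10), (10, 20)]:
            assert relevance_network(R, k1).edges <= relevance_network(R, k2).edges

    def test_sign_kept_on_edges(self):
        R = np.eye(3)
        R[0, 1] = R[1, 0] = -0.8
        net = relevance_network(R, top_k=1)
        assert net.graph.edges[("T0", "T1")]["sign"] == -1

    def test_too_large_request_errors(self):
        with pytest.raises(DataError):
            relevance_network(np.eye(3), top_k=10)


class TestAssortativity:
    def _tax(self, genus_of):
        return TaxonomyTable(pd.DataFrame(
            {"genus": pd.Series(genus_of)}).rename_axis("taxon_id"))

    def test_same_category_cliques(self):
        edges = list(combinations("abc", 2)) + list(combinations("xyz", 2))
        net = _net_from_edges(edges)
        tax = self._tax({t: "G1" for t in "abc"} | {t: "G2" for t in "xyz"})
        assert assortativity_categorical(net, tax) == pytest.approx(1.0)

    def test_complete_bipartite(self):
        edges = [(a, b) for a in "abc" for b in "xyz"]
        net = _net_from_edges(edges)
        tax = self._tax({t: "G1" for t in "abc"} | {t: "G2" for t in "xyz"})
        assert assortativity_categorical(net, tax) == pytest.approx(-1.0)

    def test_random_labels_near_zero(self, rng):
        g = nx.gnm_random_graph(30, 90, seed=4)
        g = nx.relabel_nodes(g, {i: f"t{i}" for i in range(30)})
        net = TaxonNetwork(g, sorted(g.nodes))
        coefs = []
        for _ in range(100):
            labels = rng.permutation(np.repeat(["G1", "G2", "G3"], 10))
            tax = self._tax(dict(zip(sorted(g.nodes), labels)))
            coefs.append(assortativity_categorical(net, tax))
        assert abs(np.mean(coefs)) < 0.05

    def test_edgeless_graph_sentinel(self):
        net = _net_from_edges([], nodes=["a", "b"])
        assert np.isnan(assortativity_categorical(net, self._tax({"a": "G", "b": "G"})))


def _exhaustive_best_modularity(g):
    """Brute-force best partition modularity over all set partitions."""
    nodes = list(g.nodes)

    def partitions(collection):
        if len(collection) == 1:
            yield [collection]
            return
        first, rest = collection[0], collection[1:]
        for smaller in partitions(rest):
            for i, subset in enumerate(smaller):
                yield smaller[:i] + [[first] + subset] + smaller[i + 1:]
            yield [[first]] + smaller

    best = -1.0
    for part in partitions(nodes):
        q = nx.community.modularity(g, [set(s) for s in part])
        best = max(best, q)
    return best


class TestModularity:
    def test_two_triangles(self):
        edges = list(combinations("abc", 2)) + list(combinations("xyz", 2))
        net = _net_from_edges(edges)
        assign, q = modularity_communities(net)
        assert q == pytest.approx(0.5)
        assert assign.nunique() == 2

    def test_complete_graph_single_module(self):
        net = _net_from_edges(list(combinations("abcde", 2)))
        _, q = modularity_communities(net)
        assert q == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_greedy_close_to_exhaustive_on_small_graphs(self, seed):
        g = nx.gnm_random_graph(7, 11, seed=seed)
        g = nx.relabel_nodes(g, {i: f"t{i}" for i in range(7)})
        g.remove_nodes_from(list(nx.isolates(g)))
        net = TaxonNetwork(g, sorted(g.nodes))
        _, q = modularity_communities(net)
        assert q >= _exhaustive_best_modularity(g) - 0.05

    def test_empty_graph_errors(self):
        with pytest.raises(DataError):
            modularity_communities(_net_from_edges([], nodes=["a"]))


class TestConsensus:
    def test_identical_networks(self):
        edges = [("a", "b"), ("b", "c")]
        nets = [_net_from_edges(edges, "abc") for _ in range(3)]
        cons, table = consensus_network(nets)
        assert cons.edges == {("a", "b"), ("b", "c")}

    def test_disjoint_edge_sets_empty_consensus(self):
        n1 = _net_from_edges([("a", "b")], "abcd")
        n2 = _net_from_edges([("c", "d")], "abcd")
        cons, _ = consensus_network([n1, n2])
        assert cons.edges == set()

    def test_venn_counts_match_set_algebra(self, rng):
        nodes = [f"t{i}" for i in range(8)]
        all_pairs = list(combinations(nodes, 2))
        sets = []
        for s in range(3):
            idx = rng.choice(len(all_pairs), size=10, replace=False)
            sets.append({all_pairs[i] for i in idx})
        nets = {f"N{s}": _net_from_edges(sorted(es), nodes)
                for s, es in enumerate(sets)}
        cons, table = consensus_network(nets)
        assert cons.edges == sets[0] & sets[1] & sets[2]
        lookup = {tuple(r["networks"]): r["exclusive_edges"]
                  for _, r in table.iterrows()}
        assert lookup[("N0",)] == len(sets[0] - sets[1] - sets[2])
        assert lookup[("N0", "N1", "N2")] == len(sets[0] & sets[1] & sets[2])
        assert lookup[("N0", "N1")] == len((sets[0] & sets[1]) - sets[2])

    def test_disjoint_universes_error(self):
        n1 = _net_from_edges([("a", "b")], "ab")
        n2 = _net_from_edges([("c", "d")], "cd")
        with pytest.raises(DataError):
            consensus_network([n1, n2])


class TestPurityOnSyntheticBlocks:
    def test_purity_improves_with_sample_size(self):
        # unequal blocks: a mixed cluster has an unbalanced family profile,
        # which the effective-number purity scores below 1
        scores = {}
        for n in (25, 1000):
            vals = []
            for s in range(3):
                spec = block_spec(p=30, n=n, sizes=[16, 9, 5], within=0.6,
                                  seed=900 + s, base_spread=1.5)
                sim = simulate_counts(spec)
                tax = make_taxonomy(spec)
                R = shrinkage_correlation(clr(sim.counts))
                ca = spectral_cluster(spectral_affinity(R),
                                      taxon_ids=R.taxon_ids, seed=s)
                vals.append(cluster_purity(ca, tax)[1])
            scores[n] = np.mean(vals)
        assert scores[1000] > scores[25]
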