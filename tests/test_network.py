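"""SparCC estimates, permutation nulls, graph construction, Louvain oracle."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from gutmwas import CohortConfig, generate_cohort
from gutmwas import network as nw
from tests.conftest import make_counts


@pytest.fixture(scope="module")
def clustered_counts():
    cfg = CohortConfig(
        n_cases=100, n_controls=100, n_features=40, n_differential=0,
        n_clusters=3, cluster_size_range=(8, 8), latent_factor_sd=0.8, seed=3,
    )
    counts, _, _, truth = generate_cohort(cfg)
    return counts, truth


class TestSparcc:
    def test_symmetric_with_unit_diagonal(self, rng):
        r = nw.sparcc(make_counts(rng.integers(0, 500, size=(30, 8))), n_iterations=10, seed=0)
        arr = r.to_numpy()
        assert np.allclose(arr, arr.T, atol=1e-12)
        assert np.allclose(np.diag(arr), 1.0)
        assert np.nanmax(np.abs(arr)) <= 1.0

    def test_planted_pair_stronger_than_independent(self, clustered_counts):
        counts, truth = clustered_counts
        r = nw.sparcc(counts, n_iterations=20, seed=0)
        cl = pd.Series(truth.cluster_assignment)
        members = list(cl.index[cl == 0])
        within = r.loc[members, members].to_numpy()[np.triu_indices(len(members), 1)]
        free = [f for f in counts.columns if f not in cl.index]
        between = r.loc[free, free].to_numpy()[np.triu_indices(len(free), 1)]
        assert within.mean() > 0.2
        assert np.abs(between).mean() < 0.1

    def test_independent_features_center_near_zero(self, rng):
        counts = make_counts(rng.integers(100, 10000, size=(200, 10)))
        r = nw.sparcc(counts, n_iterations=20, seed=1).to_numpy()
        off = r[np.triu_indices(10, 1)]
        assert abs(off.mean()) < 0.05

    def test_scale_invariance_of_single_sample(self, rng):
        base = rng.integers(50, 5000, size=(60, 12))
        doubled = base.copy()
        doubled[0] *= 7
        r1 = nw.sparcc(make_counts(base), n_iterations=100, seed=5).to_numpy()
        r2 = nw.sparcc(make_counts(doubled), n_iterations=100, seed=5).to_numpy()
        delta = np.abs(r1 - r2)[np.triu_indices(12, 1)]
        assert np.median(delta) < 0.02

    def test_too_few_features_rejected(self, rng):
        with pytest.raises(ValueError):
            nw.sparcc(make_counts(rng.integers(0, 10, size=(20, 3))))


class TestPermutationPvalues:
    def test_grid_and_planted_pair(self, clustered_counts):
        counts, truth = clustered_counts
        sub = counts.iloc[:, :20]
        r = nw.sparcc(sub, n_iterations=10, seed=0)
        p = nw.permutation_pvalues(sub, r, n_random=100, seed=1, n_iterations=5)
        arr = p.to_numpy()
        assert np.allclose(arr * 100, np.round(arr * 100), atol=1e-9)  # multiples of 1/n_random
        # the strongest planted pair has no random exceedances
        cl = pd.Series(truth.cluster_assignment)
        members = [f for f in cl.index if f in sub.columns]
        pairs = [
            (a, b) for a in members for b in members
            if a < b and cl[a] == cl[b]
        ]
        assert pairs, "fixture must place cluster pairs in the subset"
        best = max(pairs, key=lambda ab: abs(r.loc[ab]))
        assert p.loc[best] == 0.0

    def test_low_resolution_warns(self, rng):
        counts = make_counts(rng.integers(10, 100, size=(20, 5)))
        r = nw.sparcc(counts, n_iterations=5, seed=0)
        with pytest.warns(UserWarning, match="resolution"):
            nw.permutation_pvalues(counts, r, n_random=20, seed=0, n_iterations=3)


class TestBuildNetwork:
    @staticmethod
    def _mats(r_vals, p_vals, feats):
        r = pd.DataFrame(r_vals, index=feats, columns=feats)
        p = pd.DataFrame(p_vals, index=feats, columns=feats)
        return r, p

    def test_thresholds_strict_and_negative_edges_kept(self):
        feats = list("abc")
        r_vals = np.eye(3)
        r_vals[0, 1] = r_vals[1, 0] = 0.19  # below strict threshold
        r_vals[0, 2] = r_vals[2, 0] = -0.25  # negative but strong
        p_vals = np.full((3, 3), 0.001)
        net = nw.build_network(*self._mats(r_vals, p_vals, feats))
        assert [(e[0], e[1]) for e in net.edges] == [("a", "c")]
        assert net.edges[0][2] == pytest.approx(-0.25)
        assert "b" not in net.graph.nodes  # isolated feature excluded

    def test_degrees_match_brute_force_recount(self, rng):
        n = 12
        r_vals = np.clip((x := rng.normal(0, 0.3, (n, n))) + x.T, -1, 1)
        np.fill_diagonal(r_vals, 1.0)
        p_vals = rng.random((n, n))
        p_vals = (p_vals + p_vals.T) / 2
        feats = [f"f{i}" for i in range(n)]
        net = nw.build_network(*self._mats(r_vals, p_vals, feats))
        for f in net.graph.nodes:
            brute = sum(1 for e in net.edges if f in (e[0], e[1]))
            assert net.degree[f] == brute

    def test_empty_network_warns(self):
        feats = list("abcd")
        with pytest.warns(UserWarning, match="no edges"):
            net = nw.build_network(*self._mats(np.eye(4), np.ones((4, 4)), feats))
        assert net.graph.number_of_nodes() == 0


def all_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


class TestLouvain:
    def _network_from_graph(self, g):
        feats = sorted(g.nodes)
        r = pd.DataFrame(np.eye(len(feats)), index=feats, columns=feats)
        net = nw.CorrelationNetwork(r=r, perm_p=r * 0, edges=[(u, v, 1.0) for u, v in g.edges], graph=g)
        net.degree = {n_: int(d) for n_, d in g.degree()}
        return net

    def test_two_cliques_recovered_exactly(self):
        g = nx.Graph()
        g.add_edges_from(itertools.combinations(range(5), 2))
        g.add_edges_from(itertools.combinations(range(5, 10), 2))
        g.add_edge(0, 5)
        assign = nw.louvain_clusters(self._network_from_graph(g), seed=0)
        assert len({assign[i] for i in range(5)}) == 1
        assert len({assign[i] for i in range(5, 10)}) == 1
        assert assign[0] != assign[5]

    def test_partition_modularity_matches_exhaustive_optimum(self, rng):
        # 7 nodes: exhaustive search over all 877 set partitions
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3), (5, 6), (4, 6)])
        assign = nw.louvain_clusters(self._network_from_graph(g), seed=1)
        found = [set(n for n, c in assign.items() if c == cid) for cid in set(assign.values())]
        q_found = nx.community.modularity(g, found)
        q_best = max(
            nx.community.modularity(g, [set(p) for p in part])
            for part in all_partitions(sorted(g.nodes))
        )
        assert q_found == pytest.approx(q_best, abs=1e-12)

    def test_single_edge_graph_is_one_cluster(self):
        g = nx.Graph([("a", "b")])
        assign = nw.louvain_clusters(self._network_from_graph(g), seed=0)
        assert assign["a"] == assign["b"]

    def test_beats_trivial_partition(self, rng):
        g = nx.gnp_random_graph(12, 0.3, seed=4)
        assign = nw.louvain_clusters(self._network_from_graph(g), seed=0)
        parts = [set(n for n, c in assign.items() if c == cid) for cid in set(assign.values())]
        assert nx.community.modularity(g, parts) >= nx.community.modularity(g, [set(g.nodes)])


class TestMapHits:
    def test_empty_calls_annotate_none(self, rng):
        g = nx.Graph([("a", "b"), ("b", "c")])
        feats = list("abc")
        r = pd.DataFrame(np.eye(3), index=feats, columns=feats)
        net = nw.CorrelationNetwork(r=r, perm_p=r * 0, edges=[("a", "b", 0.5), ("b", "c", 0.5)], graph=g)
        net.degree = {n_: int(d) for n_, d in g.degree()}
        nw.louvain_clusters(net, seed=0)
        summary = nw.map_hits(net, pd.DataFrame(columns=["direction"]))
        assert all(v == "none" for v in net.hit_annotation.values())
        assert summary["n_elevated"].sum() == 0

    def test_planted_hits_counted_and_mean_degree_recounted(self, clustered_counts):
        counts, truth = clustered_counts
        r = nw.sparcc(counts, n_iterations=20, seed=0)
        p = nw.permutation_pvalues(counts, r, n_random=100, seed=2, n_iterations=5)
        net = nw.build_network(r, p)
        nw.louvain_clusters(net, seed=0)
        cl = pd.Series(truth.cluster_assignment)
        members = list(cl.index[cl == 1])
        calls = pd.DataFrame({"direction": "elevated"}, index=members)
        summary = nw.map_hits(net, calls)
        assert summary["n_elevated"].sum() == sum(1 for m in members if m in net.graph.nodes)
        md = nw.mean_degree(net, members)
        assert md == pytest.approx(np.mean([net.degree.get(m, 0) for m in members]))
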