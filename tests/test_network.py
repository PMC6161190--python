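"""Weighted PPI graphs and spectral modularity clustering."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from psdnet.network import (
    build_network,
    cluster_all_regions,
    modularity,
    spectral_partition,
    weight_edges,
)
from psdnet.simulate import SimConfig, simulate_abundance, simulate_ppi


def bruteforce_modularity(graph: nx.Graph, membership: dict) -> float:
    """Independent double-sum oracle for weighted Newman-Girvan Q."""
    nodes = list(graph.nodes)
    A = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    two_m = A.sum()
    s = A.sum(axis=1)
    q = 0.0
    for i, ni in enumerate(nodes):
        for j, nj in enumerate(nodes):
            if membership[ni] == membership[nj]:
                q += A[i, j] - s[i] * s[j] / two_m
    return q / two_m


def bridge_graph() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])
    return g


class TestBuildNetwork:
    def test_dedupe_and_self_loop(self):
        edges = pd.DataFrame(
            {"protein_a": ["A", "B", "A"], "protein_b": ["B", "A", "A"]}
        )
        g = build_network(edges, {"A", "B"})
        assert g.number_of_edges() == 1
        assert g.graph["edges_dropped"] == 2

    def test_unquantified_endpoints_dropped(self):
        edges = pd.DataFrame({"protein_a": ["A", "C"], "protein_b": ["B", "D"]})
        g = build_network(edges, {"A", "B", "C"})
        assert set(g.edges) == {("A", "B")}

    def test_disjoint_quantified_set_rejected(self):
        edges = pd.DataFrame({"protein_a": ["A"], "protein_b": ["B"]})
        with pytest.raises(ValueError):
            build_network(edges, {"X", "Y"})

    def test_counts_match_generator(self, small_config):
        tensor, truth = simulate_abundance(small_config)
        edges = simulate_ppi(small_config, truth)
        g = build_network(edges, set(tensor.proteins))
        assert g.number_of_edges() == len(edges)
        assert set(g.nodes) == {n for e in edges.itertuples(index=False) for n in e}


class TestWeightEdges:
    def test_mean_of_endpoint_abundances(self):
        g = nx.Graph([("a", "b")])
        means = pd.DataFrame({"R1": [2.0, 4.0]}, index=["a", "b"])
        weighted = weight_edges(g, means)
        assert weighted["R1"]["a"]["b"]["weight"] == 3.0

    def test_missing_abundance_names_protein(self):
        g = nx.Graph([("a", "b")])
        means = pd.DataFrame({"R1": [2.0]}, index=["a"])
        with pytest.raises(ValueError, match="b"):
            weight_edges(g, means)

    def test_regional_weights_differ_iff_abundances_differ(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        means = pd.DataFrame(
            {"R1": [1.0, 2.0, 3.0], "R2": [1.0, 2.0, 3.0], "R3": [9.0, 2.0, 3.0]},
            index=["a", "b", "c"],
        )
        w = weight_edges(g, means)
        assert w["R1"]["a"]["b"]["weight"] == w["R2"]["a"]["b"]["weight"]
        assert w["R3"]["a"]["b"]["weight"] != w["R1"]["a"]["b"]["weight"]

    def test_equal_abundance_reduces_to_unweighted(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        means = pd.DataFrame({"R1": [2.0] * 6}, index=range(6))
        w = weight_edges(g, means)["R1"]
        part = spectral_partition(w)
        assert part.n_communities == 2
        assert np.isclose(part.Q, 0.5)


class TestModularity:
    def test_single_community_zero(self):
        g = bridge_graph()
        assert modularity(g, {n: 1 for n in g}) == pytest.approx(0.0, abs=1e-15)

    def test_disjoint_triangles(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        q = modularity(g, {0: 1, 1: 1, 2: 1, 3: 2, 4: 2, 5: 2})
        assert np.isclose(q, 0.5)

    def test_bridge_split_value(self):
        g = bridge_graph()
        q = modularity(g, {0: 1, 1: 1, 2: 1, 3: 2, 4: 2, 5: 2})
        assert np.isclose(q, 3 / 7 + 3 / 7 - 0.5, rtol=1e-12)

    def test_matches_bruteforce_on_random_weighted_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(5, 30))
            g = nx.gnp_random_graph(n, 0.3, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.uniform(0.1, 5))
            membership = {node: int(rng.integers(1, 4)) for node in g}
            assert modularity(g, membership) == pytest.approx(
                bruteforce_modularity(g, membership), abs=1e-12
            )

    def test_matches_networkx_reference(self):
        g = nx.les_miserables_graph()
        part = spectral_partition(g)
        comms = list(part.communities().values())
        ref = nx.algorithms.community.modularity(g, comms, weight="weight")
        assert part.Q == pytest.approx(ref, abs=1e-10)

    def test_weightless_graph_rejected(self):
        g = nx.Graph()
        g.add_nodes_from([1, 2])
        with pytest.raises(ValueError):
            modularity(g, {1: 1, 2: 1})


class TestSpectralPartition:
    def test_two_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        part = spectral_partition(g)
        assert part.n_communities == 2
        assert len(set(part.membership[i] for i in range(5))) == 1

    def test_bridge_graph_optimum(self):
        part = spectral_partition(bridge_graph())
        assert part.membership[0] == part.membership[1] == part.membership[2]
        assert part.membership[3] == part.membership[4] == part.membership[5]
        assert np.isclose(part.Q, 3 / 7 + 3 / 7 - 0.5, rtol=1e-12)

    def test_singleton_graph(self):
        g = nx.Graph()
        g.add_node("x")
        part = spectral_partition(g)
        assert part.membership == {"x": 1} and part.Q == 0.0

    def test_q_at_least_trivial_partition(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            g = nx.gnp_random_graph(15, 0.3, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            assert spectral_partition(g).Q >= -1e-12

    def test_label_equivariance(self):
        rng = np.random.default_rng(4)
        g = nx.gnp_random_graph(12, 0.4, seed=9)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.5, 2))
        part = spectral_partition(g)
        mapping = {i: f"node_{(i * 7) % 12:02d}" for i in g}
        h = nx.relabel_nodes(g, mapping)
        part_h = spectral_partition(h)
        for a, b in itertools.combinations(g.nodes, 2):
            same_g = part.membership[a] == part.membership[b]
            same_h = part_h.membership[mapping[a]] == part_h.membership[mapping[b]]
            assert same_g == same_h

    def test_sbm_recovery_sample(self):
        from sklearn.metrics import adjusted_rand_score

        cfg = SimConfig(
            n_proteins=80, n_modules=4, ppi_p_in=0.9, ppi_p_out=0.05, seed=1
        )
        _, truth = simulate_abundance(cfg)
        edges = simulate_ppi(cfg, truth)
        g = build_network(edges, set(truth.module_labels))
        part = spectral_partition(g)
        nodes = sorted(g.nodes)
        ari = adjusted_rand_score(
            [truth.community_labels[n] for n in nodes],
            [part.membership[n] for n in nodes],
        )
        assert ari >= 0.9

    def test_community_ids_contiguous(self):
        part = spectral_partition(bridge_graph())
        ids = sorted(set(part.membership.values()))
        assert ids == list(range(1, len(ids) + 1))


class TestClusterAllRegions:
    def test_identical_weights_identical_partitions(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        means = pd.DataFrame({"R1": [2.0] * 8, "R2": [2.0] * 8}, index=range(8))
        res = cluster_all_regions(weight_edges(g, means))
        p1, p2 = res["partitions"]["R1"], res["partitions"]["R2"]
        assert p1.membership == p2.membership

    def test_divergent_abundances_change_comembership(self):
        """Planted regional divergence must alter at least one edge's
        co-membership in at least one seed-pair of regions."""
        changed = 0
        for seed in range(10):
            cfg = SimConfig(
                n_proteins=60,
                n_regions=3,
                n_modules=3,
                module_effect_sd=1.5,
                noise_cv=0.1,
                ppi_p_in=0.4,
                ppi_p_out=0.1,
                frac_coupled=0.0,
                seed=seed,
            )
            tensor, truth = simulate_abundance(cfg)
            edges = simulate_ppi(cfg, truth)
            g = build_network(edges, set(tensor.proteins))
            res = cluster_all_regions(weight_edges(g, tensor.region_means()))
            parts = list(res["partitions"].values())
            for a, b in g.edges:
                flags = [p.membership[a] == p.membership[b] for p in parts]
                if len(set(flags)) > 1:
                    changed += 1
                    break
        assert changed >= 5

    def test_q_within_bounds_and_summary(self, small_config):
        tensor, truth = simulate_abundance(small_config)
        edges = simulate_ppi(small_config, truth)
        g = build_network(edges, set(tensor.proteins))
        res = cluster_all_regions(weight_edges(g, tensor.region_means()))
        assert res["summary"]["Q"].between(-0.5, 1).all()
        assert (res["summary"]["n_communities"] >= 1).all()
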