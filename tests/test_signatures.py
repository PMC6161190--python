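"""Differential stability, module detection and Circos links."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from psdnet.signatures import (
    choose_k,
    circos_links,
    cut_dendrogram,
    differential_stability,
    hierarchical_cluster,
    linkage_to_newick,
    select_high_ds,
)
from psdnet.simulate import SimConfig, simulate_abundance
from tests.conftest import make_tensor


def _tensor_from_brains(*profiles):
    """Stack per-brain region profiles into a single-protein tensor."""
    arr = np.stack(profiles, axis=-1)[None, :, :]  # (1, R, B)
    return make_tensor(arr)


class TestDifferentialStability:
    @pytest.mark.parametrize(
        "b2,expected",
        [
            ([2.0, 4.0, 6.0], 1.0),  # proportional
            ([3.0, 2.0, 1.0], -1.0),  # reversed
            ([1.0, 3.0, 2.0], 0.5),  # hand Pearson: cov 0.5, sds 1
        ],
    )
    def test_hand_examples(self, b2, expected):
        t = _tensor_from_brains([1.0, 2.0, 3.0], b2)
        ds = differential_stability(t)
        assert np.isclose(ds["avg_cor"].iloc[0], expected, rtol=1e-12)
        assert ds["n_pairs"].iloc[0] == 1

    def test_constant_brain_skipped_and_flagged(self):
        t = _tensor_from_brains([1.0, 2.0, 3.0], [5.0, 5.0, 5.0], [2.0, 4.0, 6.0])
        ds = differential_stability(t)
        assert bool(ds["flagged"].iloc[0])
        assert ds["n_pairs"].iloc[0] == 1  # only the non-constant pair

    def test_bounded_and_pair_count(self, small_config):
        tensor, _ = simulate_abundance(small_config)
        ds = differential_stability(tensor)
        B = small_config.n_replicates
        assert ds["avg_cor"].between(-1, 1).all()
        assert (ds["n_pairs"] == B * (B - 1) // 2).all()

    def test_consistent_beats_shuffled(self):
        """Proteins with reproducible profiles must out-score per-brain
        shuffled ones (Mann-Whitney, each of 5 seeds)."""
        from scipy.stats import mannwhitneyu

        for seed in range(5):
            cfg = SimConfig(
                n_proteins=100,
                noise_cv=0.1,
                module_effect_sd=0.5,
                frac_unstable=0.5,
                frac_de=0.0,
                frac_coupled=0.0,
                seed=seed,
            )
            tensor, truth = simulate_abundance(cfg)
            ds = differential_stability(tensor).set_index("protein_id")
            stable = [p for p in tensor.proteins if p not in truth.unstable]
            res = mannwhitneyu(
                ds.loc[stable, "avg_cor"],
                ds.loc[sorted(truth.unstable), "avg_cor"],
                alternative="greater",
            )
            assert res.pvalue < 0.01

    def test_high_ds_selection_boundaries(self, small_config):
        tensor, _ = simulate_abundance(small_config)
        ds = differential_stability(tensor)
        assert select_high_ds(ds, cutoff=-1.0) == set(tensor.proteins)
        assert select_high_ds(ds, cutoff=ds["avg_cor"].max() + 0.1) == set()

    def test_median_cutoff_selects_consistent_half(self):
        """Default (median) cutoff recovers the planted stable half."""
        for seed in range(20):
            cfg = SimConfig(
                n_proteins=100,
                noise_cv=0.1,
                module_effect_sd=0.5,
                frac_unstable=0.5,
                frac_de=0.0,
                frac_coupled=0.0,
                seed=100 + seed,
            )
            tensor, truth = simulate_abundance(cfg)
            ds = differential_stability(tensor)
            high = select_high_ds(ds)
            stable = set(tensor.proteins) - truth.unstable
            jacc = len(high & stable) / len(high | stable)
            assert jacc >= 0.9


class TestHierarchicalCluster:
    def test_duplicated_row_groups_split_first(self):
        rows = [[1.0, 2.0, 5.0]] * 4 + [[9.0, 1.0, 4.0]] * 3
        m = pd.DataFrame(rows, index=[f"P{i}" for i in range(7)], columns=list("abc"))
        res = hierarchical_cluster(m)
        labels = cut_dendrogram(res["row_linkage"], 2, m.index)
        assert labels.iloc[:4].nunique() == 1
        assert labels.iloc[4:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_row_permutation_leaves_cut_invariant(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(size=(20, 5)), index=[f"P{i}" for i in range(20)])
        perm = rng.permutation(20)
        a = cut_dendrogram(hierarchical_cluster(m)["row_linkage"], 4, m.index)
        mp = m.iloc[perm]
        b = cut_dendrogram(hierarchical_cluster(mp)["row_linkage"], 4, mp.index)
        # compare as co-membership relations (labels may be renumbered)
        for p1, p2 in itertools.combinations(m.index, 2):
            assert (a[p1] == a[p2]) == (b[p1] == b[p2])

    def test_uniform_scaling_leaves_cut_invariant(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(15, 4)), index=[f"P{i}" for i in range(15)])
        a = cut_dendrogram(hierarchical_cluster(m)["row_linkage"], 3, m.index)
        b = cut_dendrogram(hierarchical_cluster(m * 7.0)["row_linkage"], 3, m.index)
        for p1, p2 in itertools.combinations(m.index, 2):
            assert (a[p1] == a[p2]) == (b[p1] == b[p2])

    def test_planted_region_group_forms_clade(self):
        """Regions sharing module effects (the cortex-like group) must
        cluster together in the region dendrogram."""
        hits = 0
        for seed in range(20):
            cfg = SimConfig(
                n_proteins=120,
                n_modules=6,
                noise_cv=0.1,
                module_effect_sd=0.6,
                group_jitter_sd=0.1,
                region_group=(0, 1, 2),
                frac_de=0.0,
                frac_coupled=0.0,
                seed=seed,
            )
            tensor, _ = simulate_abundance(cfg)
            res = hierarchical_cluster(tensor.region_means())
            tree = hierarchy.to_tree(res["col_linkage"])
            clades = []

            def collect(node):
                if node.is_leaf():
                    return {node.id}
                leaves = collect(node.left) | collect(node.right)
                clades.append(leaves)
                return leaves

            collect(tree)
            if {0, 1, 2} in clades:
                hits += 1
        assert hits >= 18

    def test_newick_roundtrip_structure(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(size=(6, 4)), index=[f"P{i}" for i in range(6)])
        res = hierarchical_cluster(m)
        nwk = linkage_to_newick(res["row_linkage"], list(m.index))
        assert nwk.endswith(";") and nwk.count("P") == 6
        import io as _io

        from Bio import Phylo

        tree = Phylo.read(_io.StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(m.index)


class TestChooseK:
    def test_three_blobs(self):
        correct = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            centers = np.array([[0, 0, 0, 0], [8.0, 0, 0, 0], [0, 8.0, 0, 0]])
            X = np.vstack(
                [c + rng.normal(0, 0.4, size=(12, 4)) for c in centers]
            )
            m = pd.DataFrame(X, index=[f"P{i}" for i in range(36)])
            if choose_k(m, k_range=(2, 6), zscore_rows=False)["K"] == 3:
                correct += 1
        assert correct >= 18

    def test_duplicated_groups_perfect_silhouette(self):
        rows = [[0.0, 0.0, 5.0]] * 5 + [[5.0, 0.0, 0.0]] * 5
        m = pd.DataFrame(rows, index=[f"P{i}" for i in range(10)])
        res = choose_k(m, k_range=(2, 4), zscore_rows=False)
        assert res["K"] == 2
        assert np.isclose(
            res["scores"].set_index("K").loc[2, "silhouette"], 1.0
        )

    def test_forced_k_range(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(12, 4)))
        assert choose_k(m, k_range=(2, 2), zscore_rows=False)["K"] == 2

    def test_degenerate_matrix_rejected(self):
        m = pd.DataFrame(np.ones((6, 3)))
        with pytest.raises(ValueError, match="degenerate"):
            choose_k(m, k_range=(2, 3), zscore_rows=False)


class TestCircosLinks:
    def test_single_region_protein_contributes_nothing(self):
        modules = pd.Series([1, 1], index=["P1", "P2"])
        presence = pd.DataFrame(
            [[True, False, False], [True, False, False]],
            index=["P1", "P2"],
            columns=["A", "B", "C"],
        )
        assert len(circos_links(modules, presence)) == 0

    def test_module_shared_between_two_regions(self):
        modules = pd.Series([1, 1, 1, 2], index=["P1", "P2", "P3", "P4"])
        presence = pd.DataFrame(
            {
                "A": [True, True, True, True],
                "B": [True, True, True, False],
                "C": [False, False, False, False],
            },
            index=modules.index,
        )
        links = circos_links(modules, presence)
        assert len(links) == 1
        row = links.iloc[0]
        # module 1's three proteins positive in A and B; |A positives| = 4
        assert (row["region_a"], row["region_b"], row["module"]) == ("A", "B", 1)
        assert np.isclose(row["width"], 3 / 4)

    def test_per_region_width_sums_bounded(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(5, 40))
            modules = pd.Series(
                rng.integers(1, 4, size=n), index=[f"P{i}" for i in range(n)]
            )
            presence = pd.DataFrame(
                rng.random((n, 5)) < 0.5,
                index=modules.index,
                columns=list("ABCDE"),
            )
            links = circos_links(modules, presence)
            if len(links) == 0:
                continue
            for region in "ABCDE":
                total = links.loc[links.region_a == region, "width"].sum()
                assert total <= 1.0 + 1e-9
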