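"""Correlation networks, modularity, and the eigenvalue-variance integration."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from nicheweb.niche_integration import (
    INDEX_COLUMNS,
    abundance_correlation,
    assemble_index_matrix,
    build_correlation_network,
    correlation_matrix_from_pairs,
    cross_scale_correlation,
    integration_index,
    modularity_partition,
    pairwise_correlations,
    r_squared_from_t,
)


def set_partitions(items):
    """All partitions of a small set (exhaustive modularity oracle)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for k in range(len(partition)):
            yield partition[:k] + [partition[k] | {first}] + partition[k + 1 :]
        yield partition + [{first}]


def best_partition_exhaustive(graph):
    best_q, best = -np.inf, None
    for partition in set_partitions(graph.nodes):
        q = nx.community.modularity(graph, partition, weight="weight")
        if q > best_q:
            best_q, best = q, partition
    return best, best_q


class TestAssembly:
    @staticmethod
    def niche_rows(taxa, niche_type):
        return pd.DataFrame(
            {
                "taxon": taxa,
                "niche_type": niche_type,
                "marginality": np.linspace(0.1, 0.5, len(taxa)),
                "volume": np.linspace(0.2, 0.9, len(taxa)),
            }
        )

    @staticmethod
    def role_rows(taxa):
        n = len(taxa)
        return pd.DataFrame(
            {
                "taxon": taxa,
                "degree": range(1, n + 1),
                "species_strength": np.linspace(0.5, 2.0, n),
                "betweenness": np.linspace(0, 1, n),
                "partner_diversity": np.linspace(0, 2, n),
                "node_specialization_index": np.linspace(1, 2, n),
                "d_prime": np.linspace(0, 1, n),
            }
        )

    def test_missing_niche_type_yields_missing_cells(self):
        niches = pd.concat(
            [self.niche_rows(["t1", "t2"], "grinnellian"), self.niche_rows(["t1"], "trait")]
        )
        im = assemble_index_matrix(niches, self.role_rows(["t1", "t2"]))
        assert list(im.columns) == list(INDEX_COLUMNS)
        assert np.isnan(im.loc["t2", "trait_marginality"])
        assert not im.loc["t1"].isna().any()

    def test_duplicate_taxon_rows_rejected(self):
        niches = pd.concat([self.niche_rows(["t1", "t1"], "grinnellian")])
        with pytest.raises(ValueError, match="duplicate"):
            assemble_index_matrix(niches, self.role_rows(["t1"]))

    def test_complete_inputs_have_no_missing_cells(self):
        taxa = ["t1", "t2", "t3"]
        niches = pd.concat(
            [self.niche_rows(taxa, "grinnellian"), self.niche_rows(taxa, "trait")]
        )
        im = assemble_index_matrix(niches, self.role_rows(taxa))
        assert not im.isna().any().any()


class TestPairwiseCorrelations:
    def test_three_point_pearson_closed_form(self):
        im = pd.DataFrame({"x": [1, 2, 3], "y": [1, 2, 4]})
        out = pairwise_correlations(im)
        assert np.isclose(out.loc[0, "r"], 3 / np.sqrt(2 * 14 / 3), atol=1e-9)
        assert np.isclose(out.loc[0, "r"] ** 2, 0.9643, atol=1e-4)

    def test_identical_columns_give_unit_correlation(self):
        im = pd.DataFrame({"x": [1.0, 2, 5], "y": [1.0, 2, 5]})
        assert np.isclose(pairwise_correlations(im).loc[0, "r"], 1.0)

    def test_t_to_r_squared_identity_holds(self):
        rng = np.random.default_rng(0)
        im = pd.DataFrame(rng.normal(size=(12, 2)), columns=["x", "y"])
        out = pairwise_correlations(im).iloc[0]
        df = out["n"] - 2
        t = out["r"] * np.sqrt(df / (1 - out["r"] ** 2))
        assert np.isclose(r_squared_from_t(t, df), out["r"] ** 2, atol=1e-12)

    def test_zero_variance_pair_skipped_with_warning(self):
        im = pd.DataFrame({"x": [1.0, 1, 1], "y": [1.0, 2, 3]})
        with pytest.warns(UserWarning, match="zero variance"):
            out = pairwise_correlations(im)
        assert len(out) == 0

    def test_too_few_complete_rows_skipped(self):
        im = pd.DataFrame({"x": [1.0, 2, np.nan], "y": [1.0, np.nan, 3]})
        with pytest.warns(UserWarning, match="complete observations"):
            assert len(pairwise_correlations(im)) == 0


class TestNetworkAndModularity:
    @staticmethod
    def corr_table(rows):
        return pd.DataFrame(rows, columns=["index_a", "index_b", "r", "p", "n"])

    def test_only_significant_pairs_become_edges(self):
        corr = self.corr_table([("a", "b", 0.9, 0.01, 10), ("a", "c", 0.5, 0.2, 10)])
        g = build_correlation_network(corr, alpha=0.05, nodes=["a", "b", "c"])
        assert g.number_of_edges() == 1
        assert np.isclose(g["a"]["b"]["weight"], 0.81)
        assert g["a"]["b"]["sign"] == 1

    def test_all_significant_pairs_give_complete_ten_node_graph(self):
        pairs = list(itertools.combinations(INDEX_COLUMNS, 2))
        corr = self.corr_table([(a, b, 0.5, 0.001, 20) for a, b in pairs])
        g = build_correlation_network(corr)
        assert g.number_of_nodes() == 10 and g.number_of_edges() == 45

    def test_two_triangles_match_exhaustive_partition(self):
        g = nx.Graph()
        for offset in (0, 3):
            for u, v in itertools.combinations(range(offset, offset + 3), 2):
                g.add_edge(u, v, weight=1.0)
        partition, q = modularity_partition(g)
        oracle_partition, oracle_q = best_partition_exhaustive(g)
        assert np.isclose(q, oracle_q, atol=1e-12)
        assert {frozenset(s) for s in partition} == {frozenset(s) for s in oracle_partition}

    def test_complete_equal_weight_graph_is_one_module(self):
        g = nx.complete_graph(5)
        nx.set_edge_attributes(g, 1.0, "weight")
        partition, q = modularity_partition(g)
        _, oracle_q = best_partition_exhaustive(g)
        assert np.isclose(q, oracle_q, atol=1e-12)
        assert np.isclose(q, 0.0, atol=1e-12)
        assert len(partition) == 1

    def test_single_edge_merges_both_nodes(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.4)
        partition, q = modularity_partition(g)
        assert partition == [{"a", "b"}]

    def test_edgeless_network_gives_singletons_and_zero_q(self):
        g = nx.empty_graph(4)
        partition, q = modularity_partition(g)
        assert q == 0.0 and len(partition) == 4


class TestIntegration:
    def test_identity_matrix_has_zero_integration(self):
        raw, corrected = integration_index(np.eye(5), n_effective=100)
        assert raw == 0.0 and corrected == 0.0

    def test_two_by_two_closed_form(self):
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        raw, corrected = integration_index(R, n_effective=21)
        assert np.isclose(raw, 0.25)
        assert np.isclose(corrected, 0.25 - 1 / 20)

    def test_eigenvalue_variance_equals_mean_offdiagonal_r2(self, rng):
        for _ in range(30):
            n = rng.integers(3, 9)
            data = rng.normal(size=(30, n))
            R = np.corrcoef(data, rowvar=False)
            raw, _ = integration_index(R, n_effective=30)
            off = R[~np.eye(n, dtype=bool)]
            assert np.isclose(raw, (n - 1) * np.mean(off**2), atol=1e-10)

    def test_iid_noise_has_unbiased_corrected_integration(self, rng):
        # before the floor at 0, raw − (N−1)/(n−1) is centered on 0 under the null
        n_obs, n_idx = 25, 6
        excess = []
        for _ in range(200):
            data = rng.normal(size=(n_obs, n_idx))
            raw, _ = integration_index(np.corrcoef(data, rowvar=False), n_effective=n_obs)
            excess.append(raw - (n_idx - 1) / (n_obs - 1))
        se = np.std(excess) / np.sqrt(len(excess))
        assert abs(np.mean(excess)) < 4 * se

    def test_asymmetric_matrix_rejected(self):
        R = np.array([[1.0, 0.2], [0.6, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            integration_index(R, n_effective=10)

    def test_missing_pairs_imputed_with_warning(self):
        corr = pd.DataFrame(
            [("a", "b", 0.5, 0.01, 10)], columns=["index_a", "index_b", "r", "p", "n"]
        )
        R = correlation_matrix_from_pairs(corr, nodes=["a", "b", "c"])
        with pytest.warns(UserWarning, match="imputing"):
            raw, _ = integration_index(R, n_effective=10)
        assert np.isclose(raw, 2 * np.mean([0.25, 0.0, 0.0]), atol=1e-12)


class TestCrossScaleAndAbundance:
    def test_identical_vectors_have_unit_r_squared(self, rng):
        values = rng.normal(size=10)
        im = pd.DataFrame({"idx": values}, index=[f"t{k}" for k in range(10)])
        out = cross_scale_correlation(im, im.copy())
        assert np.isclose(out.loc[0, "r2"], 1.0)

    def test_seventeen_shared_taxa_give_df_fifteen(self, rng):
        taxa = [f"t{k}" for k in range(17)]
        local = pd.DataFrame({"idx": rng.normal(size=17)}, index=taxa)
        regional = pd.DataFrame({"idx": rng.normal(size=17)}, index=taxa)
        assert cross_scale_correlation(local, regional).loc[0, "df"] == 15

    def test_anticorrelated_vectors_still_have_unit_r_squared(self):
        taxa = [f"t{k}" for k in range(8)]
        x = np.linspace(0, 1, 8)
        local = pd.DataFrame({"idx": x}, index=taxa)
        regional = pd.DataFrame({"idx": -x}, index=taxa)
        out = cross_scale_correlation(local, regional)
        assert np.isclose(out.loc[0, "r2"], 1.0)
        assert out.loc[0, "t"] < 0

    def test_too_few_shared_taxa_marked_not_computable(self):
        local = pd.DataFrame({"idx": [1.0, 2.0]}, index=["t1", "t2"])
        regional = pd.DataFrame({"idx": [1.0, 3.0]}, index=["t1", "t3"])
        out = cross_scale_correlation(local, regional)
        assert not out.loc[0, "computable"]

    def test_abundance_correlation_recovers_constructed_signal(self, rng):
        taxa = [f"t{k}" for k in range(20)]
        totals = pd.Series(rng.integers(5, 200, size=20), index=taxa, dtype=float)
        im = pd.DataFrame({"degree": totals * 2 + rng.normal(0, 1e-6, 20)}, index=taxa)
        out = abundance_correlation(totals, im)
        assert out.loc[0, "r"] > 0.999 and out.loc[0, "significant"]

    def test_constant_index_skipped_with_warning(self):
        taxa = ["t1", "t2", "t3"]
        totals = pd.Series([1.0, 2.0, 3.0], index=taxa)
        im = pd.DataFrame({"idx": [5.0, 5.0, 5.0]}, index=taxa)
        with pytest.warns(UserWarning, match="zero variance"):
            assert len(abundance_correlation(totals, im)) == 0

    def test_joint_permutation_leaves_r_unchanged(self, rng):
        taxa = [f"t{k}" for k in range(12)]
        totals = pd.Series(rng.normal(size=12), index=taxa)
        im = pd.DataFrame({"idx": rng.normal(size=12)}, index=taxa)
        base = abundance_correlation(totals, im).loc[0, "r"]
        perm = rng.permutation(taxa)
        shuffled = abundance_correlation(totals.loc[perm], im.loc[perm]).loc[0, "r"]
        assert np.isclose(base, shuffled)
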