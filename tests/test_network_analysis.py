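"""Interaction matrices, bipartite networks, degree correlation, PCC."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirframe.network_analysis import (
    build_adjacency,
    build_bipartite,
    compare_conditions,
    cross_transcript_pcc,
    degree_correlation,
    degree_profile,
    expression_pcc,
    inventories_from_fixtures,
    network_variants,
    select_pcc_genes,
)
from mirframe.synthetic_data import SimulationConfig, make_expression
from _oracles import brute_force_degree_correlation


class TestAdjacency:
    def test_empty_pairs_give_empty_matrix(self):
        assert build_adjacency([]).shape == (0, 0)

    def test_entries_follow_pair_list(self):
        matrix = build_adjacency([("m1", "t1"), ("m1", "t2"), ("m2", "t2")])
        assert matrix.loc["m1"].tolist() == [1, 1]
        assert matrix.loc["m2"].tolist() == [0, 1]

    def test_fixture_jh_matrix_marks_cmo(self, fixture_tables):
        jh, _ = inventories_from_fixtures(fixture_tables)
        matrix = build_adjacency(sorted(jh.target_pairs))
        assert matrix.loc["miR-156", "choline monooxygenase [EC:1.14.15.7]"] == 1

    def test_edge_count_conserved_into_network(self):
        matrix = build_adjacency([("m1", "t1"), ("m2", "t1"), ("m2", "t2")])
        network = build_bipartite(matrix)
        assert network.number_of_edges() == int(matrix.values.sum())

    def test_identity_matrix_network(self):
        matrix = pd.DataFrame(
            np.eye(2, dtype=int), index=["m1", "m2"], columns=["t1", "t2"]
        )
        network = build_bipartite(matrix)
        assert network.number_of_nodes() == 4
        assert network.number_of_edges() == 2

    def test_three_variants_constructible(self, fixture_tables):
        jh, jv = inventories_from_fixtures(fixture_tables)
        variants = network_variants(jh.target_pairs, jv.target_pairs)
        assert set(variants) == {"JH_unique", "JV_unique", "common"}
        jh_unique_mirnas = {
            n for n, d in variants["JH_unique"].nodes(data=True) if d["bipartite"] == 0
        }
        assert jh_unique_mirnas == {"miR-172", "miR-414", "miR-529"}


class TestCompareConditions:
    def test_fixture_comparison_counts(self, fixture_tables):
        jh, jv = inventories_from_fixtures(fixture_tables)
        cmp_ = compare_conditions(jh, jv)
        assert len(cmp_.common_mirnas) == 8
        assert cmp_.unique_mirnas["JH"] == {"miR-172", "miR-414", "miR-529"}

    def test_cmo_called_up(self, fixture_tables):
        jh, jv = inventories_from_fixtures(fixture_tables)
        cmp_ = compare_conditions(jh, jv)
        fa, fb, call = cmp_.regulation["choline monooxygenase [EC:1.14.15.7]"]
        assert (fa, fb, call) == (2092.64, 6282.87, "up")

    def test_identical_inventories_have_no_unique(self, fixture_tables):
        jh, _ = inventories_from_fixtures(fixture_tables)
        cmp_ = compare_conditions(jh, jh)
        assert all(not s for s in cmp_.unique_mirnas.values())
        assert all(not s for s in cmp_.unique_targets.values())

    def test_swapping_inputs_flips_calls(self, fixture_tables):
        jh, jv = inventories_from_fixtures(fixture_tables)
        fwd = compare_conditions(jh, jv)
        rev = compare_conditions(jv, jh)
        assert fwd.unique_mirnas["JH"] == rev.unique_mirnas["JH"]
        flip = {"up": "down", "down": "up", "unchanged": "unchanged"}
        for target, (fa, fb, call) in fwd.regulation.items():
            rb, ra, rcall = rev.regulation[target]
            assert (ra, rb) == (fa, fb)
            assert rcall == flip[call]


class TestDegreeProfile:
    def test_star_profile(self):
        profile = degree_profile(nx.star_graph(4))
        assert profile.degree[0] == 4
        assert profile.distribution == {1: 0.8, 4: 0.2}

    def test_empty_graph(self):
        profile = degree_profile(nx.Graph())
        assert profile.degree == {} and profile.distribution == {}

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(2, 30), st.integers(0, 100))
    def test_distribution_sums_to_one(self, n, seed):
        g = nx.gnm_random_graph(n, min(n * 2, n * (n - 1) // 2), seed=seed)
        profile = degree_profile(g)
        assert sum(profile.distribution.values()) == pytest.approx(1.0)


def _connected_graphs_up_to(n_max):
    """All connected graphs with 2..n_max nodes (via the networkx atlas)."""
    from networkx.generators.atlas import graph_atlas_g

    for g in graph_atlas_g():
        if 2 <= g.number_of_nodes() <= n_max and g.number_of_edges() >= 1:
            if nx.is_connected(g):
                yield g


class TestDegreeCorrelation:
    def test_star_is_minus_one(self):
        for n in (2, 3, 5, 8):
            assert degree_correlation(nx.star_graph(n)) == pytest.approx(-1.0)

    def test_path_of_three_is_minus_one(self):
        assert degree_correlation(nx.path_graph(3)) == pytest.approx(-1.0)

    def test_regular_graph_is_undefined(self):
        assert math.isnan(degree_correlation(nx.cycle_graph(6)))
        assert math.isnan(degree_correlation(nx.complete_graph(4)))

    def test_edgeless_graph_is_an_error(self):
        g = nx.Graph()
        g.add_nodes_from([1, 2])
        with pytest.raises(ValueError):
            degree_correlation(g)

    def test_matches_brute_force_on_all_small_connected_graphs(self):
        """Exhaustive small-graph suite against the independent evaluator."""
        count = 0
        for g in _connected_graphs_up_to(6):
            ours = degree_correlation(g)
            oracle = brute_force_degree_correlation(list(g.edges()))
            if oracle is None:
                assert math.isnan(ours), g.edges()
            else:
                assert ours == pytest.approx(oracle, abs=1e-9), g.edges()
                # networkx implements the same statistic
                ref = nx.degree_assortativity_coefficient(g)
                assert ours == pytest.approx(ref, abs=1e-6)
            count += 1
        assert count > 50  # the atlas really was enumerated

    def test_directed_bipartite_uses_undirected_degrees(self):
        matrix = build_adjacency([("m1", "t1"), ("m1", "t2"), ("m1", "t3")])
        network = build_bipartite(matrix)
        assert degree_correlation(network) == pytest.approx(-1.0)


class TestExpressionPcc:
    def _table(self, values_by_cond):
        rows = []
        for cond, values in values_by_cond.items():
            for i, v in enumerate(values, 1):
                rows.append(
                    {"transcript_id": "g1", "condition": cond, "replicate": i,
                     "fpkm": v}
                )
        return pd.DataFrame(rows)

    def test_identical_vectors_give_one(self):
        table = self._table({"JH": [1, 2, 3, 4], "JV": [1, 2, 3, 4]})
        assert expression_pcc(table, "g1", "JH", "JV") == pytest.approx(1.0)

    def test_negated_centered_vectors_give_minus_one(self):
        table = self._table({"JH": [1, 2, 3], "JV": [3, 2, 1]})
        assert expression_pcc(table, "g1", "JH", "JV") == pytest.approx(-1.0)

    def test_zero_variance_is_nan(self):
        table = self._table({"JH": [2, 2, 2], "JV": [1, 2, 3]})
        assert math.isnan(expression_pcc(table, "g1", "JH", "JV"))

    def test_too_few_replicates_directs_to_cross_mode(self):
        table = self._table({"JH": [1, 2], "JV": [1, 2]})
        with pytest.raises(ValueError, match="cross_transcript_pcc"):
            expression_pcc(table, "g1", "JH", "JV")

    def test_cross_transcript_mode(self):
        rows = []
        for i, (a, b) in enumerate([(1, 2), (2, 4), (3, 6), (4, 8)]):
            rows.append({"transcript_id": f"g{i}", "condition": "JH",
                         "replicate": 1, "fpkm": a})
            rows.append({"transcript_id": f"g{i}", "condition": "JV",
                         "replicate": 1, "fpkm": b})
        table = pd.DataFrame(rows)
        r = cross_transcript_pcc(table, [f"g{i}" for i in range(4)], "JH", "JV")
        assert r == pytest.approx(1.0)

    def test_planted_correlation_recovered(self, correlated_expression):
        """A planted rho = 0.95 latent factor is recovered within 0.1."""
        config, table = correlated_expression
        from mirframe.coexpression import pair_pcc

        r = pair_pcc(table, "gene001", "gene002")
        assert r == pytest.approx(0.95, abs=0.1)


class TestSelectPccGenes:
    def test_packaged_rule_reproduces_published_query_set(self, fixture_tables):
        jh, jv = inventories_from_fixtures(fixture_tables)
        cmp_ = compare_conditions(jh, jv)
        genes = select_pcc_genes(cmp_, tables=fixture_tables, rule="packaged")
        assert genes == [
            "CMO", "RPS5", "RPL9", "EIF5", "MVA1", "PPC", "PSAX", "SUMO",
            "CYP707A1", "DXS",
        ]

    def test_empty_comparison_selects_nothing(self, fixture_tables):
        from mirframe.mirna_discovery import MiRNAInventory

        empty = MiRNAInventory(condition="JH", families={})
        cmp_ = compare_conditions(empty, MiRNAInventory(condition="JV", families={}))
        assert select_pcc_genes(cmp_, tables=fixture_tables, rule="packaged") == []

    def test_pass_all_rule_returns_common_mirna_targets(self, fixture_tables):
        jh, jv = inventories_from_fixtures(fixture_tables)
        cmp_ = compare_conditions(jh, jv)
        genes = select_pcc_genes(cmp_, rule="all")
        assert set(genes) == cmp_.common_mirna_targets
        assert genes == sorted(genes)
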