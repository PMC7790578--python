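"""Centrality measures, median-consensus selection and MCC ranking."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netpharm import (
    METRICS,
    MCCRanking,
    betweenness_centrality,
    closeness_centrality,
    compute_all,
    degree_centrality,
    eigenvector_centrality,
    local_average_connectivity,
    mcc,
    median_filter,
    network_centrality,
    top_k,
)
from netpharm.errors import CliqueCapExceeded, ConvergenceError, DomainError

from conftest import random_graph
from oracles import (
    bf_betweenness,
    bf_closeness,
    bf_degree,
    bf_lac,
    bf_mcc,
    bf_median,
    bf_nc,
    check_eigenvector,
)


def two_triangles() -> nx.Graph:
    """Two triangles sharing the vertex S."""
    return nx.Graph(
        [("S", "A"), ("S", "B"), ("A", "B"), ("S", "C"), ("S", "D"), ("C", "D")]
    )


class TestClosedForms:
    def test_k5_all_metrics(self, k5):
        table = compute_all(k5)
        assert (table["dc"] == 4).all()
        assert (table["bc"] == 0).all()
        assert (table["cc"] == 1.0).all()
        assert np.allclose(table["ec"], 1 / math.sqrt(5))
        assert (table["lac"] == 3.0).all()
        # 4 incident edges, each ECC = 3/3
        assert (table["nc"] == 4.0).all()

    def test_star_centre_and_leaves(self, star5):
        bc = betweenness_centrality(star5)
        assert bc["C"] == pytest.approx(6.0)  # C(4,2) leaf pairs
        assert all(bc[f"L{i}"] == 0 for i in range(1, 5))
        cc = closeness_centrality(star5)
        assert cc["L1"] == pytest.approx(4 / 7)
        assert cc["C"] == pytest.approx(1.0)
        ec = eigenvector_centrality(star5)
        assert ec["C"] == pytest.approx(1 / math.sqrt(2), abs=1e-9)
        assert ec["L2"] == pytest.approx(1 / (2 * math.sqrt(2)), abs=1e-9)
        assert local_average_connectivity(star5)["C"] == 0.0
        assert all(v == 0 for v in network_centrality(star5).values())

    def test_triangle(self):
        g = nx.complete_graph(3)
        assert all(v == 1.0 for v in local_average_connectivity(g).values())
        assert all(v == 2.0 for v in network_centrality(g).values())

    def test_k4_network_centrality(self):
        g = nx.complete_graph(4)
        assert all(v == pytest.approx(3.0) for v in network_centrality(g).values())

    def test_single_edge(self):
        g = nx.Graph([("A", "B")])
        table = compute_all(g)
        assert (table["dc"] == 1).all()
        assert (table["bc"] == 0).all()
        assert (table["cc"] == 1.0).all()
        assert np.allclose(table["ec"], 1 / math.sqrt(2))

    def test_ecc_degenerate_flag(self, star5):
        nc1 = network_centrality(star5, degenerate_value=1.0)
        assert nc1["C"] == pytest.approx(4.0)  # all four edges fall back to 1


class TestEigenvector:
    def test_complete_graph_uniform(self):
        for n in (3, 6, 10):
            ec = eigenvector_centrality(nx.complete_graph(n))
            assert all(abs(v - 1 / math.sqrt(n)) < 1e-9 for v in ec.values())

    def test_matches_dense_solver_on_random_graph(self):
        g = random_graph(10, 0.4, seed=2)
        ec = eigenvector_centrality(g)
        check_eigenvector(g, ec, atol=1e-8)

    def test_requires_an_edge(self):
        g = nx.Graph()
        g.add_nodes_from("AB")
        with pytest.raises(DomainError):
            eigenvector_centrality(g)

    def test_nonconvergence_is_explicit(self, star5):
        with pytest.raises(ConvergenceError):
            eigenvector_centrality(star5, tol=0.0, max_iter=3)

    def test_unit_norm_and_nonnegative(self):
        g = random_graph(12, 0.25, seed=5)
        g.remove_nodes_from(list(nx.isolates(g)))
        ec = eigenvector_centrality(g)
        vec = np.array(list(ec.values()))
        assert np.all(vec >= 0)
        assert np.linalg.norm(vec) == pytest.approx(1.0, abs=1e-9)


class TestBruteForceAgreement:
    """Every metric versus its naive oracle on random graphs."""

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("p", [0.15, 0.4, 0.8])
    def test_all_metrics(self, seed, p):
        g = random_graph(8, p, seed=seed)
        assert degree_centrality(g) == bf_degree(g)
        bc, bc_o = betweenness_centrality(g), bf_betweenness(g)
        assert all(abs(bc[v] - bc_o[v]) < 1e-9 for v in g.nodes)
        cc, cc_o = closeness_centrality(g), bf_closeness(g)
        assert all(abs(cc[v] - cc_o[v]) < 1e-9 for v in g.nodes)
        lac, lac_o = local_average_connectivity(g), bf_lac(g)
        assert all(abs(lac[v] - lac_o[v]) < 1e-9 for v in g.nodes)
        nc, nc_o = network_centrality(g), bf_nc(g)
        assert all(abs(nc[v] - nc_o[v]) < 1e-9 for v in g.nodes)
        assert mcc(g).scores == bf_mcc(g)
        if g.number_of_edges():
            check_eigenvector(g, eigenvector_centrality(g))


class TestMedianFilter:
    def test_published_medians_retain_all_thirteen(self, table2):
        medians = table2.attrs["medians"]
        for rule in ("inclusive", "strict"):
            sel = median_filter(table2, rule=rule, medians=medians)
            assert len(sel.retained) == 13
        sel = median_filter(table2, medians=medians)
        assert sel.retained[0] == "FOS"  # highest degree first

    def test_node_maximal_in_all_metrics_always_retained(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            rng.uniform(0, 1, size=(9, 6)), columns=list(METRICS),
            index=[f"N{i}" for i in range(9)],
        )
        table.loc["TOP"] = 2.0
        for rule in ("inclusive", "strict"):
            assert "TOP" in median_filter(table, rule=rule).retained

    def test_medians_match_sort_based_oracle(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(
            rng.normal(size=(5, 6)), columns=list(METRICS),
            index=[f"N{i}" for i in range(5)],
        )
        sel = median_filter(table)
        for m in METRICS:
            assert sel.medians[m] == pytest.approx(bf_median(table[m]))

    def test_even_count_median_is_mean_of_middle_two(self):
        table = pd.DataFrame(
            {m: [1.0, 2.0, 4.0, 8.0] for m in METRICS},
            index=["A", "B", "C", "D"],
        )
        assert median_filter(table).medians["dc"] == pytest.approx(3.0)

    def test_retained_small_under_independent_metrics(self):
        # with 6 independent continuous metrics, joint above-median
        # membership is rare (~n/64 expected); never above ceil(n/2)
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(8, 40))
            table = pd.DataFrame(
                rng.normal(size=(n, 6)), columns=list(METRICS),
                index=[f"N{i}" for i in range(n)],
            )
            assert len(median_filter(table).retained) <= math.ceil(n / 2)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            median_filter(pd.DataFrame(columns=list(METRICS)))


class TestMCC:
    def test_k5_single_maximal_clique(self, k5):
        assert all(v == 24 for v in mcc(k5).scores.values())

    def test_star(self, star5):
        scores = mcc(star5).scores
        assert scores["C"] == 4
        assert all(scores[f"L{i}"] == 1 for i in range(1, 5))

    def test_two_triangles_sharing_vertex(self):
        scores = mcc(two_triangles()).scores
        assert scores["S"] == 4  # two maximal triangles, 2! each
        assert all(scores[v] == 2 for v in "ABCD")

    def test_isolated_node_scores_zero(self):
        g = nx.Graph([("A", "B")])
        g.add_node("Z")
        assert mcc(g).scores["Z"] == 0

    def test_clique_components_closed_form(self):
        g = nx.disjoint_union_all(
            [nx.complete_graph(k) for k in (2, 3, 5)]
        )
        sizes = [2] * 2 + [3] * 3 + [5] * 5
        scores = mcc(g).scores
        for node, size in zip(sorted(scores), sizes):
            assert scores[node] == math.factorial(size - 1)

    def test_cap_is_enforced(self):
        g = nx.complete_multipartite_graph(2, 2, 2, 2)  # many maximal cliques
        with pytest.raises(CliqueCapExceeded):
            mcc(g, max_cliques=3)


class TestTopK:
    def test_clique_beats_isolated_edge(self, k5):
        g = nx.union(k5, nx.Graph([("X", "Y")]))
        top = top_k(mcc(g), 5)
        assert set(top) == {f"N{i}" for i in range(5)}

    def test_all_equal_mcc_alphabetical(self):
        ranking = MCCRanking(
            scores={v: 1 for v in "DBCA"}, degrees={v: 1 for v in "DBCA"}
        )
        assert top_k(ranking, 2) == ["A", "B"]

    def test_degree_breaks_mcc_ties(self):
        ranking = MCCRanking(
            scores={"A": 2, "B": 2}, degrees={"A": 1, "B": 3}
        )
        assert top_k(ranking, 1) == ["B"]

    def test_k_bounds(self, k5):
        ranking = mcc(k5)
        with pytest.raises(ValueError):
            top_k(ranking, 0)
        with pytest.raises(ValueError):
            top_k(ranking, 6)


class TestComputeAll:
    def test_empty_graph_gives_empty_table(self):
        assert compute_all(nx.Graph()).empty

    def test_table_round_trip(self, tmp_path, k5):
        table = compute_all(k5)
        path = tmp_path / "centrality.tsv"
        table.to_csv(path, sep="\t")
        back = pd.read_csv(path, sep="\t", index_col=0)
        pd.testing.assert_frame_equal(table, back, check_names=False)
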