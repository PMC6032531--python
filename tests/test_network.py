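"""Edge filtering, centralities and the two-stage candidate-gene rule."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from tgsig import (
    build_network,
    compute_topology,
    filter_edges_by_median,
    select_candidates,
    select_major_genes,
)
from tgsig._exceptions import DataError, EmptyInputError, MissingRecordError
from tgsig.datasets import SIGNATURE_GENES, load_major_gene_table
from tgsig.network import read_edge_table


def edges_df(pairs):
    return pd.DataFrame(pairs, columns=["gene_a", "gene_b", "combined_score"])


class TestMedianFilter:
    def test_strictly_above_median(self):
        edges = edges_df([(f"a{i}", f"b{i}", s) for i, s in enumerate([1, 2, 3, 4, 5])])
        out = filter_edges_by_median(edges)
        assert sorted(out["combined_score"]) == [4, 5]

    def test_all_equal_scores_empty_result(self):
        edges = edges_df([(f"a{i}", f"b{i}", 7) for i in range(10)])
        assert len(filter_edges_by_median(edges)) == 0

    def test_empty_input_raises(self):
        with pytest.raises(EmptyInputError):
            filter_edges_by_median(edges_df([]))

    def test_matches_bruteforce_and_size_bound(self):
        rng = np.random.default_rng(0)
        scores = rng.integers(150, 1000, size=1000)
        edges = edges_df([(f"a{i}", f"b{i}", s) for i, s in enumerate(scores)])
        out = filter_edges_by_median(edges)
        med = float(np.median(scores))
        assert set(out.index.size for _ in [0]) and len(out) == sum(s > med for s in scores)
        assert len(out) <= (len(edges) + 1) // 2

    def test_self_loops_rejected(self):
        with pytest.raises(DataError):
            filter_edges_by_median(edges_df([("a", "a", 5), ("a", "b", 6)]))


class TestBuildNetwork:
    def test_drops_edges_leaving_deg_set_and_dedups(self):
        edges = edges_df(
            [("A", "B", 900), ("B", "A", 901), ("A", "X", 950), ("B", "C", 800)]
        )
        net = build_network(["A", "B", "C", "D"], edges)
        assert set(net.nodes) == {"A", "B", "C"}  # D isolated, X not a DEG
        assert net.number_of_edges() == 2
        assert net.number_of_nodes() <= 4


class TestTopology:
    def test_path_graph_enumerable(self):
        net = build_network(["A", "B", "C"], edges_df([("A", "B", 9), ("B", "C", 9)]))
        topo = compute_topology(net)
        assert topo.loc["B", "degree"] == 2
        assert topo.loc["B", "betweenness"] == 1.0
        assert topo.loc["A", "betweenness"] == topo.loc["C", "betweenness"] == 0.0
        # closeness (nc-1)/sum(d): B -> 2/2, A -> 2/3
        assert np.isclose(topo.loc["B", "closeness"], 1.0)
        assert np.isclose(topo.loc["A", "closeness"], 2 / 3)

    def test_complete_graph_symmetry(self):
        nodes = list("ABCD")
        edges = edges_df([(a, b, 9) for a, b in itertools.combinations(nodes, 2)])
        topo = compute_topology(build_network(nodes, edges))
        assert topo["closeness"].nunique() == 1
        assert (topo["betweenness"] == 0).all()

    def test_weighted_degree_sums_scores(self):
        net = build_network(["A", "B", "C"], edges_df([("A", "B", 10), ("A", "C", 20)]))
        topo = compute_topology(net, weighted_degree=True)
        assert topo.loc["A", "degree"] == 30.0

    @pytest.mark.parametrize("seed", range(10))
    def test_betweenness_matches_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(0, 2**31)))
        net = nx.Graph()
        net.add_nodes_from(g.nodes)
        net.add_edges_from(g.edges, combined_score=500.0)
        if net.number_of_nodes() == 0:
            pytest.skip("empty draw")
        topo = compute_topology(net)
        # oracle: enumerate every shortest path for every pair
        expected = {v: 0.0 for v in net.nodes}
        for s, t in itertools.combinations(net.nodes, 2):
            if not nx.has_path(net, s, t):
                continue
            paths = list(nx.all_shortest_paths(net, s, t))
            for v in net.nodes:
                if v in (s, t):
                    continue
                expected[v] += sum(v in p for p in paths) / len(paths)
        for v in net.nodes:
            assert np.isclose(topo.loc[str(v) if isinstance(v, str) else v, "betweenness"],
                              expected[v])

    def test_centralities_invariant_under_relabeling(self):
        edges = edges_df(
            [("A", "B", 9), ("B", "C", 9), ("C", "D", 9), ("B", "D", 9), ("D", "E", 9)]
        )
        mapping = {"A": "V", "B": "W", "C": "X", "D": "Y", "E": "Z"}
        renamed = edges.replace(mapping)
        t1 = compute_topology(build_network(list("ABCDE"), edges))
        t2 = compute_topology(build_network(list("VWXYZ"), renamed))
        for feat in ("degree", "closeness", "betweenness"):
            for old, new in mapping.items():
                assert np.isclose(t1.loc[old, feat], t2.loc[new, feat])


class TestMajorGenes:
    def test_identical_topology_selects_nothing(self):
        records = pd.DataFrame(
            {"gene_id": list("ABCD"), "degree": 2, "closeness": 0.5, "betweenness": 1.0}
        ).set_index("gene_id", drop=False)
        assert select_major_genes(records) == []

    def test_matches_bruteforce_triple_predicate(self):
        rng = np.random.default_rng(4)
        records = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(200)],
                "degree": rng.integers(1, 10, 200),
                "closeness": rng.uniform(0, 1, 200),
                "betweenness": rng.uniform(0, 30, 200),
            }
        ).set_index("gene_id", drop=False)
        expected = sorted(
            r.gene_id
            for r in records.itertuples()
            if r.degree > records["degree"].median()
            and r.closeness > records["closeness"].median()
            and r.betweenness > records["betweenness"].median()
        )
        assert select_major_genes(records) == expected

    def test_planted_dominant_hub_selected(self):
        records = pd.DataFrame(
            {
                "gene_id": ["hub"] + [f"g{i}" for i in range(9)],
                "degree": [20] + [2] * 9,
                "closeness": [0.9] + list(np.linspace(0.1, 0.5, 9)),
                "betweenness": [50.0] + list(np.linspace(0, 2, 9)),
            }
        ).set_index("gene_id", drop=False)
        assert "hub" in select_major_genes(records)


class TestCandidates:
    def test_worked_example_selects_the_six_gene_signature(self):
        table = load_major_gene_table()
        out = select_candidates(list(table["gene_id"]), table, 1.5, 0.05)
        assert out == sorted(SIGNATURE_GENES)

    def test_downregulated_gene_below_reciprocal_threshold_included(self):
        table = load_major_gene_table()
        assert "MX1" in select_candidates(list(table["gene_id"]), table)
        assert float(table.loc["MX1", "fc"]) == 0.55

    def test_fold_change_boundary_is_strict(self):
        records = pd.DataFrame(
            {"gene_id": ["at", "above"], "fc": [1.5, 1.51], "p_value": [0.01, 0.01]}
        ).set_index("gene_id", drop=False)
        assert select_candidates(["at", "above"], records) == ["above"]

    def test_missing_record_names_gene(self):
        records = pd.DataFrame(
            {"gene_id": ["A"], "fc": [2.0], "p_value": [0.01]}
        ).set_index("gene_id", drop=False)
        with pytest.raises(MissingRecordError, match="B"):
            select_candidates(["A", "B"], records)

    def test_selection_subset_chain(self, small_cohort):
        from tgsig import rvm_ttest, screen_degs

        deg_table = rvm_ttest(small_cohort.expression)
        degs = screen_degs(deg_table)
        filtered = filter_edges_by_median(small_cohort.edges)
        net = build_network(list(degs["gene_id"]), filtered)
        topo = compute_topology(net)
        major = select_major_genes(topo)
        cand = select_candidates(major, deg_table)
        assert set(cand) <= set(major) <= set(net.nodes) <= set(degs["gene_id"])


def test_read_edge_table_dialects(tmp_path):
    tsv = tmp_path / "edges.tsv"
    tsv.write_text("gene_a\tgene_b\tcombined_score\nA\tB\t900\nB\tC\t400\n")
    string_style = tmp_path / "links.txt"
    string_style.write_text("protein1 protein2 combined_score\nA B 900\nB C 400\n")
    headerless = tmp_path / "plain.tsv"
    headerless.write_text("A\tB\t900\nB\tC\t400\n")
    frames = [read_edge_table(p) for p in (tsv, string_style, headerless)]
    for df in frames[1:]:
        pd.testing.assert_frame_equal(frames[0], df)
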