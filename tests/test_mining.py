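import numpy as np
import pandas as pd
import pytest

from mirmod import (
    DOWN,
    GENE,
    MIRNA,
    NONE,
    UP,
    ClosedSubgraphMiner,
    Pattern,
    absolute_min_support,
    contains,
    merge_comodule,
    mine_closed_frequent,
    mining_summary,
    occurrence_score,
    pattern_significance,
    support_percent,
)
from mirmod.mining import read_patterns, write_patterns

from conftest import brute_force_mine, make_patient_graph, make_template


def star_template(n_genes=4, sign="-"):
    return make_template([("m1", f"g{i + 1}", sign) for i in range(n_genes)])


def worked_example():
    """One miRNA negatively targeting g1..g4; three nested patient graphs."""
    template = star_template(4)
    graphs = [
        make_patient_graph(
            "P1", {"m1": DOWN, "g1": UP, "g2": UP, "g3": UP, "g4": UP}, template
        ),
        make_patient_graph(
            "P2", {"m1": DOWN, "g1": UP, "g2": UP, "g3": UP}, template
        ),
        make_patient_graph("P3", {"m1": DOWN, "g1": UP, "g2": UP}, template),
    ]
    return template, graphs


def random_instance(rng, n_mirnas=3, n_genes=8, n_patients=8, edge_p=0.5, tag_p=0.35):
    edges = []
    for i in range(n_mirnas):
        for j in range(n_genes):
            if rng.random() < edge_p:
                edges.append((f"m{i}", f"g{j}", rng.choice(["+", "-"])))
    if not edges:
        edges = [("m0", "g0", "-")]
    template = make_template(edges)
    features = [f"m{i}" for i in range(n_mirnas)] + [f"g{j}" for j in range(n_genes)]
    graphs = []
    for p in range(n_patients):
        tags = {
            f: rng.choice([UP, DOWN]) if rng.random() < tag_p else NONE
            for f in features
        }
        graphs.append(make_patient_graph(f"P{p}", tags, template))
    return template, graphs


class TestSupportConversion:
    def test_fraction_to_absolute_by_ceiling(self):
        assert absolute_min_support(0.066, 196) == 13
        assert absolute_min_support(5, 100) == 5

    def test_absolute_to_percent(self):
        assert round(support_percent(13, 196), 1) == 6.6
        assert round(support_percent(14, 96), 1) == 14.6

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            absolute_min_support(1.5, 10)


class TestContains:
    def test_subset_with_induced_edges(self):
        template, graphs = worked_example()
        pattern = Pattern(
            frozenset({("m1", MIRNA, DOWN), ("g1", GENE, UP)}),
            frozenset({("m1", "g1")}),
            0,
            frozenset(),
        )
        assert all(contains(pattern, g) for g in graphs)

    def test_tag_mismatch_fails(self):
        template, graphs = worked_example()
        pattern = Pattern(
            frozenset({("g1", GENE, DOWN)}), frozenset(), 0, frozenset()
        )
        assert not any(contains(pattern, g) for g in graphs)

    def test_empty_pattern_contained_everywhere(self):
        _, graphs = worked_example()
        empty = Pattern(frozenset(), frozenset(), 0, frozenset())
        assert all(contains(empty, g) for g in graphs)


class TestMineClosedFrequent:
    def test_worked_example_exact_pattern_set(self):
        template, graphs = worked_example()
        patterns = mine_closed_frequent(graphs, template, 2, min_gene_nodes=2)
        by_nodes = {p.node_ids: p for p in patterns}
        assert set(by_nodes) == {
            frozenset({("m1", DOWN), ("g1", UP), ("g2", UP)}),
            frozenset({("m1", DOWN), ("g1", UP), ("g2", UP), ("g3", UP)}),
        }
        small = by_nodes[frozenset({("m1", DOWN), ("g1", UP), ("g2", UP)})]
        assert small.support == 3 and small.patients == {"P1", "P2", "P3"}
        large = by_nodes[frozenset({("m1", DOWN), ("g1", UP), ("g2", UP), ("g3", UP)})]
        assert large.support == 2 and large.patients == {"P1", "P2"}

    def test_min_support_above_cohort_size(self):
        template, graphs = worked_example()
        assert mine_closed_frequent(graphs, template, 4, 0) == []

    def test_single_patient_yields_its_components(self):
        template = make_template([("m1", "g1", "-"), ("m2", "g2", "-")])
        g = make_patient_graph(
            "P1", {"m1": DOWN, "g1": UP, "m2": DOWN, "g2": UP}, template
        )
        patterns = mine_closed_frequent([g], template, 1, 0)
        assert {p.node_ids for p in patterns} == {
            frozenset({("m1", DOWN), ("g1", UP)}),
            frozenset({("m2", DOWN), ("g2", UP)}),
        }
        assert all(p.support == 1 for p in patterns)

    def test_empty_graph_list(self):
        template = star_template()
        assert mine_closed_frequent([], template, 1, 0) == []

    def test_anti_monotonicity_of_support(self):
        rng = np.random.default_rng(21)
        template, graphs = random_instance(rng)
        patterns = mine_closed_frequent(graphs, template, 2, 0)
        support_of = {
            frozenset(n for n in p.nodes): p.support for p in patterns
        }
        for p in patterns:
            for drop in p.nodes:  # connected sub-patterns of size-1 less
                sub = frozenset(p.nodes) - {drop}
                if not sub:
                    continue
                count = sum(
                    1
                    for g in graphs
                    if {(f, t) for f, _, t in sub} <= g.node_ids
                )
                assert count >= p.support

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("min_support,min_gene_nodes", [(1, 0), (2, 1), (3, 2)])
    def test_matches_brute_force_enumeration(self, seed, min_support, min_gene_nodes):
        rng = np.random.default_rng(seed)
        template, graphs = random_instance(rng)
        mined = {
            p.nodes: p.support
            for p in mine_closed_frequent(graphs, template, min_support, min_gene_nodes)
        }
        oracle = brute_force_mine(graphs, template, min_support, min_gene_nodes)
        assert mined == oracle

    def test_support_equals_subgraph_isomorphism_count(self):
        # identity labels collapse isomorphism to containment; cross-check
        # against networkx's generic matcher on the induced graphs
        import networkx as nx
        from networkx.algorithms.isomorphism import GraphMatcher, categorical_node_match

        rng = np.random.default_rng(5)
        template, graphs = random_instance(rng, n_patients=5)
        patterns = mine_closed_frequent(graphs, template, 2, 0)
        match = categorical_node_match(["feature", "tag"], [None, None])
        for p in patterns[:10]:
            pat_g = nx.Graph()
            for f, _, tag in p.nodes:
                pat_g.add_node(f, feature=f, tag=tag)
            pat_g.add_edges_from(p.edges)
            iso_count = 0
            for g in graphs:
                host = nx.Graph()
                for f, _, tag in g.nodes:
                    host.add_node(f, feature=f, tag=tag)
                host.add_edges_from(g.edges)
                if GraphMatcher(host, pat_g, node_match=match).subgraph_is_monomorphic():
                    iso_count += 1
            assert iso_count == p.support

    def test_miner_estimator_wrapper(self):
        template, graphs = worked_example()
        miner = ClosedSubgraphMiner(min_support=2, min_gene_nodes=2)
        assert miner.get_params()["min_support"] == 2
        miner.fit(graphs, template)
        assert len(miner.patterns_) == 2
        assert miner.summary_["n_patterns"] == 2
        with pytest.raises(ValueError):
            miner.set_params(bogus=1)


class TestPatternSignificance:
    def test_saturated_pattern_has_p_one(self):
        tag_table = pd.DataFrame(
            {"m1": [DOWN] * 5, "g1": [UP] * 5},
            index=[f"P{i}" for i in range(5)],
        )
        pattern = Pattern(
            frozenset({("m1", MIRNA, DOWN), ("g1", GENE, UP)}),
            frozenset({("m1", "g1")}),
            5,
            frozenset(tag_table.index),
        )
        assert pattern_significance(pattern, tag_table, n_perm=200, rng=0) == 1.0

    def test_coordinated_rare_tags_are_significant(self):
        # each tag occurs in 6/40 patients, always the same 6: far beyond the
        # independence null whose expected joint support is 40*(6/40)^3 ~ 0.1
        n = 40
        idx = [f"P{i}" for i in range(n)]
        col = np.array([UP] * 6 + [NONE] * (n - 6))
        tag_table = pd.DataFrame({"g1": col, "g2": col, "g3": col}, index=idx)
        pattern = Pattern(
            frozenset({("g1", GENE, UP), ("g2", GENE, UP), ("g3", GENE, UP)}),
            frozenset(),
            6,
            frozenset(idx[:6]),
        )
        p = pattern_significance(pattern, tag_table, n_perm=500, rng=1)
        assert p < 0.01

    def test_zero_support_pattern_has_p_one(self):
        tag_table = pd.DataFrame({"g1": [NONE, NONE]}, index=["P0", "P1"])
        pattern = Pattern(frozenset({("g1", GENE, UP)}), frozenset(), 0, frozenset())
        assert pattern_significance(pattern, tag_table, n_perm=99, rng=2) == 1.0


class TestMergeAndScores:
    def test_union_of_worked_example(self):
        template, graphs = worked_example()
        patterns = mine_closed_frequent(graphs, template, 2, 2)
        com = merge_comodule(patterns)
        assert {f for f, _, _ in com.nodes} == {"m1", "g1", "g2", "g3"}
        assert len(com.edges) == 3

    def test_single_pattern_identity(self):
        template, graphs = worked_example()
        patterns = mine_closed_frequent(graphs, template, 3, 2)
        com = merge_comodule(patterns)
        assert com.nodes == patterns[0].nodes
        assert com.edges == patterns[0].edges

    def test_disjoint_patterns_add_up(self):
        a = Pattern(frozenset({("g1", GENE, UP)}), frozenset(), 1, frozenset({"P"}))
        b = Pattern(frozenset({("g2", GENE, DOWN)}), frozenset(), 1, frozenset({"P"}))
        assert len(merge_comodule([a, b]).nodes) == 2

    def test_occurrence_score_ratio(self):
        template, graphs = worked_example()
        pattern = mine_closed_frequent(graphs, template, 2, 3)[0]  # m1+g1..g3
        assert occurrence_score(pattern, graphs[0]) == 1.0
        assert occurrence_score(pattern, graphs[2]) == pytest.approx(3 / 4)
        empty_graph = make_patient_graph("PX", {}, template)
        assert occurrence_score(pattern, empty_graph) == 0.0

    def test_empty_pattern_rejected(self):
        _, graphs = worked_example()
        empty = Pattern(frozenset(), frozenset(), 0, frozenset())
        with pytest.raises(ValueError):
            occurrence_score(empty, graphs[0])


class TestMiningSummary:
    def test_single_pattern_ratio(self):
        nodes = frozenset(
            {("m1", MIRNA, DOWN)} | {(f"g{i}", GENE, UP) for i in range(1, 5)}
        )
        p = Pattern(nodes, frozenset(), 3, frozenset({"P1"}))
        summary = mining_summary([p])
        assert summary["n_vertices"] == 5
        assert summary["mean_patterns_per_vertex"] == pytest.approx(0.2)

    def test_empty_input(self):
        summary = mining_summary([])
        assert summary["n_patterns"] == 0
        assert np.isnan(summary["mean_patterns_per_vertex"])


def test_pattern_jsonl_round_trip(tmp_path):
    template, graphs = worked_example()
    patterns = mine_closed_frequent(graphs, template, 2, 2)
    path = tmp_path / "patterns.jsonl"
    write_patterns(patterns, path)
    back = read_patterns(path)
    assert {(p.nodes, p.edges, p.support, p.patients) for p in back} == {
        (p.nodes, p.edges, p.support, p.patients) for p in patterns
    }
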