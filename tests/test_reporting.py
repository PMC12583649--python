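import numpy as np
import pandas as pd
import pytest

import coregflow as cf
from coregflow.reporting import read_graphml


def _prog(target, acts, reps=()):
    return cf.LocalProgram(target, frozenset(acts), frozenset(reps))


def _dirs(rows):
    """rows: feature_id -> (delta, class)"""
    return pd.DataFrame(
        {
            "feature_id": list(rows),
            "mean_A": 0.0,
            "mean_B": [rows[r][0] for r in rows],
            "delta": [rows[r][0] for r in rows],
            "log2_fc": np.nan,
            "t_value": 1.0,
            "p_value": 0.01,
            "adj_p": 0.01,
            "class": [rows[r][1] for r in rows],
        }
    )


class TestBuildGraph:
    def test_shared_targets_and_ppi_typing(self):
        programs = {f"g{i}": _prog(f"g{i}", {"a", "b"}) for i in range(30)}
        net = cf.RegulatoryNetwork(programs)
        ev = cf.EvidenceSet(set(), {("a", "b", "x")})
        graph = cf.build_coreg_graph(net, _dirs({"a": (1.0, "up"), "b": (0.8, "up")}), ev)
        edge = graph.edges[("a", "b")]
        assert edge["shared_target_count"] == 30
        assert edge["types"] == frozenset({"ppi_evidence"})
        assert graph.nodes["a"]["n_targets"] == 30

    def test_no_shared_targets_no_edge(self):
        net = cf.RegulatoryNetwork({"g1": _prog("g1", {"a"}), "g2": _prog("g2", {"b"})})
        graph = cf.build_coreg_graph(
            net, _dirs({"a": (1.0, "up"), "b": (1.0, "up")}), cf.EvidenceSet()
        )
        assert graph.edges == {}

    def test_inferred_only_default_type(self):
        net = cf.RegulatoryNetwork({"g1": _prog("g1", {"a", "b"})})
        graph = cf.build_coreg_graph(
            net, _dirs({"a": (1.0, "up"), "b": (1.0, "up")}), cf.EvidenceSet()
        )
        assert graph.edges[("a", "b")]["types"] == frozenset({"inferred_only"})

    def test_transcriptional_evidence_direction(self):
        # regulator b's own gene is an evidenced target of a
        net = cf.RegulatoryNetwork({"g1": _prog("g1", {"a", "b"})})
        ev = cf.EvidenceSet({("a", "b", "chip")}, set())
        graph = cf.build_coreg_graph(
            net, _dirs({"a": (1.0, "up"), "b": (1.0, "up")}), ev
        )
        edge = graph.edges[("a", "b")]
        assert "transcriptional_evidence" in edge["types"]
        assert edge["tx_direction"] == "a>b"

    def test_ns_regulators_excluded(self):
        net = cf.RegulatoryNetwork({"g1": _prog("g1", {"a", "b"})})
        graph = cf.build_coreg_graph(
            net, _dirs({"a": (1.0, "up"), "b": (0.1, "ns")}), cf.EvidenceSet()
        )
        assert set(graph.nodes) == {"a"}

    def test_n_targets_consistent_with_network(self, default_bundle):
        run = default_bundle[0]
        graph = cf.build_coreg_graph(run["network"], run["dirs"], run["evidence"])
        view = run["network"].regulon_view()
        for r, attrs in graph.nodes.items():
            a, i = view[r]
            assert attrs["n_targets"] == len(a | i)


def _graph_from_edges(up_nodes, edges, down_nodes=()):
    nodes = {n: {"n_targets": 5, "delta_influence": 1.0, "class": "up"} for n in up_nodes}
    nodes |= {n: {"n_targets": 5, "delta_influence": -1.0, "class": "down"} for n in down_nodes}
    e = {
        tuple(sorted(pair)): {
            "types": frozenset({"inferred_only"}),
            "shared_target_count": 1,
            "tx_direction": "",
        }
        for pair in edges
    }
    return cf.CoRegulatoryGraph(nodes, e)


def _brute_components(nodes, edges):
    """Independent component finder: iterate closure by hand."""
    comps = []
    remaining = set(nodes)
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    while remaining:
        start = min(remaining)
        comp, stack = set(), [start]
        while stack:
            n = stack.pop()
            if n in comp:
                continue
            comp.add(n)
            stack.extend(adj[n] - comp)
        comps.append(comp)
        remaining -= comp
    return comps


class TestExtractNode:
    def test_largest_component(self):
        g = _graph_from_edges("abcdef", [("a", "b"), ("b", "c"), ("d", "e")])
        members, size = cf.extract_regulatory_node(g, "up")
        assert members == {"a", "b", "c"} and size == 3

    def test_six_member_clique(self):
        import itertools

        nodes = [f"r{i}" for i in range(6)]
        g = _graph_from_edges(nodes, list(itertools.combinations(nodes, 2)))
        members, size = cf.extract_regulatory_node(g, "up")
        assert size == 6

    def test_no_up_nodes_gives_empty(self):
        g = _graph_from_edges([], [], down_nodes=["x"])
        members, size = cf.extract_regulatory_node(g, "up")
        assert members == set() and size == 0

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(2, 13))
            nodes = [f"n{i}" for i in range(n)]
            edges = [
                (nodes[i], nodes[j])
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.25
            ]
            g = _graph_from_edges(nodes, edges)
            members, size = cf.extract_regulatory_node(g, "up")
            comps = _brute_components(nodes, edges)
            best = sorted(comps, key=lambda c: (-len(c), min(c)))[0]
            assert members == best and size == len(best)


class TestMeanGroupInfluence:
    def test_arithmetic_mean_of_deltas(self):
        dirs = _dirs({"a": (1.0, "up"), "b": (2.0, "up"), "c": (3.0, "up")})
        assert cf.mean_group_influence({"a", "b", "c"}, dirs) == 2.0

    def test_single_member(self):
        dirs = _dirs({"a": (1.5, "up")})
        assert cf.mean_group_influence({"a"}, dirs) == 1.5

    def test_empty_node_rejected(self):
        with pytest.raises(cf.CoregflowError):
            cf.mean_group_influence(set(), _dirs({"a": (1.0, "up")}))

    def test_planted_node_exceeds_background(self, default_bundle):
        run = default_bundle[0]
        graph = cf.build_coreg_graph(run["network"], run["dirs"], run["evidence"])
        members, _ = cf.extract_regulatory_node(graph, "up")
        mgi = cf.mean_group_influence(members, run["dirs"])
        assert mgi > run["dirs"]["delta"].mean()


class TestExportGraph:
    def _sample_graph(self):
        g = _graph_from_edges("abc", [("a", "b"), ("b", "c")])
        g.edges[("a", "b")] = {
            "types": frozenset({"ppi_evidence", "transcriptional_evidence"}),
            "shared_target_count": 4,
            "tx_direction": "a>b",
        }
        return g

    def test_graphml_round_trip(self, tmp_path):
        g = self._sample_graph()
        cf.export_graph(g, tmp_path / "g.graphml", "graphml")
        back = read_graphml(tmp_path / "g.graphml")
        assert back.nodes == g.nodes
        assert back.edges == g.edges

    def test_sif_row_count_is_total_types(self, tmp_path):
        g = self._sample_graph()  # edge a-b has 2 types, b-c has 1
        cf.export_graph(g, tmp_path / "g.sif", "sif")
        rows = (tmp_path / "g.sif").read_text().splitlines()
        assert len(rows) == 3

    def test_empty_graph_exports_valid_documents(self, tmp_path):
        g = cf.CoRegulatoryGraph({}, {})
        cf.export_graph(g, tmp_path / "g.graphml", "graphml")
        cf.export_graph(g, tmp_path / "g.sif", "sif")
        assert read_graphml(tmp_path / "g.graphml").nodes == {}
        assert (tmp_path / "g.sif").read_text() == ""

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(cf.CoregflowError):
            cf.export_graph(cf.CoRegulatoryGraph({}, {}), tmp_path / "g.x", "dot")


class TestTargetMatrix:
    def _setup(self):
        net = cf.RegulatoryNetwork(
            {
                "g1": _prog("g1", {"r1"}),
                "g2": _prog("g2", set(), {"r1"}),
                "g3": _prog("g3", {"r2"}, set()),
                "g4": _prog("g4", {"r1"}, {"r2"}),
            }
        )
        samples = ["s1", "s2"]
        expr = cf.ExpressionDataset(
            pd.DataFrame(
                np.arange(10.0).reshape(5, 2),
                index=["g1", "g2", "g3", "g4", "g5"],
                columns=samples,
            )
        )
        degs = pd.DataFrame(
            {
                "feature_id": ["g1", "g2", "g3", "g4", "g5"],
                "log2_fc": [1.0, -2.0, 0.1, 3.0, 5.0],
                "class": ["up", "down", "ns", "up", "up"],
            }
        )
        return net, expr, degs

    def test_direction_annotations(self):
        net, expr, degs = self._setup()
        sub, directions = cf.target_matrix(net, expr, degs, {"r1"})
        d = {(r.gene, r.regulator): r.sign for r in directions.itertuples()}
        assert d[("g1", "r1")] == 1
        assert d[("g2", "r1")] == -1
        assert "g3" not in set(directions["gene"])  # ns gene excluded

    def test_multi_label_gene(self):
        net, expr, degs = self._setup()
        _, directions = cf.target_matrix(net, expr, degs, {"r1", "r2"})
        g4 = directions[directions["gene"] == "g4"]
        assert set(zip(g4["regulator"], g4["sign"])) == {("r1", 1), ("r2", -1)}

    def test_ordering_and_truncation(self):
        net, expr, degs = self._setup()
        sub, _ = cf.target_matrix(net, expr, degs, {"r1"})
        # up genes first, |log2_fc| descending: g4 (3.0) before g1 (1.0)
        assert list(sub.index) == ["g4", "g1", "g2"]
        sub1, _ = cf.target_matrix(net, expr, degs, {"r1"}, top_n=1)
        assert list(sub1.index) == ["g4"]

    def test_unknown_regulator_rejected(self):
        net, expr, degs = self._setup()
        with pytest.raises(cf.CoregflowError):
            cf.target_matrix(net, expr, degs, {"rX"})

    def test_empty_selection_is_valid(self):
        net, expr, degs = self._setup()
        degs_ns = degs.assign(**{"class": "ns"})
        sub, directions = cf.target_matrix(net, expr, degs_ns, {"r1"})
        assert sub.empty and directions.empty
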