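import json
import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plexrank.core import (
    build_transition,
    multiplex_pagerank,
    pagerank_seeded,
    restart_vector,
    union_node_order,
)
from plexrank.graph_io import (
    GraphIOError,
    SeedSet,
    WeightedNetwork,
    build_network,
    read_edge_list,
    read_rank_table,
    read_seeds,
    write_edge_list,
    write_module_report,
    write_rank_table,
)
from plexrank.mining import Module, ModuleEdge


def write_lines(tmp_path, name, lines):
    path = tmp_path / name
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadEdgeList:
    def test_duplicate_identical_weight_merged(self, tmp_path):
        path = write_lines(tmp_path, "e.tsv", ["g1\tg2\t0.8", "g2\tg1\t0.8"])
        net = read_edge_list(path, "A")
        assert net.n_edges == 1
        assert net.weight("g1", "g2") == 0.8

    def test_self_loop_dropped_with_warning(self, tmp_path, caplog):
        path = write_lines(tmp_path, "e.tsv", ["g1\tg1\t0.5"])
        with caplog.at_level(logging.WARNING):
            net = read_edge_list(path, "A")
        assert net.n_edges == 0
        assert net.nodes == {"g1"}
        assert any("self-loop" in r.message for r in caplog.records)

    def test_negative_weight_reports_line(self, tmp_path):
        path = write_lines(tmp_path, "e.tsv", ["g1\tg2\t-0.3"])
        with pytest.raises(GraphIOError, match=r":1.*negative"):
            read_edge_list(path, "A")

    def test_conflicting_duplicates_keep_max(self, tmp_path, caplog):
        path = write_lines(tmp_path, "e.tsv", ["g1\tg2\t0.3", "g2\tg1\t0.9"])
        with caplog.at_level(logging.WARNING):
            net = read_edge_list(path, "A")
        assert net.weight("g1", "g2") == 0.9
        assert any("duplicate" in r.message for r in caplog.records)

    def test_header_detected(self, tmp_path):
        path = write_lines(tmp_path, "e.tsv", ["source\ttarget\tweight", "g1\tg2\t1.5"])
        net = read_edge_list(path, "A")
        assert net.n_edges == 1

    def test_any_whitespace_separator(self, tmp_path):
        path = write_lines(tmp_path, "e.tsv", ["g1   g2  0.25"])
        assert read_edge_list(path, "A").weight("g1", "g2") == 0.25

    def test_non_numeric_weight(self, tmp_path):
        path = write_lines(tmp_path, "e.tsv", ["g1\tg2\t0.5", "g3\tg4\tx"])
        with pytest.raises(GraphIOError, match="non-numeric"):
            read_edge_list(path, "A")

    def test_missing_file(self, tmp_path):
        with pytest.raises(GraphIOError, match="not found"):
            read_edge_list(tmp_path / "nope.tsv", "A")

    def test_zero_weight_dropped(self, tmp_path):
        path = write_lines(tmp_path, "e.tsv", ["g1\tg2\t0.0", "g2\tg3\t1.0"])
        net = read_edge_list(path, "A")
        assert net.n_edges == 1
        assert net.nodes == {"g1", "g2", "g3"}

    def test_empty_after_filtering(self, tmp_path):
        path = write_lines(tmp_path, "e.tsv", ["# comment only"])
        with pytest.raises(GraphIOError, match="empty"):
            read_edge_list(path, "A")

    def test_sif_unit_weights(self, tmp_path):
        path = write_lines(tmp_path, "e.sif", ["g1\tpp\tg2\tg3"])
        net = read_edge_list(path, "B", fmt="sif")
        assert net.weight("g1", "g2") == 1.0
        assert net.weight("g1", "g3") == 1.0
        assert net.n_edges == 2

    def test_node_order_deterministic(self, tmp_path):
        path = write_lines(tmp_path, "e.tsv", ["gB\tgA\t1", "gC\tgA\t1"])
        assert read_edge_list(path, "A").node_list == ["gA", "gB", "gC"]


class TestReadSeeds:
    def test_both_present(self, tmp_path):
        net_b = build_network("B", [("KRP2", "CDC2", 1.0)])
        path = write_lines(tmp_path, "s.txt", ["KRP2", "CDC2"])
        seeds = read_seeds(path, [net_b])
        assert seeds.seeds == ("KRP2", "CDC2")
        assert seeds.k == 2

    def test_duplicates_first_kept(self, tmp_path, caplog):
        net = build_network("A", [("g1", "g2", 1.0)])
        path = write_lines(tmp_path, "s.txt", ["g1", "g1", "g2"])
        with caplog.at_level(logging.WARNING):
            seeds = read_seeds(path, [net])
        assert seeds.seeds == ("g1", "g2")
        assert any("duplicate" in r.message for r in caplog.records)

    def test_missing_seed_named(self, tmp_path):
        net = build_network("A", [("g1", "g2", 1.0)])
        path = write_lines(tmp_path, "s.txt", ["gX"])
        with pytest.raises(GraphIOError, match="gX"):
            read_seeds(path, [net])

    def test_comments_and_blanks_skipped(self, tmp_path):
        net = build_network("A", [("g1", "g2", 1.0)])
        path = write_lines(tmp_path, "s.txt", ["# seeds", "", "g1"])
        assert read_seeds(path, [net]).seeds == ("g1",)

    def test_present_in_either_layer_suffices(self, tmp_path):
        net_a = build_network("A", [("g1", "g2", 1.0)])
        net_b = build_network("B", [("g3", "g4", 1.0)])
        path = write_lines(tmp_path, "s.txt", ["g3"])
        assert read_seeds(path, [net_a, net_b]).k == 1


def _rank_pair(tiny_pair):
    net_a, net_b, seeds = tiny_pair
    order = union_node_order(net_a, net_b)
    p = restart_vector(seeds, order)
    x_a = pagerank_seeded(build_transition(net_a, order), p)
    x_ab = multiplex_pagerank(build_transition(net_b, order), x_a, p)
    return x_a, x_ab


class TestRankTable:
    def test_rows_and_sorting(self, tmp_path, tiny_pair):
        x_a, x_ab = _rank_pair(tiny_pair)
        path = tmp_path / "ranks.tsv"
        write_rank_table(x_a, x_ab, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "gene\tscore_A\tscore_AB\trank_AB"
        assert len(lines) == len(x_a.node_order) + 1
        scores = [float(l.split("\t")[2]) for l in lines[1:]]
        assert scores == sorted(scores, reverse=True)

    def test_column_sums_conserved(self, tmp_path, tiny_pair):
        x_a, x_ab = _rank_pair(tiny_pair)
        path = tmp_path / "ranks.tsv"
        write_rank_table(x_a, x_ab, path)
        table = read_rank_table(path)
        assert sum(v[0] for v in table.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(v[1] for v in table.values()) == pytest.approx(1.0, abs=1e-9)

    def test_round_trip_bit_for_bit(self, tmp_path, tiny_pair):
        x_a, x_ab = _rank_pair(tiny_pair)
        path = tmp_path / "ranks.tsv"
        write_rank_table(x_a, x_ab, path)
        table = read_rank_table(path)
        for gene, (sa, sab) in table.items():
            i = x_a.node_order.index(gene)
            assert sa == x_a.scores[i]
            assert sab == x_ab.scores[i]


def _module_fixture():
    edges = (
        ModuleEdge("a", "b", 0.5, None, "A"),
        ModuleEdge("a", "c", 0.4, None, "A"),
        ModuleEdge("b", "d", 0.3, None, "A"),
        ModuleEdge("c", "d", None, 1.0, "B"),
        ModuleEdge("a", "d", None, 1.0, "B"),
        ModuleEdge("b", "c", 0.9, 1.0, "AB"),
    )
    return Module(
        nodes=("a", "b", "c", "d"),
        edges=edges,
        seeds=("a",),
        score=0.3,
        z_score=2.0,
        p_value=0.02275,
        null_mean=0.1,
        null_sd=0.1,
        n_samples=1000,
        rng_seed=7,
        parameters={"alpha_A": 0.85, "alpha_B": 0.85, "tol": 1e-10, "n_top": 4},
    )


class TestModuleReport:
    def test_counts_and_rows(self, tmp_path):
        edges_path, json_path = write_module_report(_module_fixture(), tmp_path / "mod")
        summary = json.loads(json_path.read_text())
        assert summary["edge_counts"] == {"A": 3, "B": 2, "AB": 1}
        assert len(edges_path.read_text().splitlines()) == 7  # header + 6 edges

    def test_empty_edges(self, tmp_path):
        mod = Module(nodes=("a", "b"), edges=(), seeds=("a",))
        edges_path, json_path = write_module_report(mod, tmp_path / "mod")
        assert edges_path.read_text().splitlines() == [
            "source\ttarget\tweight_A\tweight_B\tprovenance"
        ]
        summary = json.loads(json_path.read_text())
        assert summary["edge_counts"] == {"A": 0, "B": 0, "AB": 0}

    def test_parameters_round_trip(self, tmp_path):
        mod = _module_fixture()
        _, json_path = write_module_report(mod, tmp_path / "mod")
        summary = json.loads(json_path.read_text())
        assert summary["parameters"] == dict(mod.parameters)
        assert summary["rng_seed"] == 7
        assert summary["n_samples"] == 1000


edge_lists = st.lists(
    st.tuples(
        st.sampled_from(["g1", "g2", "g3", "g4", "g5"]),
        st.sampled_from(["g1", "g2", "g3", "g4", "g5"]),
        st.floats(min_value=0.01, max_value=10.0, allow_nan=False),
    ),
    min_size=1,
    max_size=12,
)


@settings(max_examples=60, deadline=None)
@given(edges=edge_lists)
def test_read_write_read_round_trip(edges, tmp_path_factory):
    tmp = tmp_path_factory.mktemp("rt")
    path = tmp / "edges.tsv"
    lines = [f"{u}\t{v}\t{w!r}" for u, v, w in edges]
    path.write_text("\n".join(lines) + "\n")
    try:
        net1 = read_edge_list(path, "A")
    except GraphIOError:
        return  # everything filtered away; nothing to round-trip
    if net1.n_edges == 0:
        return  # isolated nodes are not representable in an edge list
    out = tmp / "out.tsv"
    write_edge_list(net1, out)
    net2 = read_edge_list(out, "A")
    assert net2.edges.keys() == net1.edges.keys()
    for key, w in net1.edges.items():
        assert net2.edges[key] == pytest.approx(w, abs=1e-12)
    # isolated nodes (self-loop survivors) are not representable in an
    # edge list, so compare the edge-supporting node sets
    support = {n for pair in net1.edges for n in pair}
    assert net2.nodes >= support


@settings(max_examples=40, deadline=None)
@given(edges=edge_lists, seed=st.integers(0, 2**16))
def test_reader_is_order_insensitive(edges, seed, tmp_path_factory):
    tmp = tmp_path_factory.mktemp("perm")
    lines = [f"{u}\t{v}\t{w!r}" for u, v, w in edges]
    rng = np.random.default_rng(seed)
    shuffled = [lines[i] for i in rng.permutation(len(lines))]
    p1, p2 = tmp / "a.tsv", tmp / "b.tsv"
    p1.write_text("\n".join(lines) + "\n")
    p2.write_text("\n".join(shuffled) + "\n")
    try:
        n1 = read_edge_list(p1, "A")
    except GraphIOError:
        with pytest.raises(GraphIOError):
            read_edge_list(p2, "A")
        return
    n2 = read_edge_list(p2, "A")
    assert n1.nodes == n2.nodes
    assert n1.edges == n2.edges


def test_weighted_network_invariants_enforced():
    with pytest.raises(GraphIOError):
        WeightedNetwork("A", frozenset({"a"}), {("a", "a"): 1.0})
    with pytest.raises(GraphIOError):
        WeightedNetwork("A", frozenset({"a", "b"}), {("b", "a"): 1.0})
    with pytest.raises(GraphIOError):
        WeightedNetwork("A", frozenset({"a", "b"}), {("a", "b"): -1.0})


def test_seed_set_invariants():
    with pytest.raises(GraphIOError):
        SeedSet(())
    with pytest.raises(GraphIOError):
        SeedSet(("g1", "g1"))
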