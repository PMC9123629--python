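import logging

import pytest
from hypothesis import given, settings, strategies as st

from ppiscreen import (
    ActionEdge,
    Network,
    ParseError,
    ValidationError,
    read_action_table,
    read_edge_list,
    read_string_links,
    write_action_table,
    write_edge_list,
    write_node_table,
)
from ppiscreen.centrality import CentralityRecord


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadEdgeList:
    def test_dedup_selfloop_and_symmetry(self, tmp_path, caplog):
        p = _write(tmp_path, "e.tsv", "A B\nB A\nA A\nB C\n")
        with caplog.at_level(logging.WARNING):
            net = read_edge_list(p, "d1")
        assert net.nodes == {"A", "B", "C"}
        assert net.edges == {("A", "B"), ("B", "C")}
        assert "self-loop" in caplog.text

    def test_score_column_tolerated(self, tmp_path):
        p = _write(tmp_path, "e.tsv", "A B 0.91\n")
        net = read_edge_list(p, "d1")
        assert net.edges == {("A", "B")}

    def test_empty_file_warns(self, tmp_path, caplog):
        p = _write(tmp_path, "e.tsv", "")
        with caplog.at_level(logging.WARNING):
            net = read_edge_list(p, "d1")
        assert net.n_nodes == 0 and net.n_edges == 0
        assert "empty" in caplog.text

    def test_comments_skipped(self, tmp_path):
        p = _write(tmp_path, "e.tsv", "# a comment\nA B\n")
        assert read_edge_list(p, "d1").edges == {("A", "B")}

    def test_short_line_names_line_number(self, tmp_path):
        p = _write(tmp_path, "e.tsv", "A B\nXONLY\n")
        with pytest.raises(ParseError, match=r":2"):
            read_edge_list(p, "d1")

    def test_missing_file_is_io_error(self, tmp_path):
        with pytest.raises(OSError):
            read_edge_list(tmp_path / "nope.tsv", "d1")


class TestReadStringLinks:
    def test_header_detected_and_skipped(self, tmp_path):
        p = _write(tmp_path, "s.tsv",
                   "node1 node2 combined_score\nTP53 AKT1 0.99\n")
        net = read_string_links(p, "d1")
        assert net.edges == {("AKT1", "TP53")}

    def test_duplicate_both_orders_collapse(self, tmp_path):
        p = _write(tmp_path, "s.tsv",
                   "node1 node2 combined_score\nA B 0.9\nB A 0.9\n")
        assert read_string_links(p, "d1").edges == {("A", "B")}

    def test_headerless_fallback(self, tmp_path, caplog):
        p = _write(tmp_path, "s.tsv", "A B 0.5\nB C 0.7\n")
        with caplog.at_level(logging.INFO):
            net = read_string_links(p, "d1")
        assert net.edges == {("A", "B"), ("B", "C")}
        assert "no header" in caplog.text

    def test_two_column_header_names(self, tmp_path):
        p = _write(tmp_path, "s.tsv", "node1 node2\nA B\n")
        assert read_string_links(p, "d1").edges == {("A", "B")}


class TestActionTable:
    def test_basic_row(self, tmp_path):
        p = _write(tmp_path, "a.tsv", "EGF EGFR activation true\n")
        assert read_action_table(p) == [
            ActionEdge("EGF", "EGFR", "activation", True)
        ]

    def test_unknown_mode_lists_allowed(self, tmp_path):
        p = _write(tmp_path, "a.tsv", "X Y binding true\n")
        with pytest.raises(ValidationError) as exc:
            read_action_table(p)
        for mode in ("activation", "inhibition", "expression"):
            assert mode in str(exc.value)

    def test_empty_table(self, tmp_path):
        assert read_action_table(_write(tmp_path, "a.tsv", "")) == []

    @pytest.mark.parametrize("flag,expect", [
        ("true", True), ("false", False), ("1", True), ("no", False),
    ])
    def test_directed_flag_parsing(self, tmp_path, flag, expect):
        p = _write(tmp_path, "a.tsv", f"A B inhibition {flag}\n")
        assert read_action_table(p)[0].directed is expect

    def test_self_action_rejected(self, tmp_path):
        p = _write(tmp_path, "a.tsv", "A A expression true\n")
        with pytest.raises(ValidationError, match="self-action"):
            read_action_table(p)

    def test_round_trip(self, tmp_path):
        edges = [
            ActionEdge("A", "B", "activation", True),
            ActionEdge("C", "B", "inhibition", False),
        ]
        p = tmp_path / "a.tsv"
        write_action_table(edges, p)
        assert sorted(read_action_table(p), key=lambda e: e.source) == edges


class TestWriteNodeTable:
    def test_three_decimal_format_and_order(self, tmp_path):
        records = [
            CentralityRecord("AKT1", 59, 0.0091, 0.6838, 1300),
            CentralityRecord("TP53", 60, 0.5, 0.5, 10),
        ]
        p = tmp_path / "t.csv"
        write_node_table(records, p)
        lines = p.read_text().splitlines()
        assert lines[0] == "node,degree,betweenness,closeness,stress"
        assert lines[1].startswith("TP53,60")  # higher degree first
        assert lines[2] == "AKT1,59,0.009,0.684,1300"

    def test_equal_degree_orders_lexicographically(self, tmp_path):
        records = [
            CentralityRecord("B", 2, 0.0, 0.5, 0),
            CentralityRecord("A", 2, 0.0, 0.5, 0),
        ]
        p = tmp_path / "t.csv"
        write_node_table(records, p)
        rows = [line.split(",")[0] for line in p.read_text().splitlines()[1:]]
        assert rows == ["A", "B"]

    def test_single_record_two_lines(self, tmp_path):
        p = tmp_path / "t.csv"
        write_node_table([CentralityRecord("A", 0, 0.0, 0.0, 0)], p)
        assert len(p.read_text().splitlines()) == 2

    def test_empty_records_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            write_node_table([], tmp_path / "t.csv")


@given(
    edges=st.lists(
        st.tuples(st.sampled_from("ABCDEFG"), st.sampled_from("ABCDEFG")),
        max_size=15,
    ),
    isolated=st.sets(st.sampled_from(["X1", "X2"]), max_size=2),
)
@settings(deadline=None, max_examples=60, derandomize=True)
def test_edge_list_round_trip_preserves_sets(tmp_path_factory, edges, isolated):
    """Write→read preserves node and edge sets exactly, isolated nodes included."""
    net = Network.from_edges("rt", edges, extra_nodes=isolated)
    p = tmp_path_factory.mktemp("rt") / "net.tsv"
    write_edge_list(net, p)
    back = read_edge_list(p, "rt")
    assert back.nodes == net.nodes
    assert back.edges == net.edges


def test_reader_output_independent_of_row_and_column_order(tmp_path):
    a = _write(tmp_path, "a.tsv", "A B\nB C\nC D\n")
    b = _write(tmp_path, "b.tsv", "D C\nB A\nC B\n")
    na, nb = read_edge_list(a, "x"), read_edge_list(b, "x")
    assert na.nodes == nb.nodes and na.edges == nb.edges
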