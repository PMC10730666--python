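import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from polyqnet import net_io
from polyqnet.geometry import HyperbolicPoint
from polyqnet.net_io import PWM, GeneSet
from polyqnet.sectors import GapParams, angular_gap_clusters


class TestInteractionTable:
    def test_threshold_self_and_duplicate_rules(self, toy_interaction_file):
        g = net_io.read_interaction_table(toy_interaction_file, 0.71)
        assert g.number_of_edges() == 2
        assert g.has_edge("A", "B") and g.has_edge("B", "C")
        # duplicate A-B keeps the max score 0.9
        assert g.edges["A", "B"]["score"] == pytest.approx(0.9)

    def test_zero_threshold_keeps_everything_but_self(self, toy_interaction_file):
        g = net_io.read_interaction_table(toy_interaction_file, 0.0)
        assert g.number_of_edges() == 4  # self pair still dropped

    def test_self_pairs_kept_when_not_discarding(self, toy_interaction_file):
        g = net_io.read_interaction_table(toy_interaction_file, 0.0, discard_self=False)
        assert g.has_edge("E", "E")

    def test_threshold_filter_is_idempotent(self, toy_interaction_file, tmp_path):
        g1 = net_io.read_interaction_table(toy_interaction_file, 0.71)
        rewritten = tmp_path / "again.txt"
        rows = [
            f"{u}\t0\t{v}\t0\t{d['score']}\tx" for u, v, d in g1.edges(data=True)
        ]
        rewritten.write_text("\n".join(rows) + "\n")
        g2 = net_io.read_interaction_table(rewritten, 0.71)
        assert set(map(frozenset, g1.edges)) == set(map(frozenset, g2.edges))

    def test_symbol_fallback_to_numeric_id(self, tmp_path):
        path = tmp_path / "e.txt"
        path.write_text("-\t111\tB\t2\t0.9\tx\n")
        g = net_io.read_interaction_table(path, 0.5)
        assert g.has_edge("111", "B")

    def test_unparseable_row_names_line_number(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("A\t1\tB\t2\t0.9\tx\nA\t1\tC\t3\tnotascore\tx\n")
        with pytest.raises(ValueError, match="line 2"):
            net_io.read_interaction_table(path, 0.5)

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "empty.txt"
        path.write_text("")
        with pytest.raises(ValueError):
            net_io.read_interaction_table(path, 0.5)


class TestLCC:
    def test_connected_graph_is_unchanged(self, triangle_graph):
        lcc = net_io.extract_lcc(triangle_graph)
        assert set(lcc.nodes) == {"A", "B", "C"}
        assert lcc.number_of_edges() == 3

    def test_larger_component_wins(self):
        g = nx.Graph()
        nx.add_path(g, ["a", "b", "c", "d", "e"])  # size 5
        nx.add_path(g, ["x", "y", "z"])  # size 3
        lcc = net_io.extract_lcc(g)
        assert set(lcc.nodes) == {"a", "b", "c", "d", "e"}
        assert nx.is_connected(lcc)

    def test_size_tie_broken_by_smallest_node_id(self):
        g = nx.Graph()
        g.add_edge("m", "n")
        g.add_edge("a", "z")
        lcc = net_io.extract_lcc(g)
        assert set(lcc.nodes) == {"a", "z"}

    def test_output_is_node_induced_subgraph(self):
        g = nx.Graph()
        nx.add_cycle(g, ["a", "b", "c", "d"])
        g.add_edge("a", "c")
        g.add_edge("p", "q")
        lcc = net_io.extract_lcc(g)
        assert lcc.number_of_edges() == 5  # all edges among the component kept

    def test_empty_network_is_an_error(self):
        with pytest.raises(ValueError):
            net_io.extract_lcc(nx.Graph())


class TestGeneSets:
    def test_parse_two_lines(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("T1\tfirst\tA\tB\tC\nT2\tsecond\tB\tD\n")
        coll = net_io.read_gene_sets(p)
        assert set(coll) == {"T1", "T2"}
        assert coll["T1"].genes == frozenset("ABC")
        assert coll["T2"].genes == frozenset("BD")

    def test_duplicate_members_collapse(self, tmp_path):
        p = tmp_path / "dup.gmt"
        p.write_text("T1\tx\tA\tA\tB\n")
        assert net_io.read_gene_sets(p)["T1"].genes == frozenset("AB")

    def test_short_line_errors_with_position(self, tmp_path):
        p = tmp_path / "short.gmt"
        p.write_text("T1\tx\tA\nT2\tonly-description\n")
        with pytest.raises(ValueError, match="line 2"):
            net_io.read_gene_sets(p)

    def test_round_trip(self, tmp_path):
        coll = {
            "T1": GeneSet("T1", "first", frozenset("ABC")),
            "T2": GeneSet("T2", "second", frozenset("XY")),
        }
        p = tmp_path / "rt.gmt"
        net_io.write_gene_sets(p, coll)
        back = net_io.read_gene_sets(p)
        assert {t: s.genes for t, s in back.items()} == {
            t: s.genes for t, s in coll.items()
        }


class TestFasta:
    def test_t_normalized_to_u_and_uppercased(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">r1\nacgt\n")
        assert net_io.read_fasta(p) == [("r1", "ACGU")]

    def test_order_preserved(self, tmp_path):
        p = tmp_path / "multi.fa"
        p.write_text(">b\nAAA\n>a\nCCC\n>c\nGGG\n")
        assert [r[0] for r in net_io.read_fasta(p)] == ["b", "a", "c"]

    def test_round_trip(self, tmp_path):
        records = [("s1", "ACGUACGU"), ("s2", "GGGCCC")]
        p = tmp_path / "rt.fa"
        net_io.write_fasta(p, records)
        assert net_io.read_fasta(p) == records

    def test_empty_sequence_is_an_error(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text(">r1\n\n>r2\nACG\n")
        with pytest.raises(ValueError, match="r1"):
            net_io.read_fasta(p)


class TestPWMIO:
    def test_uniform_matrix(self, tmp_path):
        p = tmp_path / "u.pwm"
        p.write_text(
            "Pos\tA\tC\tG\tU\n"
            "1\t0.25\t0.25\t0.25\t0.25\n"
            "2\t0.25\t0.25\t0.25\t0.25\n"
            "3\t0.25\t0.25\t0.25\t0.25\n"
        )
        pwm = net_io.read_pwm(p)
        assert pwm.width == 3
        assert np.allclose(pwm.probs, 0.25)

    def test_degenerate_column_accepted(self, tmp_path):
        p = tmp_path / "d.pwm"
        p.write_text("Pos\tA\tC\tG\tU\n1\t1\t0\t0\t0\n")
        pwm = net_io.read_pwm(p)
        assert pwm.probs[0, 0] == 1.0

    def test_dna_header_auto_converted(self, tmp_path):
        p = tmp_path / "dna.pwm"
        p.write_text("Pos\tA\tC\tG\tT\n1\t0.25\t0.25\t0.25\t0.25\n")
        assert net_io.read_pwm(p).width == 1

    def test_row_sum_off_by_more_than_tolerance_errors(self, tmp_path):
        p = tmp_path / "bad.pwm"
        p.write_text("Pos\tA\tC\tG\tU\n1\t0.2\t0.2\t0.2\t0.2\n")
        with pytest.raises(ValueError, match="line 2"):
            net_io.read_pwm(p)

    def test_small_row_deviation_renormalized(self, tmp_path):
        p = tmp_path / "renorm.pwm"
        p.write_text("Pos\tA\tC\tG\tU\n1\t0.2502\t0.25\t0.25\t0.25\n")
        pwm = net_io.read_pwm(p)
        assert pwm.probs[0].sum() == pytest.approx(1.0, abs=1e-12)

    def test_width_bounds_enforced(self, tmp_path):
        rows = "".join(f"{i}\t0.25\t0.25\t0.25\t0.25\n" for i in range(1, 32))
        p = tmp_path / "wide.pwm"
        p.write_text("Pos\tA\tC\tG\tU\n" + rows)
        with pytest.raises(ValueError, match="width"):
            net_io.read_pwm(p)


class TestOutputRoundTrips:
    def test_coordinates_row_per_node_and_round_trip(self, tmp_path, random_coords):
        p = tmp_path / "coords.tsv"
        net_io.write_coordinates(p, random_coords)
        back = net_io.read_coordinates(p)
        assert set(back) == set(random_coords)
        for node in random_coords:
            assert back[node].r == pytest.approx(random_coords[node].r, abs=1e-12)
            assert back[node].theta == pytest.approx(
                random_coords[node].theta, abs=1e-12
            )

    def test_three_node_coordinates_file_has_three_rows(self, tmp_path):
        coords = {c: HyperbolicPoint(1.0, i) for i, c in enumerate("abc")}
        p = tmp_path / "c.tsv"
        net_io.write_coordinates(p, coords)
        assert len(p.read_text().strip().splitlines()) == 4  # header + 3

    def test_sectors_round_trip(self, tmp_path, random_coords):
        part = angular_gap_clusters(random_coords, GapParams(g=0.3, min_size=1))
        p = tmp_path / "sectors.tsv"
        net_io.write_sectors(p, part)
        df = net_io.read_sectors(p)
        assert set(df["node"]) == set(random_coords)
        assert set(df["sector_id"]) == {s.sector_id for s in part.sectors}

    def test_empty_enrichment_writes_header_only(self, tmp_path):
        p = tmp_path / "enr.tsv"
        net_io.write_enrichment(p, pd.DataFrame())
        lines = p.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].split("\t") == net_io.ENRICHMENT_COLUMNS

    def test_edge_list_round_trip(self, tmp_path, triangle_graph):
        p = tmp_path / "edges.tsv"
        net_io.write_edge_list(p, triangle_graph)
        back = net_io.read_edge_list(p)
        assert set(map(frozenset, back.edges)) == set(map(frozenset, triangle_graph.edges))


def test_pwm_invariants_enforced_on_construction():
    with pytest.raises(ValueError):
        PWM(np.array([[0.5, 0.5, 0.5, 0.5]]))
    with pytest.raises(ValueError):
        PWM(np.ones((0, 4)))
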