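import pytest

from karyocover import graph_io
from karyocover.ccr import ContigCovering, run_ccr
from karyocover.decomposition import solve_min_edp
from karyocover.iag import GraphError, Walk, walks_equal
from karyocover.simulator import SimConfig, simulate
from conftest import make_f1


def write_f1(tmp_path):
    g = make_f1()
    seg, adj = tmp_path / "segments.tsv", tmp_path / "adjacencies.tsv"
    graph_io.write_iag(g, seg, adj)
    return g, seg, adj


class TestReadIag:
    def test_f1_round_trip(self, tmp_path):
        g, seg, adj = write_f1(tmp_path)
        g2 = graph_io.read_iag(seg, adj)
        assert graph_io.canonical_signature(g2) == graph_io.canonical_signature(g)

    def test_empty_adjacency_file(self, tmp_path):
        g, seg, adj = write_f1(tmp_path)
        adj.write_text("\t".join(graph_io.ADJACENCY_COLUMNS) + "\n")
        g2 = graph_io.read_iag(seg, adj)
        assert not g2.adjacencies
        assert len(g2.segments) == 3

    def test_interior_breakend_rejected(self, tmp_path):
        g, seg, adj = write_f1(tmp_path)
        adj.write_text(
            "\t".join(graph_io.ADJACENCY_COLUMNS)
            + "\na1\tchr\t150\t+\tchr\t101\t-\tN\t1\n"
        )
        with pytest.raises(GraphError, match="matches no segment boundary"):
            graph_io.read_iag(seg, adj)

    def test_malformed_row_reports_line(self, tmp_path):
        g, seg, adj = write_f1(tmp_path)
        seg.write_text("chrom\tstart\tend\tcn\nchr\tone\t100\t1\n")
        with pytest.raises(GraphError, match=":2"):
            graph_io.read_iag(seg, adj)

    def test_missing_header(self, tmp_path):
        g, seg, adj = write_f1(tmp_path)
        seg.write_text("")
        with pytest.raises(GraphError, match="header"):
            graph_io.read_iag(seg, adj)

    def test_simulated_round_trip(self, tmp_path):
        case = simulate(SimConfig(seed=8, tandem_duplications=2, inversions=1))
        graph_io.write_iag(case.graph, tmp_path / "s.tsv", tmp_path / "a.tsv")
        g2 = graph_io.read_iag(tmp_path / "s.tsv", tmp_path / "a.tsv")
        assert graph_io.canonical_signature(g2) == graph_io.canonical_signature(
            case.graph
        )


class TestCoveringTable:
    def test_round_trip_walks_equal(self, tmp_path):
        g = make_f1()
        t = run_ccr(g)
        path = tmp_path / "contigs.tsv"
        graph_io.write_covering(t, path, g)
        t2 = graph_io.read_covering(path, g)
        assert len(t2.walks) == len(t.walks)
        for w1, w2 in zip(t.walks, t2.walks):
            assert walks_equal(w1, w2)

    def test_closed_flag(self, tmp_path, f3):
        t = run_ccr(f3)
        path = tmp_path / "contigs.tsv"
        graph_io.write_covering(t, path, f3)
        assert "closed" in path.read_text()
        t2 = graph_io.read_covering(path, f3)
        assert t2.walks[0].closed

    def test_empty_covering(self, tmp_path, f1):
        path = tmp_path / "contigs.tsv"
        graph_io.write_covering(ContigCovering([], f1), path, f1)
        assert path.read_text().strip() == "\t".join(graph_io.COVERING_COLUMNS)


class TestAgp:
    def test_single_segment_object(self, tmp_path, f1):
        t = ContigCovering([Walk((("a", "+"),), ())], f1)
        path = tmp_path / "out.agp"
        graph_io.write_agp(t, path, f1)
        lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == 1
        obj, beg, end, part, kind, comp, cbeg, cend, orient = lines[0].split("\t")
        assert (beg, end, kind, orient) == ("1", "100", "W", "+")

    def test_object_lengths_match_components(self, tmp_path, f1):
        t = run_ccr(f1)
        path = tmp_path / "out.agp"
        graph_io.write_agp(t, path, f1)
        rows = [
            l.split("\t")
            for l in path.read_text().splitlines()
            if not l.startswith("#")
        ]
        spans = {}
        for r in rows:
            spans.setdefault(r[0], 0)
            assert int(r[2]) - int(r[1]) + 1 == int(r[7]) - int(r[6]) + 1
            spans[r[0]] += int(r[2]) - int(r[1]) + 1
        for obj in spans:
            obj_end = max(int(r[2]) for r in rows if r[0] == obj)
            assert obj_end == spans[obj]

    def test_reverse_orientation(self, tmp_path, f1):
        ab = list(f1.adjacencies)[0]
        t = solve_min_edp(f1)
        w = t.walks[0].reverse()
        path = tmp_path / "out.agp"
        graph_io.write_agp(ContigCovering([w], f1), path, f1)
        assert "\t-\n" in path.read_text()

    def test_cycle_rejected(self, tmp_path, f3):
        t = run_ccr(f3)
        with pytest.raises(GraphError, match="closed"):
            graph_io.write_agp(t, tmp_path / "out.agp", f3)
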