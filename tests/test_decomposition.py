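import pytest

from karyocover.decomposition import (
    Decomposition,
    NonDecomposableError,
    expected_path_count,
    k3_reduction,
    merge_cycle_into,
    min_decomposition_size,
    solve_edp,
    solve_min_edp,
    validate_decomposition,
)
from karyocover.iag import (
    Adjacency,
    GraphError,
    Segment,
    Walk,
    build_iag,
    copy_number_excess,
    usage_of,
)
from karyocover import oracle
from conftest import ext, make_f1, make_f3, small_sim_cases


def union_f1_f3():
    g = make_f1()
    g.add_segment(Segment("z", "chr2", 1, 100), 1)
    g.add_adjacency(Adjacency(ext("z", "h"), ext("z", "t"), "N"), 1)
    return g


class TestSolveEdp:
    def test_f3_single_cycle(self, f3):
        d = solve_edp(f3)
        assert len(d) == 1 and d.walks[0].closed
        assert validate_decomposition(f3, d)[0]

    def test_f1_valid(self, f1):
        d = solve_edp(f1)
        ok, violations = validate_decomposition(f1, d)
        assert ok, violations
        assert usage_of(d.walks).counts == f1.mu

    def test_bare_copies_become_paths(self):
        g = build_iag([Segment("a")], [], segment_mu={"a": 3})
        d = solve_edp(g)
        assert len(d) == 3
        assert all(not w.closed and len(w) == 1 for w in d.walks)

    def test_non_decomposable_reports_vertices(self):
        g = build_iag(
            [Segment("a")],
            [Adjacency(ext("a", "h"), ext("a", "h"))],
            segment_mu={"a": 1},
        )
        with pytest.raises(NonDecomposableError) as exc:
            solve_edp(g)
        assert exc.value.violations
        assert exc.value.violations[0][1] == -1


class TestMinEdp:
    def test_f1_single_path(self, f1):
        d = solve_min_edp(f1)
        assert len(d) == 1
        assert d.walks[0].steps == (("a", "+"), ("b", "+"), ("b", "+"), ("c", "+"))

    def test_two_circles(self):
        g = build_iag(
            [Segment("y"), Segment("z")],
            [
                Adjacency(ext("y", "h"), ext("y", "t")),
                Adjacency(ext("z", "h"), ext("z", "t")),
            ],
        )
        d = solve_min_edp(g)
        assert len(d) == 2 and all(w.closed for w in d.walks)

    def test_f2_two_paths(self, f2):
        d = solve_min_edp(f2)
        assert len(d) == 2
        assert all(not w.closed for w in d.walks)
        assert validate_decomposition(f2, d)[0]

    def test_never_larger_than_edp(self, f1, f2):
        for g in (f1, f2):
            assert len(solve_min_edp(g)) <= len(solve_edp(g))


class TestSizeIdentities:
    @pytest.mark.parametrize(
        "maker,paths,minsize",
        [(make_f1, 1, 1), (make_f3, 0, 1), (union_f1_f3, 1, 2)],
    )
    def test_counts(self, maker, paths, minsize):
        g = maker()
        assert expected_path_count(g) == paths
        assert min_decomposition_size(g) == minsize

    def test_f2(self, f2):
        assert expected_path_count(f2) == 2
        assert min_decomposition_size(f2) == 2

    def test_empty(self):
        g = build_iag([], [])
        assert min_decomposition_size(g) == 0


class TestValidate:
    def test_missing_copy_reported(self, f1):
        d = solve_min_edp(f1)
        w = d.walks[0]
        broken = Decomposition(
            [Walk(w.steps[:2], w.adjs[:1], False)], f1
        )
        ok, violations = validate_decomposition(f1, broken)
        assert not ok
        assert any("used" in v for v in violations)

    def test_wrong_adjacency_reported(self, f1):
        bad_adj = Adjacency(ext("a", "h"), ext("c", "t"), "N").key
        w = Walk((("a", "+"), ("c", "+")), (bad_adj,))
        ok, violations = validate_decomposition(f1, Decomposition([w], f1))
        assert not ok

    def test_self_consistency_on_simulations(self):
        for case in small_sim_cases(40):
            for solver in (solve_edp, solve_min_edp):
                d = solver(case.graph)
                ok, violations = validate_decomposition(case.graph, d)
                assert ok, violations
                assert len(d.paths) == expected_path_count(case.graph)


class TestMerge:
    def test_merge_preserves_usage(self, f3):
        path = Walk((("x", "+"), ("a", "+")), (Adjacency(ext("x", "h"), ext("a", "t")).key,))
        cycle = solve_edp(f3).walks[0]
        # merging a cycle into a path through the shared segment keeps usage
        merged = merge_cycle_into(path, cycle, "a")
        u = usage_of([merged])
        assert u[("S", "a")] == 2 and u[("S", "x")] == 1
        assert not merged.closed

    def test_second_argument_must_be_cycle(self):
        p = Walk((("a", "+"),), ())
        with pytest.raises(GraphError):
            merge_cycle_into(p, p, "a")


TRIANGLE = [(1, 2), (2, 3), (1, 3)]
C4 = [(1, 2), (2, 3), (3, 4), (4, 1)]
C6 = [(1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 1)]
BOWTIE = [(1, 2), (2, 3), (1, 3), (3, 4), (4, 5), (3, 5)]


class TestK3Reduction:
    def test_triangle_structure(self):
        g = k3_reduction(TRIANGLE)
        assert len(g.segments) == 3
        assert all(copy_number_excess(g, v) == 0 for v in g.vertices())
        segs = [g.mu[k] for k in g.segment_edge_keys()]
        assert segs == [2, 2, 2]

    def test_odd_degree_rejected(self):
        with pytest.raises(GraphError, match="odd degree"):
            k3_reduction([(1, 2)])

    def test_self_loop_rejected(self):
        with pytest.raises(GraphError):
            k3_reduction([(1, 1), (1, 2), (2, 1)])

    @pytest.mark.parametrize(
        "edges,has_partition",
        [(TRIANGLE, True), (C4, False), (BOWTIE, True), (C6, False)],
    )
    def test_partition_iff_max_ed_matches(self, edges, has_partition):
        g = k3_reduction(edges)
        best = oracle.max_ed_bruteforce(g, cap=30)
        assert (len(best) == len(edges) // 3 and len(edges) % 3 == 0) == has_partition
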