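import pytest
from hypothesis import given, settings, strategies as st

from karyocover.iag import (
    Adjacency,
    Extremity,
    GraphError,
    Segment,
    Walk,
    build_iag,
    classify_components,
    copy_number_excess,
    is_decomposable,
    positive_restriction,
    usage_of,
    walks_equal,
)
from conftest import ext, make_f1


class TestBuild:
    def test_smallest_valid_input(self):
        g = build_iag([Segment("a")], [], segment_mu={"a": 1})
        assert len(g.vertices()) == 2
        assert g.mu[("S", "a")] == 1
        assert not g.adjacencies

    def test_two_segments_one_adjacency(self):
        g = build_iag(
            [Segment("a"), Segment("b")],
            [Adjacency(ext("a", "h"), ext("b", "t"))],
            segment_mu={"a": 1, "b": 1},
        )
        assert len(g.vertices()) == 4
        assert len(g.mu) == 3

    def test_unknown_extremity_rejected(self):
        with pytest.raises(GraphError, match="unknown segment"):
            build_iag(
                [Segment("a"), Segment("b")],
                [Adjacency(ext("a", "h"), ext("c", "t"))],
            )

    def test_negative_multiplicity_rejected(self):
        with pytest.raises(GraphError, match="negative"):
            build_iag([Segment("a")], [], segment_mu={"a": -1})

    def test_zero_copy_segment_with_live_adjacency_rejected(self):
        with pytest.raises(GraphError, match="zero-copy"):
            build_iag(
                [Segment("a"), Segment("b")],
                [Adjacency(ext("a", "h"), ext("b", "t"))],
                segment_mu={"a": 0, "b": 1},
            )


class TestPositiveRestriction:
    def test_drops_zero_adjacency(self):
        g = build_iag(
            [Segment("a"), Segment("b")],
            [Adjacency(ext("a", "h"), ext("b", "t"))],
            segment_mu={"a": 1, "b": 1},
            adjacency_mu={Adjacency(ext("a", "h"), ext("b", "t")).key: 0},
        )
        p = positive_restriction(g)
        assert not p.adjacencies
        assert set(p.segments) == {"a", "b"}

    def test_identity_on_positive_graph(self):
        g = make_f1()
        p = positive_restriction(g)
        assert p.mu == g.mu

    def test_drops_zero_segment_vertices(self):
        g = build_iag(
            [Segment("a"), Segment("b")], [], segment_mu={"a": 1, "b": 0}
        )
        p = positive_restriction(g)
        assert set(p.segments) == {"a"}
        assert len(p.vertices()) == 2


class TestExcess:
    def test_no_adjacency(self):
        g = build_iag([Segment("a")], [], segment_mu={"a": 2})
        assert copy_number_excess(g, ext("a", "t")) == 2

    def test_loop_counts_twice(self):
        g = build_iag(
            [Segment("a")],
            [Adjacency(ext("a", "h"), ext("a", "h"))],
            segment_mu={"a": 1},
        )
        assert copy_number_excess(g, ext("a", "h")) == -1
        assert not is_decomposable(g)

    def test_f1_excesses(self, f1):
        expect = {
            ("a", "t"): 1,
            ("a", "h"): 0,
            ("b", "t"): 0,
            ("b", "h"): 0,
            ("c", "t"): 0,
            ("c", "h"): 1,
        }
        for (sid, side), x in expect.items():
            assert copy_number_excess(f1, ext(sid, side)) == x
        assert is_decomposable(f1)

    def test_unknown_vertex(self, f1):
        with pytest.raises(GraphError):
            copy_number_excess(f1, ext("zz", "t"))

    def test_empty_graph_decomposable(self):
        assert is_decomposable(build_iag([], []))


class TestComponents:
    def test_f1_is_c_plus(self, f1):
        c_plus, c_zero = classify_components(f1)
        assert len(c_plus) == 1 and len(c_zero) == 0

    def test_f3_is_c_zero(self, f3):
        c_plus, c_zero = classify_components(f3)
        assert len(c_plus) == 0 and len(c_zero) == 1

    def test_union_graph(self):
        g = build_iag(
            [Segment("a"), Segment("b"), Segment("c"), Segment("z")],
            [
                Adjacency(ext("a", "h"), ext("b", "t"), "R"),
                Adjacency(ext("b", "h"), ext("b", "t"), "N"),
                Adjacency(ext("b", "h"), ext("c", "t"), "R"),
                Adjacency(ext("z", "h"), ext("z", "t"), "N"),
            ],
            segment_mu={"a": 1, "b": 2, "c": 1, "z": 1},
        )
        c_plus, c_zero = classify_components(g)
        assert len(c_plus) == 1 and len(c_zero) == 1


AB = Adjacency(ext("a", "h"), ext("b", "t")).key


class TestWalks:
    def test_reversal_equality(self):
        w1 = Walk((("a", "+"), ("b", "+")), (AB,))
        w2 = Walk((("b", "-"), ("a", "-")), (AB,))
        assert walks_equal(w1, w2)

    def test_rotation_equality(self):
        a_loop = Adjacency(ext("a", "h"), ext("b", "t")).key
        closing = Adjacency(ext("b", "h"), ext("a", "t")).key
        c1 = Walk((("a", "+"), ("b", "+")), (a_loop, closing), True)
        c2 = Walk((("b", "+"), ("a", "+")), (closing, a_loop), True)
        assert walks_equal(c1, c2)

    def test_different_walks(self):
        ac = Adjacency(ext("a", "h"), ext("c", "t")).key
        w1 = Walk((("a", "+"), ("b", "+")), (AB,))
        w2 = Walk((("a", "+"), ("c", "+")), (ac,))
        assert not walks_equal(w1, w2)

    def test_open_closed_never_equal(self):
        w1 = Walk((("a", "+"),), ())
        loop = Adjacency(ext("a", "h"), ext("a", "t")).key
        w2 = Walk((("a", "+"),), (loop,), True)
        assert not walks_equal(w1, w2)

    def test_usage_single_path(self):
        w = Walk((("a", "+"), ("b", "+")), (AB,))
        u = usage_of([w])
        assert u[("S", "a")] == 1 and u[("S", "b")] == 1 and u[AB] == 1

    def test_usage_additive(self):
        w = Walk((("a", "+"), ("b", "+")), (AB,))
        u = usage_of([w, w])
        assert u[("S", "a")] == 2 and u[AB] == 2

    def test_usage_loop_closure(self):
        loop = Adjacency(ext("a", "h"), ext("a", "t")).key
        w = Walk((("a", "+"),), (loop,), True)
        u = usage_of([w])
        assert u[("S", "a")] == 1 and u[loop] == 1


# property: excess recomputed from raw incidence always matches
@given(st.integers(0, 5), st.integers(0, 3), st.integers(0, 3))
def test_excess_matches_manual_recount(mu_a, mu_loop, mu_ab):
    if mu_a == 0 and (mu_loop or mu_ab):
        return
    segs = [Segment("a"), Segment("b")]
    adjs, amu = [], {}
    loop = Adjacency(ext("a", "h"), ext("a", "h"))
    ab = Adjacency(ext("a", "h"), ext("b", "t"))
    if mu_loop:
        adjs.append(loop)
        amu[loop.key] = mu_loop
    if mu_ab:
        adjs.append(ab)
        amu[ab.key] = mu_ab
    if mu_ab and mu_a == 0:
        return
    g = build_iag(segs, adjs, segment_mu={"a": mu_a, "b": max(mu_ab, 1)}, adjacency_mu=amu)
    assert copy_number_excess(g, ext("a", "h")) == mu_a - 2 * mu_loop - mu_ab


@st.composite
def random_walk(draw):
    n = draw(st.integers(1, 5))
    steps = tuple(
        (draw(st.sampled_from("abc")), draw(st.sampled_from("+-")))
        for _ in range(n)
    )
    closed = draw(st.booleans())
    n_adj = n if closed else n - 1
    adjs = []
    for i in range(n_adj):
        sid_a, o_a = steps[i]
        sid_b, o_b = steps[(i + 1) % n]
        p = Extremity(sid_a, "h" if o_a == "+" else "t")
        q = Extremity(sid_b, "t" if o_b == "+" else "h")
        adjs.append(Adjacency(p, q).key)
    return Walk(steps, tuple(adjs), closed)


@settings(max_examples=150)
@given(random_walk(), random_walk(), random_walk())
def test_walks_equal_is_equivalence(w1, w2, w3):
    assert walks_equal(w1, w1)
    assert walks_equal(w1, w2) == walks_equal(w2, w1)
    if walks_equal(w1, w2) and walks_equal(w2, w3):
        assert walks_equal(w1, w3)


@settings(max_examples=100)
@given(random_walk())
def test_reverse_is_involution(w):
    assert w.reverse().reverse() == w
    assert walks_equal(w, w.reverse())
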