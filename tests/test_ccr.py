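import pytest

from karyocover import oracle
from karyocover.ccr import (
    balance_transform,
    contiguity_discordance,
    is_pair_forced,
    naive_covering,
    primitive_covering,
    run_ccr,
    run_ccr_detailed,
    validate_covering,
    ContigCovering,
)
from karyocover.decomposition import solve_min_edp
from karyocover.iag import (
    Adjacency,
    GraphError,
    Segment,
    Walk,
    build_iag,
    copy_number_excess,
    seg_key,
    walks_equal,
)
from conftest import ext, small_sim_cases, medium_sim_cases


AB = Adjacency(ext("a", "h"), ext("b", "t"), "N").key  # F2 kinds are N
AB_R = Adjacency(ext("a", "h"), ext("b", "t"), "R").key  # F1 reference kind
CB = Adjacency(ext("c", "h"), ext("b", "t"), "N").key
BD = Adjacency(ext("b", "h"), ext("d", "t"), "N").key


class TestPrimitive:
    def test_f1(self, f1):
        t = primitive_covering(f1)
        assert len(t.walks) == 4
        assert contiguity_discordance(f1, t) == 3

    def test_adjacency_free(self):
        g = build_iag([Segment("a")], [], segment_mu={"a": 2})
        assert contiguity_discordance(g, primitive_covering(g)) == 0

    def test_f2(self, f2):
        t = primitive_covering(f2)
        assert len(t.walks) == 6
        assert contiguity_discordance(f2, t) == 4


class TestDiscordance:
    def test_eulerian_decomposition_is_zero(self, f1):
        d = solve_min_edp(f1)
        assert contiguity_discordance(f1, ContigCovering(d.walks, f1)) == 0

    def test_invalid_covering_raises(self, f1):
        # uses an adjacency twice although mu is 1
        w = Walk((("a", "+"), ("b", "+")), (AB_R,))
        t = ContigCovering([w, w, Walk((("b", "+"),), ()), Walk((("c", "+"),), ())], f1)
        with pytest.raises(GraphError):
            contiguity_discordance(f1, t)

    def test_missing_segment_copy_detected(self, f1):
        t = primitive_covering(f1)
        t.walks.pop()
        ok, _ = validate_covering(f1, t)
        assert not ok


class TestBalanceTransform:
    def test_f1(self, f1):
        state = balance_transform(f1)
        g = state.graph
        assert g.mu[seg_key("supp")] == 2
        supp = [k for k in g.adjacencies if g.adjacencies[k].is_supplemental]
        loops = [k for k in supp if g.adjacencies[k].is_loop]
        assert len(loops) == 1 and g.mu[loops[0]] == 1
        assert len(supp) == 3  # two attachments + the head loop
        assert all(copy_number_excess(g, v) == 0 for v in g.vertices())

    def test_f3_unchanged(self, f3):
        state = balance_transform(f3)
        assert state.graph.mu == f3.mu

    def test_f2(self, f2):
        state = balance_transform(f2)
        g = state.graph
        assert g.mu[seg_key("supp")] == 4
        supp_loops = [
            k
            for k in g.adjacencies
            if g.adjacencies[k].is_supplemental and g.adjacencies[k].is_loop
        ]
        assert g.mu[supp_loops[0]] == 2

    def test_single_cycle_min_ed(self, f1, f2):
        for g in (f1, f2):
            d = solve_min_edp(balance_transform(g).graph)
            assert len(d) == 1 and d.walks[0].closed


class TestIsPairForced:
    def test_f1_forced(self, f1):
        state = balance_transform(f1)
        BB = Adjacency(ext("b", "h"), ext("b", "t"), "N").key
        assert is_pair_forced(state, AB_R, "b", BB)

    def test_f2_not_forced(self, f2):
        state = balance_transform(f2)
        assert not is_pair_forced(state, AB, "b", BD)

    def test_forced_in_balanced_cycle(self):
        # re-pairing would split the single cycle of a balanced component
        g = build_iag(
            [Segment("a"), Segment("b")],
            [
                Adjacency(ext("a", "h"), ext("b", "t"), "N"),
                Adjacency(ext("b", "h"), ext("a", "t"), "N"),
            ],
        )
        state = balance_transform(g)
        e = Adjacency(ext("b", "h"), ext("a", "t"), "N").key
        assert is_pair_forced(state, e, "a", AB)

    def test_matches_oracle_on_simulations(self):
        for case in small_sim_cases(30):
            g = case.graph
            forced = oracle.forced_pairs_bruteforce(g)
            _, triples = run_ccr_detailed(g)
            got = {oracle.canonical_triple(*t) for t in triples}
            assert got == forced


class TestRunCcr:
    def test_f1_full_chromosome(self, f1):
        t = run_ccr(f1)
        assert len(t.walks) == 1
        assert t.walks[0].steps == (("a", "+"), ("b", "+"), ("b", "+"), ("c", "+"))
        assert contiguity_discordance(f1, t) == 0

    def test_f2_discordance_two(self, f2):
        t = run_ccr(f2)
        assert contiguity_discordance(f2, t) == 2

    def test_f3_closed_contig(self, f3):
        t = run_ccr(f3)
        assert len(t.walks) == 1 and t.walks[0].closed
        assert contiguity_discordance(f3, t) == 0

    def test_matches_bruteforce_optimum(self):
        for case in small_sim_cases(30):
            g = case.graph
            t = run_ccr(g)
            opt, _ = oracle.optimal_covering_bruteforce(g)
            assert contiguity_discordance(g, t) == opt

    def test_contigs_in_every_min_ed(self):
        for case in small_sim_cases(25):
            g = case.graph
            t = run_ccr(g)
            mins = oracle.enumerate_min_eds(g)
            for w in t.walks:
                assert all(oracle.walk_in_decomposition(w, d) for d in mins)

    def test_deterministic(self, f2):
        t1 = run_ccr(f2)
        t2 = run_ccr(f2)
        assert [w.steps for w in t1.walks] == [w.steps for w in t2.walks]

    def test_row_order_invariance(self, f2):
        # rebuild with permuted record order; covering must be identical
        segs = list(f2.segments.values())[::-1]
        adjs = list(f2.adjacencies.values())[::-1]
        g2 = build_iag(
            segs, adjs, segment_mu={s.id: f2.mu[seg_key(s.id)] for s in segs},
            adjacency_mu={a.key: f2.mu[a.key] for a in adjs},
        )
        t1, t2 = run_ccr(f2), run_ccr(g2)
        assert [w.steps for w in t1.walks] == [w.steps for w in t2.walks]


class TestNaive:
    def test_simple_path_fully_recovered(self):
        g = build_iag(
            [Segment("a"), Segment("b"), Segment("c")],
            [
                Adjacency(ext("a", "h"), ext("b", "t"), "R"),
                Adjacency(ext("b", "h"), ext("c", "t"), "R"),
            ],
        )
        t = naive_covering(g)
        assert len(t.walks) == 1
        assert contiguity_discordance(g, t) == 0

    def test_f1_fragments_at_b(self, f1):
        t = naive_covering(f1)
        assert contiguity_discordance(f1, t) == 3
        assert contiguity_discordance(f1, run_ccr(f1)) == 0

    def test_f2_everything_ambiguous(self, f2):
        assert contiguity_discordance(f2, naive_covering(f2)) == 4


class TestDominance:
    def test_on_medium_simulations(self):
        for case in medium_sim_cases(30):
            g = case.graph
            dc = contiguity_discordance(g, run_ccr(g))
            dn = contiguity_discordance(g, naive_covering(g))
            dp = contiguity_discordance(g, primitive_covering(g))
            assert dc <= dn <= dp == g.mu_adjacency_total()

    def test_validators_accept_all_strategies(self):
        for case in medium_sim_cases(15):
            g = case.graph
            for t in (run_ccr(g), naive_covering(g), primitive_covering(g)):
                ok, violations = validate_covering(g, t)
                assert ok, violations


class TestRecovery:
    def test_unit_copy_number_exact(self):
        recovered = 0
        for case in medium_sim_cases(40, base_seed=5000):
            g = case.graph
            if any(v != 1 for v in g.mu.values()):
                continue
            recovered += 1
            t = run_ccr(g)
            assert len(t.walks) == len(case.truth)
            for w in t.walks:
                assert any(walks_equal(w, chrom) for chrom in case.truth)
        assert recovered >= 3
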