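import random

import pytest

from karyocover.iag import Adjacency, Extremity, Segment, build_iag
from karyocover.simulator import SimConfig, simulate


def ext(sid, side):
    return Extremity(sid, side)


def make_f1():
    """Tandem-duplication fixture: a, b, b, c with mu(b) = 2."""
    return build_iag(
        [Segment("a", "chr", 1, 100), Segment("b", "chr", 101, 200), Segment("c", "chr", 201, 300)],
        [
            Adjacency(ext("a", "h"), ext("b", "t"), "R"),
            Adjacency(ext("b", "h"), ext("b", "t"), "N"),
            Adjacency(ext("b", "h"), ext("c", "t"), "R"),
        ],
        segment_mu={"a": 1, "b": 2, "c": 1},
    )


def make_f2():
    """Ambiguity fixture: two minimal decompositions pair {a,c} with {d,e}
    across the two copies of b either way."""
    return build_iag(
        [Segment(s, "chr", 1 + 100 * i, 100 + 100 * i) for i, s in enumerate("abcde")],
        [
            Adjacency(ext("a", "h"), ext("b", "t"), "N"),
            Adjacency(ext("c", "h"), ext("b", "t"), "N"),
            Adjacency(ext("b", "h"), ext("d", "t"), "N"),
            Adjacency(ext("b", "h"), ext("e", "t"), "N"),
        ],
        segment_mu={"a": 1, "b": 2, "c": 1, "d": 1, "e": 1},
    )


def make_f3():
    """Circular fixture: one segment closed into a cycle."""
    return build_iag(
        [Segment("a", "chr", 1, 100)],
        [Adjacency(ext("a", "h"), ext("a", "t"), "N")],
        segment_mu={"a": 1},
    )


@pytest.fixture
def f1():
    return make_f1()


@pytest.fixture
def f2():
    return make_f2()


@pytest.fixture
def f3():
    return make_f3()


def small_sim_cases(n_seeds, mu_cap=12, base_seed=0):
    """Simulated cases with total edge multiplicity under the oracle cap."""
    out = []
    for seed in range(base_seed, base_seed + n_seeds):
        r = random.Random(seed)
        cfg = SimConfig(
            seed=seed,
            n_chromosomes=r.choice([1, 1, 2]),
            segments_per_chromosome=r.choice([2, 3, 3, 4]),
            segment_length=100,
            deletions=r.choice([0, 0, 1]),
            tandem_duplications=r.choice([0, 1, 1, 2]),
            inversions=r.choice([0, 1]),
            translocations=r.choice([0, 1]),
            circularizations=r.choice([0, 0, 1]),
            whole_genome_duplications=r.choice([0, 0, 0, 1]),
        )
        case = simulate(cfg)
        if case.graph.mu_total() <= mu_cap:
            out.append(case)
    return out


def medium_sim_cases(n_seeds, base_seed=1000):
    out = []
    for seed in range(base_seed, base_seed + n_seeds):
        r = random.Random(seed)
        cfg = SimConfig(
            seed=seed,
            n_chromosomes=r.choice([1, 2, 3]),
            segments_per_chromosome=r.choice([3, 5, 8]),
            segment_length=1000,
            deletions=r.choice([0, 1, 2]),
            tandem_duplications=r.choice([0, 1, 2, 3]),
            inversions=r.choice([0, 1, 2]),
            translocations=r.choice([0, 1, 2]),
            circularizations=r.choice([0, 1]),
            whole_genome_duplications=r.choice([0, 0, 1]),
        )
        out.append(simulate(cfg))
    return out
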