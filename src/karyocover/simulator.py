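"""Simulation of rearranged genomes with known chromosome structure.

A reference genome is segmented up front (segment boundaries are the only
allowed breakpoints), large-scale events are applied to the derived
chromosomes, and the induced weighted interval adjacency graph is emitted by
counting edge traversals — so the simulated genome is, by construction, an
Eulerian decomposition of its own graph.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from .iag import (
    Adjacency,
    Extremity,
    GraphError,
    NOVEL,
    REFERENCE,
    Segment,
    Walk,
    WeightedIAG,
    build_iag,
)

__all__ = [
    "SimConfig",
    "SimGenome",
    "SimulatedCase",
    "simulate_reference",
    "apply_events",
    "genome_to_iag",
    "simulate",
    "truth_walks",
]

EVENT_TYPES = (
    "deletion",
    "tandem_duplication",
    "inversion",
    "translocation",
    "circularization",
)


@dataclass(frozen=True)
class SimConfig:
    """All randomness flows from ``seed``; every count may be zero."""

    seed: int
    n_chromosomes: int = 2
    segments_per_chromosome: int = 4
    segment_length: int = 1000
    deletions: int = 0
    tandem_duplications: int = 0
    inversions: int = 0
    translocations: int = 0
    circularizations: int = 0
    whole_genome_duplications: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_chromosomes",
            "segments_per_chromosome",
            "segment_length",
            "deletions",
            "tandem_duplications",
            "inversions",
            "translocations",
            "circularizations",
            "whole_genome_duplications",
        ):
            if getattr(self, name) < 0:
                raise GraphError(f"{name} must be >= 0")


@dataclass
class SimGenome:
    """Derived chromosomes as oriented segment sequences plus the reference
    adjacency relation needed to classify induced adjacencies."""

    chromosomes: list[tuple[tuple[tuple[str, str], ...], bool]]
    reference_adjacencies: frozenset = frozenset()
    event_log: list[str] = field(default_factory=list)


@dataclass
class SimulatedCase:
    segments: dict[str, Segment]
    genome: SimGenome
    graph: WeightedIAG
    truth: list[Walk]


def simulate_reference(cfg: SimConfig) -> tuple[dict[str, Segment], SimGenome]:
    segments: dict[str, Segment] = {}
    chromosomes = []
    ref_pairs = set()
    for c in range(1, cfg.n_chromosomes + 1):
        chrom = f"chr{c}"
        ids = []
        for i in range(cfg.segments_per_chromosome):
            sid = f"{chrom}.{i + 1:03d}"
            start = i * cfg.segment_length + 1
            segments[sid] = Segment(
                sid, chrom, start, start + cfg.segment_length - 1
            )
            ids.append(sid)
        chromosomes.append((tuple((sid, "+") for sid in ids), False))
        for a, b in zip(ids, ids[1:]):
            ref_pairs.add(
                tuple(sorted((Extremity(a, "h"), Extremity(b, "t"))))
            )
    return segments, SimGenome(chromosomes, frozenset(ref_pairs))


def _flip(step: tuple[str, str]) -> tuple[str, str]:
    return (step[0], "-" if step[1] == "+" else "+")


def apply_events(genome: SimGenome, cfg: SimConfig) -> SimGenome:
    rng = random.Random(cfg.seed)
    chroms = [(list(steps), closed) for steps, closed in genome.chromosomes]
    log: list[str] = []

    events = (
        ["deletion"] * cfg.deletions
        + ["tandem_duplication"] * cfg.tandem_duplications
        + ["inversion"] * cfg.inversions
        + ["translocation"] * cfg.translocations
        + ["circularization"] * cfg.circularizations
    )
    rng.shuffle(events)

    for ev in events:
        for attempt in range(50):
            if _try_event(ev, chroms, rng, log):
                break
        else:
            log.append(f"{ev}: inapplicable after 50 draws, skipped")

    for _ in range(cfg.whole_genome_duplications):
        chroms = chroms + [(list(steps), closed) for steps, closed in chroms]
        log.append("whole_genome_duplication")

    return SimGenome(
        [(tuple(steps), closed) for steps, closed in chroms if steps],
        genome.reference_adjacencies,
        genome.event_log + log,
    )


def _try_event(ev: str, chroms: list, rng: random.Random, log: list) -> bool:
    candidates = [i for i, (steps, _) in enumerate(chroms) if steps]
    if not candidates:
        return False
    ci = rng.choice(candidates)
    steps, closed = chroms[ci]
    n = len(steps)
    if ev == "deletion":
        if n <= 1:
            return False
        i = rng.randrange(n)
        del steps[i]
        log.append(f"deletion of position {i} on chromosome {ci}")
        return True
    if ev == "tandem_duplication":
        i = rng.randrange(n)
        steps.insert(i + 1, steps[i])
        log.append(f"tandem duplication of position {i} on chromosome {ci}")
        return True
    if ev == "inversion":
        i = rng.randrange(n)
        j = min(n - 1, i + rng.randrange(1, 4) - 1)
        steps[i : j + 1] = [_flip(s) for s in reversed(steps[i : j + 1])]
        log.append(f"inversion of positions {i}-{j} on chromosome {ci}")
        return True
    if ev == "translocation":
        linear = [
            k for k in candidates if not chroms[k][1] and k != ci
        ]
        if closed or not linear:
            return False
        cj = rng.choice(linear)
        other, _ = chroms[cj]
        i = rng.randrange(n + 1)
        j = rng.randrange(len(other) + 1)
        new_a = steps[:i] + other[j:]
        new_b = other[:j] + steps[i:]
        if not new_a or not new_b:
            return False
        chroms[ci] = (new_a, False)
        chroms[cj] = (new_b, False)
        log.append(
            f"reciprocal translocation between chromosomes {ci} and {cj}"
        )
        return True
    if ev == "circularization":
        if closed:
            return False
        chroms[ci] = (steps, True)
        log.append(f"circularization of chromosome {ci}")
        return True
    raise GraphError(f"unknown event type {ev}")


def _adjacency_of(
    genome: SimGenome, a: tuple[str, str], b: tuple[str, str]
) -> Adjacency:
    p = Extremity(a[0], "h" if a[1] == "+" else "t")
    q = Extremity(b[0], "t" if b[1] == "+" else "h")
    pair = tuple(sorted((p, q)))
    kind = REFERENCE if pair in genome.reference_adjacencies else NOVEL
    return Adjacency(p, q, kind)


def genome_to_iag(
    segments: dict[str, Segment], genome: SimGenome
) -> WeightedIAG:
    """Induced graph: multiplicities are traversal counts of the derived
    chromosomes; adjacency kinds follow the reference relation."""
    seg_counts: dict[str, int] = {}
    adj_counts: dict = {}
    adj_objs: dict = {}
    for steps, closed in genome.chromosomes:
        for sid, _ in steps:
            seg_counts[sid] = seg_counts.get(sid, 0) + 1
        pairs = list(zip(steps, steps[1:]))
        if closed and steps:
            pairs.append((steps[-1], steps[0]))
        for a, b in pairs:
            adj = _adjacency_of(genome, a, b)
            adj_objs[adj.key] = adj
            adj_counts[adj.key] = adj_counts.get(adj.key, 0) + 1
    used = {sid: segments[sid] for sid in seg_counts}
    return build_iag(
        [used[sid] for sid in sorted(used)],
        [adj_objs[k] for k in sorted(adj_objs)],
        segment_mu=seg_counts,
        adjacency_mu=adj_counts,
    )


def truth_walks(genome: SimGenome) -> list[Walk]:
    """The derived chromosomes as full walks with adjacency edge keys."""
    walks = []
    for steps, closed in genome.chromosomes:
        pairs = list(zip(steps, steps[1:]))
        if closed:
            pairs.append((steps[-1], steps[0]))
        adjs = tuple(_adjacency_of(genome, a, b).key for a, b in pairs)
        walks.append(Walk(tuple(steps), adjs, closed))
    return walks


def simulate(cfg: SimConfig) -> SimulatedCase:
    segments, reference = simulate_reference(cfg)
    genome = apply_events(reference, cfg)
    graph = genome_to_iag(segments, genome)
    return SimulatedCase(segments, genome, graph, truth_walks(genome))
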