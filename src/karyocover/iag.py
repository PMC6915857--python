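"""Weighted interval adjacency graph (karyotype graph) data model.

The graph is built on *segments* (continuous reference intervals) whose two
endpoints, the tail ``t`` and head ``h`` *extremities*, form the vertex set.
Two edge classes connect the vertices: one *segment edge* per segment
(joining its own extremities) and *adjacency edges* joining arbitrary
extremities.  Every edge carries a non-negative integer multiplicity ``mu``
(its copy number).  Chromosomes and contigs are segment/adjacency
edge-alternating walks over this graph.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple

__all__ = [
    "Extremity",
    "Segment",
    "Adjacency",
    "Walk",
    "WeightedIAG",
    "EdgeUsage",
    "REFERENCE",
    "NOVEL",
    "SUPPLEMENTAL",
    "FORWARD",
    "REVERSE",
    "build_iag",
    "positive_restriction",
    "copy_number_excess",
    "is_decomposable",
    "classify_components",
    "walks_equal",
    "usage_of",
    "GraphError",
]

# adjacency kinds; contracted edges receive unique "ctr<N>" kinds at runtime
REFERENCE = "R"
NOVEL = "N"
SUPPLEMENTAL = "supp"
CONTRACTED_PREFIX = "ctr"

FORWARD = "+"
REVERSE = "-"

TAIL = "t"
HEAD = "h"


class GraphError(ValueError):
    """Raised for structurally invalid graphs, walks, or references."""


class Extremity(NamedTuple):
    """One endpoint of a segment: ``(segment_id, 't' | 'h')``."""

    segment_id: str
    side: str

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return f"{self.segment_id}^{self.side}"


def tail(segment_id: str) -> Extremity:
    return Extremity(segment_id, TAIL)


def head(segment_id: str) -> Extremity:
    return Extremity(segment_id, HEAD)


def opposite(v: Extremity) -> Extremity:
    return Extremity(v.segment_id, TAIL if v.side == HEAD else HEAD)


@dataclass(frozen=True)
class Segment:
    """A reference interval.  Coordinates are 1-based inclusive."""

    id: str
    chrom: str = ""
    start: int = 0
    end: int = 0

    def __post_init__(self) -> None:
        if self.start and self.end and self.start > self.end:
            raise GraphError(f"segment {self.id}: start > end")

    @property
    def length(self) -> int:
        if self.start and self.end:
            return self.end - self.start + 1
        return 1


@dataclass(frozen=True)
class Adjacency:
    """An unordered pair of extremities; ``{p, q} == {q, p}``.

    ``kind`` distinguishes parallel edges between the same extremities:
    reference/novel from the input, plus supplemental and contracted
    bookkeeping edges used by the covering algorithm.
    """

    first: Extremity
    second: Extremity
    kind: str = NOVEL

    def __post_init__(self) -> None:
        if self.second < self.first:
            a, b = self.second, self.first
            object.__setattr__(self, "first", a)
            object.__setattr__(self, "second", b)

    @property
    def is_loop(self) -> bool:
        return self.first == self.second

    @property
    def is_supplemental(self) -> bool:
        return self.kind == SUPPLEMENTAL

    @property
    def is_contracted(self) -> bool:
        return self.kind.startswith(CONTRACTED_PREFIX)

    def extremities(self) -> tuple[Extremity, Extremity]:
        return (self.first, self.second)

    def other(self, v: Extremity) -> Extremity:
        if v == self.first:
            return self.second
        if v == self.second:
            return self.first
        raise GraphError(f"{v} is not an endpoint of {self}")

    @property
    def key(self) -> "AdjKey":
        return ("A", (self.first, self.second), self.kind)


# Edge keys: hashable identifiers usable in ``mu`` mappings.
SegKey = tuple[str, str]  # ("S", segment_id)
AdjKey = tuple[str, tuple[Extremity, Extremity], str]
EdgeKey = SegKey | AdjKey


def seg_key(segment_id: str) -> SegKey:
    return ("S", segment_id)


def is_seg_key(key: EdgeKey) -> bool:
    return key[0] == "S"


@dataclass(frozen=True)
class Walk:
    """A segment/adjacency edge-alternating path or cycle.

    ``steps`` is the ordered sequence of oriented segment traversals; a
    forward step enters through the tail and exits through the head.
    ``adjs`` holds the adjacency edge key between consecutive steps; closed
    walks carry one extra closing adjacency (``len(adjs) == len(steps)``),
    open walks start and end with a segment edge
    (``len(adjs) == len(steps) - 1``).
    """

    steps: tuple[tuple[str, str], ...]
    adjs: tuple[AdjKey, ...]
    closed: bool = False

    def __post_init__(self) -> None:
        expect = len(self.steps) if self.closed else len(self.steps) - 1
        if len(self.adjs) != expect:
            raise GraphError(
                f"walk with {len(self.steps)} steps has {len(self.adjs)} "
                f"adjacencies (expected {expect})"
            )
        if not self.steps:
            raise GraphError("empty walk")

    def __len__(self) -> int:
        return len(self.steps)

    @staticmethod
    def _flip(step: tuple[str, str]) -> tuple[str, str]:
        sid, o = step
        return (sid, REVERSE if o == FORWARD else FORWARD)

    def entry_extremity(self, i: int) -> Extremity:
        sid, o = self.steps[i]
        return Extremity(sid, TAIL if o == FORWARD else HEAD)

    def exit_extremity(self, i: int) -> Extremity:
        sid, o = self.steps[i]
        return Extremity(sid, HEAD if o == FORWARD else TAIL)

    def reverse(self) -> "Walk":
        n = len(self.steps)
        steps = tuple(self._flip(s) for s in reversed(self.steps))
        if not self.closed:
            return Walk(steps, tuple(reversed(self.adjs)), False)
        adjs = tuple(self.adjs[n - 2 - i] for i in range(n - 1)) + (
            self.adjs[n - 1],
        )
        return Walk(steps, adjs, True)

    def rotate(self, k: int) -> "Walk":
        if not self.closed:
            raise GraphError("cannot rotate an open walk")
        n = len(self.steps)
        k %= n
        return Walk(
            self.steps[k:] + self.steps[:k], self.adjs[k:] + self.adjs[:k], True
        )

    def _token_seq(self) -> tuple:
        toks: list = []
        for i, s in enumerate(self.steps):
            toks.append(s)
            if i < len(self.adjs):
                toks.append(self.adjs[i])
        return tuple(toks)

    def sort_key(self) -> tuple:
        """Total order over canonical walks (string-mapped tokens, so step
        and adjacency tokens compare safely)."""
        w = self.canonical()
        return (w.closed, tuple(repr(t) for t in w._token_seq()))

    def canonical(self) -> "Walk":
        """Representative under reversal (open) / rotation+reversal (closed)."""
        if not self.closed:
            rev = self.reverse()
            return min((self, rev), key=lambda w: w._token_seq())
        candidates = []
        for w in (self, self.reverse()):
            for k in range(len(w.steps)):
                candidates.append(w.rotate(k))
        return min(candidates, key=lambda w: w._token_seq())

    def consecutive_adjacency_triples(
        self,
    ) -> Iterator[tuple[AdjKey, str, AdjKey]]:
        """Yield ``(e, segment_id, f)`` for adjacency edges consecutive
        across a segment traversal (wrapping around for closed walks)."""
        n = len(self.adjs)
        if n < 2 and not (self.closed and n == 1):
            return
        if self.closed:
            for i in range(n):
                e = self.adjs[i - 1]
                f = self.adjs[i % n]
                yield (e, self.steps[i][0], f)
        else:
            for i in range(1, n):
                yield (self.adjs[i - 1], self.steps[i][0], self.adjs[i])

    def length_bp(self, g: "WeightedIAG") -> int:
        return sum(g.segments[sid].length for sid, _ in self.steps)


def walks_equal(w1: Walk, w2: Walk) -> bool:
    """Equality up to reversal (open) or rotation and reversal (closed)."""
    if w1.closed != w2.closed:
        return False
    return w1.canonical() == w2.canonical()


@dataclass
class EdgeUsage:
    """Exact per-edge traversal tallies of a walk multiset."""

    counts: Counter

    def __getitem__(self, key: EdgeKey) -> int:
        return self.counts.get(key, 0)


def usage_of(walks: Iterable[Walk]) -> EdgeUsage:
    counts: Counter = Counter()
    for w in walks:
        for sid, _ in w.steps:
            counts[seg_key(sid)] += 1
        for a in w.adjs:
            counts[a] += 1
    return EdgeUsage(counts)


@dataclass
class WeightedIAG:
    """A weighted interval adjacency graph.

    The vertex set is always derived from ``segments`` and never supplied.
    Iteration over vertices and edges is in canonical sorted order so every
    downstream algorithm is deterministic.
    """

    segments: dict[str, Segment] = field(default_factory=dict)
    adjacencies: dict[AdjKey, Adjacency] = field(default_factory=dict)
    mu: dict[EdgeKey, int] = field(default_factory=dict)

    # -- vertex / incidence queries -------------------------------------

    def vertices(self) -> list[Extremity]:
        out: list[Extremity] = []
        for sid in sorted(self.segments):
            out.append(tail(sid))
            out.append(head(sid))
        return out

    def has_vertex(self, v: Extremity) -> bool:
        return v.segment_id in self.segments

    def segment_edge(self, v: Extremity) -> SegKey:
        return seg_key(v.segment_id)

    def adjacency_keys_at(self, v: Extremity) -> list[AdjKey]:
        """Adjacency edge keys incident to ``v`` (loops listed once)."""
        out = []
        for key, adj in self.adjacencies.items():
            if v in (adj.first, adj.second):
                out.append(key)
        return sorted(out)

    def adjacency_endpoint_count(self, v: Extremity) -> int:
        """Sum of ``l(e) * mu(e)`` over adjacency edges at ``v``."""
        total = 0
        for key in self.adjacency_keys_at(v):
            adj = self.adjacencies[key]
            l = 2 if adj.is_loop else 1
            total += l * self.mu[key]
        return total

    def adjacency_edge_keys(self) -> list[AdjKey]:
        return sorted(self.adjacencies)

    def segment_edge_keys(self) -> list[SegKey]:
        return [seg_key(sid) for sid in sorted(self.segments)]

    def mu_total(self) -> int:
        return sum(self.mu.values())

    def mu_adjacency_total(self) -> int:
        return sum(self.mu[k] for k in self.adjacencies)

    # -- mutation helpers (used by the covering algorithm) --------------

    def add_segment(self, segment: Segment, mu: int) -> None:
        if mu < 0:
            raise GraphError(f"negative multiplicity for segment {segment.id}")
        self.segments[segment.id] = segment
        self.mu[seg_key(segment.id)] = mu

    def add_adjacency(self, adj: Adjacency, mu: int) -> None:
        for v in adj.extremities():
            if not self.has_vertex(v):
                raise GraphError(f"adjacency endpoint {v} has no segment")
        if mu < 0:
            raise GraphError(f"negative multiplicity for adjacency {adj}")
        key = adj.key
        if key in self.adjacencies:
            self.mu[key] += mu
        else:
            self.adjacencies[key] = adj
            self.mu[key] = mu

    def remove_adjacency_copy(self, key: AdjKey, n: int = 1) -> None:
        if self.mu.get(key, 0) < n:
            raise GraphError(f"cannot remove {n} copies of {key}")
        self.mu[key] -= n
        if self.mu[key] == 0:
            del self.mu[key]
            del self.adjacencies[key]

    def remove_segment_copy(self, sid: str, n: int = 1) -> None:
        key = seg_key(sid)
        if self.mu.get(key, 0) < n:
            raise GraphError(f"cannot remove {n} copies of segment {sid}")
        self.mu[key] -= n
        if self.mu[key] == 0:
            for akey in self.adjacency_keys_at(tail(sid)) + self.adjacency_keys_at(
                head(sid)
            ):
                if self.mu.get(akey, 0) > 0:
                    raise GraphError(
                        f"removing last copy of segment {sid} would strand "
                        f"adjacency {akey}"
                    )
            del self.mu[key]
            del self.segments[sid]

    def copy(self) -> "WeightedIAG":
        return WeightedIAG(
            dict(self.segments), dict(self.adjacencies), dict(self.mu)
        )

    # -- connectivity ---------------------------------------------------

    def connected_components(self) -> list[set[Extremity]]:
        """Components of the positive graph, in canonical order."""
        adj_map: dict[Extremity, set[Extremity]] = {
            v: set() for v in self.vertices()
        }
        for sid in self.segments:
            adj_map[tail(sid)].add(head(sid))
            adj_map[head(sid)].add(tail(sid))
        for key, adj in self.adjacencies.items():
            if self.mu.get(key, 0) > 0:
                adj_map[adj.first].add(adj.second)
                adj_map[adj.second].add(adj.first)
        seen: set[Extremity] = set()
        comps: list[set[Extremity]] = []
        for v in self.vertices():
            if v in seen:
                continue
            stack, comp = [v], set()
            while stack:
                u = stack.pop()
                if u in comp:
                    continue
                comp.add(u)
                stack.extend(adj_map[u] - comp)
            seen |= comp
            comps.append(comp)
        return comps

    def restrict_to(self, comp: set[Extremity]) -> "WeightedIAG":
        sids = {v.segment_id for v in comp}
        segs = {sid: self.segments[sid] for sid in sids}
        adjs = {
            k: a
            for k, a in self.adjacencies.items()
            if a.first.segment_id in sids
        }
        mu = {seg_key(sid): self.mu[seg_key(sid)] for sid in sids}
        mu.update({k: self.mu[k] for k in adjs})
        return WeightedIAG(segs, adjs, mu)


def build_iag(
    segments: Iterable[Segment],
    adjacencies: Iterable[Adjacency],
    multiplicities: Mapping[EdgeKey, int] | None = None,
    *,
    segment_mu: Mapping[str, int] | None = None,
    adjacency_mu: Mapping[AdjKey, int] | None = None,
) -> WeightedIAG:
    """Assemble a :class:`WeightedIAG` from records.

    Multiplicities may be passed either as a single mapping keyed by edge
    key, or split into ``segment_mu`` (by segment id) / ``adjacency_mu``
    (by adjacency key).  A zero-multiplicity segment carrying a positive
    adjacency is rejected: such an edge could never appear in any
    decomposition, so the input is inconsistent.
    """
    g = WeightedIAG()
    mult = dict(multiplicities or {})
    for seg in segments:
        if seg.id in g.segments:
            raise GraphError(f"duplicate segment id {seg.id}")
        key = seg_key(seg.id)
        mu = mult[key] if key in mult else (segment_mu or {}).get(seg.id, 1)
        if mu < 0:
            raise GraphError(f"negative multiplicity for segment {seg.id}")
        g.segments[seg.id] = seg
        g.mu[key] = mu
    for adj in adjacencies:
        key = adj.key
        for v in adj.extremities():
            if v.segment_id not in g.segments:
                raise GraphError(
                    f"adjacency endpoint {v} references unknown segment"
                )
        mu = mult[key] if key in mult else (adjacency_mu or {}).get(key, 1)
        if mu < 0:
            raise GraphError(f"negative multiplicity for adjacency {adj}")
        if key in g.adjacencies:
            raise GraphError(f"duplicate adjacency {key}")
        g.adjacencies[key] = adj
        g.mu[key] = mu
    for key, adj in g.adjacencies.items():
        if g.mu[key] < 1:
            continue
        for v in adj.extremities():
            if g.mu[seg_key(v.segment_id)] == 0:
                raise GraphError(
                    f"adjacency {key} with mu>=1 attached to zero-copy "
                    f"segment {v.segment_id}"
                )
    return g


def positive_restriction(g: WeightedIAG) -> WeightedIAG:
    """Drop all edges with multiplicity 0; vertices of fully removed
    segments disappear with them."""
    segs = {sid: s for sid, s in g.segments.items() if g.mu[seg_key(sid)] >= 1}
    adjs = {}
    mu = {seg_key(sid): g.mu[seg_key(sid)] for sid in segs}
    for key, adj in g.adjacencies.items():
        if g.mu[key] < 1:
            continue
        for v in adj.extremities():
            if v.segment_id not in segs:
                raise GraphError(
                    f"adjacency {key} dangles from removed segment "
                    f"{v.segment_id}"
                )
        adjs[key] = adj
        mu[key] = g.mu[key]
    return WeightedIAG(segs, adjs, mu)


def copy_number_excess(g: WeightedIAG, v: Extremity) -> int:
    """``x(v) = mu(e_S(v)) - sum_{e in E_A(v)} l(e) * mu(e)`` where ``l``
    doubles loop edges."""
    if not g.has_vertex(v):
        raise GraphError(f"unknown vertex {v}")
    return g.mu[g.segment_edge(v)] - g.adjacency_endpoint_count(v)


def is_decomposable(g: WeightedIAG) -> bool:
    """An Eulerian decomposition exists iff no vertex has negative excess."""
    return all(copy_number_excess(g, v) >= 0 for v in g.vertices())


def classify_components(
    g: WeightedIAG,
) -> tuple[list[set[Extremity]], list[set[Extremity]]]:
    """Split connected components into ``(C_plus, C_zero)``: components
    containing a positive-excess vertex versus fully balanced ones."""
    c_plus, c_zero = [], []
    for comp in g.connected_components():
        if any(copy_number_excess(g, v) > 0 for v in comp):
            c_plus.append(comp)
        else:
            c_zero.append(comp)
    return c_plus, c_zero
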