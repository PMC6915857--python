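"""Eulerian decomposition of weighted interval adjacency graphs.

``solve_edp`` constructs some Eulerian decomposition in linear time by
balancing every component with temporary adjacency edges, matching segment
with adjacency edge copies at each vertex into alternating cycles, and
stripping the temporary edges to split cycles into paths.  ``solve_min_edp``
then merges cycles with paths/cycles through shared segment edges until each
fully balanced component is a single cycle and no other component retains a
cycle, reaching the provable minimum

    |D| = 1/2 * sum_v x(v) + |C_0(G)|.

``k3_reduction`` builds the instance family showing that *maximising* the
decomposition cardinality is NP-hard; it is solved only by brute force (see
:mod:`karyocover.oracle`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable

from .iag import (
    Adjacency,
    AdjKey,
    Extremity,
    GraphError,
    NOVEL,
    Segment,
    Walk,
    WeightedIAG,
    classify_components,
    copy_number_excess,
    head,
    seg_key,
    tail,
    usage_of,
)

__all__ = [
    "Decomposition",
    "NonDecomposableError",
    "solve_edp",
    "solve_min_edp",
    "expected_path_count",
    "min_decomposition_size",
    "validate_decomposition",
    "k3_reduction",
    "merge_cycle_into",
]

_TMP = "tmp-balance"  # kind of throwaway balancing edges inside solve_edp


class NonDecomposableError(GraphError):
    def __init__(self, violations: list[tuple[Extremity, int]]):
        self.violations = violations
        detail = ", ".join(f"x({v}) = {x}" for v, x in violations)
        super().__init__(f"graph is not decomposable: {detail}")


@dataclass
class Decomposition:
    """A multiset of walks using every edge exactly its multiplicity."""

    walks: list[Walk]
    source: WeightedIAG | None = None

    def __len__(self) -> int:
        return len(self.walks)

    @property
    def paths(self) -> list[Walk]:
        return [w for w in self.walks if not w.closed]

    @property
    def cycles(self) -> list[Walk]:
        return [w for w in self.walks if w.closed]

    def canonical_key(self) -> tuple:
        return tuple(sorted(w.sort_key() for w in self.walks))


def _check_decomposable(g: WeightedIAG) -> None:
    bad = [
        (v, copy_number_excess(g, v))
        for v in g.vertices()
        if copy_number_excess(g, v) < 0
    ]
    if bad:
        raise NonDecomposableError(bad)


def expected_path_count(g: WeightedIAG) -> int:
    """Number of open walks in *any* Eulerian decomposition."""
    total = sum(copy_number_excess(g, v) for v in g.vertices())
    assert total % 2 == 0, "total copy number excess must be even"
    return total // 2


def min_decomposition_size(g: WeightedIAG) -> int:
    _check_decomposable(g)
    _, c_zero = classify_components(g)
    return expected_path_count(g) + len(c_zero)


# -- transition-system construction -----------------------------------------

SegPort = tuple[str, int, str]  # (segment_id, copy index, 't'|'h')
AdjPort = tuple[AdjKey, int, int]  # (adjacency key, copy index, end 0|1)


def _adjacency_ports_at(g: WeightedIAG, v: Extremity) -> list[AdjPort]:
    ports: list[AdjPort] = []
    for key in g.adjacency_keys_at(v):
        adj = g.adjacencies[key]
        for j in range(g.mu[key]):
            if adj.is_loop:
                ports.append((key, j, 0))
                ports.append((key, j, 1))
            elif adj.first == v:
                ports.append((key, j, 0))
            else:
                ports.append((key, j, 1))
    return ports


def _extract_cycles(g: WeightedIAG) -> list[Walk]:
    """Decompose a fully balanced graph into alternating cycles by matching
    segment-edge with adjacency-edge copies at every vertex in canonical
    order."""
    seg_to_adj: dict[SegPort, AdjPort] = {}
    adj_to_seg: dict[AdjPort, SegPort] = {}
    for v in g.vertices():
        m = g.mu[g.segment_edge(v)]
        seg_ports = [(v.segment_id, i, v.side) for i in range(m)]
        adj_ports = _adjacency_ports_at(g, v)
        assert len(seg_ports) == len(adj_ports), f"vertex {v} is unbalanced"
        for sp, ap in zip(seg_ports, adj_ports):
            seg_to_adj[sp] = ap
            adj_to_seg[ap] = sp

    visited: set[tuple[str, int]] = set()
    cycles: list[Walk] = []
    for sid in sorted(g.segments):
        for i in range(g.mu[seg_key(sid)]):
            if (sid, i) in visited:
                continue
            steps: list[tuple[str, str]] = []
            adjs: list[AdjKey] = []
            cur, orient = (sid, i), "+"
            while True:
                visited.add(cur)
                steps.append((cur[0], orient))
                exit_side = "h" if orient == "+" else "t"
                akey, j, end = seg_to_adj[(cur[0], cur[1], exit_side)]
                adjs.append(akey)
                nsid, ni, nside = adj_to_seg[(akey, j, 1 - end)]
                cur, orient = (nsid, ni), ("+" if nside == "t" else "-")
                if cur == (sid, i):
                    break
            cycles.append(Walk(tuple(steps), tuple(adjs), True))
    return cycles


def _strip_tmp(cycle: Walk) -> list[Walk]:
    """Remove temporary balancing adjacencies, splitting the cycle into
    open paths that start and end with segment edges."""
    tmp_idx = [i for i, a in enumerate(cycle.adjs) if a[2] == _TMP]
    if not tmp_idx:
        return [cycle]
    n = len(cycle.steps)
    out: list[Walk] = []
    for k, i in enumerate(tmp_idx):
        j = tmp_idx[(k + 1) % len(tmp_idx)]
        # path runs from step i+1 to step j (cyclically)
        idxs = []
        t = (i + 1) % n
        while True:
            idxs.append(t)
            if t == j:
                break
            t = (t + 1) % n
        steps = tuple(cycle.steps[t] for t in idxs)
        adjs = tuple(cycle.adjs[t] for t in idxs[:-1])
        out.append(Walk(steps, adjs, False))
    return out


def solve_edp(g: WeightedIAG) -> Decomposition:
    """Construct some Eulerian decomposition of a decomposable graph."""
    _check_decomposable(g)
    work = g.copy()
    # balance every positive-excess vertex with temporary loops, then pair
    # leftover excess-1 vertices in canonical order
    odd: list[Extremity] = []
    for v in work.vertices():
        x = copy_number_excess(work, v)
        if x >= 2:
            work.add_adjacency(Adjacency(v, v, _TMP), x // 2)
        if x % 2 == 1:
            odd.append(v)
    assert len(odd) % 2 == 0, "odd number of excess-1 vertices"
    for a, b in zip(odd[::2], odd[1::2]):
        work.add_adjacency(Adjacency(a, b, _TMP), 1)
    walks: list[Walk] = []
    for cycle in _extract_cycles(work):
        walks.extend(_strip_tmp(cycle))
    return Decomposition(walks, g)


def merge_cycle_into(q: Walk, c: Walk, sid: str) -> Walk:
    """Splice cycle ``c`` into walk ``q`` at a shared segment edge ``sid``,
    consuming both copies of the segment."""
    if not c.closed:
        raise GraphError("second argument must be a cycle")
    i = next(k for k, s in enumerate(q.steps) if s[0] == sid)
    j = next(k for k, s in enumerate(c.steps) if s[0] == sid)
    if c.steps[j][1] != q.steps[i][1]:
        c = c.reverse()
        j = next(k for k, s in enumerate(c.steps) if s[0] == sid)
    c = c.rotate(j)
    steps = q.steps[: i + 1] + c.steps[1:] + (c.steps[0],) + q.steps[i + 1 :]
    adjs = q.adjs[:i] + c.adjs + q.adjs[i:]
    return Walk(steps, adjs, q.closed)


def solve_min_edp(g: WeightedIAG) -> Decomposition:
    """Minimal-cardinality Eulerian decomposition via iterative merging of
    cycles through shared segment edges."""
    d = solve_edp(g)
    comps = g.connected_components()
    comp_of_sid: dict[str, int] = {}
    for ci, comp in enumerate(comps):
        for v in comp:
            comp_of_sid[v.segment_id] = ci
    balanced = [
        all(copy_number_excess(g, v) == 0 for v in comp) for comp in comps
    ]
    groups: dict[int, list[Walk]] = {ci: [] for ci in range(len(comps))}
    for w in d.walks:
        groups[comp_of_sid[w.steps[0][0]]].append(w)

    out: list[Walk] = []
    for ci in range(len(comps)):
        walks = sorted(groups[ci], key=lambda w: w.sort_key())
        while True:
            cycles = [w for w in walks if w.closed]
            done = (
                (len(walks) <= 1) if balanced[ci] else (len(cycles) == 0)
            )
            if done:
                break
            merged = False
            for c in cycles:
                sids = {s for s, _ in c.steps}
                partners = [
                    w
                    for w in walks
                    if w is not c and sids & {s for s, _ in w.steps}
                ]
                if partners:
                    q = min(partners, key=lambda w: w.sort_key())
                    sid = min(sids & {s for s, _ in q.steps})
                    walks.remove(c)
                    walks.remove(q)
                    walks.append(merge_cycle_into(q, c, sid))
                    merged = True
                    break
            assert merged, (
                "no mergeable cycle found although a cycle remains; "
                "component connectivity guarantees this cannot happen"
            )
        out.extend(walks)
    result = Decomposition(out, g)
    assert len(result) == min_decomposition_size(g)
    return result


def validate_decomposition(
    g: WeightedIAG, d: Decomposition
) -> tuple[bool, list[str]]:
    """Check alternation, endpoint, and exact edge-usage conditions.

    Violations are returned as data, not raised.
    """
    violations = validate_walks(g, d.walks)
    usage = usage_of(d.walks)
    for key in list(g.mu) + [k for k in usage.counts if k not in g.mu]:
        want = g.mu.get(key, 0)
        got = usage[key]
        if want != got:
            violations.append(f"edge {key}: used {got} times, mu = {want}")
    return (not violations, violations)


def validate_walks(g: WeightedIAG, walks: Iterable[Walk]) -> list[str]:
    """Structural validity of walks over ``g``: every step references a
    known segment and every recorded adjacency joins the facing extremities
    implied by the flanking steps."""
    violations: list[str] = []
    for wi, w in enumerate(walks):
        for sid, o in w.steps:
            if sid not in g.segments:
                violations.append(f"walk {wi}: unknown segment {sid}")
            if o not in "+-":
                violations.append(f"walk {wi}: bad orientation {o}")
        n = len(w.steps)
        for k, akey in enumerate(w.adjs):
            if akey not in g.adjacencies:
                violations.append(f"walk {wi}: unknown adjacency {akey}")
                continue
            p = w.exit_extremity(k)
            q = w.entry_extremity((k + 1) % n)
            want = tuple(sorted((p, q)))
            if akey[1] != want:
                violations.append(
                    f"walk {wi}: adjacency {akey} does not join {p} and {q}"
                )
    return violations


def k3_reduction(edges: Iterable[tuple[Hashable, Hashable]]) -> WeightedIAG:
    """Encode a simple even-degree graph as a balanced IAG whose maximal
    Eulerian decomposition reveals whether a triangle edge partition exists.

    Per vertex ``v``: a segment with ``mu = deg(v)`` and an adjacency loop
    at its tail with ``mu = deg(v) / 2``; per input edge ``{u, v}``: an
    adjacency between the two heads with ``mu = 1``.
    """
    edge_list = [tuple(e) for e in edges]
    deg: dict[Hashable, int] = {}
    for u, v in edge_list:
        if u == v:
            raise GraphError("self-loops are not allowed in a simple graph")
        deg[u] = deg.get(u, 0) + 1
        deg[v] = deg.get(v, 0) + 1
    if len({tuple(sorted((str(u), str(v)))) for u, v in edge_list}) != len(
        edge_list
    ):
        raise GraphError("parallel edges are not allowed in a simple graph")
    for v, dv in deg.items():
        if dv % 2:
            raise GraphError(f"vertex {v} has odd degree {dv}")
    g = WeightedIAG()
    for v in sorted(deg, key=str):
        g.add_segment(Segment(str(v)), deg[v])
    for v in sorted(deg, key=str):
        g.add_adjacency(Adjacency(tail(str(v)), tail(str(v)), NOVEL), deg[v] // 2)
    for u, v in edge_list:
        g.add_adjacency(Adjacency(head(str(u)), head(str(v)), NOVEL), 1)
    for v in g.vertices():
        assert copy_number_excess(g, v) == 0
    return g
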