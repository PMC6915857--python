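"""Consistent contig covering of karyotype graphs (the CCR algorithm).

A *contig covering* uses every segment edge exactly its multiplicity and
every adjacency edge at most its multiplicity; its *contiguity discordance*
is the total unused adjacency multiplicity.  The algorithm recovers, per
connected component, the covering of minimum discordance among those whose
every walk occurs in every minimal Eulerian decomposition:

1. balance the component so its minimal decomposition is a single cycle
   (supplemental segment + adjacencies toward every positive-excess vertex);
2. compute one minimal decomposition;
3. repeatedly test consecutive non-supplemental adjacency pairs for being
   *forced* (present in all minimal decompositions) and contract forced
   pairs into bookkeeping adjacency edges while growing the output contigs;
4. on the terminal graph, select a maximum multiset of leftover adjacency
   copies such that no two share a segment copy (a degree-budgeted
   b-matching), and attach them to free segment copies.

The forced-pair test is exact: a pair ``(e, y, f)`` is forced iff no
single-cycle decomposition of the (balanced, connected) working graph
avoids every ``e-y-f`` transition.  Avoidability is decided by choosing the
transition pattern through segment ``y`` only — transitions elsewhere are
free — so the question reduces to finding a forbidden-cell-free assignment
of tail-side to head-side adjacency endpoint copies at ``y`` whose support
reconnects the graph split at ``y``; that is a spanning-tree search over
class-level transition cells plus a bipartite feasibility check.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx

from .iag import (
    Adjacency,
    AdjKey,
    Extremity,
    GraphError,
    SUPPLEMENTAL,
    CONTRACTED_PREFIX,
    Segment,
    Walk,
    WeightedIAG,
    copy_number_excess,
    head,
    seg_key,
    tail,
    usage_of,
)
from .decomposition import (
    solve_min_edp,
    validate_walks,
    _check_decomposable,
)

__all__ = [
    "ContigCovering",
    "CcrState",
    "primitive_covering",
    "contiguity_discordance",
    "balance_transform",
    "is_pair_forced",
    "contract_forced_pair",
    "terminal_selection",
    "run_ccr",
    "run_ccr_detailed",
    "naive_covering",
    "validate_covering",
]

SUPP_SEGMENT_ID = "supp"


@dataclass
class ContigCovering:
    """A multiset of walks covering segment edges exactly and adjacency
    edges at most their multiplicities."""

    walks: list[Walk]
    source: WeightedIAG | None = None

    def __len__(self) -> int:
        return len(self.walks)


def primitive_covering(g: WeightedIAG) -> ContigCovering:
    """One single-segment open walk per segment copy; its discordance is
    the whole adjacency multiplicity."""
    walks = []
    for sid in sorted(g.segments):
        for _ in range(g.mu[seg_key(sid)]):
            walks.append(Walk(((sid, "+"),), (), False))
    return ContigCovering(walks, g)


def validate_covering(g: WeightedIAG, t: ContigCovering) -> tuple[bool, list[str]]:
    """Segment-usage exactness, adjacency boundedness, and alternation."""
    violations = validate_walks(g, t.walks)
    usage = usage_of(t.walks)
    for key in g.segment_edge_keys():
        if usage[key] != g.mu[key]:
            violations.append(
                f"segment {key}: used {usage[key]}, mu = {g.mu[key]}"
            )
    for key in g.adjacency_edge_keys():
        if usage[key] > g.mu[key]:
            violations.append(
                f"adjacency {key}: used {usage[key]} > mu = {g.mu[key]}"
            )
    for key in usage.counts:
        if key not in g.mu:
            violations.append(f"unknown edge {key} used")
    return (not violations, violations)


def contiguity_discordance(g: WeightedIAG, t: ContigCovering) -> int:
    ok, violations = validate_covering(g, t)
    if not ok:
        raise GraphError("invalid covering: " + "; ".join(violations))
    usage = usage_of(t.walks)
    return sum(g.mu[k] - usage[k] for k in g.adjacency_edge_keys())


# ---------------------------------------------------------------------------
# contig assembly bookkeeping


class _Fragment:
    """A growing output contig; ends expose the extremities still free."""

    __slots__ = ("steps", "adjs", "closed", "flip", "tag")

    def __init__(self, steps, adjs, closed=False, tag=0):
        self.steps = list(steps)
        self.adjs = list(adjs)
        self.closed = closed
        self.flip = False  # parity of reversals; anchors end bookkeeping
        self.tag = tag

    def left_exposes(self) -> Extremity:
        sid, o = self.steps[0]
        return Extremity(sid, "t" if o == "+" else "h")

    def right_exposes(self) -> Extremity:
        sid, o = self.steps[-1]
        return Extremity(sid, "h" if o == "+" else "t")

    def reverse(self) -> None:
        w = Walk(tuple(self.steps), tuple(self.adjs), self.closed).reverse()
        self.steps, self.adjs = list(w.steps), list(w.adjs)
        self.flip = not self.flip

    def orient_right(self, p: Extremity) -> None:
        """Reverse if needed so the right end exposes ``p``."""
        if self.right_exposes() != p:
            assert self.left_exposes() == p
            self.reverse()

    def orient_left(self, p: Extremity) -> None:
        if self.left_exposes() != p:
            assert self.right_exposes() == p
            self.reverse()

    def to_walk(self) -> Walk:
        return Walk(tuple(self.steps), tuple(self.adjs), self.closed)


class _CoveringBuilder:
    """Maintains the partial covering over the original graph: fragments
    under construction plus the pool of untouched segment copies."""

    def __init__(self, g: WeightedIAG):
        self.g = g
        self.free = {sid: g.mu[seg_key(sid)] for sid in g.segments}
        self.fragments: list[_Fragment] = []
        self.current_tag = 0  # component marker for terminal replicas

    def take_fresh(self, sid: str, orient: str = "+") -> _Fragment:
        if self.free[sid] < 1:
            raise GraphError(f"no free copy of segment {sid} available")
        self.free[sid] -= 1
        frag = _Fragment([(sid, orient)], [], tag=self.current_tag)
        self.fragments.append(frag)
        return frag

    def release_copy(self, sid: str) -> None:
        self.free[sid] += 1

    def drop(self, frag: _Fragment) -> None:
        self.fragments.remove(frag)

    def finalize(self) -> list[Walk]:
        walks = [f.to_walk() for f in self.fragments]
        for sid in sorted(self.free):
            for _ in range(self.free[sid]):
                walks.append(Walk(((sid, "+"),), (), False))
        return sorted(walks, key=lambda w: w.sort_key())


# ---------------------------------------------------------------------------
# balance transform


@dataclass
class CcrState:
    """Working state of the covering algorithm on one connected component."""

    graph: WeightedIAG  # balanced working graph (mutated in place)
    min_ed: Walk | None = None  # current single-cycle decomposition
    processed: set = field(default_factory=set)  # not-forced class triples
    chains: dict = field(default_factory=dict)  # contracted key -> ChainInfo
    builder: "_CoveringBuilder | None" = None
    contracted_triples: list = field(default_factory=list)
    n_contracted: int = 0
    component_graph: WeightedIAG | None = None  # original (unbalanced) component
    static_graph: WeightedIAG | None = None  # balanced component, never mutated
    tau_cache: dict = field(default_factory=dict)  # original triple -> forced?
    unplaced: Counter = field(default_factory=Counter)  # contracted but not in T
    recoverable: Counter = field(default_factory=Counter)  # re-insertable drops


def balance_transform(g: WeightedIAG) -> CcrState:
    """Add the supplemental segment, per-telomere supplemental adjacencies
    and the supplemental head loop so every vertex is balanced and the
    minimal decomposition of the (connected) component is one cycle."""
    work = g.copy()
    excess = {v: copy_number_excess(work, v) for v in work.vertices()}
    total = sum(excess.values())
    if total > 0:
        assert total % 2 == 0, "total excess must be even"
        if SUPP_SEGMENT_ID in work.segments:
            raise GraphError(f"segment id {SUPP_SEGMENT_ID!r} is reserved")
        work.add_segment(Segment(SUPP_SEGMENT_ID), total)
        for v in sorted(v for v, x in excess.items() if x > 0):
            work.add_adjacency(
                Adjacency(v, tail(SUPP_SEGMENT_ID), SUPPLEMENTAL), excess[v]
            )
        work.add_adjacency(
            Adjacency(
                head(SUPP_SEGMENT_ID), head(SUPP_SEGMENT_ID), SUPPLEMENTAL
            ),
            total // 2,
        )
    for v in work.vertices():
        assert copy_number_excess(work, v) == 0
    return CcrState(graph=work)


# ---------------------------------------------------------------------------
# exact forced-pair test
#
# Transition "items" at a segment extremity are adjacency edge classes,
# except that the two ends of a *contracted loop* edge are distinct items:
# they abbreviate different original adjacency chains, so forcing must be
# decided per end.


@dataclass
class ChainInfo:
    """Bookkeeping for a contracted adjacency edge: per-end extremities,
    per-end original adjacencies, and per-end output fragment anchors.

    A fragment anchor is ``(fragment, side, flip_snapshot)``: at snapshot
    time the chain end sat at ``side`` ("L"/"R") of the fragment; the
    current side follows from the fragment's reversal parity.  An anchor is
    ``None`` when the corresponding attachment was dropped (no free copy
    was left), i.e. the chain continues in the working graph but not in
    the output covering.
    """

    exts: tuple[Extremity, Extremity]
    origs: tuple[AdjKey, AdjKey]
    frags: list  # [anchor | None, anchor | None]

    @property
    def is_loop(self) -> bool:
        return self.exts[0] == self.exts[1]

    def end_index(self, ext: Extremity, tag: int | None) -> int:
        if self.is_loop:
            assert tag in (0, 1), "loop chain end requires an explicit tag"
            return tag
        return self.exts.index(ext)

    def orig_at(self, ext: Extremity, tag: int | None = None) -> AdjKey:
        return self.origs[self.end_index(ext, tag)]


def _anchor(frag: _Fragment, side: str):
    return (frag, side, frag.flip)


def _anchor_side(anchor) -> str:
    frag, side, snap = anchor
    if frag.flip != snap:
        return "L" if side == "R" else "R"
    return side


def _orient_anchor(anchor, want: str) -> _Fragment:
    frag = anchor[0]
    if _anchor_side(anchor) != want:
        frag.reverse()
    return frag


def _item_budgets(g: WeightedIAG, v: Extremity) -> Counter:
    budget: Counter = Counter()
    for key in g.adjacency_keys_at(v):
        adj = g.adjacencies[key]
        if adj.is_loop and adj.is_contracted:
            budget[(key, 0)] += 1
            budget[(key, 1)] += 1
        else:
            l = 2 if adj.is_loop else 1
            budget[(key, None)] += l * g.mu[key]
    return budget


def _loop_contracted(g: WeightedIAG, key: AdjKey) -> bool:
    adj = g.adjacencies[key]
    return adj.is_loop and adj.is_contracted


def _base_components(g: WeightedIAG, y: str) -> dict[Extremity, int]:
    """Connected components of the graph with segment ``y`` and its two
    vertices deleted; adjacency endpoints at y's extremities dangle."""
    yt, yh = tail(y), head(y)
    uf = nx.utils.UnionFind()
    for sid in g.segments:
        if sid != y:
            uf.union(tail(sid), head(sid))
    for key, adj in g.adjacencies.items():
        a, b = adj.first, adj.second
        if a in (yt, yh) or b in (yt, yh):
            continue
        uf.union(a, b)
    comp: dict[Extremity, int] = {}
    roots: dict = {}
    for v in g.vertices():
        if v in (yt, yh):
            continue
        r = uf[v]
        comp[v] = roots.setdefault(r, len(roots))
    return comp


def _margins_feasible(
    t_budget: Counter, h_budget: Counter, forbidden: set, required: list
) -> bool:
    """Can the tail/head endpoint budgets be fully paired while avoiding
    forbidden cells and using each required cell at least once?"""
    tb, hb = Counter(t_budget), Counter(h_budget)
    for a, b in required:
        tb[a] -= 1
        hb[b] -= 1
        if tb[a] < 0 or hb[b] < 0:
            return False
    total = sum(tb.values())
    if total != sum(hb.values()):
        return False
    if total == 0:
        return True
    G = nx.DiGraph()
    for a, n in tb.items():
        if n:
            G.add_edge("src", ("t", a), capacity=n)
    for b, n in hb.items():
        if n:
            G.add_edge(("h", b), "snk", capacity=n)
    for a, n in tb.items():
        if not n:
            continue
        for b, m in hb.items():
            if m and (a, b) not in forbidden:
                G.add_edge(("t", a), ("h", b), capacity=total)
    if "src" not in G or "snk" not in G:
        return False
    return nx.maximum_flow_value(G, "src", "snk") == total


def _normalize_pair(
    g: WeightedIAG, e: AdjKey, y: str, f: AdjKey
) -> tuple[AdjKey, AdjKey]:
    """Return the pair ordered so ``e`` attaches at y's tail and ``f`` at
    y's head."""
    yt, yh = tail(y), head(y)

    def touches(key: AdjKey, v: Extremity) -> bool:
        a, b = key[1]
        return v in (a, b)

    if touches(e, yt) and touches(f, yh):
        return e, f
    if touches(f, yt) and touches(e, yh):
        return f, e
    raise GraphError(f"pair ({e}, {f}) is not consecutive across {y}")


def _pair_realizations(g: WeightedIAG, e: AdjKey, y: str, f: AdjKey):
    """Distinct concrete realizations of the junction e-y-f: each is
    ``(tail_edge, head_edge, tail_tag, head_tag)`` with the tail edge
    entering y's tail extremity.  Realizations differ when a contracted
    edge can participate with either of its (distinguishable) ends."""
    yt, yh = tail(y), head(y)

    def touches(key: AdjKey, v: Extremity) -> bool:
        a, b = key[1]
        return v in (a, b)

    out = []
    seen = set()
    for A, B in ((e, f), (f, e)):
        if not (touches(A, yt) and touches(B, yh)):
            continue
        a_tags = (0, 1) if _loop_contracted(g, A) else (None,)
        b_tags = (0, 1) if _loop_contracted(g, B) else (None,)
        for at in a_tags:
            for bt in b_tags:
                key = (A, B, at, bt)
                if key in seen:
                    continue
                seen.add(key)
                out.append(key)
    return out


def _item(g: WeightedIAG, key: AdjKey, tag):
    return (key, tag if _loop_contracted(g, key) else None)


def _realization_cell(g: WeightedIAG, A: AdjKey, B: AdjKey, at, bt):
    return (_item(g, A, at), _item(g, B, bt))


def _exists_avoiding_single_cycle(
    g: WeightedIAG, y: str, forbidden: set
) -> bool:
    """Does some single-cycle Eulerian decomposition of the balanced,
    connected working graph avoid all forbidden transition cells through
    segment ``y``?  Transitions at other segments are free, so the search
    reduces to the transition pattern through ``y`` alone: the chosen
    cells must be margin-feasible and their support must reconnect the
    graph split at ``y`` (a spanning-tree search over class-level cells
    plus bipartite feasibility checks)."""
    yt, yh = tail(y), head(y)
    t_budget = _item_budgets(g, yt)
    h_budget = _item_budgets(g, yh)
    assert sum(t_budget.values()) == g.mu[seg_key(y)] == sum(h_budget.values())
    if not forbidden:
        return True
    # quick necessary condition: margins must be pairable at all while
    # avoiding the forbidden cells (settles every unit-copy-number pair
    # without touching the rest of the graph)
    if not _margins_feasible(t_budget, h_budget, forbidden, []):
        return False

    comp = _base_components(g, y)

    def node_of(itm):
        key, _tag = itm
        a, b = key[1]
        outside = [v for v in (a, b) if v not in (yt, yh)]
        if outside:
            return ("comp", comp[outside[0]])
        return ("pure", key)

    nodes = {("comp", c) for c in comp.values()}
    nodes |= {node_of(i) for i in set(t_budget) | set(h_budget)}
    k = len(nodes)
    if k <= 1:
        return True  # margins already feasible and nothing to reconnect
    bridging = [
        (a, b)
        for a in sorted(t_budget)
        for b in sorted(h_budget)
        if (a, b) not in forbidden and node_of(a) != node_of(b)
    ]
    for tree in itertools.combinations(bridging, k - 1):
        uf = nx.utils.UnionFind(nodes)
        ok = True
        for a, b in tree:
            na, nb = node_of(a), node_of(b)
            if uf[na] == uf[nb]:
                ok = False
                break
            uf.union(na, nb)
        if not ok:
            continue
        if _margins_feasible(t_budget, h_budget, forbidden, list(tree)):
            return True
    return False


def _class_forbidden(g: WeightedIAG, e: AdjKey, y: str, f: AdjKey) -> set:
    return {
        _realization_cell(g, A, B, at, bt)
        for A, B, at, bt in _pair_realizations(g, e, y, f)
    }


def is_pair_forced(state: CcrState, e: AdjKey, y: str, f: AdjKey) -> bool:
    """True iff every minimal (single-cycle) Eulerian decomposition of the
    working graph contains the sub-walk e-y-f at least once (class-level
    semantics: any realization of the junction counts)."""
    g = state.graph
    for key in (e, f):
        if key not in g.adjacencies:
            raise GraphError(f"adjacency {key} not in working graph")
    forbidden = _class_forbidden(g, e, y, f)
    if not forbidden:
        raise GraphError(f"pair ({e}, {f}) is not consecutive across {y}")
    return not _exists_avoiding_single_cycle(g, y, forbidden)


# ---------------------------------------------------------------------------
# contraction


def _rewrite_min_ed(
    w: Walk, e: AdjKey, y: str, f: AdjKey, j: AdjKey
) -> Walk | None:
    """Replace one occurrence of e-y-f (either direction) in the cycle with
    the contracted edge ``j``; returns None when the cycle is consumed."""
    n = len(w.steps)
    if n == 1:
        return None
    steps, adjs = list(w.steps), list(w.adjs)
    for i in range(n):
        prev_adj = adjs[i - 1]
        next_adj = adjs[i]
        if steps[i][0] != y:
            continue
        if (prev_adj, next_adj) in ((e, f), (f, e)):
            new_steps = steps[:i] + steps[i + 1 :]
            new_adjs = adjs[:i] + adjs[i + 1 :]
            # adjacency formerly at i-1 must become j
            new_adjs[(i - 1) % len(new_adjs)] = j
            return Walk(tuple(new_steps), tuple(new_adjs), True)
    raise GraphError("pair not consecutive in the current decomposition")


def _whole_component(state: CcrState, steps, adjs) -> bool:
    """Would a closed walk over these steps/adjacencies use every edge of
    the component exactly its (original) multiplicity?  Only such cycles
    may be emitted closed: minimal decompositions of a balanced component
    consist of one cycle covering everything."""
    g0 = state.component_graph
    if g0 is None:
        return False
    step_use = Counter(sid for sid, _ in steps)
    adj_use = Counter(adjs)
    for sid in g0.segments:
        if step_use.get(sid, 0) != g0.mu[seg_key(sid)]:
            return False
    for key in g0.adjacencies:
        if adj_use.get(key, 0) != g0.mu[key]:
            return False
    return sum(step_use.values()) == sum(
        g0.mu[seg_key(sid)] for sid in g0.segments
    ) and sum(adj_use.values()) == sum(g0.mu[k] for k in g0.adjacencies)


def contract_forced_pair(
    state: CcrState,
    e: AdjKey,
    y: str,
    f: AdjKey,
    e_tag=None,
    f_tag=None,
    merge: bool = True,
) -> AdjKey:
    """Remove ``e``, one copy of ``y`` and ``f`` from the working graph,
    insert the contracted replacement edge, rewrite the current
    decomposition, and grow the output contig fragments.

    ``e_tag``/``f_tag`` pick the chain end when the edge is a contracted
    loop (its two ends abbreviate different original adjacencies).
    ``merge=False`` records the contraction and updates the working graph
    but keeps the flanking output fragments separate (used when the
    junction between these specific chains is not itself present in every
    minimal decomposition); original adjacencies are then placed as
    standalone single-adjacency contigs when free copies allow."""
    g = state.graph
    builder = state.builder
    assert builder is not None
    yt, yh = tail(y), head(y)

    e2, f2 = _normalize_pair(g, e, y, f)
    if (e2, f2) != (e, f):
        e, f = e2, f2
        e_tag, f_tag = f_tag, e_tag
    e_adj, f_adj = g.adjacencies[e], g.adjacencies[f]
    e_contracted = e_adj.is_contracted
    f_contracted = f_adj.is_contracted
    e_info = state.chains.get(e)
    f_info = state.chains.get(f)

    closure = len(state.min_ed.steps) == 1
    if closure:
        assert e == f
        orig_e = e_info.orig_at(yt) if e_contracted else e
        orig_f = f_info.orig_at(yh) if f_contracted else f
    else:
        orig_e = e_info.orig_at(yt, e_tag) if e_contracted else e
        orig_f = f_info.orig_at(yh, f_tag) if f_contracted else f
    state.contracted_triples.append((orig_e, y, orig_f))

    if not closure:
        if e_contracted:
            e_idx = e_info.end_index(yt, e_tag)
            far_e = e_info.exts[1 - e_idx]
            far_e_orig = e_info.origs[1 - e_idx]
        else:
            far_e = e_adj.other(yt)
            far_e_orig = e
        if f_contracted:
            f_idx = f_info.end_index(yh, f_tag)
            far_f = f_info.exts[1 - f_idx]
            far_f_orig = f_info.origs[1 - f_idx]
        else:
            far_f = f_adj.other(yh)
            far_f_orig = f

    # ---- grow the output contig ----
    if closure:
        if e_contracted:
            a0, a1 = e_info.frags
            if (
                a0 is not None
                and a1 is not None
                and a0[0] is a1[0]
                and not a0[0].closed
            ):
                frag = a0[0]
                if (
                    frag.steps[0][0] == y
                    and frag.steps[-1][0] == y
                    and _whole_component(state, frag.steps[:-1], frag.adjs)
                ):
                    frag.steps = frag.steps[:-1]
                    frag.closed = True
                    builder.release_copy(y)
        else:
            if builder.free.get(y, 0) >= 1 and _whole_component(
                state, [(y, "+")], [e]
            ):
                frag = builder.take_fresh(y, "+")
                frag.adjs = [e]
                frag.closed = True
    else:
        end0_anchor, end1_anchor = _grow_contig(
            state,
            merge,
            (e, e_contracted, e_info, e_idx if e_contracted else None, far_e),
            y,
            (f, f_contracted, f_info, f_idx if f_contracted else None, far_f),
        )

    # ---- update working graph ----
    g.remove_adjacency_copy(e)
    if f != e or not closure:
        # a non-closure pair with e == f consumes two copies of the class
        g.remove_adjacency_copy(f)
    state.n_contracted += 1
    kind = f"{CONTRACTED_PREFIX}{state.n_contracted}"
    if closure:
        g.remove_segment_copy(y)
        state.min_ed = None
        return e
    j_adj = Adjacency(far_e, far_f, kind)
    j = j_adj.key
    state.min_ed = _rewrite_min_ed(state.min_ed, e, y, f, j)
    g.remove_segment_copy(y)
    g.add_adjacency(j_adj, 1)
    state.chains[j] = ChainInfo(
        exts=(far_e, far_f),
        origs=(far_e_orig, far_f_orig),
        frags=[end0_anchor, end1_anchor],
    )
    return j


def _side_state(state: CcrState, edge, contracted, info, idx, yext):
    """Classify one flank of a junction for contig growth: the chain end
    carries its y-side copy ("direct"), lost it to an earlier drop but the
    missing original adjacency can be re-inserted ("gap"), is a raw
    original adjacency ("raw"), or cannot contribute ("none")."""
    if not contracted:
        return ("raw", None, edge, None)
    anch = info.frags[idx]
    if anch is not None:
        if anch[0].closed:
            return ("none", None, None, None)
        return ("direct", anch, None, None)
    orig = info.origs[idx]
    other = info.frags[1 - idx]
    if other is None or other[0].closed or state.recoverable.get(orig, 0) < 1:
        return ("none", None, None, None)
    far = None
    o_adj = state.builder.g.adjacencies[orig]
    a, b = o_adj.extremities()
    far = b if a == yext else (a if b == yext else None)
    if far is None:
        return ("none", None, None, None)
    frag = other[0]
    if far not in (frag.left_exposes(), frag.right_exposes()):
        return ("none", None, None, None)
    return ("gap", other, orig, far)


def _grow_contig(state: CcrState, merge, left_spec, y: str, right_spec):
    """Update the output fragments for a contraction; returns the two
    fragment anchors (far-e side, far-f side) for the new contracted edge.

    When ``merge`` is false (or a side cannot contribute), raw adjacencies
    are deferred to the terminal selection instead of being placed."""
    builder = state.builder
    yt, yh = tail(y), head(y)
    e, e_contracted, e_info, e_idx, far_e = left_spec
    f, f_contracted, f_info, f_idx, far_f = right_spec
    e_other = e_info.frags[1 - e_idx] if e_contracted else None
    f_other = f_info.frags[1 - f_idx] if f_contracted else None

    def defer(edge, contracted):
        if not contracted:
            state.unplaced[edge] += 1

    if not merge:
        defer(e, e_contracted)
        defer(f, f_contracted)
        return (_open_or_none(e_other), _open_or_none(f_other))

    ls, l_anch, l_edge, l_far = _side_state(
        state, e, e_contracted, e_info, e_idx, yt
    )
    rs, r_anch, r_edge, r_far = _side_state(
        state, f, f_contracted, f_info, f_idx, yh
    )

    if ls == "none" or rs == "none":
        defer(e, e_contracted)
        defer(f, f_contracted)
        return (_open_or_none(e_other), _open_or_none(f_other))

    # locate / create the shared y copy
    if ls == "direct" and rs == "direct":
        fragE = _orient_anchor(l_anch, "R")
        fragF = _orient_anchor(r_anch, "L")
        assert fragE is not fragF
        assert fragE.steps[-1][0] == y and fragF.steps[0][0] == y
        fragE.steps = fragE.steps + fragF.steps[1:]
        fragE.adjs = fragE.adjs + fragF.adjs
        builder.drop(fragF)
        builder.release_copy(y)
        core = fragE

        def remap(anch):
            if anch is not None and anch[0] is fragF:
                return _anchor(core, "R")
            return anch

        return (_open_or_none(remap(e_other)), _open_or_none(remap(f_other)))

    if ls == "direct":
        core = _orient_anchor(l_anch, "R")
        e_end = "same"
    elif rs == "direct":
        core = _orient_anchor(r_anch, "L")
        e_end = None
    else:
        if builder.free.get(y, 0) < 1:
            defer(e, e_contracted)
            defer(f, f_contracted)
            return (_open_or_none(e_other), _open_or_none(f_other))
        core = builder.take_fresh(y, "+")
        e_end = None

    # resolve the right flank (needs core's right end at the y copy, y^h out)
    end1_anchor = _open_or_none(f_other)
    if rs != "direct":
        assert core.right_exposes() == yh
        if rs == "gap":
            other_frag = r_anch[0]
            if other_frag.left_exposes() != r_far:
                other_frag.reverse()
            assert other_frag.left_exposes() == r_far
            assert other_frag is not core
            core.steps = core.steps + other_frag.steps
            core.adjs = core.adjs + [r_edge] + other_frag.adjs
            builder.drop(other_frag)
            state.unplaced[r_edge] -= 1
            state.recoverable[r_edge] -= 1
            end1_anchor = _anchor(core, "R")
        else:  # raw
            status = _attach(state, core, f, yh, far_f)
            if status == "attached":
                end1_anchor = _anchor(core, "R")
            elif status == "closed":
                return (None, None)

    # resolve the left flank (reverse so the y copy sits at the right, y^t out)
    end0_anchor = _open_or_none(e_other)
    if ls != "direct":
        core.reverse()
        assert core.right_exposes() == yt
        if ls == "gap":
            other_frag = l_anch[0]
            if other_frag.left_exposes() != l_far:
                other_frag.reverse()
            assert other_frag.left_exposes() == l_far
            assert other_frag is not core
            core.steps = core.steps + other_frag.steps
            core.adjs = core.adjs + [l_edge] + other_frag.adjs
            builder.drop(other_frag)
            state.unplaced[l_edge] -= 1
            state.recoverable[l_edge] -= 1
            end0_anchor = _anchor(core, "R")
        else:  # raw
            status = _attach(state, core, e, yt, far_e)
            if status == "attached":
                end0_anchor = _anchor(core, "R")
            elif status == "closed":
                return (None, None)
        core.reverse()
    else:
        # e side already carried the y copy; its far anchor may be this
        # same fragment
        if e_other is not None and e_other[0] is core:
            end0_anchor = _open_or_none(e_other)

    return (_open_or_none(end0_anchor), _open_or_none(end1_anchor))


def _open_or_none(anch):
    if anch is None or anch[0].closed:
        return None
    return anch


def _attach(
    state: CcrState,
    frag: _Fragment,
    akey: AdjKey,
    here: Extremity,
    far: Extremity,
) -> str:
    """Extend ``frag`` on the right through adjacency ``akey`` onto a copy
    of ``far``'s segment.  Returns "attached" (fresh copy consumed),
    "closed" (the fragment closed onto its own other end and covers its
    whole component), or "dropped" (no valid placement; the adjacency is
    left out of the covering)."""
    builder = state.builder
    assert frag.right_exposes() == here
    sid = far.segment_id
    if builder.free.get(sid, 0) >= 1:
        ext = builder.take_fresh(sid, "+" if far.side == "t" else "-")
        builder.drop(ext)
        frag.steps = frag.steps + ext.steps
        frag.adjs = frag.adjs + [akey]
        return "attached"
    if frag.left_exposes() == far and _whole_component(
        state, frag.steps, frag.adjs + [akey]
    ):
        frag.adjs = frag.adjs + [akey]
        frag.closed = True
        return "closed"
    state.unplaced[akey] += 1
    state.recoverable[akey] += 1
    return "dropped"


# ---------------------------------------------------------------------------
# terminal selection
#
# After pair processing, leftover adjacency copies can still enter the
# covering in two consistent ways: as isolated single-adjacency contigs
# (an adjacency is always flanked by its own segments in every walk that
# uses it), or as extra replicas of (sub-walks of) the chains already
# proven consistent during contraction — walk presence in a decomposition
# is a per-walk property, so a consistent walk may appear any number of
# times the copy budgets allow.  Both kinds compete for the free segment
# copies, so the maximum is found with an exact small integer program.


def terminal_selection(state: CcrState) -> list[tuple[str, object]]:
    """Maximum-usage selection of leftover adjacency copies, as a list of
    ``("single", adjacency_key)`` and ``("walk", Walk)`` directives."""
    g = state.graph
    builder = state.builder
    assert builder is not None
    residual = Counter(
        {
            key: g.mu[key]
            for key in g.adjacency_edge_keys()
            if not g.adjacencies[key].is_supplemental
            and not g.adjacencies[key].is_contracted
            and g.mu[key] > 0
        }
    )
    residual.update(state.unplaced)
    if not residual:
        return []
    chain_walks = [
        f.to_walk()
        for f in builder.fragments
        if f.tag == builder.current_tag and f.adjs
    ]
    columns: list[tuple[int, Counter, Counter, object]] = []
    # (gain, adjacency usage, segment usage, directive payload)
    for key in sorted(residual):
        # unplaced keys may already be gone from the working graph; the
        # original graph still knows every original adjacency class
        p_, q_ = builder.g.adjacencies[key].extremities()
        seg_use = Counter({p_.segment_id: 1})
        seg_use[q_.segment_id] += 1
        columns.append((1, Counter({key: 1}), seg_use, ("single", key)))
    budget_cap = sum(
        n * n for n in (len(w.adjs) for w in chain_walks)
    )
    for w in chain_walks:
        m = len(w.adjs)
        intervals: list[tuple[int, int]] = []
        if budget_cap <= 20000:
            if w.closed:
                intervals = [
                    (i, k) for i in range(m) for k in range(1, m)
                ] + [(0, m)]
            else:
                intervals = [
                    (i, k) for i in range(m) for k in range(1, m - i + 1)
                ]
        else:  # very long chains: full replica only
            intervals = [(0, m)]
        for i, k in intervals:
            sub = _chain_subwalk(w, i, k)
            if sub is None:
                continue
            adj_use = Counter(sub.adjs)
            if any(adj_use[a] > residual.get(a, 0) for a in adj_use):
                continue
            seg_use = Counter(sid for sid, _ in sub.steps)
            columns.append((k, adj_use, seg_use, ("walk", sub)))
    counts = _solve_selection_ilp(columns, residual, builder.free)
    out: list[tuple[str, object]] = []
    for (gain, adj_use, seg_use, payload), n in zip(columns, counts):
        out.extend([payload] * n)
    return out


def _chain_subwalk(w: Walk, i: int, k: int) -> Walk | None:
    """Sub-walk of a chain covering adjacencies ``i .. i+k-1`` (wrapping
    when the chain is a cycle); ``k == len(w.adjs)`` on a cycle replicates
    the full cycle."""
    m = len(w.adjs)
    n = len(w.steps)
    if w.closed and k == m:
        return w
    if not w.closed and i + k > m:
        return None
    steps = tuple(w.steps[(i + t) % n] for t in range(k + 1))
    adjs = tuple(w.adjs[(i + t) % m] for t in range(k))
    return Walk(steps, adjs, False)


def _solve_selection_ilp(
    columns: list, residual: dict, free: dict
) -> list[int]:
    import numpy as np
    from scipy.optimize import milp, LinearConstraint, Bounds

    if not columns:
        return []
    akeys = sorted(residual)
    a_ix = {k: i for i, k in enumerate(akeys)}
    sids = sorted(
        {s for _, _, seg_use, _ in columns for s in seg_use}
    )
    s_ix = {s: i for i, s in enumerate(sids)}
    ncol = len(columns)
    A = np.zeros((len(akeys) + len(sids), ncol))
    for j, (gain, adj_use, seg_use, _) in enumerate(columns):
        for a, n in adj_use.items():
            A[a_ix[a], j] = n
        for sname, n in seg_use.items():
            A[len(akeys) + s_ix[sname], j] = n
    ub = np.array(
        [residual[k] for k in akeys] + [free.get(sname, 0) for sname in sids],
        dtype=float,
    )
    c = -np.array([gain for gain, _, _, _ in columns], dtype=float)
    res = milp(
        c=c,
        constraints=LinearConstraint(A, -np.inf, ub),
        bounds=Bounds(0, np.inf),
        integrality=np.ones(ncol),
    )
    assert res.success, "terminal selection ILP failed"
    return [int(round(x)) for x in res.x]


def _apply_selection(state: CcrState, selected: list) -> None:
    builder = state.builder
    g = state.graph
    for kind, payload in selected:
        if kind == "single":
            p, q = builder.g.adjacencies[payload].extremities()
            left = builder.take_fresh(p.segment_id, "+" if p.side == "h" else "-")
            right = builder.take_fresh(q.segment_id, "+" if q.side == "t" else "-")
            builder.drop(right)
            left.steps = left.steps + right.steps
            left.adjs = [payload]
        else:
            w: Walk = payload
            frag = None
            for sid, orient in w.steps:
                piece = builder.take_fresh(sid, orient)
                if frag is None:
                    frag = piece
                else:
                    builder.drop(piece)
                    frag.steps = frag.steps + piece.steps
            frag.adjs = list(w.adjs)
            frag.closed = w.closed


# ---------------------------------------------------------------------------
# the full algorithm


def _triple_key(e: AdjKey, y: str, f: AdjKey) -> tuple:
    a, b = sorted((e, f))
    return (a, y, b)


def _tau_forced(state: CcrState, o1: AdjKey, y: str, o2: AdjKey) -> bool:
    """Is the original junction o1-y-o2 present (in some realization) in
    every minimal decomposition of the component?  Evaluated once, on the
    untouched balanced component graph, and cached."""
    key = (y,) + tuple(sorted((o1, o2)))
    if key not in state.tau_cache:
        g0 = state.static_graph
        forbidden = _class_forbidden(g0, o1, y, o2)
        state.tau_cache[key] = not _exists_avoiding_single_cycle(
            g0, y, forbidden
        )
    return state.tau_cache[key]


def _process_component(state: CcrState) -> None:
    d = solve_min_edp(state.graph)
    assert len(d) == 1 and d.walks[0].closed, (
        "balanced connected component must decompose into one cycle"
    )
    state.min_ed = d.walks[0]
    state.static_graph = state.graph.copy()
    while state.min_ed is not None:
        progressed = False
        for e, y, f in state.min_ed.consecutive_adjacency_triples():
            gw = state.graph
            if (
                gw.adjacencies[e].is_supplemental
                or gw.adjacencies[f].is_supplemental
            ):
                continue
            key = _triple_key(e, y, f)
            if key in state.processed:
                continue
            if len(state.min_ed.steps) == 1:
                # single remaining copy: the cycle is the unique minimal
                # decomposition of the residual component
                contract_forced_pair(state, e, y, f)
                progressed = True
                break
            done = False
            for A, B, at, bt in _pair_realizations(gw, e, y, f):
                yt, yh = tail(y), head(y)
                a_info = state.chains.get(A)
                b_info = state.chains.get(B)
                o1 = a_info.orig_at(yt, at) if a_info else A
                o2 = b_info.orig_at(yh, bt) if b_info else B
                if not _tau_forced(state, o1, y, o2):
                    continue
                # the junction between these specific chains may still be
                # avoidable; then the chains stay separate in the output
                cell = {_realization_cell(gw, A, B, at, bt)}
                merge = not _exists_avoiding_single_cycle(gw, y, cell)
                contract_forced_pair(state, A, y, B, at, bt, merge=merge)
                done = True
                break
            if not done:
                state.processed.add(key)
            progressed = True
            break
        if not progressed:
            break
    selected = terminal_selection(state)
    _apply_selection(state, selected)


def run_ccr_detailed(g: WeightedIAG) -> tuple[ContigCovering, list[tuple]]:
    """Run the covering algorithm; also return the contracted pairs mapped
    back to original adjacency edges as ``(e, segment, f)`` triples."""
    _check_decomposable(g)
    builder = _CoveringBuilder(g)
    triples: list[tuple] = []
    for comp in g.connected_components():
        builder.current_tag += 1
        sub = g.restrict_to(comp)
        state = balance_transform(sub)
        state.component_graph = sub
        state.builder = builder
        _process_component(state)
        triples.extend(state.contracted_triples)
    covering = ContigCovering(builder.finalize(), g)
    ok, violations = validate_covering(g, covering)
    assert ok, violations
    return covering, triples


def run_ccr(g: WeightedIAG) -> ContigCovering:
    covering, _ = run_ccr_detailed(g)
    return covering


# ---------------------------------------------------------------------------
# naive baseline


def _sole_exact_class(g: WeightedIAG, v: Extremity) -> AdjKey | None:
    keys = [k for k in g.adjacency_keys_at(v) if g.mu[k] > 0]
    if len(keys) != 1:
        return None
    key = keys[0]
    l = 2 if g.adjacencies[key].is_loop else 1
    if l * g.mu[key] != g.mu[seg_key(v.segment_id)]:
        return None
    return key


def naive_covering(g: WeightedIAG) -> ContigCovering:
    """Baseline: chain through an adjacency only when both of its endpoint
    extremities carry that adjacency alone with exactly matching copy
    counts; everything else stays primitive."""
    included: set[AdjKey] = set()
    for key in g.adjacency_edge_keys():
        adj = g.adjacencies[key]
        if all(_sole_exact_class(g, v) == key for v in set(adj.extremities())):
            included.add(key)
    # wire copies canonically: i-th adjacency copy onto i-th segment copy
    from .oracle import _walks_from_pairings, _TEL

    pairing: dict[str, list[tuple]] = {}
    for sid in sorted(g.segments):
        m = g.mu[seg_key(sid)]
        items = {}
        for side, v in (("t", tail(sid)), ("h", head(sid))):
            key = _sole_exact_class(g, v)
            if key is not None and key in included:
                adj = g.adjacencies[key]
                ports = []
                for j in range(g.mu[key]):
                    if adj.is_loop:
                        ports.append((key, j, 0))
                        ports.append((key, j, 1))
                    elif adj.first == v:
                        ports.append((key, j, 0))
                    else:
                        ports.append((key, j, 1))
                items[side] = ports
            else:
                items[side] = [(_TEL, v, i) for i in range(m)]
        pairing[sid] = list(zip(items["t"], items["h"]))
    walks = _walks_from_pairings(g, pairing)
    covering = ContigCovering(
        sorted(walks, key=lambda w: w.sort_key()), g
    )
    ok, violations = validate_covering(g, covering)
    assert ok, violations
    return covering
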