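"""Exponential brute-force references for the polynomial algorithms.

Everything here enumerates exhaustively at the level of individual edge
copies and is intended for tests and ``--verify`` runs on small instances
only (guarded by a total-multiplicity cap).  The enumeration is the ground
truth: the polynomial solvers and the covering algorithm are required to
agree with it wherever it can be run.
"""

from __future__ import annotations

import itertools
from typing import Iterator

from .iag import (
    AdjKey,
    Extremity,
    GraphError,
    Walk,
    WeightedIAG,
    copy_number_excess,
    head,
    seg_key,
    tail,
    walks_equal,
)
from .decomposition import (
    Decomposition,
    _adjacency_ports_at,
    min_decomposition_size,
    validate_decomposition,
)

__all__ = [
    "enumerate_eds",
    "enumerate_min_eds",
    "max_ed_bruteforce",
    "forced_pairs_bruteforce",
    "optimal_covering_bruteforce",
    "is_subwalk",
    "canonical_triple",
    "InstanceTooLarge",
]

DEFAULT_CAP = 12


class InstanceTooLarge(GraphError):
    pass


def _check_cap(g: WeightedIAG, cap: int) -> None:
    if g.mu_total() > cap:
        raise InstanceTooLarge(
            f"total edge multiplicity {g.mu_total()} exceeds cap {cap}"
        )


# ports are (adjacency key, copy, end) triples or ("telomere", n) markers
_TEL = "telomere"


def _segment_items(g: WeightedIAG, v: Extremity) -> list:
    items: list = list(_adjacency_ports_at(g, v))
    x = copy_number_excess(g, v)
    for n in range(x):
        items.append((_TEL, v, n))
    return items


def _walks_from_pairings(
    g: WeightedIAG, pairing: dict[str, list[tuple]]
) -> list[Walk]:
    """Assemble alternating walks from per-segment (tail item, head item)
    copy pairings.  Telomere items mark open-walk ends."""
    port_loc: dict[tuple, tuple[str, int, str]] = {}
    copies: dict[str, list[tuple]] = {}
    for sid, pairs in pairing.items():
        copies[sid] = pairs
        for i, (a, b) in enumerate(pairs):
            if a[0] != _TEL:
                port_loc[a] = (sid, i, "t")
            if b[0] != _TEL:
                port_loc[b] = (sid, i, "h")

    visited: set[tuple[str, int]] = set()
    walks: list[Walk] = []

    def trace(sid: str, i: int, orient: str) -> tuple[list, list, bool]:
        steps, adjs = [], []
        cur = (sid, i)
        while True:
            visited.add(cur)
            steps.append((cur[0], orient))
            a, b = copies[cur[0]][cur[1]]
            out_item = b if orient == "+" else a
            if out_item[0] == _TEL:
                return steps, adjs, False
            akey, j, end = out_item
            nsid, ni, nside = port_loc[(akey, j, 1 - end)]
            adjs.append(akey)
            cur, orient = (nsid, ni), ("+" if nside == "t" else "-")
            if cur == (sid, i):
                return steps, adjs, True

    # open walks first: start from copies whose tail item is a telomere
    for sid in sorted(copies):
        for i, (a, b) in enumerate(copies[sid]):
            if (sid, i) in visited:
                continue
            if a[0] == _TEL:
                steps, adjs, closed = trace(sid, i, "+")
                assert not closed
                walks.append(Walk(tuple(steps), tuple(adjs), False))
            elif b[0] == _TEL:
                steps, adjs, closed = trace(sid, i, "-")
                assert not closed
                walks.append(Walk(tuple(steps), tuple(adjs), False))
    for sid in sorted(copies):
        for i in range(len(copies[sid])):
            if (sid, i) in visited:
                continue
            steps, adjs, closed = trace(sid, i, "+")
            assert closed
            walks.append(Walk(tuple(steps), tuple(adjs), True))
    return walks


def enumerate_eds(
    g: WeightedIAG, cap: int = DEFAULT_CAP
) -> list[Decomposition]:
    """All Eulerian decompositions, deduplicated up to walk equivalence and
    multiset equality, by exhaustive backtracking over vertex-local
    pairings of segment-edge copies to adjacency-edge copies."""
    _check_cap(g, cap)
    if not g.segments:
        return [Decomposition([], g)]
    sids = sorted(g.segments)
    tail_items = {sid: _segment_items(g, tail(sid)) for sid in sids}
    head_items = {sid: _segment_items(g, head(sid)) for sid in sids}
    for sid in sids:
        m = g.mu[seg_key(sid)]
        if len(tail_items[sid]) != m or len(head_items[sid]) != m:
            raise GraphError(f"segment {sid} is not balanced after padding")

    seen: dict[tuple, Decomposition] = {}
    per_segment_perms = [
        [list(p) for p in itertools.permutations(head_items[sid])]
        for sid in sids
    ]
    for combo in itertools.product(*per_segment_perms):
        pairing = {
            sid: list(zip(tail_items[sid], perm))
            for sid, perm in zip(sids, combo)
        }
        walks = _walks_from_pairings(g, pairing)
        d = Decomposition(walks, g)
        key = d.canonical_key()
        if key not in seen:
            ok, violations = validate_decomposition(g, d)
            assert ok, violations
            seen[key] = d
    return [seen[k] for k in sorted(seen)]


def enumerate_min_eds(
    g: WeightedIAG, cap: int = DEFAULT_CAP
) -> list[Decomposition]:
    size = min_decomposition_size(g)
    return [d for d in enumerate_eds(g, cap) if len(d) == size]


def max_ed_bruteforce(g: WeightedIAG, cap: int = DEFAULT_CAP) -> Decomposition:
    eds = enumerate_eds(g, cap)
    best = max(len(d) for d in eds)
    return next(d for d in eds if len(d) == best)


def canonical_triple(e: AdjKey, sid: str, f: AdjKey) -> tuple:
    a, b = sorted((e, f))
    return (a, sid, b)


def _triples_of(d: Decomposition) -> set[tuple]:
    out: set[tuple] = set()
    for w in d.walks:
        for e, sid, f in w.consecutive_adjacency_triples():
            out.add(canonical_triple(e, sid, f))
    return out


def forced_pairs_bruteforce(
    g: WeightedIAG,
    cap: int = DEFAULT_CAP,
    *,
    full_multiplicity: bool = False,
) -> set[tuple]:
    """Triples ``(e, y, f)`` present in every minimal Eulerian
    decomposition.

    Default semantics require at least one occurrence per decomposition;
    ``full_multiplicity=True`` instead intersects occurrence counts and
    keeps triples whose minimum count across decompositions is positive
    (identical membership, retained to make the distinction measurable on
    multi-copy pairs).
    """
    min_eds = enumerate_min_eds(g, cap)
    if not min_eds:
        return set()
    if not full_multiplicity:
        forced = _triples_of(min_eds[0])
        for d in min_eds[1:]:
            forced &= _triples_of(d)
        return forced
    from collections import Counter

    def counts(d: Decomposition) -> Counter:
        c: Counter = Counter()
        for w in d.walks:
            for e, sid, f in w.consecutive_adjacency_triples():
                c[canonical_triple(e, sid, f)] += 1
        return c

    common = counts(min_eds[0])
    for d in min_eds[1:]:
        other = counts(d)
        common = Counter(
            {t: min(n, other.get(t, 0)) for t, n in common.items()}
        )
    return {t for t, n in common.items() if n > 0}


def is_subwalk(w: Walk, host: Walk) -> bool:
    """Is ``w`` a contiguous sub-walk of ``host`` (up to reversal; with
    wrap-around when the host is a cycle)?  Closed ``w`` requires full
    walk equality with a closed host."""
    if w.closed:
        return host.closed and walks_equal(w, host)
    needle = w._token_seq()
    rneedle = w.reverse()._token_seq()
    if host.closed:
        ring = host._token_seq()
        hay = ring + ring
    else:
        hay = host._token_seq()
    for probe in (needle, rneedle):
        n = len(probe)
        if n > len(hay):
            continue
        limit = len(ring) if host.closed else len(hay) - n + 1
        for i in range(0, max(limit, 0)):
            if i % 2 == 0 and hay[i : i + n] == probe:
                return True
    return False


def walk_in_decomposition(w: Walk, d: Decomposition) -> bool:
    return any(is_subwalk(w, host) for host in d.walks)


def optimal_covering_bruteforce(
    g: WeightedIAG, cap: int = DEFAULT_CAP
) -> tuple[int, list[Walk]]:
    """Exhaustive minimum of the contiguity discordance over consistent
    contig coverings; returns ``(min discordance, one witness)``."""
    _check_cap(g, cap)
    min_eds = enumerate_min_eds(g, cap)
    akeys = g.adjacency_edge_keys()
    sids = sorted(g.segments)

    best: tuple[int, list[Walk]] | None = None

    # choose how many copies of each adjacency class to use
    ranges = [range(g.mu[k], -1, -1) for k in akeys]
    for use in itertools.product(*ranges):
        used_total = sum(use)
        if best is not None and g.mu_adjacency_total() - used_total >= best[0]:
            continue
        sub = {k: n for k, n in zip(akeys, use)}
        # per-segment tail/head ports restricted to used copies
        t_ports: dict[str, list] = {sid: [] for sid in sids}
        h_ports: dict[str, list] = {sid: [] for sid in sids}
        ok = True
        for k, n in sub.items():
            adj = g.adjacencies[k]
            for j in range(n):
                for end, v in enumerate(adj.extremities()):
                    side = t_ports if v.side == "t" else h_ports
                    side[v.segment_id].append((k, j, end))
        per_seg_options = []
        for sid in sids:
            m = g.mu[seg_key(sid)]
            ts, hs = t_ports[sid], h_ports[sid]
            opts = []
            for pairs in _iter_chain_pairings(len(ts), len(hs), m):
                opts.append(pairs)
            if not opts:
                ok = False
                break
            per_seg_options.append((sid, ts, hs, opts))
        if not ok:
            continue
        for combo in itertools.product(*[o[3] for o in per_seg_options]):
            pairing: dict[str, list[tuple]] = {}
            feasible = True
            for (sid, ts, hs, _), pairs in zip(per_seg_options, combo):
                m = g.mu[seg_key(sid)]
                used_t = {t for t, _ in pairs}
                used_h = {h for _, h in pairs}
                n_copies = (
                    len(pairs)
                    + (len(ts) - len(used_t))
                    + (len(hs) - len(used_h))
                )
                if n_copies > m:
                    feasible = False
                    break
                cps: list[tuple] = []
                tel = itertools.count()
                for t, h in pairs:
                    cps.append((ts[t], hs[h]))
                for t in range(len(ts)):
                    if t not in used_t:
                        cps.append((ts[t], (_TEL, head(sid), next(tel))))
                for h in range(len(hs)):
                    if h not in used_h:
                        cps.append(((_TEL, tail(sid), next(tel)), hs[h]))
                while len(cps) < m:
                    cps.append(
                        ((_TEL, tail(sid), next(tel)), (_TEL, head(sid), next(tel)))
                    )
                pairing[sid] = cps
            if not feasible:
                continue
            walks = _walks_from_pairings(g, pairing)
            if any(
                not all(walk_in_decomposition(w, d) for d in min_eds)
                for w in walks
                if w.adjs
            ):
                continue
            disc = g.mu_adjacency_total() - used_total
            if best is None or disc < best[0]:
                best = (disc, walks)
    assert best is not None, "the primitive covering is always consistent"
    return best


def _iter_chain_pairings(nt: int, nh: int, m: int) -> Iterator[list]:
    """All injective partial maps between ``nt`` tail and ``nh`` head items
    feasible on ``m`` segment copies."""
    for k in range(min(nt, nh), -1, -1):
        if nt + nh - k > m:
            continue
        for t_sub in itertools.combinations(range(nt), k):
            for h_perm in itertools.permutations(range(nh), k):
                yield list(zip(t_sub, h_perm))
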