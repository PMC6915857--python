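"""Tab-separated input/output for karyotype graphs and contig coverings.

The graph dialect mirrors RCK-style exports: a segments table
(``chrom  start  end  cn``) and an adjacencies table
(``aid  chrom1  coord1  strand1  chrom2  coord2  strand2  kind  cn``), all
coordinates 1-based inclusive.  A ``+`` strand breakend maps to the head of
the segment ending at that coordinate, a ``-`` strand breakend to the tail
of the segment starting there.  Extra columns are ignored.

Coverings are written as a contig-path table and, for linear contigs, as
AGP v2.1.
"""

from __future__ import annotations

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
    seg_key,
)
from .ccr import ContigCovering

__all__ = [
    "read_iag",
    "write_iag",
    "write_covering",
    "read_covering",
    "write_agp",
    "canonical_signature",
]

SEGMENT_COLUMNS = ("chrom", "start", "end", "cn")
ADJACENCY_COLUMNS = (
    "aid",
    "chrom1",
    "coord1",
    "strand1",
    "chrom2",
    "coord2",
    "strand2",
    "kind",
    "cn",
)
COVERING_COLUMNS = ("contig_id", "topology", "path", "length", "adj_kinds")


def _read_table(path, required: tuple[str, ...]) -> list[tuple[int, dict]]:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise GraphError(f"{path}: missing header line")
        cols = header.split("\t")
        missing = [c for c in required if c not in cols]
        if missing:
            raise GraphError(f"{path}: missing columns {missing}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            vals = line.split("\t")
            if len(vals) < len(cols):
                raise GraphError(f"{path}:{lineno}: expected {len(cols)} fields")
            rows.append((lineno, dict(zip(cols, vals))))
    return rows


def _seg_id(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


def read_iag(segments_path, adjacencies_path) -> WeightedIAG:
    """Parse segment and adjacency tables into a weighted graph."""
    segments: list[Segment] = []
    seg_mu: dict[str, int] = {}
    head_at: dict[tuple[str, int], Extremity] = {}
    tail_at: dict[tuple[str, int], Extremity] = {}
    for lineno, row in _read_table(segments_path, SEGMENT_COLUMNS):
        try:
            chrom = row["chrom"]
            start, end, cn = int(row["start"]), int(row["end"]), int(row["cn"])
        except ValueError as exc:
            raise GraphError(f"{segments_path}:{lineno}: {exc}") from exc
        if start > end:
            raise GraphError(f"{segments_path}:{lineno}: start > end")
        if cn < 0:
            raise GraphError(f"{segments_path}:{lineno}: negative copy number")
        sid = _seg_id(chrom, start, end)
        segments.append(Segment(sid, chrom, start, end))
        seg_mu[sid] = cn
        head_at[(chrom, end)] = Extremity(sid, "h")
        tail_at[(chrom, start)] = Extremity(sid, "t")

    def breakend(chrom: str, coord: int, strand: str, where: str) -> Extremity:
        if strand == "+":
            ext = head_at.get((chrom, coord))
        elif strand == "-":
            ext = tail_at.get((chrom, coord))
        else:
            raise GraphError(f"{where}: bad strand {strand!r}")
        if ext is None:
            raise GraphError(
                f"{where}: breakend {chrom}:{coord}:{strand} matches no "
                "segment boundary"
            )
        return ext

    adjacencies: list[Adjacency] = []
    adj_mu: dict = {}
    for lineno, row in _read_table(adjacencies_path, ADJACENCY_COLUMNS):
        where = f"{adjacencies_path}:{lineno}"
        try:
            c1, c2 = int(row["coord1"]), int(row["coord2"])
            cn = int(row["cn"])
        except ValueError as exc:
            raise GraphError(f"{where}: {exc}") from exc
        kind = row["kind"]
        if kind not in (REFERENCE, NOVEL):
            raise GraphError(f"{where}: kind must be R or N, got {kind!r}")
        if cn < 0:
            raise GraphError(f"{where}: negative copy number")
        p = breakend(row["chrom1"], c1, row["strand1"], where)
        q = breakend(row["chrom2"], c2, row["strand2"], where)
        adj = Adjacency(p, q, kind)
        if adj.key in adj_mu:
            raise GraphError(f"{where}: duplicate adjacency {adj.key}")
        adjacencies.append(adj)
        adj_mu[adj.key] = cn
    return build_iag(
        segments, adjacencies, segment_mu=seg_mu, adjacency_mu=adj_mu
    )


def _extremity_breakend(g: WeightedIAG, v: Extremity) -> tuple[str, int, str]:
    seg = g.segments[v.segment_id]
    if v.side == "h":
        return (seg.chrom or seg.id, seg.end, "+")
    return (seg.chrom or seg.id, seg.start, "-")


def write_iag(g: WeightedIAG, segments_path, adjacencies_path) -> None:
    with open(segments_path, "w") as fh:
        fh.write("\t".join(SEGMENT_COLUMNS) + "\n")
        for sid in sorted(g.segments):
            s = g.segments[sid]
            fh.write(
                f"{s.chrom or s.id}\t{s.start}\t{s.end}\t{g.mu[seg_key(sid)]}\n"
            )
    with open(adjacencies_path, "w") as fh:
        fh.write("\t".join(ADJACENCY_COLUMNS) + "\n")
        for i, key in enumerate(g.adjacency_edge_keys(), start=1):
            adj = g.adjacencies[key]
            c1, p1, s1 = _extremity_breakend(g, adj.first)
            c2, p2, s2 = _extremity_breakend(g, adj.second)
            fh.write(
                f"a{i}\t{c1}\t{p1}\t{s1}\t{c2}\t{p2}\t{s2}\t{adj.kind}\t"
                f"{g.mu[key]}\n"
            )


def canonical_signature(g: WeightedIAG) -> tuple:
    """Coordinate-based serialization used to compare graphs read from
    different sources (segment ids are not part of the signature)."""
    segs = tuple(
        sorted(
            (s.chrom or s.id, s.start, s.end, g.mu[seg_key(sid)])
            for sid, s in g.segments.items()
        )
    )
    adjs = tuple(
        sorted(
            (
                tuple(
                    sorted(
                        (
                            _extremity_breakend(g, adj.first),
                            _extremity_breakend(g, adj.second),
                        )
                    )
                ),
                adj.kind,
                g.mu[key],
            )
            for key, adj in g.adjacencies.items()
        )
    )
    return (segs, adjs)


def _step_token(g: WeightedIAG, step: tuple[str, str]) -> str:
    sid, o = step
    s = g.segments[sid]
    if s.chrom and s.start and s.end:
        return f"{s.chrom}:{s.start}-{s.end}:{o}"
    return f"{sid}:{o}"


def write_covering(t: ContigCovering, path, g: WeightedIAG | None = None) -> None:
    g = g or t.source
    with open(path, "w") as fh:
        fh.write("\t".join(COVERING_COLUMNS) + "\n")
        for i, w in enumerate(t.walks, start=1):
            tokens = ";".join(_step_token(g, s) for s in w.steps)
            kinds = ",".join(a[2] for a in w.adjs)
            fh.write(
                f"ctg{i}\t{'closed' if w.closed else 'open'}\t{tokens}\t"
                f"{w.length_bp(g)}\t{kinds}\n"
            )


def read_covering(path, g: WeightedIAG) -> ContigCovering:
    by_token: dict[str, str] = {}
    for sid, s in g.segments.items():
        by_token[sid] = sid
        if s.chrom and s.start and s.end:
            by_token[f"{s.chrom}:{s.start}-{s.end}"] = sid
    walks = []
    for lineno, row in _read_table(path, COVERING_COLUMNS):
        closed = row["topology"] == "closed"
        steps = []
        for token in row["path"].split(";"):
            name, _, orient = token.rpartition(":")
            if name not in by_token:
                raise GraphError(f"{path}:{lineno}: unknown segment {name!r}")
            steps.append((by_token[name], orient))
        kinds = row["adj_kinds"].split(",") if row["adj_kinds"] else []
        adjs = []
        n = len(steps)
        expect = n if closed else n - 1
        if len(kinds) != expect:
            raise GraphError(f"{path}:{lineno}: {expect} adjacency kinds expected")
        for k in range(expect):
            sid_a, o_a = steps[k]
            sid_b, o_b = steps[(k + 1) % n]
            p = Extremity(sid_a, "h" if o_a == "+" else "t")
            q = Extremity(sid_b, "t" if o_b == "+" else "h")
            key = ("A", tuple(sorted((p, q))), kinds[k])
            if key not in g.adjacencies:
                raise GraphError(f"{path}:{lineno}: unknown adjacency {key}")
            adjs.append(key)
        walks.append(Walk(tuple(steps), tuple(adjs), closed))
    return ContigCovering(walks, g)


def write_agp(t: ContigCovering, path, g: WeightedIAG | None = None) -> None:
    """AGP v2.1 with one object per open contig; closed walks are not
    representable and raise."""
    g = g or t.source
    closed = [w for w in t.walks if w.closed]
    if closed:
        raise GraphError(
            f"{len(closed)} closed walk(s) present; AGP describes linear "
            "objects only — use the contig table format instead"
        )
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for i, w in enumerate(t.walks, start=1):
            obj = f"ctg{i}"
            pos = 1
            for part, (sid, orient) in enumerate(w.steps, start=1):
                s = g.segments[sid]
                length = s.length
                comp = s.chrom or s.id
                beg = s.start if s.start else 1
                end = s.end if s.end else length
                fh.write(
                    f"{obj}\t{pos}\t{pos + length - 1}\t{part}\tW\t{comp}\t"
                    f"{beg}\t{end}\t{orient}\n"
                )
                pos += length
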