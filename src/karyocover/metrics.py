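"""Contiguity statistics for contig coverings."""

from __future__ import annotations

from dataclasses import dataclass

from .iag import GraphError, Walk, WeightedIAG, seg_key
from .ccr import ContigCovering, contiguity_discordance, validate_covering
from .simulator import SimGenome, truth_walks

__all__ = ["CoveringStats", "n50", "covering_stats", "contig_supported"]


@dataclass(frozen=True)
class CoveringStats:
    count: int
    total_length: int
    n50: int
    closed_count: int
    discordance: int

    def to_tsv_row(self) -> str:
        return "\t".join(
            str(v)
            for v in (
                self.count,
                self.total_length,
                self.n50,
                self.closed_count,
                self.discordance,
            )
        )

    TSV_HEADER = "n_contigs\ttotal_length\tn50\tn_closed\tdiscordance"


def n50(lengths) -> int:
    """Largest L such that contigs of length >= L sum to at least half the
    total length (ties resolve to the larger qualifying length)."""
    lengths = sorted(lengths, reverse=True)
    if not lengths:
        raise GraphError("N50 of an empty length collection is undefined")
    half = sum(lengths) / 2
    acc = 0
    for L in lengths:
        acc += L
        if acc >= half:
            return L
    raise AssertionError("unreachable")


def covering_stats(g: WeightedIAG, t: ContigCovering) -> CoveringStats:
    ok, violations = validate_covering(g, t)
    if not ok:
        raise GraphError("invalid covering: " + "; ".join(violations))
    lengths = [w.length_bp(g) for w in t.walks]
    total = sum(lengths)
    expected = sum(
        g.mu[seg_key(sid)] * g.segments[sid].length for sid in g.segments
    )
    assert total == expected, "covering exactness implies the length identity"
    return CoveringStats(
        count=len(t.walks),
        total_length=total,
        n50=n50(lengths) if lengths else 0,
        closed_count=sum(1 for w in t.walks if w.closed),
        discordance=contiguity_discordance(g, t),
    )


def contig_supported(contig: Walk, genome: SimGenome) -> bool:
    """Is the contig a sub-walk of some true chromosome (up to reversal,
    with wrap-around inside circular chromosomes)?"""
    from .oracle import is_subwalk

    return any(is_subwalk(contig, w) for w in truth_walks(genome))
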