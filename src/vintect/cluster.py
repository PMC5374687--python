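"""Positional clustering of retained host hits and C+/C- partitioning.

Hits on one chromosome are chained into a cluster while consecutive
sorted start positions are closer than d + 2*sigma. Each cluster is then
partitioned by junction orientation: a member whose read prefix aligns on
the + strand (or suffix on the - strand) supports an integration with the
host 5' of the virus (C+); the complementary layouts support C-.
Whole-read alignments follow their strand.
"""
from __future__ import annotations

from .model import HitCluster, LibraryStats

# Bases of slack when judging whether an alignment reaches a read end;
# absorbs aligner end-trimming.
EDGE_TOL = 3


def cluster_hits(hits: list, stats: LibraryStats) -> list[HitCluster]:
    """Chain-link host hits into clusters per chromosome.

    ``hits`` is a list of (ReadPair, LocalHit). A new cluster starts when
    the gap between consecutive sorted start positions reaches
    d + 2*sigma. Output order (chromosome, then position) and membership
    are independent of input order.
    """
    gap = stats.cluster_gap
    by_chrom: dict[str, list] = {}
    for pair, hit in hits:
        by_chrom.setdefault(hit.subject_id, []).append((pair, hit))
    clusters = []
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom],
                         key=lambda m: (m[1].L, m[1].subject_end, m[0].id))
        current = [members[0]]
        for m in members[1:]:
            if m[1].L - current[-1][1].L < gap:
                current.append(m)
            else:
                clusters.append(HitCluster(chrom=chrom, members=current))
                current = [m]
        clusters.append(HitCluster(chrom=chrom, members=current))
    return clusters


def _end_class(hit, read_len: int) -> str:
    """Classify the host-aligned part of the read: whole, prefix, suffix,
    or internal (judged on forward-read coordinates with EDGE_TOL)."""
    at_start = hit.qstart <= EDGE_TOL
    at_end = hit.qend >= read_len - EDGE_TOL
    if at_start and at_end:
        return "whole"
    if at_start:
        return "prefix"
    if at_end:
        return "suffix"
    return "internal"


def member_orientation(pair, hit, mate: int) -> str:
    """'plus' (C+), 'minus' (C-) or 'noise' for one cluster member."""
    cls = _end_class(hit, len(pair.mate_seq(mate)))
    if cls == "internal":
        return "noise"
    if cls == "whole":
        return "plus" if hit.strand == "+" else "minus"
    if hit.strand == "+":
        return "plus" if cls == "prefix" else "minus"
    return "plus" if cls == "suffix" else "minus"


def _mate_of(pair, hit) -> int:
    return 0 if hit.query_id.endswith("/1") else 1


def partition_orientation(cluster: HitCluster
                          ) -> tuple[HitCluster, HitCluster]:
    """Split a cluster into its C+ and C- sub-clusters.

    Members whose host alignment is internal to the read support neither
    junction geometry and are dropped as noise, so |C+| + |C-| equals the
    cluster size minus noise members.
    """
    plus, minus = [], []
    for pair, hit in cluster.members:
        side = member_orientation(pair, hit, _mate_of(pair, hit))
        if side == "plus":
            plus.append((pair, hit))
        elif side == "minus":
            minus.append((pair, hit))
    return (HitCluster(chrom=cluster.chrom, members=plus,
                       orientation="plus"),
            HitCluster(chrom=cluster.chrom, members=minus,
                       orientation="minus"))


def median_rank(cluster: HitCluster) -> int:
    """Lower median of member hit ranks (even-sized clusters round down,
    which is conservative for the rank-1 reliability filter)."""
    if not cluster.members:
        raise ValueError("median rank of an empty cluster")
    ranks = sorted(h.rank for _, h in cluster.members)
    return ranks[(len(ranks) - 1) // 2]
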