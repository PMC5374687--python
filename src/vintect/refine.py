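"""Cluster refinement: noise filtering, deduplication, split-read rescue.

Three cleanups run on every oriented cluster. Reads whose hit layout is
more complex than one host segment plus one virus segment are discarded
(e.g. a host segment sandwiched between two viral segments), as are
host-host pairs that are not forward-reverse on one chromosome.
Optionally, pairs with byte-identical alignments are collapsed to one
copy — multiple identically-mapped fragments are implausible outside
targeted sequencing. Finally, reads with a viral alignment and an
unaligned tail of at least 10 bases are rescued as split reads by
Smith-Waterman against the d+2*sigma host window flanking their mate:
host segments too short for the seeded aligner (or pushed away from the
junction by a short random insert) are recovered this way.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from ._seq import encode, revcomp
from ._sw import sw_align
from .align import AlignParams, ReferenceIndex
from .model import HitCluster, LibraryStats, ReadPair, SplitRead

# A native split read may leave a small unexplained gap between its host
# and virus segments (random insert shorter than the rescue threshold)
# and small overlaps where the two alignments claim the same bases.
MAX_SEGMENT_OVERLAP = 8

# A host segment must be this clean to define a junction; a noisy local
# alignment dragged across a random insert would misplace the breakpoint.
SPLIT_MIN_IDENTITY = 0.9


def _identity_ok(hit, thr: float = SPLIT_MIN_IDENTITY) -> bool:
    if hit.n_cols == 0:  # identity unknown (synthetic hit): accept
        return True
    return hit.n_match / hit.n_cols >= thr


@dataclass(frozen=True)
class RescueParams:
    """Acceptance thresholds for Smith-Waterman split-read rescue."""

    min_unaligned: int = 10   # tail length needed to attempt rescue
    min_identity: float = 0.9
    min_span: int = 10        # aligned columns needed to accept


@dataclass
class RescueResult:
    rescued: bool
    host_pos: Optional[int] = None       # 1-based junction coordinate
    query_breakpos: Optional[int] = None  # forward-read boundary index
    split: Optional[SplitRead] = None


def _merged_intervals(hits) -> list[tuple[int, int]]:
    """Merge overlapping query spans; alternative placements of the same
    segment collapse to one interval."""
    spans = sorted((h.qstart, h.qend) for h in hits)
    merged: list[list[int]] = []
    for a, b in spans:
        if merged and a < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def _pair_is_complex(pair: ReadPair) -> bool:
    for mate in (0, 1):
        if len(_merged_intervals(pair.host_hits[mate])) > 1:
            return True
        if len(_merged_intervals(pair.virus_hits[mate])) > 1:
            return True
    # Both-ends-host pairs must be forward-reverse on one chromosome.
    h1, h2 = pair.host_hits[0], pair.host_hits[1]
    if h1 and h2:
        consistent = any(
            a.subject_id == b.subject_id and a.strand != b.strand
            for a in h1 for b in h2)
        if not consistent:
            return True
    return False


def filter_complex(members: list) -> list:
    """Drop cluster members of pairs with complex or inconsistent layouts."""
    bad = {p.id for p, _ in members if _pair_is_complex(p)}
    return [(p, h) for p, h in members if p.id not in bad]


def _pair_signature(pair: ReadPair) -> tuple:
    sig = []
    for mate in (0, 1):
        for kind, hits in (("H", pair.host_hits[mate]),
                           ("V", pair.virus_hits[mate])):
            for h in hits:
                sig.append((mate, kind) + h.key())
    return tuple(sorted(sig))


def dedupe(members: list, enabled: bool = True) -> list:
    """Collapse identically-aligned pairs to one copy (smallest read id).

    Idempotent; with ``enabled=False`` the input passes through.
    """
    if not enabled:
        return list(members)
    pairs: dict[str, ReadPair] = {p.id: p for p, _ in members}
    keep_of: dict[tuple, str] = {}
    for pid in sorted(pairs):
        sig = _pair_signature(pairs[pid])
        if sig not in keep_of:
            keep_of[sig] = pid
    kept_ids = set(keep_of.values())
    return [(p, h) for p, h in members if p.id in kept_ids]


def _best(hits):
    return min(hits, key=lambda h: (h.e, -h.score, h.subject_id, h.L))


def _junction_from_segments(host_hit, virus_hit) -> SplitRead | None:
    """Junction coordinates implied by adjacent host and virus segments
    of one read; None when the segments are not a clean split layout."""
    virus_right = virus_hit.qstart >= host_hit.qstart
    if virus_right:
        gap = virus_hit.qstart - host_hit.qend
    else:
        gap = host_hit.qstart - virus_hit.qend
    if gap < -MAX_SEGMENT_OVERLAP:
        return None
    five_prime = (virus_right) == (host_hit.strand == "+")
    host_junction = host_hit.subject_end if five_prime else host_hit.L + 1
    if virus_right:
        v_at_start = virus_hit.strand == "+"
    else:
        v_at_start = virus_hit.strand == "-"
    virus_junction = (virus_hit.L + 1 if v_at_start
                      else virus_hit.subject_end)
    # fragment-level virus orientation: + when the segment's 5' end faces
    # a 5p_host junction (or its 3' end a 3p_host junction)
    orient = "+" if five_prime == v_at_start else "-"
    return SplitRead(pair_id="", mate=-1, host_chrom=host_hit.subject_id,
                     host_junction=host_junction,
                     host_side="5p_host" if five_prime else "3p_host",
                     virus_id=virus_hit.subject_id,
                     virus_junction=virus_junction,
                     virus_strand=virus_hit.strand,
                     virus_orient=orient, source="aligned")


def detect_split_read(pair: ReadPair, mate: int,
                      max_gap: int) -> SplitRead | None:
    """Find a natively aligned split layout on one mate: exactly one host
    and one virus segment, adjacent within ``max_gap`` bases."""
    hosts = [h for h in pair.host_hits[mate] if _identity_ok(h)]
    viruses = pair.virus_hits[mate]
    if not hosts or not viruses:
        return None
    if len(_merged_intervals(hosts)) != 1 or len(_merged_intervals(viruses)) != 1:
        return None
    if len(hosts) > 1:
        return None  # ambiguous host placement: junction not trustworthy
    host_hit = hosts[0]
    virus_hit = _best(viruses)
    virus_right = virus_hit.qstart >= host_hit.qstart
    gap = (virus_hit.qstart - host_hit.qend if virus_right
           else host_hit.qstart - virus_hit.qend)
    if gap > max_gap:
        return None
    split = _junction_from_segments(host_hit, virus_hit)
    if split is not None:
        split.pair_id = pair.id
        split.mate = mate
    return split


def _unaligned_tail(pair: ReadPair, mate: int) -> tuple[int, int] | None:
    """Terminal query interval left unaligned next to the virus segment."""
    viruses = pair.virus_hits[mate]
    if not viruses or len(_merged_intervals(viruses)) != 1:
        return None
    clean_hosts = [h for h in pair.host_hits[mate] if _identity_ok(h)]
    covered = _merged_intervals(viruses + clean_hosts)
    v0, v1 = _merged_intervals(viruses)[0]
    read_len = len(pair.mate_seq(mate))
    left = min(a for a, _ in covered)
    right = max(b for _, b in covered)
    # prefer the longer uncovered terminal run
    head, tail = left, read_len - right
    if head >= tail:
        return (0, left) if head > 0 else None
    return (right, read_len)


def rescue_split_read(pair: ReadPair, host_index: ReferenceIndex,
                      stats: LibraryStats,
                      align_params: AlignParams,
                      params: RescueParams = RescueParams()
                      ) -> RescueResult:
    """Attempt to rescue one mate as a split read via targeted SW.

    Preconditions: one mate has a virus hit leaving >= min_unaligned
    contiguous terminal bases unaligned, and the other mate is anchored in
    the host and is not itself split. The unaligned tail is aligned
    (both orientations) against the d+2*sigma host window on the
    junction-facing side of the anchor; an alignment of >= min_span
    columns at >= min_identity makes the read a true split read with an
    exact junction. Failure leaves the pair's paired-end support intact
    but contributes no split read.
    """
    for mate in (0, 1):
        other = 1 - mate
        if not pair.virus_hits[mate]:
            continue
        anchors = pair.host_hits[other]
        if not anchors or pair.virus_hits[other]:
            continue  # mate unmapped on host, or itself chimeric/split
        if len(anchors) > 1:
            continue  # ambiguous anchor placement
        tail = _unaligned_tail(pair, mate)
        if tail is None or tail[1] - tail[0] < params.min_unaligned:
            continue
        return _attempt_rescue(pair, mate, tail, anchors[0], host_index,
                               stats, align_params, params)
    return RescueResult(rescued=False)


def _attempt_rescue(pair, mate, tail, anchor, host_index, stats,
                    align_params, params) -> RescueResult:
    t0, t1 = tail
    seq = pair.mate_seq(mate)[t0:t1]
    # The fragment extends from the anchor toward the junction, so the
    # split mate's host segment lies within d+2*sigma of the anchor's
    # junction-facing start: downstream of L for a + anchor, upstream of
    # its end for a - anchor.
    width = int(round(stats.cluster_gap))
    sidx = host_index.ids.index(anchor.subject_id)
    chrom_len = int(host_index.lengths[sidx])
    if anchor.strand == "+":
        ws, we = anchor.L, min(chrom_len, anchor.L + width)
    else:
        ws, we = max(0, anchor.subject_end - width), anchor.subject_end
    if we - ws < params.min_span:
        return RescueResult(rescued=False)
    window = host_index.encoded[sidx][ws:we]

    best = None
    for orient in ("+", "-"):
        s = seq if orient == "+" else revcomp(seq)
        res = sw_align(encode(s), window, align_params.match,
                       align_params.mismatch, align_params.gap_open,
                       align_params.gap_extend)
        if best is None or res[0] > best[1][0]:
            best = (orient, res)
    orient, (score, q0, q1, s0, s1, n_match, n_cols) = best
    if (score <= 0 or n_cols < params.min_span
            or n_match / n_cols < params.min_identity):
        return RescueResult(rescued=False)

    # Which end of the tail touches the virus segment, in forward-read
    # coordinates: a head tail ends at the virus, a tail tail starts there.
    virus_at_right = t0 == 0
    # Map that boundary onto the window: with a '+' placement the tail's
    # right end maps to s1, with '-' it maps to s0 (and vice versa).
    if (orient == "+") == virus_at_right:
        host_pos = ws + s1       # host 5' of virus: last host base (1-based)
        five_prime = True
    else:
        host_pos = ws + s0 + 1   # host 3' of virus: first host base
        five_prime = False

    virus_hit = _best(pair.virus_hits[mate])
    if virus_at_right:
        v_at_start = virus_hit.strand == "+"
    else:
        v_at_start = virus_hit.strand == "-"
    virus_junction = (virus_hit.L + 1 if v_at_start
                      else virus_hit.subject_end)

    split = SplitRead(pair_id=pair.id, mate=mate,
                      host_chrom=anchor.subject_id, host_junction=host_pos,
                      host_side="5p_host" if five_prime else "3p_host",
                      virus_id=virus_hit.subject_id,
                      virus_junction=virus_junction,
                      virus_strand=virus_hit.strand,
                      virus_orient="+" if five_prime == v_at_start else "-",
                      source="rescued")
    return RescueResult(rescued=True, host_pos=host_pos,
                        query_breakpos=t1 if virus_at_right else t0,
                        split=split)


def refine_cluster(cluster: HitCluster, host_index: ReferenceIndex,
                   stats: LibraryStats, align_params: AlignParams,
                   rescue: RescueParams = RescueParams(),
                   dedupe_enabled: bool = True) -> HitCluster:
    """Run the full refinement on one oriented cluster.

    Members are filtered and deduplicated; split reads (native and
    rescued) falling within the cluster's span (extended by d+2*sigma)
    are attached.
    """
    members = filter_complex(cluster.members)
    members = dedupe(members, dedupe_enabled)
    refined = HitCluster(chrom=cluster.chrom, members=members,
                         orientation=cluster.orientation)
    if not members:
        return refined

    lo, hi = refined.span
    margin = stats.cluster_gap
    side = "5p_host" if refined.orientation == "plus" else "3p_host"

    def belongs(split) -> bool:
        return (split.host_chrom == refined.chrom
                and split.host_side == side
                and lo - margin <= split.host_junction <= hi + margin)

    seen_pairs = set()
    for pair, _ in members:
        if pair.id in seen_pairs:
            continue
        seen_pairs.add(pair.id)
        found_native = False
        for mate in (0, 1):
            split = detect_split_read(pair, mate,
                                      max_gap=rescue.min_unaligned)
            if split is not None and belongs(split):
                refined.split_reads.append(split)
                found_native = True
        if found_native:
            continue
        res = rescue_split_read(pair, host_index, stats, align_params,
                                rescue)
        if res.rescued and belongs(res.split):
            refined.split_reads.append(res.split)
    return refined
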