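"""Turning refined clusters into integration calls.

For a C+ cluster the host breakpoint is estimated as the 3'-most aligned
read end, max{L + aligned_len}; for C- as the 5'-most aligned start,
min{L}. Without a junction-spanning read these estimates can be off by up
to the library's insert span; a split read pins the junction exactly, and
the median over split reads absorbs per-read alignment wobble. The virus
side is decided by an epsilon-majority vote between the V+ and V- strand
sub-clusters; which extremum of the winning virus hits faces the junction
follows from the host side and the winning strand:

    host side   winning strand   virus orient   junction-proximal end
    5p_host     -                +              5'-most (min L)
    5p_host     +                -              3'-most (max end)
    3p_host     +                +              3'-most (max end)
    3p_host     -                -              5'-most (min L)

Clusters whose median hit rank exceeds 1 fall in repetitive sequence and
go to a separate unreliable table. Rank-1 clusters without split reads
fall back on consensus assembly of their members; a consensus with a
unique best host placement yields an exact call, multiple equal-best
placements yield one call per placement, each marked ambiguous.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .align import AlignParams, ReferenceIndex, local_align, rank_hits
from .cluster import median_rank
from .model import HitCluster, IntegrationCall
from .refine import _best, _junction_from_segments, _merged_intervals

# Overlap-layout consensus thresholds for the assembly fallback.
MIN_OVERLAP = 30
MIN_OVERLAP_IDENTITY = 0.75


@dataclass(frozen=True)
class CallParams:
    epsilon: int = 2          # read-count margin for majority votes
    min_support: int = 1      # minimum supporting pairs to report
    correctness_window: int = 300  # evaluation-only matching window

    def __post_init__(self) -> None:
        if self.epsilon < 1:
            raise ValueError("epsilon must be >= 1")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")


def _lower_median(values) -> int:
    vals = sorted(values)
    return vals[(len(vals) - 1) // 2]


def host_breakpoint(cluster: HitCluster) -> tuple[int, bool]:
    """Host junction of an oriented cluster as (1-based position, exact).

    Cluster-edge estimate unless a confirmed split read pins the exact
    position (median over split reads when there are several).
    """
    if not cluster.members:
        raise ValueError("host breakpoint of an empty cluster")
    if cluster.split_reads:
        return _lower_median(s.host_junction
                             for s in cluster.split_reads), True
    if cluster.orientation == "plus":
        return max(h.subject_end for _, h in cluster.members), False
    if cluster.orientation == "minus":
        return min(h.L for _, h in cluster.members) + 1, False
    raise ValueError("cluster must be orientation-partitioned first")


def _virus_votes(cluster: HitCluster) -> list:
    """Best virus hit of every distinct mate among cluster pairs."""
    votes = []
    seen = set()
    for pair, _ in cluster.members:
        for mate in (0, 1):
            key = (pair.id, mate)
            if key in seen or not pair.virus_hits[mate]:
                continue
            seen.add(key)
            votes.append(_best(pair.virus_hits[mate]))
    return votes


def virus_breakpoint(cluster: HitCluster, params: CallParams
                     ) -> Optional[tuple[str, int, str]]:
    """Virus (id, 1-based position, orientation) by epsilon-majority vote.

    Returns None when no virus hits exist or the V+/V- strand vote is
    closer than epsilon — a tied vote means the viral placement cannot be
    trusted and the breakpoint is not reported.
    """
    votes = _virus_votes(cluster)
    if not votes:
        return None
    v_plus = [h for h in votes if h.strand == "+"]
    v_minus = [h for h in votes if h.strand == "-"]
    if abs(len(v_plus) - len(v_minus)) < params.epsilon:
        return None
    winner = v_plus if len(v_plus) > len(v_minus) else v_minus
    strand = winner[0].strand
    # most-supported virus id within the winning strand, ties lexicographic
    counts: dict[str, int] = {}
    for h in winner:
        counts[h.subject_id] = counts.get(h.subject_id, 0) + 1
    virus_id = sorted(counts, key=lambda v: (-counts[v], v))[0]
    vhits = [h for h in winner if h.subject_id == virus_id]

    five_prime_host = cluster.orientation == "plus"
    orient = strand if not five_prime_host else ("+" if strand == "-" else "-")
    proximal_is_5p = (strand == "-")
    if proximal_is_5p:
        pos = min(h.L for h in vhits) + 1
    else:
        pos = max(h.subject_end for h in vhits)
    return virus_id, pos, orient


# Split reads whose implied junctions are within this many bases are
# treated as agreeing; the aligner can be off by a couple of bases.
SPLIT_AGREE_TOL = 5


def _position_groups(splits) -> list[list]:
    """Chain-link split reads by implied host junction (tolerance above)."""
    ordered = sorted(splits, key=lambda s: s.host_junction)
    groups = [[ordered[0]]]
    for s in ordered[1:]:
        if s.host_junction - groups[-1][-1].host_junction <= SPLIT_AGREE_TOL:
            groups[-1].append(s)
        else:
            groups.append([s])
    return groups


def refine_with_split_reads(cluster: HitCluster, params: CallParams
                            ) -> Optional[tuple[int, Optional[int], bool]]:
    """Median split-read junction, promoted to exact by epsilon-majority.

    Returns (host_pos, virus_pos, exact) or None when the cluster has no
    split reads. Split reads are grouped by the junction they imply;
    the exact flag requires the largest group to outnumber the runner-up
    by >= epsilon, so conflicting split placements (misaligned reads,
    distinct nearby integrations) demote the call to an estimate. The
    reported positions are the lower medians of the winning group.
    """
    splits = cluster.split_reads
    if not splits:
        return None
    groups = sorted(_position_groups(splits), key=len, reverse=True)
    runner_up = len(groups[1]) if len(groups) > 1 else 0
    exact = len(groups[0]) - runner_up >= params.epsilon
    winner = groups[0]
    host_pos = _lower_median(s.host_junction for s in winner)
    v_junctions = [s.virus_junction for s in winner
                   if s.virus_junction is not None]
    virus_pos = _lower_median(v_junctions) if v_junctions else None
    return host_pos, virus_pos, exact


def _oriented_member_seqs(cluster: HitCluster) -> list[str]:
    """Member read sequences, flipped so the host part is on + strand."""
    from ._seq import revcomp
    seqs = []
    for pair, hit in cluster.members:
        mate = 0 if hit.query_id.endswith("/1") else 1
        seq = pair.mate_seq(mate)
        seqs.append(seq if hit.strand == "+" else revcomp(seq))
    return seqs


def _identity(a: str, b: str) -> float:
    n = sum(1 for x, y in zip(a, b) if x == y and x != "N")
    return n / len(a) if a else 0.0


def _vote(column: list[str]) -> str:
    counts: dict[str, int] = {}
    for base in column:  # ties resolved by first-encountered base
        counts[base] = counts.get(base, 0) + 1
    return max(counts, key=lambda b: counts[b])


def assemble_consensus(cluster: HitCluster) -> list[str]:
    """Greedy overlap-layout consensus of the cluster's member reads.

    Reads are piled onto growing contigs whenever they overlap the
    current consensus by >= 30 bp at > 75% identity; columns are resolved
    by majority vote. Reads that fit nowhere start new contigs.
    """
    contigs: list[list[tuple[int, str]]] = []  # list of (offset, seq) piles

    def consensus_of(pile) -> str:
        start = min(o for o, _ in pile)
        end = max(o + len(s) for o, s in pile)
        cols: list[list[str]] = [[] for _ in range(end - start)]
        for o, s in pile:
            for i, base in enumerate(s):
                cols[o - start + i].append(base)
        return "".join(_vote(c) for c in cols)

    for seq in _oriented_member_seqs(cluster):
        placed = False
        for pile in contigs:
            cons = consensus_of(pile)
            base = min(o for o, _ in pile)
            best_shift, best_id = None, MIN_OVERLAP_IDENTITY
            for shift in range(-len(seq) + MIN_OVERLAP,
                               len(cons) - MIN_OVERLAP + 1):
                lo = max(0, shift)
                hi = min(len(cons), shift + len(seq))
                if hi - lo < MIN_OVERLAP:
                    continue
                ident = _identity(cons[lo:hi], seq[lo - shift:hi - shift])
                if ident > best_id:
                    best_id, best_shift = ident, shift
            if best_shift is not None:
                pile.append((base + best_shift, seq))
                placed = True
                break
        if not placed:
            contigs.append([(0, seq)])
    return [consensus_of(p) for p in contigs]


def call_from_consensus(consensus: str, host_index: ReferenceIndex,
                        virus_index: ReferenceIndex, params: AlignParams
                        ) -> list[dict]:
    """Junctions implied by one consensus sequence.

    The consensus is aligned to the host; with a unique smallest expect
    value, its unaligned remainder is aligned to the virus database and a
    hit yields one exact junction at the host/virus boundary. Multiple
    equal-best host placements each yield a junction marked ambiguous; no
    virus hit yields nothing.
    """
    if len(consensus) < params.min_len:
        return []
    host_hits = rank_hits(local_align(consensus, host_index, params))
    if not host_hits:
        return []
    best_e = min(h.e for h in host_hits)
    best = [h for h in host_hits if h.e == best_e]
    ambiguous = len(best) > 1

    spans = _merged_intervals(best)
    lo = min(a for a, _ in spans)
    hi = max(b for _, b in spans)
    head, tail = (0, lo), (hi, len(consensus))
    r0, r1 = max(head, tail, key=lambda t: t[1] - t[0])
    if r1 - r0 < params.min_len:
        return []
    remainder = consensus[r0:r1]
    virus_hits = local_align(remainder, virus_index, params)
    if not virus_hits:
        return []
    vhit = virus_hits[0]
    # shift the virus hit into consensus coordinates
    vhit.qstart += r0
    vhit.qend += r0

    out = []
    for h in best:
        junc = _junction_from_segments(h, vhit)
        if junc is None:
            continue
        side = "5p_host" if junc.host_junction == h.subject_end else "3p_host"
        orient = (vhit.strand if h.strand == "+"
                  else ("+" if vhit.strand == "-" else "-"))
        out.append({"host_chr": h.subject_id,
                    "host_pos": junc.host_junction,
                    "host_side": side,
                    "virus_id": vhit.subject_id,
                    "virus_pos": junc.virus_junction,
                    "virus_orient": orient,
                    "ambiguous": ambiguous})
    return out


def call_integrations(clusters: list[HitCluster], params: CallParams,
                      host_index: ReferenceIndex,
                      virus_index: ReferenceIndex,
                      align_params: AlignParams
                      ) -> tuple[list[IntegrationCall], list[IntegrationCall]]:
    """Emit integration calls from refined, oriented clusters.

    Returns (calls, unreliable): clusters with median rank > 1 are
    reported separately rather than discarded, since they may sit in
    repeats a user still wants to inspect.
    """
    calls: list[IntegrationCall] = []
    unreliable: list[IntegrationCall] = []
    for cluster in clusters:
        if not cluster.members:
            continue
        mr = median_rank(cluster)
        side = "5p_host" if cluster.orientation == "plus" else "3p_host"
        n_pairs = cluster.n_pairs
        n_split = len(cluster.split_reads)
        host_pos, _ = host_breakpoint(cluster)
        vb = virus_breakpoint(cluster, params)
        virus_id, virus_pos, virus_orient = vb if vb else (None, None, None)
        exact = False
        ambiguous = False

        if mr > 1:
            unreliable.append(IntegrationCall(
                host_chr=cluster.chrom, host_pos=host_pos, host_side=side,
                virus_id=virus_id, virus_pos=virus_pos,
                virus_orient=virus_orient, n_pairs=n_pairs, n_split=n_split,
                exact=False, ambiguous=True, median_rank=mr))
            continue

        refined = refine_with_split_reads(cluster, params)
        if refined is not None:
            host_pos, split_virus_pos, exact = refined
            if split_virus_pos is not None and exact:
                virus_pos = split_virus_pos
                if virus_id is None:
                    # strand vote tied but split reads agree: take the
                    # winning group's consensus identity and orientation
                    counts: dict[tuple, int] = {}
                    for s in cluster.split_reads:
                        if s.virus_id is None:
                            continue
                        key = (s.virus_id, s.virus_orient)
                        counts[key] = counts.get(key, 0) + 1
                    if counts:
                        virus_id, virus_orient = sorted(
                            counts, key=lambda k: (-counts[k], k))[0]
        else:
            for cons in sorted(assemble_consensus(cluster), key=len,
                               reverse=True):
                cons_calls = call_from_consensus(cons, host_index,
                                                 virus_index, align_params)
                matching = [c for c in cons_calls
                            if c["host_chr"] == cluster.chrom
                            and c["host_side"] == side]
                if matching:
                    c = matching[0]
                    host_pos = c["host_pos"]
                    virus_id = c["virus_id"]
                    virus_pos = c["virus_pos"]
                    virus_orient = c["virus_orient"]
                    exact = not c["ambiguous"]
                    ambiguous = c["ambiguous"]
                    break

        if n_pairs >= params.min_support:
            calls.append(IntegrationCall(
                host_chr=cluster.chrom, host_pos=host_pos, host_side=side,
                virus_id=virus_id, virus_pos=virus_pos,
                virus_orient=virus_orient, n_pairs=n_pairs, n_split=n_split,
                exact=exact, ambiguous=ambiguous, median_rank=mr))
    calls.sort(key=lambda c: c.sort_key())
    unreliable.sort(key=lambda c: c.sort_key())
    return calls, unreliable
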