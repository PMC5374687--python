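"""Seed-and-extend local aligner with expect-value ranking.

Queries are seeded with exact ``word``-length matches against an indexed
reference, seed groups on nearby diagonals are extended with a full
affine-gap Smith-Waterman over a subject window, and surviving alignments
get a Karlin-Altschul expect value

    e = K * m * n * exp(-lambda * score)

with m the query length and n the total database length. Only relative
ordering of hits and a permissive cutoff feed the downstream clustering
logic, so the ungapped K and lambda constants are applied to gapped scores
and all scoring constants are configuration-exposed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._seq import encode, kmer_codes, revcomp
from ._sw import sw_align
from .model import LocalHit

# A seed word occurring more often than this in the reference is treated
# as repetitive and not extended.
MAX_WORD_OCCURRENCES = 200

# Seeds whose diagonals differ by at most this are extended together.
DIAG_BAND = 15

# Extra subject bases on each side of the seeded diagonal range; bounds
# the gap drift an extension can follow. Subjects up to _SMALL_SUBJECT
# are aligned in full so that small instances are exact.
WINDOW_PAD = 64
_SMALL_SUBJECT = 600


@dataclass(frozen=True)
class AlignParams:
    """blastn-like scoring regime; min_len is the 25 bp sensitivity floor."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    min_len: int = 25
    max_e: float = 1e-3
    word: int = 11
    KA_K: float = 0.41
    KA_lambda: float = 0.625

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.min_len < self.word:
            raise ValueError("min_len must be >= word")


class ReferenceIndex:
    """A word index over a sequence database, queried by the aligner.

    Built once per reference; the (sorted word code, position) table gives
    all exact seed locations of a query word in O(log N).
    """

    def __init__(self, db: dict[str, str], word: int = 11):
        if not db:
            raise ValueError("empty reference database")
        self.word = word
        self.ids = list(db.keys())
        self.encoded = [encode(db[i]) for i in self.ids]
        self.lengths = np.array([len(e) for e in self.encoded])
        self.offsets = np.concatenate([[0], np.cumsum(self.lengths)])
        self.total_len = int(self.lengths.sum())

        codes_all = []
        pos_all = []
        for idx, enc in enumerate(self.encoded):
            codes, valid = kmer_codes(enc, word)
            pos = np.nonzero(valid)[0]
            codes_all.append(codes[pos])
            pos_all.append(pos + self.offsets[idx])
        codes_cat = np.concatenate(codes_all) if codes_all else np.empty(0, np.int64)
        pos_cat = np.concatenate(pos_all) if pos_all else np.empty(0, np.int64)
        order = np.argsort(codes_cat, kind="stable")
        self._codes = codes_cat[order]
        self._pos = pos_cat[order]

    def seed_positions(self, code: int) -> np.ndarray:
        """Global positions of every exact occurrence of a word code."""
        lo = np.searchsorted(self._codes, code, side="left")
        hi = np.searchsorted(self._codes, code, side="right")
        return self._pos[lo:hi]

    def locate(self, global_pos: int) -> tuple[int, int]:
        """Map a global position to (sequence index, local position)."""
        idx = int(np.searchsorted(self.offsets, global_pos, side="right")) - 1
        return idx, int(global_pos - self.offsets[idx])


def expect_value(score: float, m: int, n: int, params: AlignParams) -> float:
    e = params.KA_K * m * n * math.exp(-params.KA_lambda * score)
    # exp() underflows to 0.0 for very high scores (long perfect consensus
    # alignments); clamp to the smallest positive float so e stays > 0.
    return e if e > 0.0 else 5e-324


def _seed_groups(qpos: np.ndarray, gpos: np.ndarray, ref: ReferenceIndex,
                 qlen: int):
    """Partition seeds into (seq_idx, subject window) extension jobs."""
    seq_idx = np.searchsorted(ref.offsets, gpos, side="right") - 1
    local = gpos - ref.offsets[seq_idx]
    diag = local - qpos
    order = np.lexsort((local, diag, seq_idx))
    groups = []
    cur: list[int] = []
    for o in order:
        if cur:
            p = cur[-1]
            same = (seq_idx[o] == seq_idx[p]
                    and diag[o] - diag[p] <= DIAG_BAND
                    and local[o] - local[p] <= qlen)
            if not same:
                groups.append(cur)
                cur = []
        cur.append(int(o))
    if cur:
        groups.append(cur)
    for g in groups:
        sidx = int(seq_idx[g[0]])
        dmin = int(min(diag[i] for i in g))
        dmax = int(max(diag[i] for i in g))
        slen = int(ref.lengths[sidx])
        if slen <= _SMALL_SUBJECT:
            ws, we = 0, slen
        else:
            ws = max(0, dmin - WINDOW_PAD)
            we = min(slen, dmax + qlen + WINDOW_PAD)
        yield sidx, ws, we


def local_align(query: str, ref: ReferenceIndex,
                params: AlignParams) -> list[LocalHit]:
    """All seed-extended local alignments of a query, both strands.

    Hits shorter than ``min_len`` on the query or with e > ``max_e`` are
    dropped; near-duplicate extensions of the same locus are masked,
    keeping the better score. Result is sorted by ascending e, ties broken
    by descending score then (subject_id, L).
    """
    if len(query) < params.word:
        raise ValueError("query shorter than seed word")
    if ref.word != params.word:
        raise ValueError("reference indexed with a different word size")
    m = len(query)
    hits: dict[tuple, LocalHit] = {}

    for strand in ("+", "-"):
        q = query if strand == "+" else revcomp(query)
        qenc = encode(q)
        codes, valid = kmer_codes(qenc, params.word)
        qpos_list = []
        gpos_list = []
        for qp in np.nonzero(valid)[0]:
            pos = ref.seed_positions(int(codes[qp]))
            if 0 < pos.size <= MAX_WORD_OCCURRENCES:
                qpos_list.append(np.full(pos.size, qp))
                gpos_list.append(pos)
        if not qpos_list:
            continue
        qpos = np.concatenate(qpos_list)
        gpos = np.concatenate(gpos_list)
        seen_windows = set()
        for sidx, ws, we in _seed_groups(qpos, gpos, ref, m):
            key = (strand, sidx, ws, we)
            if key in seen_windows:
                continue
            seen_windows.add(key)
            sub = ref.encoded[sidx][ws:we]
            (score, q0, q1, s0, s1,
             n_match, n_cols) = sw_align(qenc, sub, params.match,
                                         params.mismatch, params.gap_open,
                                         params.gap_extend)
            if score <= 0 or q1 - q0 < params.min_len:
                continue
            e = expect_value(score, m, ref.total_len, params)
            if e > params.max_e:
                continue
            if strand == "+":
                span = (int(q0), int(q1))
            else:
                span = (m - int(q1), m - int(q0))
            hit = LocalHit(query_id="", qstart=span[0], qend=span[1],
                           subject_id=ref.ids[sidx], L=ws + int(s0),
                           subject_end=ws + int(s1), strand=strand,
                           score=float(score), e=e, n_match=int(n_match),
                           n_cols=int(n_cols))
            k = hit.key()
            if k not in hits or hits[k].score < hit.score:
                hits[k] = hit

    return _mask_overlaps(list(hits.values()))


def _mask_overlaps(hits: list[LocalHit]) -> list[LocalHit]:
    """Drop seed-ladder duplicates: same subject, overlapping on both the
    query (>50% of the shorter span) and the subject; keep the better
    score. Distinct placements on the same chromosome do not overlap on
    the subject and are all kept."""
    hits.sort(key=lambda h: (-h.score, h.subject_id, h.L, h.strand))
    kept: list[LocalHit] = []
    for h in hits:
        shadowed = False
        for g in kept:
            if g.subject_id != h.subject_id or g.strand != h.strand:
                continue
            q_ov = min(g.qend, h.qend) - max(g.qstart, h.qstart)
            shorter = min(g.qend - g.qstart, h.qend - h.qstart)
            s_ov = min(g.subject_end, h.subject_end) - max(g.L, h.L)
            if q_ov > 0.5 * shorter and s_ov > 0:
                shadowed = True
                break
        if not shadowed:
            kept.append(h)
    kept.sort(key=lambda h: (h.e, -h.score, h.subject_id, h.L))
    return kept


def rank_hits(hits: list[LocalHit]) -> list[LocalHit]:
    """Assign each hit rank = number of hits with e <= its own e.

    A unique best hit gets rank 1; k tied best hits all get rank k. The
    ranks are a permutation-invariant function of the e multiset.
    """
    es = [h.e for h in hits]
    for h in hits:
        h.rank = sum(1 for e in es if e <= h.e)
    return hits


def retain_top_hits(hits: list[LocalHit]) -> list[LocalHit]:
    """Keep the most credible hits of one query.

    If several hits tie for the smallest expect value, exactly those are
    kept. If the best hit is unique it may still be noise, so the hits at
    the second-smallest expect value are kept alongside it.
    """
    if not hits:
        return []
    es = sorted({h.e for h in hits})
    best = [h for h in hits if h.e == es[0]]
    if len(best) >= 2 or len(es) == 1:
        return best
    return best + [h for h in hits if h.e == es[1]]
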