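"""First-pass k-mer screen against the virus database.

A read pair survives the screen when at least one sampled k-mer of either
mate matches the virus database (either strand) with at most ``r``
mismatches. This replaces a BWT all-hits mapper with a sorted 2-bit k-mer
code table plus mismatch-neighborhood enumeration, which is exact for the
small ``r`` (<= 2) the screen uses. Defaults k=18, r=1, s=5 favour
sensitivity: an 18-mer is the shortest viral segment worth chasing.
"""
from __future__ import annotations

import logging
import itertools
from dataclasses import dataclass

import numpy as np

from ._seq import encode, kmer_codes, revcomp
from .model import ReadPair

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenParams:
    k: int = 18
    r: int = 1
    s: int = 5

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ValueError("k must be >= 8")
        if not (0 <= self.r <= 2):
            raise ValueError("r must be in [0, 2]")
        if not (1 <= self.s <= self.k):
            raise ValueError("s must be in [1, k]")


class KmerIndex:
    """All k-mer occurrences of a virus database, both strands.

    ``lookup`` reports every (sequence, strand, position) occurrence of a
    k-mer; membership queries go through a sorted array of integer codes
    so that screening can test whole neighborhoods with one searchsorted.
    """

    def __init__(self, k: int):
        self.k = k
        self._positions: dict[int, list[tuple[str, str, int]]] = {}
        self._codes = np.empty(0, dtype=np.int64)

    def lookup(self, kmer: str) -> list[tuple[str, str, int]]:
        """Occurrences of ``kmer`` as (seq_id, strand, 0-based position)."""
        if len(kmer) != self.k:
            raise ValueError(f"query length {len(kmer)} != k={self.k}")
        codes, valid = kmer_codes(encode(kmer), self.k)
        if not valid[0]:
            return []
        return self._positions.get(int(codes[0]), [])

    def contains_any(self, queries: np.ndarray) -> bool:
        """True if any integer code in ``queries`` is in the database."""
        if queries.size == 0 or self._codes.size == 0:
            return False
        idx = np.searchsorted(self._codes, queries)
        idx[idx == self._codes.size] = 0
        return bool(np.any(self._codes[idx] == queries))


def build_index(virus_db: dict[str, str], k: int) -> KmerIndex:
    """Index every k-mer of every virus sequence on both strands.

    Sequences shorter than k are skipped with a warning.
    """
    index = KmerIndex(k)
    all_codes = []
    for seq_id, seq in virus_db.items():
        if len(seq) < k:
            logger.warning("virus sequence %s shorter than k=%d; skipped",
                           seq_id, k)
            continue
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            codes, valid = kmer_codes(encode(s), k)
            for pos in np.nonzero(valid)[0]:
                code = int(codes[pos])
                index._positions.setdefault(code, []).append(
                    (seq_id, strand, int(pos)))
            all_codes.append(codes[valid])
    if all_codes:
        index._codes = np.unique(np.concatenate(all_codes))
    return index


def _neighborhood_deltas(k: int, r: int) -> np.ndarray:
    """XOR deltas generating the Hamming-<=r neighborhood of a k-mer code.

    XOR-ing a 2-bit base field with 1, 2 or 3 yields the three alternative
    bases, so {0} U {d << 2p} U pairwise combinations cover all words
    within Hamming distance r.
    """
    deltas = [0]
    singles = [d << (2 * p) for p in range(k) for d in (1, 2, 3)]
    if r >= 1:
        deltas.extend(singles)
    if r >= 2:
        for (p1, p2) in itertools.combinations(range(k), 2):
            for d1 in (1, 2, 3):
                for d2 in (1, 2, 3):
                    deltas.append((d1 << (2 * p1)) | (d2 << (2 * p2)))
    return np.array(deltas, dtype=np.int64)


_DELTA_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _sampled_starts(read_len: int, params: ScreenParams) -> list[int]:
    """k-mer start offsets 0, s, 2s, ... plus the final full k-mer."""
    if read_len < params.k:
        return []
    starts = list(range(0, read_len - params.k + 1, params.s))
    last = read_len - params.k
    if starts[-1] != last:
        starts.append(last)
    return starts


def _deltas(k: int, r: int) -> np.ndarray:
    key = (k, r)
    if key not in _DELTA_CACHE:
        _DELTA_CACHE[key] = _neighborhood_deltas(k, r)
    return _DELTA_CACHE[key]


def _n_kmer_matches(enc: np.ndarray, start: int, index: KmerIndex,
                    params: ScreenParams) -> bool:
    """Slow path for a sampled k-mer containing N bases.

    An N mismatches every database base, so it consumes one unit of the
    mismatch budget and the database may carry any base there: enumerate
    all four bases at each N position with the remaining budget spent on
    the other positions.
    """
    window = enc[start:start + params.k]
    n_pos = np.nonzero(window == 4)[0]
    if len(n_pos) > params.r:
        return False
    shifts = 2 * (params.k - 1 - n_pos.astype(np.int64))
    base = window.astype(np.int64).copy()
    base[n_pos] = 0
    weights = 1 << (2 * np.arange(params.k - 1, -1, -1, dtype=np.int64))
    code = int(base @ weights)
    variants = np.array([code], dtype=np.int64)
    for sh in shifts:
        variants = (variants[:, None]
                    ^ np.array([0, 1, 2, 3], dtype=np.int64)[None, :] << sh
                    ).ravel()
    neigh = variants[:, None] ^ _deltas(params.k,
                                        params.r - len(n_pos))[None, :]
    return index.contains_any(neigh.ravel())


def _mate_matches(seq: str, index: KmerIndex, params: ScreenParams) -> bool:
    starts = _sampled_starts(len(seq), params)
    if not starts:
        return False
    enc = encode(seq)
    codes, valid = kmer_codes(enc, params.k)
    starts_arr = np.array(starts)
    keep = valid[starts_arr]
    if np.any(keep):
        sampled = codes[starts_arr[keep]]
        neigh = sampled[:, None] ^ _deltas(params.k, params.r)[None, :]
        if index.contains_any(neigh.ravel()):
            return True
    for start in starts_arr[~keep]:
        if _n_kmer_matches(enc, int(start), index, params):
            return True
    return False


def screen_pair(pair: ReadPair, index: KmerIndex,
                params: ScreenParams) -> bool:
    """True iff either mate has a sampled k-mer within Hamming r of the db.

    The read is screened as given; reverse complements are covered by the
    index side. A True result promotes the pair to stage X1.
    """
    hit = (_mate_matches(pair.seq1, index, params)
           or _mate_matches(pair.seq2, index, params))
    if hit:
        pair.advance("X1")
    return hit


def screen_pairs(pairs, index: KmerIndex, params: ScreenParams) -> list:
    """Screen a collection of pairs, returning the X1 set (order kept)."""
    return [p for p in pairs if screen_pair(p, index, params)]
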