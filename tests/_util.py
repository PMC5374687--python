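"""Shared factories for building small domain objects in tests."""
from __future__ import annotations

import math

from vintect.model import LocalHit, ReadPair


def mk_pair(pair_id: str = "p1", seq1: str = "A" * 100,
            seq2: str = "C" * 100) -> ReadPair:
    return ReadPair(id=pair_id, seq1=seq1, seq2=seq2)


def mk_hit(qid: str = "p1/1", qstart: int = 0, qend: int = 100,
           subject: str = "chr1", L: int = 0, send: int | None = None,
           strand: str = "+", score: float | None = None,
           e: float | None = None, rank: int = 1) -> LocalHit:
    if send is None:
        send = L + (qend - qstart)
    if score is None:
        score = 2.0 * (qend - qstart)
    if e is None:
        e = 0.41 * 100 * 1000 * math.exp(-0.625 * score)
        e = max(e, 5e-324)
    return LocalHit(query_id=qid, qstart=qstart, qend=qend,
                    subject_id=subject, L=L, subject_end=send,
                    strand=strand, score=score, e=e, rank=rank)


def mk_member(pair_id: str = "p1", mate: int = 0, read_len: int = 100,
              **hit_kwargs):
    """A (ReadPair, LocalHit) cluster member with consistent query_id."""
    pair = mk_pair(pair_id, "A" * read_len, "C" * read_len)
    hit_kwargs.setdefault("qend", read_len)
    hit = mk_hit(qid=f"{pair_id}/{mate + 1}", **hit_kwargs)
    pair.host_hits[mate].append(hit)
    return pair, hit
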