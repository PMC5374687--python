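"""The chimeric-read funnel: X1 -> X2 -> X_chimera.

After the k-mer screen (X1), pairs are confirmed against the virus
database with the sensitive local aligner (X2), and finally required to
also hit the host genome (X_chimera). Each stage only narrows the set, so
X_chimera is a subset of X2 is a subset of X1. The virus database is
always queried before the host genome — it is tiny by comparison, so the
expensive host alignment runs on as few reads as possible.
"""
from __future__ import annotations

from .align import AlignParams, ReferenceIndex, local_align, rank_hits, \
    retain_top_hits
from .model import ReadPair


def build_X2(X1: list[ReadPair], virus_index: ReferenceIndex,
             params: AlignParams) -> list[ReadPair]:
    """Promote X1 pairs with a genuine virus alignment on either mate.

    Pairs whose k-mer screen match does not survive local alignment (no
    hit of at least min_len bases under the e-value cutoff) are discarded.
    Virus hits are stored on the pair for later breakpoint work.
    """
    out = []
    for pair in X1:
        any_hit = False
        for mate in (0, 1):
            hits = local_align(pair.mate_seq(mate), virus_index, params)
            for h in hits:
                h.query_id = f"{pair.id}/{mate + 1}"
            pair.virus_hits[mate][:] = hits
            any_hit = any_hit or bool(hits)
        if any_hit:
            pair.advance("X2")
            out.append(pair)
    return out


def build_X_chimera(X2: list[ReadPair], host_index: ReferenceIndex,
                    params: AlignParams) -> list[ReadPair]:
    """Promote X2 pairs that also hit the host genome.

    Host hits of each mate are ranked over the full hit list, then passed
    through the retention rule (all tied-best hits; plus the second-best
    when the best is unique).
    """
    out = []
    for pair in X2:
        any_hit = False
        for mate in (0, 1):
            hits = local_align(pair.mate_seq(mate), host_index, params)
            hits = rank_hits(hits)
            hits = retain_top_hits(hits)
            for h in hits:
                h.query_id = f"{pair.id}/{mate + 1}"
            pair.host_hits[mate][:] = hits
            any_hit = any_hit or bool(hits)
        if any_hit:
            pair.advance("X_chimera")
            out.append(pair)
    return out
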