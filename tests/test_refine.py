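"""Cluster refinement: complex-read filter, dedupe, split-read rescue.

Rescue scenarios are built from real reference sequences and run through
the actual chimera funnel so the hits carry realistic coordinates.
"""
import numpy as np
import pytest

from vintect._seq import revcomp
from vintect.align import AlignParams
from vintect.chimera import build_X2, build_X_chimera
from vintect.model import LibraryStats, ReadPair
from vintect.refine import (RescueParams, dedupe, detect_split_read,
                            filter_complex, rescue_split_read)
from vintect.simulate import _extension_score
from _util import mk_hit, mk_pair

STATS = LibraryStats(300.0, 30.0)
PARAMS = AlignParams()

VSTART = 100  # virus-side junction coordinate used in rescue scenarios


def find_clean_junction(host: str, virus: str, v: int = VSTART) -> int:
    """First host position past 2000 where neither alignment can extend
    across a host|virus[v:] junction (no microhomology), so the true
    breakpoint of the constructed scenario is unambiguous."""
    for p in range(2000, 2500):
        if (_extension_score(virus[v:v + 40], host[p:p + 40]) == 0
                and _extension_score(host[p - 40:p][::-1],
                                     virus[v - 40:v][::-1]) == 0):
            return p
    raise AssertionError("no homology-free junction in test reference")


class TestFilterComplex:
    def test_host_between_two_viral_segments_discarded(self):
        pair = mk_pair("p1")
        pair.virus_hits[0].extend([mk_hit(qstart=0, qend=30, subject="v"),
                                   mk_hit(qstart=75, qend=100, subject="v",
                                          L=500)])
        pair.host_hits[0].append(mk_hit(qstart=35, qend=70))
        members = [(pair, pair.host_hits[0][0])]
        assert filter_complex(members) == []

    def test_host_host_pair_on_different_chromosomes_discarded(self):
        pair = mk_pair("p1")
        pair.host_hits[0].append(mk_hit(qid="p1/1", subject="chr1"))
        pair.host_hits[1].append(mk_hit(qid="p1/2", subject="chr7",
                                        strand="-"))
        assert filter_complex([(pair, pair.host_hits[0][0])]) == []

    def test_host_host_pair_same_strand_discarded(self):
        pair = mk_pair("p1")
        pair.host_hits[0].append(mk_hit(qid="p1/1"))
        pair.host_hits[1].append(mk_hit(qid="p1/2", L=300))
        assert filter_complex([(pair, pair.host_hits[0][0])]) == []

    def test_forward_reverse_same_chromosome_kept(self):
        pair = mk_pair("p1")
        pair.host_hits[0].append(mk_hit(qid="p1/1", L=1000))
        pair.host_hits[1].append(mk_hit(qid="p1/2", L=1300, strand="-"))
        members = [(pair, pair.host_hits[0][0])]
        assert filter_complex(members) == members


class TestDedupe:
    def _twin_pairs(self):
        out = []
        for pid in ("b_pair", "a_pair"):
            pair = mk_pair(pid)
            pair.host_hits[0].append(mk_hit(qid=f"{pid}/1", L=1000))
            pair.virus_hits[1].append(mk_hit(qid=f"{pid}/2", subject="v",
                                             L=40))
            out.append((pair, pair.host_hits[0][0]))
        return out

    def test_identical_alignments_keep_smallest_id(self):
        kept = dedupe(self._twin_pairs(), enabled=True)
        assert [p.id for p, _ in kept] == ["a_pair"]

    def test_disabled_passthrough(self):
        members = self._twin_pairs()
        assert dedupe(members, enabled=False) == members

    def test_one_base_difference_keeps_both(self):
        members = self._twin_pairs()
        members[0][1].L += 1
        members[0][1].subject_end += 1
        assert len(dedupe(members, enabled=True)) == 2

    def test_idempotent(self):
        once = dedupe(self._twin_pairs(), enabled=True)
        assert dedupe(once, enabled=True) == once


def run_funnel(pair, refs):
    """Populate virus/host hits through the real chimera stages."""
    x2 = build_X2([pair], refs["virus_index"], PARAMS)
    build_X_chimera(x2, refs["host_index"], PARAMS)
    return pair


class TestRescue:
    def _junction(self, refs) -> int:
        return find_clean_junction(refs["host"]["chr1"],
                                   refs["virus"]["virusA"])

    def _pair(self, refs, tail_len, insert="", virus_len=None):
        """Anchor mate in host, split mate = rc(host_tail+insert+virus)."""
        host = refs["host"]["chr1"]
        virus = refs["virus"]["virusA"]
        p = self._junction(refs)
        if virus_len is None:
            virus_len = 100 - tail_len - len(insert)
        frag = (host[p - tail_len:p] + insert
                + virus[VSTART:VSTART + virus_len])
        return ReadPair("r1", host[p - 100:p], revcomp(frag))

    def test_short_host_segment_rescued_exactly(self, seeded_refs):
        # 20 bp host tail: below the 25 bp aligner floor, above the 10 bp
        # rescue threshold
        pair = run_funnel(self._pair(seeded_refs, tail_len=20),
                          seeded_refs)
        res = rescue_split_read(pair, seeded_refs["host_index"], STATS,
                                PARAMS)
        assert res.rescued
        assert res.host_pos == self._junction(seeded_refs)
        assert res.split.host_side == "5p_host"
        assert res.split.virus_junction == VSTART + 1
        assert res.split.virus_orient == "+"
        assert res.split.source == "rescued"

    def test_tail_below_ten_bases_not_attempted(self, seeded_refs):
        pair = run_funnel(self._pair(seeded_refs, tail_len=8),
                          seeded_refs)
        res = rescue_split_read(pair, seeded_refs["host_index"], STATS,
                                PARAMS)
        assert not res.rescued

    def test_random_tail_rejected(self, seeded_refs):
        rng = np.random.default_rng(50)
        tail = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 30)])
        virus = seeded_refs["virus"]["virusA"]
        pair = ReadPair("r1", seeded_refs["host"]["chr1"][1900:2000],
                        revcomp(tail + virus[100:170]))
        run_funnel(pair, seeded_refs)
        res = rescue_split_read(pair, seeded_refs["host_index"], STATS,
                                PARAMS)
        assert not res.rescued

    def test_rescued_position_inside_flank_window(self, seeded_refs):
        pair = run_funnel(self._pair(seeded_refs, tail_len=15),
                          seeded_refs)
        res = rescue_split_read(pair, seeded_refs["host_index"], STATS,
                                PARAMS)
        assert res.rescued
        anchor = pair.host_hits[0][0]
        assert anchor.L <= res.host_pos <= anchor.L + STATS.cluster_gap

    def test_random_insert_does_not_shift_junction(self, seeded_refs):
        # A short random insert sits between virus and host in the read;
        # rescue still finds the host segment at the true junction. The
        # insert is drawn so it cannot itself extend an alignment across
        # the junction (as the simulator guarantees for its junctions).
        host = seeded_refs["host"]["chr1"]
        virus = seeded_refs["virus"]["virusA"]
        p = self._junction(seeded_refs)
        rng = np.random.default_rng(51)
        while True:
            ins = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 5)])
            if _extension_score(ins + virus[VSTART:VSTART + 35],
                                host[p:p + 40]) == 0:
                break
        pair = run_funnel(self._pair(seeded_refs, tail_len=15, insert=ins),
                          seeded_refs)
        res = rescue_split_read(pair, seeded_refs["host_index"], STATS,
                                PARAMS)
        assert res.rescued and res.host_pos == self._junction(seeded_refs)

    def test_unanchored_mate_not_attempted(self, seeded_refs):
        virus = seeded_refs["virus"]["virusA"]
        host = seeded_refs["host"]["chr1"]
        pair = ReadPair("r1", virus[300:400],
                        revcomp(host[1985:2000] + virus[100:185]))
        run_funnel(pair, seeded_refs)
        res = rescue_split_read(pair, seeded_refs["host_index"], STATS,
                                PARAMS)
        assert not res.rescued


class TestNativeSplit:
    def test_native_split_layout_detected(self, seeded_refs):
        host = seeded_refs["host"]["chr1"]
        virus = seeded_refs["virus"]["virusA"]
        p = find_clean_junction(host, virus)
        pair = ReadPair("r1", host[p - 100:p],
                        revcomp(host[p - 50:p] + virus[VSTART:VSTART + 50]))
        run_funnel(pair, seeded_refs)
        split = detect_split_read(pair, 1, max_gap=10)
        assert split is not None
        assert split.host_junction == p
        assert split.host_side == "5p_host"
        assert split.virus_junction == VSTART + 1
        assert split.source == "aligned"

    def test_no_split_without_virus_segment(self, seeded_refs):
        host = seeded_refs["host"]["chr1"]
        pair = ReadPair("r1", host[1900:2000], revcomp(host[2000:2100]))
        run_funnel(pair, seeded_refs)
        assert detect_split_read(pair, 1, max_gap=10) is None
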