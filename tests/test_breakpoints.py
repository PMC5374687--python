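"""Breakpoint estimation, strand voting, split-read refinement, consensus."""
import numpy as np
import pytest

from vintect.align import AlignParams, ReferenceIndex
from vintect.breakpoints import (CallParams, assemble_consensus,
                                 call_from_consensus, call_integrations,
                                 host_breakpoint, refine_with_split_reads,
                                 virus_breakpoint)
from vintect.model import HitCluster, SplitRead
from _util import mk_hit, mk_member

PARAMS = CallParams()
BASES = np.array(list("ACGT"))


def rand_seq(n, rng):
    return "".join(BASES[rng.integers(0, 4, n)])


def mk_split(host_junction, virus_junction=200, virus_orient="+",
             side="5p_host", pid="s1"):
    return SplitRead(pair_id=pid, mate=0, host_chrom="chr1",
                     host_junction=host_junction, host_side=side,
                     virus_id="v1", virus_junction=virus_junction,
                     virus_strand="-", virus_orient=virus_orient)


class TestHostBreakpoint:
    def test_c_plus_reports_rightmost_aligned_end(self):
        members = [mk_member("a", L=1000, send=1100),
                   mk_member("b", L=1040, send=1140)]
        cluster = HitCluster("chr1", members, orientation="plus")
        assert host_breakpoint(cluster) == (1140, False)

    def test_c_minus_reports_leftmost_start(self):
        members = [mk_member("a", L=1999, send=2099, strand="-"),
                   mk_member("b", L=2049, send=2149, strand="-")]
        cluster = HitCluster("chr1", members, orientation="minus")
        # 0-based start 1999 -> first host base is 1-based 2000
        assert host_breakpoint(cluster) == (2000, False)

    def test_split_read_overrides_estimate(self):
        members = [mk_member("a", L=1000, send=1100),
                   mk_member("b", L=1040, send=1140)]
        cluster = HitCluster("chr1", members, orientation="plus",
                             split_reads=[mk_split(1130)])
        assert host_breakpoint(cluster) == (1130, True)

    def test_empty_cluster_is_an_error(self):
        with pytest.raises(ValueError):
            host_breakpoint(HitCluster("chr1", [], orientation="plus"))


def cluster_with_virus_votes(n_plus, n_minus, orientation="plus",
                             minus_span=(499, 850)):
    members = []
    for i in range(n_plus + n_minus):
        pair, hit = mk_member(f"p{i}", L=1000 + i, send=1100 + i)
        strand = "+" if i < n_plus else "-"
        span = (200, 500) if strand == "+" else minus_span
        pair.virus_hits[1].append(
            mk_hit(qid=f"p{i}/2", qstart=0, qend=span[1] - span[0]
                   if span[1] - span[0] <= 100 else 100,
                   subject="v1", L=span[0],
                   send=span[1], strand=strand))
        members.append((pair, hit))
    return HitCluster("chr1", members, orientation=orientation)


class TestVirusBreakpoint:
    def test_majority_meets_epsilon(self):
        cluster = cluster_with_virus_votes(5, 2)
        result = virus_breakpoint(cluster, PARAMS)
        assert result is not None
        virus_id, pos, orient = result
        assert virus_id == "v1"
        # C+ with winning + strand: junction-proximal end is the 3'-most
        assert pos == 500
        assert orient == "-"

    def test_tie_within_epsilon_not_reported(self):
        assert virus_breakpoint(cluster_with_virus_votes(3, 2), PARAMS) is None

    def test_c_plus_minus_strand_winner_uses_five_prime_most(self):
        cluster = cluster_with_virus_votes(0, 4, minus_span=(499, 850))
        virus_id, pos, orient = virus_breakpoint(cluster, PARAMS)
        assert pos == 500  # 5'-most position of the viral segment
        assert orient == "+"

    def test_no_virus_hits_gives_none(self):
        members = [mk_member("a", L=1000)]
        cluster = HitCluster("chr1", members, orientation="plus")
        assert virus_breakpoint(cluster, PARAMS) is None


class TestSplitRefinement:
    def _cluster(self, splits):
        members = [mk_member("a", L=900, send=1000)]
        return HitCluster("chr1", members, orientation="plus",
                          split_reads=splits)

    def test_median_of_agreeing_splits(self):
        cluster = self._cluster([mk_split(1000), mk_split(1001),
                                 mk_split(1000)])
        host_pos, virus_pos, exact = refine_with_split_reads(cluster, PARAMS)
        assert host_pos == 1000 and exact

    def test_three_against_zero_is_exact(self):
        cluster = self._cluster([mk_split(1000)] * 3)
        assert refine_with_split_reads(cluster, PARAMS)[2] is True

    def test_two_against_one_conflicting_not_exact(self):
        cluster = self._cluster([mk_split(1000), mk_split(1000),
                                 mk_split(1200)])
        host_pos, _, exact = refine_with_split_reads(cluster, PARAMS)
        assert not exact and host_pos == 1000

    def test_no_splits_returns_none(self):
        assert refine_with_split_reads(self._cluster([]), PARAMS) is None


def reads_cluster(seqs_with_offsets, total=None):
    """Cluster whose members carry the given (already oriented) reads."""
    members = []
    for i, (seq, L) in enumerate(seqs_with_offsets):
        pair, hit = mk_member(f"p{i}", read_len=len(seq), L=L,
                              send=L + len(seq))
        pair.seq1 = seq
        members.append((pair, hit))
    return HitCluster("chr1", members, orientation="plus")


class TestConsensus:
    def test_overlapping_reads_merge(self):
        rng = np.random.default_rng(3)
        s = rand_seq(160, rng)
        cluster = reads_cluster([(s[:100], 0), (s[60:160], 60)])
        assert assemble_consensus(cluster) == [s]

    def test_short_overlap_not_merged(self):
        rng = np.random.default_rng(4)
        s = rand_seq(180, rng)
        cluster = reads_cluster([(s[:100], 0), (s[80:180], 80)])
        assert len(assemble_consensus(cluster)) == 2

    def test_low_identity_overlap_not_merged(self):
        rng = np.random.default_rng(5)
        s = rand_seq(160, rng)
        r2 = list(s[60:160])
        for pos in rng.choice(40, size=12, replace=False):  # 70% identity
            r2[pos] = [b for b in "ACGT" if b != r2[pos]][
                rng.integers(0, 3)]
        cluster = reads_cluster([(s[:100], 0), ("".join(r2), 60)])
        assert len(assemble_consensus(cluster)) == 2

    def test_majority_vote_fixes_lone_error(self):
        rng = np.random.default_rng(6)
        s = rand_seq(120, rng)
        bad = list(s[:100])
        bad[50] = [b for b in "ACGT" if b != bad[50]][0]
        cluster = reads_cluster([(s[:100], 0), ("".join(bad), 0),
                                 (s[:100], 0), (s[20:120], 20)])
        assert assemble_consensus(cluster) == [s]


@pytest.fixture(scope="module")
def refs():
    rng = np.random.default_rng(77)
    block = rand_seq(80, rng)
    host = {"chr1": rand_seq(500, rng) + block + rand_seq(1400, rng),
            "chr2": rand_seq(600, rng) + block + rand_seq(900, rng)}
    virus = {"v1": rand_seq(800, rng)}
    ap = AlignParams()
    return {"host": host, "virus": virus,
            "hidx": ReferenceIndex(host, ap.word),
            "vidx": ReferenceIndex(virus, ap.word), "ap": ap}


class TestCallFromConsensus:
    def test_unique_host_placement_exact_junction(self, refs):
        cons = refs["host"]["chr1"][900:980] + refs["virus"]["v1"][200:260]
        calls = call_from_consensus(cons, refs["hidx"], refs["vidx"],
                                    refs["ap"])
        assert len(calls) == 1
        c = calls[0]
        assert not c["ambiguous"]
        assert (c["host_chr"], c["host_side"]) == ("chr1", "5p_host")
        assert c["host_pos"] == 980
        assert c["virus_id"] == "v1" and c["virus_pos"] == 201
        assert c["virus_orient"] == "+"

    def test_repeat_placement_marked_ambiguous(self, refs):
        # the 80 bp block occurs on chr1 and chr2: two equal-best hits
        block = refs["host"]["chr1"][500:580]
        cons = block + refs["virus"]["v1"][200:260]
        calls = call_from_consensus(cons, refs["hidx"], refs["vidx"],
                                    refs["ap"])
        assert len(calls) == 2
        assert all(c["ambiguous"] for c in calls)
        assert {c["host_chr"] for c in calls} == {"chr1", "chr2"}

    def test_pure_host_consensus_no_call(self, refs):
        cons = refs["host"]["chr1"][900:1040]
        assert call_from_consensus(cons, refs["hidx"], refs["vidx"],
                                   refs["ap"]) == []


class TestCallIntegrations:
    def test_median_rank_above_one_goes_to_unreliable(self, refs):
        members = [mk_member("a", L=1000, send=1100, rank=2),
                   mk_member("b", L=1050, send=1150, rank=2)]
        cluster = HitCluster("chr1", members, orientation="plus",
                             split_reads=[mk_split(1130)] * 3)
        calls, unreliable = call_integrations([cluster], PARAMS,
                                              refs["hidx"], refs["vidx"],
                                              refs["ap"])
        assert calls == []
        assert len(unreliable) == 1
        assert unreliable[0].median_rank == 2

    def test_tied_virus_vote_reports_host_only(self, refs):
        cluster = cluster_with_virus_votes(1, 1)
        calls, _ = call_integrations([cluster], PARAMS, refs["hidx"],
                                     refs["vidx"], refs["ap"])
        assert len(calls) == 1
        assert calls[0].virus_id is None and calls[0].virus_pos is None
        assert calls[0].host_pos == 1101

    def test_split_reads_make_exact_call(self, refs):
        members = [mk_member("a", L=1000, send=1100),
                   mk_member("b", L=1040, send=1140)]
        cluster = HitCluster("chr1", members, orientation="plus",
                             split_reads=[mk_split(1130, pid=f"s{i}")
                                          for i in range(3)])
        calls, _ = call_integrations([cluster], PARAMS, refs["hidx"],
                                     refs["vidx"], refs["ap"])
        assert calls[0].exact and calls[0].host_pos == 1130
        assert calls[0].n_split == 3

    def test_min_support_filters_calls(self, refs):
        members = [mk_member("a", L=1000, send=1100)]
        cluster = HitCluster("chr1", members, orientation="plus",
                             split_reads=[mk_split(1090)] * 3)
        strict = CallParams(min_support=2)
        calls, _ = call_integrations([cluster], strict, refs["hidx"],
                                     refs["vidx"], refs["ap"])
        assert calls == []
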