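"""Core domain types for the integration-calling pipeline.

The pipeline narrows a read set through three stages: ``X1`` (pairs with a
k-mer match to the virus database), ``X2`` (pairs with a genuine local
alignment to a virus), and ``X_chimera`` (pairs that additionally hit the
host genome). Coordinates are 0-based half-open internally; all user-facing
output is 1-based fully closed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

# Read-pair life cycle; a pair's stage only ever advances left to right.
STAGES = ("input", "X1", "X2", "X_chimera")


@dataclass(eq=False)
class ReadPair:
    """A paired-end read with its accumulated alignment evidence.

    ``virus_hits`` / ``host_hits`` are per-mate lists of :class:`LocalHit`
    filled in by the chimera filter; they are empty until the corresponding
    stage has run.
    """

    id: str
    seq1: str
    seq2: str
    qual1: Optional[str] = None
    qual2: Optional[str] = None
    source: str = "raw"  # raw | sam_extracted
    stage: str = "input"
    virus_hits: tuple[list, list] = field(default_factory=lambda: ([], []))
    host_hits: tuple[list, list] = field(default_factory=lambda: ([], []))

    def __post_init__(self) -> None:
        if not self.seq1 or not self.seq2:
            raise ValueError(f"read pair {self.id}: empty mate sequence")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    def advance(self, stage: str) -> None:
        """Move the pair forward in the funnel; never backwards."""
        if STAGES.index(stage) < STAGES.index(self.stage):
            raise ValueError(
                f"stage may only advance: {self.stage} -> {stage} on {self.id}"
            )
        self.stage = stage

    def mate_seq(self, mate: int) -> str:
        return self.seq1 if mate == 0 else self.seq2

    def __hash__(self) -> int:
        return hash(self.id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReadPair):
            return NotImplemented
        return self.id == other.id


@dataclass(frozen=True)
class LibraryStats:
    """Insert-size model of the sequencing library.

    d is the mean insert (outer fragment) size and sigma its standard
    deviation, both in bases. The clustering gap and the split-read rescue
    window are both d + 2*sigma.
    """

    d: float
    sigma: float

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("mean insert size d must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    @property
    def cluster_gap(self) -> float:
        return self.d + 2.0 * self.sigma


@dataclass
class LocalHit:
    """One local alignment of a query read against a subject database.

    ``query_span`` is always on the forward read; for a minus-strand hit,
    ``L`` is still the smallest subject coordinate of the alignment.
    ``rank`` is the number of hits of the same query whose expect value is
    <= this hit's (itself included); rank 1 means unambiguous best.
    """

    query_id: str
    qstart: int
    qend: int
    subject_id: str
    L: int
    subject_end: int
    strand: str  # '+' or '-'
    score: float
    e: float
    n_match: int = 0
    n_cols: int = 0
    rank: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.qstart < self.qend):
            raise ValueError("invalid query span")
        if not (0 <= self.L < self.subject_end):
            raise ValueError("invalid subject span")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if self.e <= 0:
            raise ValueError("expect value must be > 0")

    @property
    def query_len_aligned(self) -> int:
        return self.qend - self.qstart

    def key(self) -> tuple:
        return (self.subject_id, self.L, self.subject_end, self.strand,
                self.qstart, self.qend)


@dataclass
class SplitRead:
    """A read whose host and virus segments pinpoint the junction exactly.

    ``host_junction`` / ``virus_junction`` are 1-based coordinates of the
    host / virus base adjacent to the junction. ``source`` records whether
    the split came straight from the aligner or from targeted
    Smith-Waterman rescue of an unaligned tail.
    """

    pair_id: str
    mate: int
    host_chrom: str
    host_junction: int
    host_side: str  # 5p_host | 3p_host
    virus_id: Optional[str]
    virus_junction: Optional[int]
    virus_strand: Optional[str]
    virus_orient: Optional[str]  # virus strand in the integrated fragment
    source: str = "aligned"  # aligned | rescued


@dataclass
class HitCluster:
    """Co-localized retained host hits, optionally orientation-partitioned.

    ``orientation`` is 'plus' for a C+ cluster (host 5' of the virus in the
    integrated fragment), 'minus' for C-, or 'unpartitioned'.
    """

    chrom: str
    members: list  # list of (ReadPair, LocalHit), sorted by hit.L
    orientation: str = "unpartitioned"
    split_reads: list = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len({p.id for p, _ in self.members})

    @property
    def span(self) -> tuple[int, int]:
        return (min(h.L for _, h in self.members),
                max(h.subject_end for _, h in self.members))


@dataclass
class IntegrationCall:
    """A called host/virus junction.

    ``host_side`` says which side of the virus the reported host position
    is on: ``5p_host`` (host upstream of virus, from a C+ cluster) or
    ``3p_host``. ``exact`` is set when the position comes from a split-read
    majority or from consensus assembly; otherwise it is a cluster-edge
    estimate that can be off by up to the insert span.
    """

    host_chr: str
    host_pos: int  # 1-based
    host_side: str  # 5p_host | 3p_host
    virus_id: Optional[str]
    virus_pos: Optional[int]  # 1-based
    virus_orient: Optional[str]  # '+' | '-'
    n_pairs: int
    n_split: int
    exact: bool
    ambiguous: bool
    median_rank: int

    def sort_key(self) -> tuple:
        return (self.host_chr, self.host_pos, self.virus_id or "",
                self.virus_pos or 0, self.host_side)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated integration.

    ``host_pos_5p`` is the 1-based position of the last host base before
    the inserted segment; ``host_pos_3p`` the first host base after it.
    ``virus_start``/``virus_end`` delimit the integrated virus segment
    (1-based closed) and ``virus_orient`` its strand in the fragment.
    """

    host_chr: str
    host_pos_5p: int
    host_pos_3p: int
    virus_id: str
    virus_start: int
    virus_end: int
    virus_orient: str
    random_insert_len: int = 0
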