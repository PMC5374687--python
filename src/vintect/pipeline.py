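"""End-to-end orchestration of the integration-calling workflow.

Stages run strictly in funnel order — k-mer screen (X1), virus
confirmation (X2), host hit (X_chimera), clustering, refinement,
breakpoint calling — and every stage's input/output cardinality is
logged and returned, so |X_chimera| <= |X2| <= |X1| can be audited.
Given the same inputs and configuration the output tables are
byte-identical.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

from .align import AlignParams, ReferenceIndex
from .breakpoints import CallParams, call_integrations
from .chimera import build_X2, build_X_chimera
from .cluster import cluster_hits, partition_orientation
from .model import IntegrationCall, LibraryStats, ReadPair
from .refine import RescueParams, refine_cluster
from .screen import ScreenParams, build_index, screen_pairs
from .simulate import evaluate_calls

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Effective parameter set of one run; dumped into the run log so a
    run can be reproduced from its log alone."""

    screen: ScreenParams = field(default_factory=ScreenParams)
    align: AlignParams = field(default_factory=AlignParams)
    library: LibraryStats = field(default_factory=lambda: LibraryStats(300.0, 30.0))
    call: CallParams = field(default_factory=CallParams)
    rescue: RescueParams = field(default_factory=RescueParams)
    dedupe: bool = True
    min_softclip: int = 10

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    calls: list[IntegrationCall]
    unreliable: list[IntegrationCall]
    stage_counts: dict[str, int]
    config: PipelineConfig


def run_call(pairs: list[ReadPair], host: dict[str, str],
             viruses: dict[str, str],
             config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full pipeline on raw read pairs.

    ``pairs`` may come straight from FASTQ (all pairs are screened) or
    from SAM/BAM candidate extraction; the funnel itself is identical.
    An empty X_chimera is a success with an empty call table.
    """
    config = config or PipelineConfig()
    # Work on fresh copies so a caller can reuse the same pairs across
    # runs (e.g. downsampling experiments) without stale stage tags.
    pairs = [ReadPair(id=p.id, seq1=p.seq1, seq2=p.seq2, qual1=p.qual1,
                      qual2=p.qual2, source=p.source) for p in pairs]
    counts = {"input": len(pairs)}
    logger.info("effective config: %s", config.as_dict())
    logger.info("input pairs: %d", counts["input"])

    kindex = build_index(viruses, config.screen.k)
    X1 = screen_pairs(pairs, kindex, config.screen)
    counts["X1"] = len(X1)
    logger.info("k-mer screen: %d -> %d pairs", len(pairs), len(X1))

    virus_index = ReferenceIndex(viruses, config.align.word)
    X2 = build_X2(X1, virus_index, config.align)
    counts["X2"] = len(X2)
    logger.info("virus alignment: %d -> %d pairs", len(X1), len(X2))

    host_index = ReferenceIndex(host, config.align.word)
    Xc = build_X_chimera(X2, host_index, config.align)
    counts["X_chimera"] = len(Xc)
    logger.info("host alignment: %d -> %d pairs", len(X2), len(Xc))

    members = [(pair, hit) for pair in Xc for mate in (0, 1)
               for hit in pair.host_hits[mate]]
    counts["host_hits"] = len(members)
    if not members:
        return PipelineResult([], [], counts, config)

    clusters = cluster_hits(members, config.library)
    counts["clusters"] = len(clusters)
    oriented = []
    for c in clusters:
        for sub in partition_orientation(c):
            if sub.members:
                oriented.append(refine_cluster(
                    sub, host_index, config.library, config.align,
                    rescue=config.rescue, dedupe_enabled=config.dedupe))
    counts["oriented_clusters"] = len(oriented)
    logger.info("clusters: %d positional, %d oriented", len(clusters),
                len(oriented))

    calls, unreliable = call_integrations(
        oriented, config.call, host_index, virus_index, config.align)
    counts["calls"] = len(calls)
    counts["unreliable"] = len(unreliable)
    logger.info("calls: %d reliable, %d unreliable", len(calls),
                len(unreliable))
    return PipelineResult(calls, unreliable, counts, config)


def run_roc(calls: list[IntegrationCall], truth, window: int = 300,
            thresholds=None) -> list[dict]:
    """ROC over minimum-support thresholds.

    For each threshold t, calls with n_pairs >= t are scored against the
    truth; tp and fp are therefore non-increasing in t. Thresholds
    default to 1..max observed support.
    """
    if thresholds is None:
        max_support = max((c.n_pairs for c in calls), default=0)
        thresholds = range(1, max_support + 1)
    rows = []
    for t in thresholds:
        kept = [c for c in calls if c.n_pairs >= t]
        res = evaluate_calls(kept, truth, window)
        rows.append({"threshold": t, "n_calls": len(kept), "tp": res["tp"],
                     "fp": res["fp"], "fn": res["fn"],
                     "sensitivity": res["sensitivity"],
                     "fpr_proxy": res["fpr_proxy"]})
    return rows
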