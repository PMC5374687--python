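"""Reading and writing the standard formats the pipeline touches.

FASTA references are loaded into plain dicts; paired FASTQ (optionally
gzipped) round-trips through :class:`~vintect.model.ReadPair`; candidate
chimeric pairs are pulled out of SAM/BAM with pysam. Coordinates are
0-based internally and 1-based in every written table.
"""
from __future__ import annotations

import gzip
import logging
import re
from pathlib import Path
from typing import Iterable, Iterator

import pysam
from Bio import SeqIO

from ._seq import revcomp
from .model import IntegrationCall, LibraryStats, ReadPair

logger = logging.getLogger(__name__)

CALL_COLUMNS = ["host_chr", "host_pos", "host_side", "virus_id", "virus_pos",
                "virus_orient", "n_pairs", "n_split", "exact", "ambiguous",
                "median_rank"]

_SOFTCLIP_RE = re.compile(r"(\d+)S")


def read_fasta(path) -> dict[str, str]:
    """Load a (multi-)FASTA into an id -> uppercase sequence dict."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq_pairs(path1, path2) -> Iterator[ReadPair]:
    """Iterate mate-synchronised FASTQ files as ReadPairs."""
    with pysam.FastxFile(str(path1)) as f1, pysam.FastxFile(str(path2)) as f2:
        for r1, r2 in zip(f1, f2):
            name1 = r1.name.removesuffix("/1")
            name2 = r2.name.removesuffix("/2")
            if name1 != name2:
                raise ValueError(
                    f"FASTQ files out of sync: {r1.name} vs {r2.name}")
            yield ReadPair(id=name1, seq1=r1.sequence.upper(),
                           seq2=r2.sequence.upper(), qual1=r1.quality,
                           qual2=r2.quality, source="raw")


def write_fastq_pairs(pairs: Iterable[ReadPair], path1, path2) -> None:
    with _open_text(path1, "wt") as f1, _open_text(path2, "wt") as f2:
        for p in pairs:
            q1 = p.qual1 or "I" * len(p.seq1)
            q2 = p.qual2 or "I" * len(p.seq2)
            f1.write(f"@{p.id}/1\n{p.seq1}\n+\n{q1}\n")
            f2.write(f"@{p.id}/2\n{p.seq2}\n+\n{q2}\n")


def _max_softclip(cigarstring: str | None) -> int:
    if not cigarstring:
        return 0
    runs = _SOFTCLIP_RE.findall(cigarstring)
    return max((int(r) for r in runs), default=0)


def _original_orientation(rec: pysam.AlignedSegment) -> tuple[str, str | None]:
    """Sequence and quality restored to forward-read orientation."""
    seq = rec.query_sequence.upper()
    qual = (None if rec.query_qualities is None
            else pysam.qualities_to_qualitystring(rec.query_qualities))
    if rec.is_reverse:
        seq = revcomp(seq)
        qual = qual[::-1] if qual else None
    return seq, qual


def extract_candidate_pairs(alignment_stream, min_softclip: int = 10
                            ) -> list[ReadPair]:
    """Pull potentially chimeric pairs out of a host alignment.

    A pair is a candidate when at least one mate is unmapped or carries a
    soft-clip run of >= ``min_softclip`` bases. Only primary alignments
    are considered; mate-less records are skipped with a warning. Output
    is sorted by read id, so it is invariant to record order.
    """
    if min_softclip < 1:
        raise ValueError("min_softclip must be >= 1")
    if isinstance(alignment_stream, (str, Path)):
        alignment_stream = pysam.AlignmentFile(str(alignment_stream),
                                               check_sq=False)
    mates: dict[str, dict[int, pysam.AlignedSegment]] = {}
    for rec in alignment_stream:
        if rec.is_secondary or rec.is_supplementary:
            continue
        if rec.query_sequence is None:
            continue
        mates.setdefault(rec.query_name, {})[1 if rec.is_read2 else 0] = rec

    out = []
    for name in sorted(mates):
        pair = mates[name]
        if len(pair) != 2:
            logger.warning("read %s has no mate in the stream; skipped", name)
            continue
        r1, r2 = pair[0], pair[1]
        interesting = (
            r1.is_unmapped or r2.is_unmapped
            or _max_softclip(r1.cigarstring) >= min_softclip
            or _max_softclip(r2.cigarstring) >= min_softclip)
        if not interesting:
            continue
        seq1, qual1 = _original_orientation(r1)
        seq2, qual2 = _original_orientation(r2)
        out.append(ReadPair(id=name, seq1=seq1, seq2=seq2, qual1=qual1,
                            qual2=qual2, source="sam_extracted"))
    return out


def estimate_library_stats(alignment_stream, max_pairs: int = 100_000
                           ) -> LibraryStats:
    """Estimate insert-size mean/SD from concordant proper pairs.

    Uses |TLEN| of read-1 records of proper pairs, up to ``max_pairs``.
    Needs at least 100 such pairs; otherwise the caller must supply d and
    sigma in the configuration.
    """
    if isinstance(alignment_stream, (str, Path)):
        alignment_stream = pysam.AlignmentFile(str(alignment_stream),
                                               check_sq=False)
    tlens = []
    for rec in alignment_stream:
        if (rec.is_proper_pair and not rec.is_secondary
                and not rec.is_supplementary and rec.template_length > 0):
            tlens.append(rec.template_length)
            if len(tlens) >= max_pairs:
                break
    if len(tlens) < 100:
        raise ValueError(
            f"only {len(tlens)} proper pairs found (need >= 100); "
            "supply insert mean d and sigma in the config instead")
    import numpy as np
    arr = np.asarray(tlens, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return LibraryStats(d=float(arr.mean()), sigma=sd)


def write_calls(calls: list[IntegrationCall], path) -> None:
    """Write calls as a deterministic 1-based tab-delimited table."""
    rows = sorted(calls, key=lambda c: c.sort_key())
    with open(path, "w") as fh:
        fh.write("\t".join(CALL_COLUMNS) + "\n")
        for c in rows:
            fh.write("\t".join([
                c.host_chr, str(c.host_pos), c.host_side,
                c.virus_id or ".",
                str(c.virus_pos) if c.virus_pos is not None else ".",
                c.virus_orient or ".",
                str(c.n_pairs), str(c.n_split),
                "1" if c.exact else "0",
                "1" if c.ambiguous else "0",
                str(c.median_rank),
            ]) + "\n")


def read_calls(path) -> list[IntegrationCall]:
    """Read a call table written by :func:`write_calls`."""
    calls = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != CALL_COLUMNS:
            raise ValueError(f"unexpected call-table header in {path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            calls.append(IntegrationCall(
                host_chr=f[0], host_pos=int(f[1]), host_side=f[2],
                virus_id=None if f[3] == "." else f[3],
                virus_pos=None if f[4] == "." else int(f[4]),
                virus_orient=None if f[5] == "." else f[5],
                n_pairs=int(f[6]), n_split=int(f[7]),
                exact=f[8] == "1", ambiguous=f[9] == "1",
                median_rank=int(f[10])))
    return calls
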