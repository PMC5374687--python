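"""Synthetic infected-genome and read simulator, plus call evaluation.

The generator emulates the classical virus-integration benchmark design:
random host chromosomes are infected by a handful of virus strains (one
strain per chromosome, round-robin), every integrated region is extracted
together with 500 bp host flanks, and paired-end reads are drawn from the
extracted regions at 20X coverage with a Gaussian insert-size model and
uniform substitution errors. Host and virus sequences are i.i.d. uniform
ACGT, so repeat-driven ambiguity of real genomes is absent: measured
sensitivity is an upper bound and the false-positive fraction a lower
bound relative to real references.

Evaluation follows the standard correctness criterion: a call is correct
if it lies within 300 bases of a simulated junction and has the correct
orientation; matching is greedy one-to-one.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._seq import revcomp
from .model import IntegrationCall, ReadPair, TruthRecord

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimParams:
    """Study conditions of the simulation; the defaults are the benchmark
    conditions (500 bp flanks, 20X coverage, d=300, sigma=30)."""

    host_len: int = 60_000       # per chromosome
    n_chroms: int = 4
    n_viruses: int = 4
    virus_len: int = 3_200       # HBV-sized strains
    n_integrations: int = 20
    flank: int = 500
    coverage: float = 20.0
    read_len: int = 100
    d: float = 300.0
    sigma: float = 30.0
    subst_error_rate: float = 0.001
    seed: int = 0
    # integrated segment length range and optional random junction insert
    seg_min: int = 400
    seg_max: int = 1_500
    random_insert_max: int = 0

    def __post_init__(self) -> None:
        if self.flank <= 0 or self.coverage <= 0:
            raise ValueError("flank and coverage must be > 0")
        if self.read_len >= self.d:
            raise ValueError("read_len must be < mean insert size d")


@dataclass
class InfectedGenome:
    """Output of :func:`simulate_infected_regions`."""

    host: dict[str, str]
    viruses: dict[str, str]
    regions: dict[str, str]
    truth: list[TruthRecord] = field(default_factory=list)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


# Context length and gap allowance used when checking that a local
# alignment cannot profitably extend across a simulated junction.
_EXT_CONTEXT = 40
_EXT_MAX_GAP = 12


def _extension_score(a: str, b: str) -> int:
    """Best prefix score of extending an alignment with read continuation
    ``a`` against reference continuation ``b`` (default blastn-like
    scoring, allowing one leading gap). Positive means an aligner would
    walk past the junction."""
    best = 0
    for g in range(_EXT_MAX_GAP + 1):
        variants = ((a, b),) if g == 0 else ((a[g:], b), (a, b[g:]))
        for x, y in variants:
            cum = 0 if g == 0 else -(5 + 2 * g)
            for ca, cb in zip(x, y):
                cum += 2 if (ca == cb and ca != "N") else -3
                if cum > best:
                    best = cum
    return best


def _junction_is_clean(region: str, host: str, p: int, flank: int,
                       ins_len: int, seg_len: int, vp: str, vs_p: int
                       ) -> bool:
    """True when no alignment can extend across either junction.

    Simulated junctions are constructed without microhomology: if the
    flanking reference happened to continue the other genome's sequence,
    the true breakpoint would be inherently ambiguous and 'exact' calls
    ill-defined.
    """
    L = _EXT_CONTEXT
    ve_p = vs_p + seg_len
    checks = (
        # host alignment extending 3'-ward across the 5p junction
        (region[flank:flank + L], host[p:p + L]),
        # virus alignment extending 5'-ward across the 5p junction
        (region[:flank + ins_len][-L:][::-1], vp[:vs_p][-L:][::-1]),
        # host alignment extending 5'-ward across the 3p junction
        (region[:flank + ins_len + seg_len][-L:][::-1],
         host[max(0, p - L):p][::-1]),
        # virus alignment extending 3'-ward across the 3p junction
        (region[flank + ins_len + seg_len:][:L], vp[ve_p:ve_p + L]),
    )
    return all(_extension_score(a, b) == 0 for a, b in checks)


def simulate_infected_regions(params: SimParams) -> InfectedGenome:
    """Plant non-overlapping integrations and extract flanked regions.

    Integrations are distributed round-robin over chromosomes, each
    chromosome carrying one virus strain. Every region is exactly
    flank + [insert] + segment + flank long; truth coordinates refer to
    the clean host reference, which is what reads are later called
    against.
    """
    rng = np.random.default_rng(params.seed)
    host = {f"chr{i + 1}": _random_seq(rng, params.host_len)
            for i in range(params.n_chroms)}
    viruses = {f"virus{i + 1}": _random_seq(rng, params.virus_len)
               for i in range(params.n_viruses)}
    virus_ids = list(viruses)
    chrom_ids = list(host)

    per_chrom = [params.n_integrations // params.n_chroms
                 + (1 if i < params.n_integrations % params.n_chroms else 0)
                 for i in range(params.n_chroms)]
    genome = InfectedGenome(host=host, viruses=viruses, regions={})
    region_no = 0
    for ci, k in enumerate(per_chrom):
        if k == 0:
            continue
        chrom = chrom_ids[ci]
        slot = params.host_len // k
        if slot < 2 * params.flank + 100:
            raise ValueError(
                f"host chromosome of {params.host_len} bp too small for "
                f"{k} integrations with {params.flank} bp flanks")
        virus_id = virus_ids[ci % params.n_viruses]
        vseq = viruses[virus_id]
        for j in range(k):
            lo = j * slot + params.flank
            hi = (j + 1) * slot - params.flank
            for _attempt in range(500):
                p = int(rng.integers(lo, hi))  # 0-based insertion point
                seg_len = int(rng.integers(params.seg_min,
                                           min(params.seg_max,
                                               params.virus_len) + 1))
                vs = int(rng.integers(0, params.virus_len - seg_len + 1))
                ve = vs + seg_len
                orient = "+" if rng.random() < 0.5 else "-"
                vp = vseq if orient == "+" else revcomp(vseq)
                vs_p = vs if orient == "+" else params.virus_len - ve
                segment = vp[vs_p:vs_p + seg_len]
                ins_len = (int(rng.integers(0, params.random_insert_max + 1))
                           if params.random_insert_max > 0 else 0)
                insert = _random_seq(rng, ins_len) if ins_len else ""
                region = (host[chrom][p - params.flank:p] + insert + segment
                          + host[chrom][p:p + params.flank])
                if _junction_is_clean(region, host[chrom], p, params.flank,
                                      ins_len, seg_len, vp, vs_p):
                    break
            else:
                raise RuntimeError("could not place a homology-free junction")
            name = f"region_{region_no:04d}"
            genome.regions[name] = region
            genome.truth.append(TruthRecord(
                host_chr=chrom, host_pos_5p=p, host_pos_3p=p + 1,
                virus_id=virus_id, virus_start=vs + 1, virus_end=ve,
                virus_orient=orient, random_insert_len=ins_len))
            region_no += 1
    return genome


def simulate_reads(regions: dict[str, str], params: SimParams,
                   seed: Optional[int] = None
                   ) -> tuple[list[ReadPair], dict]:
    """Draw paired-end reads from the extracted regions.

    Per region of length G, round(coverage*G/(2*read_len)) fragments are
    drawn with insert ~ Normal(d, sigma) truncated to [read_len, G] and a
    uniform start; mates are forward-reverse, the originating strand of
    the fragment is random, and substitution errors hit each base
    independently at ``subst_error_rate``. Fully deterministic for a
    fixed seed. Returns (pairs, info) where info records the number of
    pairs and the largest insert actually drawn.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    rl = params.read_len
    pairs: list[ReadPair] = []
    max_insert = 0
    insert_sum = 0
    for name, region in regions.items():
        G = len(region)
        if G < rl:
            import logging
            logging.getLogger(__name__).warning(
                "region %s shorter than read length; skipped", name)
            continue
        n_frag = int(round(params.coverage * G / (2.0 * rl)))
        for i in range(n_frag):
            insert = int(round(rng.normal(params.d, params.sigma)))
            insert = max(rl, min(G, insert))
            max_insert = max(max_insert, insert)
            insert_sum += insert
            start = int(rng.integers(0, G - insert + 1))
            frag = region[start:start + insert]
            left = frag[:rl]
            right = revcomp(frag[-rl:])
            if rng.random() < 0.5:
                seq1, seq2 = left, right
            else:  # fragment sequenced from the other strand
                seq1, seq2 = right, left
            seq1 = _add_errors(seq1, params.subst_error_rate, rng)
            seq2 = _add_errors(seq2, params.subst_error_rate, rng)
            pairs.append(ReadPair(id=f"{name}:{i:05d}", seq1=seq1,
                                  seq2=seq2))
    return pairs, {"n_pairs": len(pairs), "max_insert": max_insert,
                   "mean_insert": (insert_sum / len(pairs) if pairs
                                   else 0.0)}


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if hits.size == 0:
        return seq
    chars = list(seq)
    for i in hits:
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars)


def downsample(pairs: list[ReadPair], fraction: float,
               seed: int) -> list[ReadPair]:
    """Keep each pair independently with probability ``fraction``."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return list(pairs)
    rng = np.random.default_rng(seed)
    keep = rng.random(len(pairs)) < fraction
    return [p for p, k in zip(pairs, keep) if k]


@dataclass(frozen=True)
class TruthJunction:
    """One callable side of a simulated integration."""

    host_chr: str
    host_pos: int
    host_side: str
    virus_id: str
    virus_pos: int
    virus_orient: str


def truth_junctions(truth: list[TruthRecord]) -> list[TruthJunction]:
    """Expand each integration into its 5p_host and 3p_host junctions."""
    out = []
    for t in truth:
        v5 = t.virus_start if t.virus_orient == "+" else t.virus_end
        v3 = t.virus_end if t.virus_orient == "+" else t.virus_start
        out.append(TruthJunction(t.host_chr, t.host_pos_5p, "5p_host",
                                 t.virus_id, v5, t.virus_orient))
        out.append(TruthJunction(t.host_chr, t.host_pos_3p, "3p_host",
                                 t.virus_id, v3, t.virus_orient))
    return out


def evaluate_calls(calls: list[IntegrationCall], truth: list[TruthRecord],
                   window: int = 300) -> dict:
    """Score calls against simulated truth.

    Greedy one-to-one matching: each call (deterministic order) claims
    the nearest unmatched truth junction on the same chromosome and side
    with the same virus orientation within ``window`` bases. A call with
    no claimable junction — including one at the right position with a
    flipped or unreported orientation — is a false positive.
    """
    junctions = truth_junctions(truth)
    unmatched = set(range(len(junctions)))
    tp = 0
    fp = 0
    deviations = []
    for call in sorted(calls, key=lambda c: c.sort_key()):
        best_j, best_dev = None, None
        for j in unmatched:
            tj = junctions[j]
            if (tj.host_chr != call.host_chr
                    or tj.host_side != call.host_side
                    or call.virus_orient != tj.virus_orient):
                continue
            dev = abs(call.host_pos - tj.host_pos)
            if dev <= window and (best_dev is None or dev < best_dev):
                best_j, best_dev = j, dev
        if best_j is None:
            fp += 1
        else:
            tp += 1
            unmatched.discard(best_j)
            deviations.append(best_dev)
    fn = len(unmatched)
    n_truth = len(junctions)
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "sensitivity": tp / n_truth if n_truth else 0.0,
        "fpr_proxy": fp / (tp + fp) if (tp + fp) else 0.0,
        "breakpoint_deviations": deviations,
    }


TRUTH_COLUMNS = ["host_chr", "host_pos_5p", "host_pos_3p", "virus_id",
                 "virus_start", "virus_end", "virus_orient",
                 "random_insert_len"]


def write_truth(truth: list[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truth:
            fh.write("\t".join(str(getattr(t, c)) for c in TRUTH_COLUMNS)
                     + "\n")


def read_truth(path) -> list[TruthRecord]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TRUTH_COLUMNS:
            raise ValueError(f"unexpected truth-table header in {path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(TruthRecord(
                host_chr=f[0], host_pos_5p=int(f[1]), host_pos_3p=int(f[2]),
                virus_id=f[3], virus_start=int(f[4]), virus_end=int(f[5]),
                virus_orient=f[6], random_insert_len=int(f[7])))
    return out
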