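# Methods

This note documents the model behind `vintect`, the choices made where
the design was genuinely open, and what the bundled simulator does and
does not establish about real data.

## Pipeline model and assumptions

The caller assumes Illumina-style forward–reverse paired-end reads with
an approximately Gaussian insert-size distribution (mean d, SD σ), and a
host reference plus a database of virus strains. It makes no assumption
about which strain integrated or how many distinct strains are present.
Every single-ended read is assumed to contain at most one host and at
most one virus segment; reads violating this (e.g. host sequence between
two viral segments) are treated as noise and discarded during
refinement.

Stages and their contracts:

- **k-mer screen.** Pair kept iff some sampled k-mer of either mate
  matches the virus database within Hamming distance r on either
  strand. Sampled start positions are 0, s, 2s, … plus the final full
  k-mer, so read tails are not blind spots. The implementation
  (sorted 2-bit k-mer codes + XOR mismatch-neighborhood enumeration) is
  exact for r ≤ 2: it agrees with a brute-force Hamming scan by
  construction and by property test. An N in a read mismatches
  everything: it consumes one unit of the budget and the database base
  under it is unconstrained.
- **Local alignment.** Seed-and-extend: exact `word`-length seeds
  (default 11) are grouped by diagonal (band 15) and extended with a
  full affine-gap Smith–Waterman (numba kernel) over a subject window
  padded by 64 bp (whole subject when ≤ 600 bp, which makes small
  instances exactly optimal — verified against an independent dynamic
  programming oracle). Gap of length g scores `gap_open + g·gap_extend`
  = −5 − 2g. Expect values use ungapped Karlin–Altschul constants
  (K = 0.41, λ = 0.625) applied to gapped scores with n = total database
  length; this is an approximation, acceptable because only the relative
  ordering of hits and a permissive cutoff (1e−3) feed the logic
  downstream. Seed words occurring > 200 times in the reference are
  treated as repetitive and not extended.
- **Clustering and orientation.** Chain linkage with gap threshold
  d + 2σ per chromosome. Prefix/suffix classification uses the
  forward-read span with 3 bp of end tolerance; whole-read alignments
  follow their strand; internal alignments are counted as noise and
  belong to neither sub-cluster.
- **Split reads.** A native split is one host plus one virus segment on
  one mate, adjacent within 10 bp (the unexplained middle may be a
  short random insert). Rescue applies when a viral alignment leaves
  ≥ 10 contiguous terminal bases unaligned and the mate is a clean
  host anchor: the tail is Smith–Waterman-aligned (both orientations)
  against the d + 2σ host window on the junction-facing side of the
  anchor — downstream of the anchor start for a + anchor, upstream of
  its end for a − anchor, since the fragment extends from the anchor
  toward the junction. Acceptance needs ≥ 10 aligned columns at ≥ 90%
  identity. The same 90% identity floor applies to the host segment of
  a native split: a noisy local alignment dragged across a random
  insert would misplace the breakpoint.
- **Calling.** C⁺ estimate max{L + aligned length}, C⁻ estimate min{L};
  "aligned length" (not raw read length) so soft-clipped viral tails
  cannot push the estimate past the junction. The virus side needs an
  ε-majority (ε = 2) between strand sub-clusters; the winning strand
  with the host side determines orientation and which extremum of the
  winning hits faces the junction (the four-case table in
  `breakpoints.py`). Split reads are grouped by the junction position
  they imply (± 5 bp): the call is exact when the largest group
  outnumbers the runner-up by ≥ ε, and the reported position is the
  lower median of that group. Grouping by position rather than by
  strand is deliberate: a true junction legitimately produces split
  reads of both virus-strand polarities (left-end and right-end mates
  of the fragment), so a strand vote would almost never reach a
  majority, whereas conflicting *positions* are exactly the noise the
  vote should demote.

## Tunable parameters

| parameter | default | units | why |
|---|---|---|---|
| screen.k / r / s | 18 / 1 / 5 | bases / mismatches / bases | shortest viral segment worth detecting; sensitivity over speed |
| align.match/mismatch | +2 / −3 | score | blastn-like regime |
| align.gap_open/extend | −5 / −2 | score | blastn-like regime |
| align.word | 11 | bases | blastn default seed |
| align.min_len | 25 | bases | local-aligner sensitivity floor |
| align.max_e | 1e−3 | — | permissive; ranking does the real filtering |
| library d / σ | 300 / 30 | bases | typical short-insert WGS library; estimated from BAM when available |
| call.epsilon | 2 | reads | strand/split majority margin |
| call.min_support | 4 (CLI), 1 (library/ROC) | pairs | real-data reporting threshold vs. ROC sweeping |
| refine.min_unaligned | 10 | bases | minimum tail worth rescuing |
| refine.sw_min_identity / span | 0.9 / 10 | — / columns | rescue acceptance |
| consensus overlap / identity | 30 bp / 0.75 | | overlap-layout merge thresholds |
| eval window | 300 | bases | correctness criterion for benchmarks |

## The simulator

`simulate_infected_regions` plants non-overlapping integrations in
uniform-random host chromosomes (one virus strain per chromosome,
round-robin; four 3.2 kb strains by default, hepatitis-B-sized),
extracts each integrated segment with exactly 500 bp host flanks, and
records truth in clean-host coordinates — the same coordinate system the
caller reports in. Integrated segment lengths are uniform in
400–1500 bp, a realistic range for sub-genomic viral integrations; an
optional short random insert can be placed at the 5′ junction.
`simulate_reads` draws `round(coverage·G/(2·read_len))` fragments per
region with insert ~ Normal(d, σ) truncated to [read_len, G], a uniform
start, a random originating strand, and independent per-base
substitution errors. Everything is driven by one seed; identical seeds
give byte-identical FASTA/FASTQ.

**Homology-free junctions.** Junction positions and virus segments are
resampled until no local alignment can profitably extend across either
junction (checked with the default scoring, 40 bp of context and up to
12 bp of leading gap). Without this, chance microhomology between the
two references makes the true breakpoint genuinely ill-defined — both
the caller and any other aligner-based tool would place it a few bases
off, and "exact" would be unfalsifiable. The check covers substitution
and single-gap extensions; pathological multi-gap homologies are
possible in principle but were not observed at the benchmark scale.

**What the simulator does not emulate.** Uniform-random sequence has no
repeats, so rank > 1 clusters and repeat-driven false positives are
under-represented: measured sensitivity is an upper bound and the
false-positive fraction a lower bound for real, repeat-rich genomes.
The error model is substitution-only (indel-bearing reads are exercised
by targeted fixtures instead); there are no quality-score profiles, no
PCR duplicates, and no structural variation beyond the integrations.
Passing benchmarks therefore establishes the pipeline's logic and
coordinate arithmetic, not its real-genome specificity.

## Benchmark problem sizes

The benchmark replica uses 100 integrations across four 60 kb host
chromosomes (240 kb host, 12.8 kb virus database), 20X coverage of the
extracted regions (~19k read pairs), insert 300 ± 30, error 0.001 —
large enough that every stage, including rescue and consensus, is
exercised, and small enough to run in minutes on one CPU. Downsampling
robustness is measured on 50% and 25% Bernoulli subsamples of the same
pairs, with the support cutoff re-chosen per subsample as the smallest
keeping the false-positive fraction under 1%. The exactness check (every
exact call at deviation 0) runs on an error-free 12-integration replica,
where split-read medians have no excuse.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open internally, 1-based closed in all
  outputs; a C⁻ first-host-base junction is therefore L+1.
- Medians are lower medians throughout (ranks, split junctions) —
  conservative for the rank-1 filter and always an observed value.
- Hit ordering is ascending e, then descending score, then
  (subject, position): byte-deterministic outputs for identical inputs.
- Equal-scoring hits get exactly equal expect values (same closed-form),
  so rank ties are exact, not float-fragile; e underflow is clamped to
  the smallest positive double.
- Seed-ladder duplicate hits are masked only when they overlap on both
  the query (> 50% of the shorter span) and the subject: masking on
  query overlap alone would collapse genuinely distinct equal-best
  placements on one chromosome and break the rank/ambiguity logic.
- Consensus column ties resolve to the first-encountered base; contigs
  are attempted in decreasing length order.
- Empty inputs are contracts, not crashes: an empty X_chimera yields an
  empty call table; an empty cluster is an error at the operation level.
- `run_call` copies its input pairs, so one read set can be re-used
  across runs (downsampling sweeps) without stale stage tags.

## Known limitations

- Specificity on repeat-rich genomes is not established by the bundled
  benchmarks (see above); the unreliable table is the designed outlet
  for repeat-region clusters, not a solved problem.
- The Karlin–Altschul constants are not re-estimated for the configured
  scoring matrix; expect values are ordering devices, not p-values.
- Rescue searches only the d + 2σ window implied by the anchor, so
  fragments drawn from the far insert tail (~2% at the default σ) can
  miss rescue; their paired-end support is unaffected.
- Single-threaded by design; determinism is trivial and desk-scale
  inputs run in minutes. CRAM input, BAM writing and duplicate-marking
  of inputs are out of scope.
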