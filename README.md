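# vintect

Detection of virus integration sites in a host genome from paired-end
next-generation sequencing data.

## The problem

When a virus such as hepatitis B integrates into the host genome, the
junction leaves a molecular signature in whole-genome sequencing data:
*chimeric* read pairs in which one part maps to the host and another to
the virus, and *split reads* whose prefix and suffix map to different
genomes. Reads covering an integration are scarce (most of a library is
pure host), viral genomes mutate quickly, and integrations often land in
repeats — so a caller must be both sensitive to short viral segments and
explicit about mapping ambiguity. `vintect` is for researchers studying
virus-associated disease genomes who need junction calls at base-pair
resolution together with an honest reliability label, plus a simulator
for benchmarking such callers.

## The method

The pipeline narrows the read set through a three-stage funnel and then
turns read clusters into junction calls:

1. **Screen (X₁).** A pair survives if any sampled k-mer of either mate
   (k=18, sampled every s=5 bases plus the final k-mer) matches the
   virus database within r=1 mismatch, on either strand. The index is an
   exact all-occurrence k-mer table with mismatch-neighborhood lookup.
2. **Virus confirmation (X₂).** Mates are aligned to the virus database
   with a seed-and-extend local aligner (word 11, affine-gap
   Smith–Waterman extension). Alignments score
   `e = K·m·n·exp(−λ·score)` (Karlin–Altschul); pairs with no alignment
   of ≥ 25 bp under the e-cutoff are discarded.
3. **Host hit (X_chimera).** Surviving pairs are aligned to the host
   genome. Per read, a hit is *rank-N* if N hits have expect value ≤ its
   own; all tied-best hits are retained, plus the second tier when the
   best is unique.
4. **Clustering.** Retained host hits on one chromosome are chained into
   a cluster while consecutive positions are closer than d + 2σ (insert
   mean and SD). Each cluster is partitioned by junction orientation:
   C⁺ (host 5′ of the virus — read prefix on the + strand or suffix on
   the − strand) versus C⁻.
5. **Refinement.** Reads with more than one host or virus segment per
   mate are discarded, as are host–host pairs that are not
   forward–reverse on one chromosome; identically aligned duplicates are
   optionally collapsed. Reads with a viral alignment and ≥ 10 unaligned
   terminal bases are rescued as split reads by Smith–Waterman against
   the d + 2σ host window flanking their mate.
6. **Calling.** The host breakpoint of a C⁺ cluster is estimated as
   max{L + aligned length} (min{L} for C⁻); split reads override the
   estimate with their median junction, flagged *exact* when the largest
   agreeing split group outnumbers the runner-up by ε = 2. The virus
   side is an ε-majority vote between the V⁺/V⁻ strand sub-clusters.
   Clusters whose median hit rank exceeds 1 (repeat regions) go to a
   separate *unreliable* table; rank-1 clusters without split reads fall
   back on overlap-layout consensus assembly (≥ 30 bp overlap, > 75%
   identity, majority vote), with multiple equal-best host placements
   marked *ambiguous*.

A bundled simulator plants integrations with 500 bp host flanks, draws
Gaussian-insert paired-end reads at 20X from the extracted regions, and
scores calls against truth with the standard criterion: correct within
300 bp and with matching orientation.

## Worked example

`python examples/01_simulate_and_call.py` simulates eight integrations
and calls them back:

```
simulated 8 integrations, 1619 read pairs
stage funnel: {'input': 1619, 'X1': 1223, 'X2': 1211, 'X_chimera': 500}

first five calls (host junction | virus junction | support):
  chr1:3457 5p_host  virus1:1016 (+)  pairs=28 splits=14  [exact]
  chr1:3458 3p_host  virus1:2367 (+)  pairs=31 splits=12  [exact]
  chr1:16786 5p_host  virus3:2062 (-)  pairs=2 splits=0  [exact]
  chr1:29083 5p_host  virus1:689 (+)  pairs=32 splits=16  [exact]
  chr1:29084 3p_host  virus1:1451 (+)  pairs=26 splits=6  [exact]

sensitivity 100.00% (16/16 junctions), 1 false positives
max breakpoint deviation: 0 bp
```

Each simulated integration yields two junctions (host on its 5′ and 3′
side) and both are recovered exactly here. The call at `chr1:16786`
with only 2 supporting pairs is a false positive — a chance local
alignment of viral sequence to the host — and illustrates why calls are
thresholded by supporting read count: the other 16 calls all carry
≥ 26 pairs. `examples/02_screen_and_align.py` shows the two alignment
engines on a single chimeric read, and `examples/03_downsampling_roc.py`
the support-threshold ROC under 50%/25% downsampling.

The same pipeline runs from the shell:

```bash
vintect sim  --out simdir --seed 5 --n-integrations 20
vintect call --reads simdir/reads_1.fastq.gz simdir/reads_2.fastq.gz \
             --host simdir/host.fa --virus simdir/virus.fa \
             --out run --min-support 1
vintect eval --calls run.calls.tsv --truth simdir/truth.tsv
vintect roc  --calls run.calls.tsv --truth simdir/truth.tsv
```

`vintect call` also accepts `--bam` input, in which case only pairs with
an unmapped mate or a ≥ 10 bp soft-clip are screened.

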