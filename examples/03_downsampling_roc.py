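"""Support-threshold ROC and robustness to downsampling.

Calls integrations on a 20X simulation and on 50% / 25% random
subsamples of the same reads, then reports true/false positives per
minimum-support cutoff and the loss of correct calls at reduced depth.
"""
from vintect import (CallParams, PipelineConfig, SimParams, downsample,
                     run_call, run_roc, simulate_infected_regions,
                     simulate_reads)

params = SimParams(n_integrations=10, host_len=40_000, coverage=20.0,
                   subst_error_rate=0.001, seed=3)
genome = simulate_infected_regions(params)
pairs, _ = simulate_reads(genome.regions, params)
config = PipelineConfig(call=CallParams(min_support=1))


def tp_at_cutoff(calls):
    """tp at the smallest cutoff keeping the FP fraction under 1%."""
    for row in run_roc(calls, genome.truth, 300):
        if row["tp"] > 0 and row["fpr_proxy"] < 0.01:
            return row["tp"]
    return 0


full = run_call(pairs, genome.host, genome.viruses, config)
print("threshold  tp  fp")
for row in run_roc(full.calls, genome.truth, 300)[:8]:
    print(f"{row['threshold']:>9}  {row['tp']:>2}  {row['fp']:>2}")

tp_full = tp_at_cutoff(full.calls)
for frac in (0.5, 0.25):
    sub = downsample(pairs, frac, seed=100 + int(frac * 100))
    res = run_call(sub, genome.host, genome.viruses, config)
    tp = tp_at_cutoff(res.calls)
    loss = 100.0 * (tp_full - tp) / tp_full
    print(f"{int(frac * 100)}% of reads: {tp}/{tp_full} correct calls "
          f"kept ({loss:.0f}% lost)")
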