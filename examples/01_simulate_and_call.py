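"""Simulate an infected genome, call integrations, score against truth.

Plants eight viral integrations in four random host chromosomes, draws
error-free 20X paired-end reads from the flanked regions, runs the full
calling pipeline and compares the calls with the simulated junctions.
"""
from vintect import (CallParams, PipelineConfig, SimParams, evaluate_calls,
                     run_call, simulate_infected_regions, simulate_reads)

params = SimParams(n_integrations=8, host_len=30_000, coverage=20.0,
                   subst_error_rate=0.0, seed=42)
genome = simulate_infected_regions(params)
pairs, info = simulate_reads(genome.regions, params)
print(f"simulated {len(genome.truth)} integrations, "
      f"{info['n_pairs']} read pairs")

result = run_call(pairs, genome.host, genome.viruses,
                  PipelineConfig(call=CallParams(min_support=1)))
print("stage funnel:", {k: result.stage_counts[k]
                        for k in ("input", "X1", "X2", "X_chimera")})

print("\nfirst five calls (host junction | virus junction | support):")
for c in result.calls[:5]:
    exact = "exact" if c.exact else "estimate"
    print(f"  {c.host_chr}:{c.host_pos} {c.host_side}  "
          f"{c.virus_id}:{c.virus_pos} ({c.virus_orient})  "
          f"pairs={c.n_pairs} splits={c.n_split}  [{exact}]")

# Each integration has two callable junctions (host on its 5' and 3'
# side); a call is correct within 300 bp with matching orientation.
metrics = evaluate_calls(result.calls, genome.truth, window=300)
print(f"\nsensitivity {metrics['sensitivity']:.2%} "
      f"({metrics['tp']}/{metrics['tp'] + metrics['fn']} junctions), "
      f"{metrics['fp']} false positives")
print("max breakpoint deviation:",
      max(metrics["breakpoint_deviations"], default=0), "bp")
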