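"""Score disease specificity S, pick the top 1% per disease, check ground truth.

S = |beta/se| x z_het is large only when a variant is strongly associated
with one disease AND its effects differ between the diseases.  Each variant
is assigned to the disease with the larger S; the top 1% of the pruned
universe per disease plus their r2 > 0.8 proxies form the disease-specific
SNP sets.
"""

import gwaspec as g
from gwaspec.experiments import run_specificity_chain, specificity_recovery

config = g.SimulationConfig()   # 20,000 SNPs, realistic cohort asymmetry
_, truth, pruned, ranked, sets = run_specificity_chain(config, seed=1)

top_a = ranked[(ranked["assigned"] == "A") & ranked["top1pct"]]
top_b = ranked[(ranked["assigned"] == "B") & ranked["top1pct"]]
print(f"pruned universe: {len(pruned)} variants; "
      f"top-1% quota: {len(top_a)} (A), {len(top_b)} (B)")

best = top_a.sort_values("rank").iloc[0]
print(f"most A-specific variant: {best['variant_id']} "
      f"(S_A = {best['s_a']:.1f}, S_B = {best['s_b']:.1f}, "
      f"z_het = {best['z_het']:.1f})")

rec = specificity_recovery(seed=1, config=config)
print(f"\nground-truth recovery of the SNP sets (indices + proxies):")
print(f"  disease A set captures {100 * rec['recall_a']:.0f}% of A-specific "
      f"causals, {100 * rec['cross_a']:.0f}% of B-specific ones")
print(f"  disease B set captures {100 * rec['recall_b']:.0f}% of B-specific "
      f"causals, {100 * rec['cross_b']:.0f}% of A-specific ones")
print("High recall with near-zero cross-capture is what makes the top-1%")
print("lists usable for downstream cell-type enrichment.")
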