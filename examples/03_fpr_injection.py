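"""PCR duplicates inflate the false positive rate of sample comparisons.

One synthetic sample's deduplicated reads are split into two pseudo-samples
(a frequency null: no real differences exist); duplicates are then injected
at increasing rates and every heterozygous SNP is Fisher-tested between the
halves at alpha = 0.05.
"""

from smtdedup import SimulationConfig, fpr_experiment

cfg = SimulationConfig(seed=99, n_targets=100, mean_depth=1000, het_fraction=1.0)
table = fpr_experiment(cfg, rates=[0.0, 0.25, 0.5, 0.75], n_replicates=5, seed=99)

print("duplicate rate -> mean FPR over 5 replicates "
      f"({table['n_sites'].iloc[0]} het SNPs each):")
for rate, fpr in table.groupby("rate")["fpr"].mean().items():
    flag = "  (controlled at alpha)" if rate == 0 else ""
    print(f"  {rate:4.2f} -> {100 * fpr:5.2f}%{flag}")
print("With duplicates removed the FPR sits at ~5%; injected duplicates "
      "shrink the effective sample size and push it far above alpha.")
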