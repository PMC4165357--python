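"""End-to-end duplicate marking on a small synthetic amplicon sample.

Generates 15 targets at ~300X with a configured 20% PCR duplicate rate,
pushes the reads through primer-prefix assignment, primer trimming and
per-target SMT dedup, and compares the measured duplicate rate with truth.
"""

from smtdedup import (
    SimulationConfig,
    TargetMatcher,
    cluster_size_histogram,
    duplicate_rate_report,
    generate_design,
    generate_sample,
    mark_duplicates,
    trim_primers,
)

cfg = SimulationConfig(
    seed=20140807, n_targets=15, mean_depth=300, duplicate_rate=0.20,
    het_fraction=0.5, error_rate=0.005,
)
designs = generate_design(cfg)
pairs, truth = generate_sample(designs, cfg)
print(f"simulated {len(pairs)} read pairs over {len(designs)} targets "
      f"(truth duplicate rate {truth['is_duplicate'].mean():.3f})")

matcher = TargetMatcher(designs)
design_by_id = {d.target_id: d for d in designs}
assigned = []
for pair in pairs:
    a = matcher.assign(pair)
    if a.status == "ASSIGNED" and trim_primers(pair, design_by_id[a.target_id]):
        assigned.append((pair.read_id, a.target_id, pair.smt))
print(f"assigned and trimmed: {len(assigned)}/{len(pairs)} "
      f"({100 * len(assigned) / len(pairs):.1f}%)")

annotations = list(mark_duplicates(assigned))
report = duplicate_rate_report(annotations, sample_id="demo")
row = report.iloc[0]
print(f"dedup: {row.n_unique} unique + {row.n_duplicate} duplicate reads "
      f"-> measured duplicate rate {row.rate:.3f}")

hist = cluster_size_histogram(annotations)
print("cluster sizes (size: n_clusters):",
      dict(sorted(hist.items())))
print("A measured rate near 0.20 and mostly size-1/2 clusters show the tag "
      "recovers the configured duplication faithfully.")
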