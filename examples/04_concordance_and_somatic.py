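"""Duplicate-cluster allele concordance and somatic-site identification.

First shows that reads sharing a tag carry the same allele (duplicates are
real PCR copies, not collisions), then runs the 2xk Fisher + Benjamini-
Hochberg somatic caller on a germline/tumor toy table.
"""

import pandas as pd

from smtdedup import (
    SimulationConfig,
    cluster_concordance,
    extract_allele,
    generate_design,
    generate_sample,
    identify_somatic,
    mark_duplicates,
)

cfg = SimulationConfig(
    seed=5, n_targets=10, mean_depth=400, duplicate_rate=0.4,
    het_fraction=1.0, error_rate=0.0,
)
designs = generate_design(cfg)
pairs, truth = generate_sample(designs, cfg)
annotations = list(
    mark_duplicates(zip(truth["read_id"], truth["target_id"], truth["smt"]))
)
by_id = {d.target_id: d for d in designs}
calls = {
    p.read_id: extract_allele(
        p.seq2[len(by_id[t].upstream_primer):], by_id[t].snps[0]
    )
    for p, t in zip(pairs, truth["target_id"])
}
table = cluster_concordance(annotations, calls)
print("allele agreement within duplicate clusters (error-free reads):")
print(table.to_string(index=False))
print("100% agreement at every size: with 12-mer tags, shared tags mean "
      "shared template.\n")

counts = pd.DataFrame(
    [
        ("germ", "TP53_ex5", 120, 300, 1, 0),
        ("tum1", "TP53_ex5", 120, 160, 140, 0),
        ("tum2", "TP53_ex5", 120, 210, 90, 0),
        ("germ", "rs_control", 120, 150, 150, 0),
        ("tum1", "rs_control", 120, 148, 152, 0),
        ("tum2", "rs_control", 120, 155, 145, 0),
    ],
    columns=["sample_id", "target_id", "position", "n_ref", "n_alt", "n_other"],
)
result = identify_somatic(counts, germline_sample="germ")
print("somatic-site identification (2xk Fisher, BH FDR < 0.05, "
      "germline alt < 10%):")
print(result.to_string(index=False))
print("The tumor-specific site is somatic; the germline het SNP is "
      "significant but excluded by the germline-frequency filter.")
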