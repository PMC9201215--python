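"""Cross-disease comparison of significant three-SNP interactions.

Simulates two disease cohorts that share one planted interaction with the
same pattern but opposite directions (risk in disease A, protective in
disease B — the disease-specific signature) plus one effect unique to each
disease, scans both at order 3, and classifies the significant SNP sets.
"""

from episcan import compare, comparison_frame, scan, simulate, study_template
from episcan.simulate import PlantedEffect

shared = ("rs1059057", "rs2077079", "rs1124")
cfg_a = study_template(
    n_cases=1000, n_controls=1000, seed=21,
    effects=[
        PlantedEffect(shared, "dxdxa", 2.5),
        PlantedEffect(("rs1136450", "rs1136451", "rs4715"), "dxdxd", 2.0),
    ],
)
cfg_b = study_template(
    n_cases=1000, n_controls=1000, seed=22,
    effects=[
        PlantedEffect(shared, "dxdxa", 0.4),
        PlantedEffect(("rs1059046", "rs3024798", "rs721917"), "dxdxd", 2.0),
    ],
)
G_a, s_a, _ = simulate(cfg_a)
G_b, s_b, _ = simulate(cfg_b)
res_a = scan(G_a, s_a, order=3)
res_b = scan(G_b, s_b, order=3)

records = compare(res_a, res_b)
frame = comparison_frame(records)
counts = frame["category"].value_counts()
print("category counts:", dict(counts))
row = frame[frame.snp_set == ",".join(sorted(shared))].iloc[0]
print(f"\nshared triple {row.snp_set}: {row.category}")
print(f"  A: {row.patterns_a} OR {row.ors_a} ({row.direction_a})")
print(f"  B: {row.patterns_b} OR {row.ors_b} ({row.direction_b})")
print("\nThe shared triple is classified same_pattern_discordant — the "
      "same SNPs and pattern raise risk in disease A and lower it in "
      "disease B; triples echoing only one cohort's planted effects fall "
      "into the unique_a/unique_b categories.")
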