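"""Exhaustive three-SNP effect-pattern scan with a planted interaction.

Plants a d x d x a interaction (double heterozygote at two SNPs, alt
homozygote at a third) with odds ratio 3.0 and runs the full order-3 scan:
680 SNP triples x 27 patterns = 18,360 stratified CMH tests, with BH FDR
across the scan, followed by the bookkeeping summary (directions, pattern
composition, intragenic and hydrophilic/hydrophobic classification).
"""

from episcan import scan, simulate, snp_frequency_summary, study_template
from episcan.report import summarize_scan
from episcan.simulate import PlantedEffect

eff = PlantedEffect(("rs1059057", "rs2077079", "rs1124"), "dxdxa", 3.0)
cfg = study_template(n_cases=1000, n_controls=1000, effects=[eff], seed=11)
G, samples, _ = simulate(cfg)

results = scan(G, samples, order=3)
cols = ["snps", "pattern", "n_exposed", "or_mh", "p", "q", "direction"]
print(results[cols].head(5).round(4).to_string(index=False))
print()
print(summarize_scan(results))
print("SNPs most often present in reported interactions:")
print(snp_frequency_summary(results).head(5).to_string(index=False))
print("\nThe planted triple tops the list with ORs near 3 — under its true "
      "dxdxa pattern and under dxdxr, whose exposed group is the same "
      "genotype class (alt homozygotes differ only in the reference "
      "group); its SNPs also dominate the membership counts because "
      "partially overlapping triples inherit part of the signal.")
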