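"""Single-SNP scan with a planted protective dominant effect.

Plants a dominant (heterozygote-deviation) odds ratio of 0.45 on one
SFTPA1 SNP — the magnitude regime reported for protective surfactant-gene
variants — in a cohort of 1,000 cases and 1,000 controls, then runs the
order-1 scan: each of the 17 SNPs is tested under its additive, dominant
and recessive contrast (51 CMH tests stratified by sex x smoking), with
BH q-values computed across the scan.
"""

from episcan import scan, simulate, study_template
from episcan.simulate import PlantedEffect

eff = PlantedEffect(("rs1136450",), "d", 0.45)
cfg = study_template(n_cases=1000, n_controls=1000, effects=[eff], seed=7)
G, samples, _ = simulate(cfg)

results = scan(G, samples, order=1)
cols = ["snps", "genes", "pattern", "n_exposed", "or_mh", "ci_low",
        "ci_high", "p", "q"]
print(results[cols].head(6).round(4).to_string(index=False))
print(f"\n{len(results)} of 51 tests reported at p < 0.05.")
print("The planted SNP surfaces under its dominant contrast with an OR "
      "near 0.45 (protective) and a q-value far below 0.05; overlapping "
      "contrasts at the same SNP echo the signal more weakly.")
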