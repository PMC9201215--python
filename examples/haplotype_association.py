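"""Two-locus haplotype frequencies by EM and the carrier association test.

Simulates a cohort where carrying the alt-alt haplotype of a tightly
linked intragenic SNP pair multiplies the disease odds by 2.4, estimates
the four haplotype frequencies by EM from unphased genotypes (the double
heterozygote being the only phase-ambiguous diplotype), and tests each
candidate haplotype under the dominant carrier contrast.
"""

from episcan import (
    em_haplotype_freqs,
    haplotype_scan,
    simulate_haplotype_cohort,
)

hap_freqs = (0.5, 0.1, 0.1, 0.3)  # ref-ref, ref-alt, alt-ref, alt-alt
G, samples, true_carrier = simulate_haplotype_cohort(
    hap_freqs, carrier_or=2.4, n_cases=600, n_controls=600, seed=5
)

hf = em_haplotype_freqs(G.column("snpA"), G.column("snpB"))
print(f"EM haplotype frequencies (truth {hap_freqs}):")
print(f"  {hf.freqs.round(3).tolist()}  after {hf.n_iter} iterations, "
      f"log-likelihood {hf.loglik:.1f}")

results = haplotype_scan(G, samples, pairs=[("snpA", "snpB")])
cols = ["haplotype", "hap_freq", "n_carrier", "or_mh", "ci_low", "ci_high",
        "p", "q"]
print(results[cols].round(4).to_string(index=False))
print("\nThe TG (alt-alt) haplotype is the planted risk carrier: its OR is "
      "close to 2.4 with q << 0.05, while the other haplotypes absorb the "
      "complementary protective shift.")
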