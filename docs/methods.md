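# Methods

## Model and procedure

episcan tests association between multi-SNP genotype classes and
case/control status in an unrelated cohort. The unit of inference is an
*effect pattern*: an assignment of one quantitative-genetic component —
additive (a), dominance deviation (d), or recessive (r) — to each SNP of a
1-, 2- or 3-SNP tuple. Each component is binarized into an exposure
contrast compatible with a 2×2 table:

| component | included subjects | exposed subjects |
|---|---|---|
| a | homozygotes only (dosage 0 or 2) | alt homozygotes |
| d | all non-missing | heterozygotes (default) or carriers (option) |
| r | all non-missing | alt homozygotes |

For a tuple, inclusion is the intersection of the per-SNP inclusion masks
and exposure is the conjunction of the indicators: under d×d the exposed
group is exactly the double heterozygotes, and the reference group is the
pooled remainder of included subjects rather than a single contrast
genotype. The additive contrast is realized as alt-homozygote vs
ref-homozygote with heterozygotes excluded — the only binarization of the
additive effect a 2×2 table supports; the orthogonal cis/trans
double-homozygote contrast is deliberately not used. The dominant
component defaults to the heterozygote-deviation indicator (dosage == 1)
because the d×d exemplar of the framework is the double heterozygote; a
carrier coding (dosage ≥ 1) is available as `dominant_coding="carrier"`
for sensitivity analysis. Indicator polarity follows the ALT allele as
written in the input; the package never re-orients alleles by frequency,
since frequency-based orientation can silently flip odds-ratio directions
between cohorts.

Missing genotypes exclude a subject from any test touching that SNP
(per-test deletion, maximizing per-test n); subjects lacking sex or smoking
are excluded from stratified tests with a logged count.

## Stratified testing

Confounding by sex and smoking is handled by stratification, not
regression: included subjects are split into up to four sex × smoking
strata, and each hypothesis is evaluated on the stratified 2×2 tables with

* the Mantel–Haenszel common odds ratio
  `OR_MH = Σ aᵢdᵢ/nᵢ / Σ bᵢcᵢ/nᵢ`, reported as 0 or ∞ (flagged) when a
  numerator/denominator vanishes — no Haldane–Anscombe 0.5 correction is
  applied, as the MH estimator tolerates sporadic zero cells;
* a 95% CI from the Robins–Breslow–Greenland variance of log OR_MH, using
  z = 1.96;
* the Cochran–Mantel–Haenszel chi-square with the hypergeometric mean and
  variance per stratum, 1 df. The continuity correction
  `(|Σ(aᵢ−E[aᵢ])| − ½)²/ΣVar` is **on by default** because strata are small
  in cohorts of a few hundred; it is exposed as a flag. With a single
  stratum the statistic equals the Pearson chi-square rescaled by the
  exact factor (n−1)/n, the usual relation between the conditional
  (hypergeometric) and unconditional variances.

Tests with fewer than 5 exposed subjects are computed but flagged
`sparse`; tests with zero usable subjects or zero variance are reported as
NA rows flagged `degenerate`. Benjamini–Hochberg q-values are computed
across each scan order separately (orders are reported separately, so the
natural multiplicity family is within-order); rows with raw p < 0.05 are
reported and q ≤ 0.05 adds an `fdr` flag. All estimators are implemented
once, as vectorized direct formulas over a (tests × strata × 4) count
tensor shared by the scalar API and the exhaustive scan; tests verify the
two paths agree to 1e-12 and that both match statsmodels' independent
`StratifiedTable` implementation.

### Calibration and the continuity correction

The corrected statistic approximates the exact conditional (permutation)
test and is therefore conservative against the nominal 5% level; the
uncorrected statistic is the asymptotically calibrated one. The type-I
calibration check consequently evaluates the uncorrected test: over 1,000
null replicates of the study design the single-SNP rejection rate at
p < 0.05 sits within 3 binomial SEs of 0.05, while the corrected default
rejects at ≈3% — the intended conservative behavior. The permutation
check compares the corrected p with the doubled smaller conditional tail
of the exact case-relabeling distribution (hypergeometric for a fixed
2×2 margin); agreement at Monte-Carlo precision (3 SE of 1e5 shuffles)
is a statement about the asymptotic regime, so the fixture tables use
moderate totals (~1,200–3,000) and non-extreme p (0.05–0.7). At small
counts the lattice error of any chi-square approximation (~0.01–0.08)
dominates the Monte-Carlo band; there the correction still gives the
better, conservative approximation, which is why it remains the default.

## Haplotype analysis

Two-locus haplotype frequencies are estimated by the standard EM
resolution of the double-heterozygote ambiguity, started from linkage
equilibrium, stopping when the largest frequency change falls below 1e-8
(default; max 1,000 iterations). The log-likelihood is nondecreasing by
construction and asserted per iteration in tests; phase-certain cohorts
are solved by a single gamete-counting M-step. Frequencies are estimated
on the pooled cohort (cases + controls) so that phase assignment cannot
differ between the groups being compared. For testing, each subject is
hard-assigned the most probable diplotype (double heterozygotes resolve to
the phase with the larger frequency product), keeping the 2×2 counts
integral, and carrier-vs-non-carrier of the risk haplotype runs through
the stratified machinery; all four candidate haplotypes per pair are
tested with BH across the haplotype scan. Hard assignment misclassifies
part of the ambiguous subjects and therefore attenuates carrier odds
ratios toward the null; the attenuation is small for pairs in strong
positive LD (the adjacent intragenic pairs the default pair list targets)
and grows as the cis/trans products approach equality. A
fractional-weight alternative would remove the attenuation at the cost of
non-integral tables and is noted as future work. Default pairs are
adjacent SNPs within each gene; any pair list can be supplied.

## Cross-disease comparison

Significant interactions from two scans of the same order are matched on
canonical keys — SNP ids sorted lexicographically with pattern components
permuted in lockstep — and each SNP set is classified as unique_a,
unique_b, same_pattern_concordant, same_pattern_discordant (a shared
pattern with odds ratios on opposite sides of 1), or different_pattern.
A SNP set significant under several patterns yields one record carrying
all pattern/OR pairs. The classification is descriptive; no formal
between-disease heterogeneity test is attempted, and `compare(A,B)` is
exactly `compare(B,A)` with roles swapped.

## Synthetic cohorts

The generator emulates the study design the analysis assumes:

* genotypes per SNP from Hardy–Weinberg equilibrium at the configured
  alt-allele frequency, or per LD pair by drawing two gametes from a
  four-haplotype distribution (whose implied margins must match the SNP
  frequencies);
* sex and smoking drawn independently with configurable prevalences;
* status from logit P(case) = baseline + β_male·male + β_smoker·smoker +
  Σ log(OR)·indicator, the indicator being exactly the scan's conjunction
  rule; cases and controls accumulate by rejection sampling (batch 2,048,
  cap 1e7 draws) until both quotas fill, reproducing case-control
  ascertainment. The intercept (default −1.0) controls sampling
  efficiency, not prevalence.

`study_template()` fixes the study conditions: 84 cases vs 194 controls;
the 17-SNP five-gene panel; P(male) = 124/194 and P(smoker) = 91/194 from
the control demographics; confounder log-odds log((59/25)/(124/70)) ≈ 0.29
for male and log((30/54)/(91/103)) ≈ −0.46 for smoking from the cohort's
case/control splits; MAFs cycling 0.20–0.40 (population frequencies for
the panel are not pinned by the design; these are user-overridable); no
planted effects.
Allele letters in the template are plausible stand-ins, not dbSNP
annotations. Planted odds ratios are conditional logistic effects; the
pipeline's exposed-vs-unexposed MH estimate targets the same conditional
OR within each stratum, so recovery is essentially unbiased apart from
the small-sample Jensen bias of the log-OR at low exposed counts (~+0.06
at ≈60 exposed, negligible at ≥140) — the recovery checks plant effects
on MAF 0.35–0.40 SNPs for that reason. A separate generative model,
`simulate_haplotype_cohort`, drives the haplotype carrier penetrance
directly from drawn gametes and returns the realized carrier indicator as
ground truth.

What the generator does **not** emulate: population structure/admixture
(the emulated study is single-ancestry by design), age (no age adjustment
is modeled), genotyping error, HWE violations, LD beyond pairs, and
missingness is uniform rather than genotype-dependent. Passing tests
therefore certify the statistical machinery under the stated design, not
robustness of real-cohort conclusions to those complications.

## Numerical and design choices

* Counts are exact integers assembled per tuple by a base-4 joint-genotype
  bincount and mapped to all 3^k patterns with precomputed inclusion/
  indicator matrices (Kronecker products of the 3×4 component maps); a
  full 18,360-test order-3 scan of 278 subjects runs in well under a
  second on one CPU.
* The scan computes q-values over the full enumeration, then filters to
  p < alpha for reporting (sorted by p); `full=True` returns everything in
  enumeration order.
* EM tolerance 1e-8 on frequencies; initialization-robustness is tested
  from random starts. A haplotype with estimated frequency 0 yields an NA
  row rather than a 0-carrier test.
* Seeds: every stochastic routine takes an explicit seed; identical
  config + seed reproduce outputs byte-for-byte, and output headers embed
  a deterministic manifest (command, seed, version, input digests — no
  timestamps, so reruns are byte-identical).
* Exit codes of the CLI: 0 success, 2 validation error, 3 all tests
  degenerate, 4 internal error.

## Problem sizes used in the checks

Estimator-equivalence sweeps use 1,000 random stratified table sets
(1–4 strata, counts 0–200); null calibration uses 1,000 replicates of the
84/194 template (51,000 single-SNP tests, plus a full order-3 scan per
replicate for the BH false-discovery proportion); parameter recovery uses
200 replicates at 2,000/2,000; haplotype recovery uses n = 1,000 for EM
frequencies and 500 replicates of 600/600 for the carrier OR. These sizes
make the Monte-Carlo error of each check small relative to its tolerance.

## Known limitations

* Covariate adjustment is stratification-only; continuous covariates
  (e.g. age) would require the unimplemented regression route.
* The recessive contrast is ill-powered at low MAF in small cohorts
  (expected exposed counts of a few); such tests carry the `sparse` flag
  and their chi-square calibration is approximate.
* Haplotype testing is limited to two loci and hard phase assignment;
  no reference-panel imputation.
* BH assumes the usual positive-dependence conditions across the heavily
  overlapping scan hypotheses; the null simulations show it is in fact
  conservative there (E[FDP] ≈ 0.04 at the 5% level).
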