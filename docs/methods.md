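# Methods

## Problem setting

GWAS loci for a quantitative trait contain many associated variants, few
of which are functional.  One functional hypothesis is post-transcriptional:
a variant that creates or destroys an RNA-modification site (m⁶A, m⁶Am,
m¹A, 2′-O-Me, m⁵C, m⁵U, m⁷G, A-to-I editing, pseudouridine) can change
mRNA stability or translation and thereby the trait.  The pipeline takes
summary-level inputs only — a trait GWAS, an RNAm-SNP catalogue,
eQTL/pQTL summary tables, an LD reference — and produces annotation
tallies, an enrichment test, Mendelian-randomization estimates for
exposures (e.g. plasma proteins), SMR/HEIDI pleiotropy tests for gene
expression, and gene-set over-representation.

## Synthetic-data model

All ground-truth testing rests on the generative model in
`rnamsnp.synthetic`:

* **Genotypes.** Dosages 0/1/2 from two latent-Gaussian haplotypes
  thresholded at the MAF quantile.  Within a block of consecutive SNPs the
  latents follow an AR(1) process, so the pair at lag k has latent
  correlation ρᵏ; blocks are independent.  This gives simple, exactly
  controllable LD without coalescent machinery; it does not reproduce
  realistic MAF spectra, recombination hotspots, or long-range LD, so
  tests passing here say nothing about those features of real data.
* **Traits.** Exposure X = Σγⱼ Gⱼ + εₓ with γ supported on `n_causal`
  SNPs (magnitudes uniform on [0.5, 1.5] of the common scale, random
  signs) and rescaled so the genetic component explains exactly
  `heritability_x` of Var(X).  Outcome Y = βX + Σαⱼ Gⱼ + ε_y, where αⱼ are
  direct (horizontally pleiotropic) effects on a `pleiotropy_fraction`
  share of the causal SNPs.  Exposure and outcome statistics come from
  independent cohorts (two-sample design) by default.
* **Summary statistics** are exact per-SNP OLS regressions on the
  simulated individuals — not analytic approximations — so the null
  z-score calibration the tests assert is literally true of the generator.
* **RNAm flags** are Bernoulli with rate `rnam_base_rate`, multiplied by
  `rnam_enrichment` at causal SNPs (capped at 1); annotation fields
  (type, confidence, gain/loss, region) are drawn from categorical
  distributions shaped like public catalogue compositions and recorded in
  the truth record.

Defaults (the study conditions of the packaged tests): 200 blocks × 50
SNPs = 10,000 SNPs, ρ = 0.5, MAF ∈ [0.05, 0.5], 4,000 individuals per
cohort, 40 causal SNPs jointly explaining 60% of exposure variance (each
causal SNP is then individually detectable at p < 5×10⁻⁸ with margin),
β = 0.1, no pleiotropy, flag base rate 5% with 5× enrichment, seed
20221018.

For estimator-calibration studies needing hundreds of replicates,
`gen_instrument_stats` samples harmonized instrument tables directly at the
summary level: β̂ₓⱼ ~ N(γⱼ, seₓⱼ), β̂_yⱼ ~ N(βγⱼ + αⱼ, se_yⱼ) with SEs from
the standard marginal-OLS variance at the stated cohort sizes.  This is the
asymptotic distribution of the individual-level pipeline and is used where
the replicate count, not the data-generating detail, carries the test;
individual-level end-to-end recovery is tested separately at smaller
replicate counts.

## Statistical procedures and their knobs

**Annotation.** Strict inequality at every p-value gate (a p-value equal
to the threshold does not pass).  Percentages are rounded half-up — two
decimals in per-type summaries, one decimal in classification tallies —
and every printed percentage is re-derivable from the printed count and
denominator (checked at output time).  A SNP carrying several modification
types contributes one row per type to per-type summaries but counts once
(keeping its highest-confidence entry) in distinct-SNP tallies; both
counts are reported.  Loci are built by single-linkage chaining of
significant SNPs within 1,000 kb (configurable); "locus" has no canonical
definition in summary-level work, and chaining is the simplest reproducible
choice.

**Enrichment.** The resampling null matches the flagged count exactly and
samples without replacement within a replicate (B = 1000 by default).  Both
the raw empirical p (#{null ≥ obs}/B) and the +1-corrected
(1+#)/(1+B) are reported; the corrected value is the headline because a
permutation p of exactly 0 is improper.  No MAF or LD matching of sampled
SNPs is attempted — the null is plain random sampling — and a matching hook
is left as an extension point.  The binomial complement uses the
non-flagged significant fraction as the success probability.

**Instruments.** Selection at p < 5×10⁻⁴, clumping at r² < 0.001 within
10,000 kb, greedy by ascending p with deterministic tie-breaks (position,
then rsID).  Harmonization flips the outcome beta and complements its
allele frequency when allele labels are swapped.  Palindromic SNPs (A/T,
C/G) are dropped only when frequency-ambiguous (EAF within 0.5 ± 0.08 in
either study, or missing); unambiguous palindromes are aligned by
frequency.  A strict mode drops all palindromes.  Non-palindromic allele
sets that do not match are dropped as mismatches — no strand-complement
inference is attempted.  LD pairs absent from the panel count as r² = 0
(logged), mirroring common clumping-tool behaviour.

**MR estimators.** IVW defaults to multiplicative random effects with the
SE inflation √(Q/(n−1)) floored at 1 and a t reference (n−1 df); a
fixed-effect variant is available.  MR-Egger orients all instruments to
positive exposure effects, fits weighted least squares with weights
1/se_Y², inflates both SEs by max(1, √(Q/(n−2))) and uses t with n−2 df.
The weighted median interpolates the ratio at standardized cumulative
weight 0.5 using first-order ratio SEs (se_Y/|β_X|); its SE is the SD over
1000 parametric-bootstrap draws with a fixed seed.  MR-PRESSO simulates
the no-pleiotropy distribution of the leave-one-out residual sum of
squares (1000 draws), Bonferroni-adjusts the per-SNP empirical outlier
p-values, and measures distortion against removals of random same-size
subsets; empirical p-values carry the +1 correction (raw fractions are
also emitted).  Both the all-SNP and outlier-corrected estimates are
reported, since published tables rarely say which they print.

**SMR/HEIDI.** T_SMR = z₁²z₂²/(z₁²+z₂²) against χ²₁; effect
b_xy = β_GWAS/β_eQTL with se = |b_xy|/√T.  HEIDI uses SNP-selection
defaults from the published SMR tool conventions (|z_eQTL| ≥ 3.16, r² to
the top SNP within [0.05, 0.9], at most 20 SNPs), propagates errors to the
b_xy differences with LD correlation r as the within-study estimate
correlation, and evaluates T_HEIDI = Σz_d² against the eigenvalue-weighted
chi-square mixture by Satterthwaite moment matching (scale Σλ²/Σλ, df
(Σλ)²/Σλ²).  Moment matching is accurate where the 0.05 gate operates; a
multivariate-normal Monte-Carlo mode serves as oracle and fallback.  The
scan's cis region is ±1,000 kb of the target TSS, matching the QTL-linking
default.

**ORA.** Hypergeometric upper tail, identical to one-sided Fisher; BH
across sets.  The default universe is the union of catalogue genes, an
explicit universe overrides, and an EASE-style conservative mode (tail at
k−1) sits behind a flag.

## Numerical and degenerate-input choices

Input p-values of 0 are clamped to 1e-300 with a warning; computed
p-values are floored there too.  Monomorphic SNPs get β = 0, a huge SE and
p = 1 rather than NaNs.  Zero exposure betas abort MR with the offending
rsID named.  HEIDI with fewer than 3 eligible SNPs reports a missing
p-value with reason `insufficient_snps`.  When MR-PRESSO flags every
instrument, the corrected estimate is reported as undefined.  All
stochastic steps take explicit seeds and are byte-reproducible; the
pipeline's stages are sequential, and no result depends on thread count.

## Problem sizes used in the packaged tests

Operating characteristics are measured at sizes chosen to make the
binomial noise of the measured rate small relative to its acceptance band:
200 replicates for IVW recovery/coverage and the permutation-null and
MR-PRESSO-null calibrations, 500 for the Egger intercept type-I error, 100
for enrichment power, outlier detection and the SMR positive-control and
linkage scenarios.  Individual-level end-to-end IVW recovery runs 25
replicates at 20,000 individuals.  SMR scenarios use one 25-SNP locus at
ρ = 0.7 with 20,000 individuals per cohort and a 2,000-individual LD
reference.

## Known limitations

Single-ancestry, autosomal, biallelic SNPs only; no liftover, no
strand-complement repair, no MAF/LD-matched enrichment null, no
multivariable MR or mode-based estimators, no Steiger filtering, no
multi-probe conditional SMR, and no reading of binary formats (PLINK,
BESD).  The synthetic LD model is blockwise AR(1) and should not be
mistaken for population realism; conclusions about real data require real
inputs.
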