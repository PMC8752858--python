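# Methods

## The inference chain

The package mirrors how a scat-based genetic monitoring program turns raw
replicate PCR calls into population-level inference:

1. **Screening and consensus.** Each sample is amplified in replicate
   (default 4 PCRs).  A sample continues only if ≥ 5 of the 18 loci amplified
   in its first two PCRs.  Per locus, a heterozygous pair confirmed in ≥ 2
   independent PCRs or a lone allele seen in ≥ 3 PCRs (with no other allele
   itself replicated) yields a consensus call; everything else is missing.
   A replicated second allele vetoes a homozygote call, and two differently
   confirmed heterozygote pairs cancel to missing — the calling rules imply
   but do not fix these conflict resolutions, so they are documented choices
   here.
2. **Individual identification.** Consensus genotypes are compared under a
   dropout-tolerant rule: identical over jointly confirmed loci except at
   most one locus where one genotype is homozygous for an allele of the
   other's heterozygote.  Because this relation is not transitive, samples
   are clustered greedily in order of decreasing confirmed-locus count
   (sample id ascending as tie-break), joining the first matching catalog
   entry; the entry representative is the per-locus consensus of members
   with heterozygote evidence overriding dropout homozygotes.  The minimum
   overlap to compare two partial genotypes defaults to 10 of 18 loci —
   a balance of discriminating power against data loss; configurable.
3. **Reliability of single detections.** For genotypes supported by one
   sample, each confirmed locus gets the posterior probability that the call
   is the true genotype, with Hardy–Weinberg priors and the per-PCR
   emission model below; the sample score is the product over confirmed
   loci, flagged against a 0.95 threshold.  This is a simplified Bayesian
   accuracy test, not a reimplementation of any particular published tool.
4. **Parentage.** For each pup, all dam × sire pairs among sampled adults
   (≥ 2 years old in the pup's birth year) plus dam-only / sire-only /
   no-parent hypotheses are scored by the conditional likelihood of the
   pup's observed genotype; unknown parents are integrated over
   Hardy–Weinberg genotype frequencies from that year's allele frequencies.
   The best hypothesis is accepted when it leads the runner-up by ≥ 3
   log-units (≈ LOD 1.3; no published threshold exists for this design, so
   the margin is configurable).  Otherwise exclusion is tried: a unique pair
   explaining all but ≤ 2 offspring alleles (minimum over transmission
   assignments per locus, summed) is accepted.  Joint sibship–parentage
   optimization over the whole sample is deliberately out of scope: the
   per-offspring trio likelihood plus cross-offspring sire reconstruction is
   desk-scale and suffices for breeder identity, sneaker counts and pair
   histories.
5. **Sneaker-sire reconstruction.** For maternal half/full-sib groups with
   no sampled sire, each offspring contributes its non-maternal allele per
   locus (ambiguous when both alleles could be maternal); singleton
   contributions fix paternal alleles, ambiguous sets are intersected across
   siblings, and per-locus completeness (0, 0.5, 1) is reported.
6. **Relatedness.** The Queller–Goodnight moment estimator (numerators and
   denominators summed over loci and both reference directions before
   dividing) is unbiased and is the default inside the random-mating null,
   where a well-defined mean of 0.00 matters.  The maximum-likelihood
   estimator maximizes the dyadic likelihood over the non-inbred IBD modes
   (k0, k1, k2) on the simplex; the per-locus likelihood is linear in k, so
   the log-likelihood is concave and EM converges to the global maximum
   (tolerance 1e-10, ≤ 500 iterations).  The triadic variant (a reference
   third genotype) is replaced by this dyadic form — the downstream uses
   (median/range among breeders, null comparison, first-degree calibration)
   do not depend on the triadic refinement.  Inbred (Jacquard) modes are out
   of scope; founders are outbred by design.  Near the k0 = 1 boundary the
   MLE truncates, so unrelated dyads have a point mass at r = 0 and a small
   positive mean; at 18 loci with ~8 alleles the median for unrelated pairs
   is ≈ 0.02 and first-degree dyads average ≈ 0.51.
7. **Population statistics.** Observed heterozygosity is heterozygous/typed
   loci per individual, and population summaries average over individuals
   (not loci), matching the reporting of an SD across individuals.  Harvest
   rate is matched harvest genotypes / previous-summer catalog size under
   the same dropout-tolerant matching.  Pair-bond duration starts at 1 in
   the first breeding year and increments per breeding year; a gap year does
   not reset the counter (only the start of the bond is well-defined, so the
   continuation rule is a documented choice).  A pup is alive at 15 months
   if re-detected the next summer; detected only in that year's harvest, or
   absent, means dead.  The harvest covariate attached to a pup cohort is
   the rate during the cohort's first year of life (between birth summer and
   next-summer resampling).
8. **Models.** Covariates are z-scored (n−1 denominator).  The fixed model
   is an ordinary logistic ML fit (statsmodels backend).  The mixed model
   adds a Gaussian random intercept per mated pair and maximizes the
   marginal likelihood by adaptive Gauss–Hermite quadrature: per group the
   conditional mode and curvature are found by Newton iterations, nodes are
   recentered/rescaled there, and 21 nodes (configurable ≥ 15) integrate the
   random effect; L-BFGS-B optimizes (β, log σ) and standard errors come
   from the numerical Hessian.  P-values are asymptotic Wald tests
   throughout (no small-sample degrees-of-freedom correction).  AIC counts
   the variance parameter.  The t-test is Welch by default (unequal n and
   spread in the sneaker-male comparison); the pooled variant is available.

## Per-PCR error model

Each true allele in a PCR independently drops out with probability d
(default 0.01); an amplified allele is mis-scored as one of the other k−1
alleles of the locus with total probability f (default 0.01); the whole
locus fails with probability `failure` (default 0 in analysis, 0.05 in the
sampling simulator).  A lone surviving allele reads as an apparent
homozygote; both lost reads as no amplification.  The same genotype-level
emission matrix (failure excluded — a failed locus is simply skipped) enters
the trio likelihood and the reliability score.  Only the two rates are
standard reporting; the per-allele decomposition is the conventional one.

## The synthetic-data generator

`simulate_population` emulates the study design: 16 groups sampled over 10
summers, 18 microsatellite loci with ~8 alleles (frequencies from a
symmetric Dirichlet), founders in Hardy–Weinberg proportions.  Each group
has a bonded breeding pair; litters are Poisson (mean 4.3, so 83 pair-years
produce ≈ 357 pups); with probability 0.12 a litter is sired by an unsampled
sneaker male (10 of 83 breeding events at the study's scale), whose genotype
can be biased toward homozygosity (`sneaker_hom_boost`) to emulate the lower
diversity of unaffiliated males; polygyny (a second resident female
breeding) occurs with probability 0.05.  Harvest removes non-pup animals at
a per-year scheduled rate (default: none in year 1, a pause in year 3, then
≈ 0.2 annually — the on/off/on pattern of a newly opened hunt); dying pups
are recorded as harvested with the same exposure.  Breeder vacancies are
filled by immigrants with fresh genotypes (probability 0.7) or by resident
floaters — the metapopulation immigration that keeps diversity high.
Surviving pups stay as yearlings, then disperse to a floater pool at age 2
(age structure is deliberately coarse: pup / yearling / adult ≥ 2).

Pup survival to 15 months is drawn from a logistic model on standardized
covariates (harvest rate, group adults, pair H_o, density, years paired)
with a pair-level Gaussian random intercept.  Because survival feeds back
into next year's group composition, the full simulator standardizes
covariates against fixed reference moments (documented defaults near the
realized distributions).  The parameter-recovery harness
`simulate_survival_dataset` has no feedback loop: it draws 83 pair-year
covariate vectors at realistic scales, z-scores the realized pup table
exactly, and applies the generating coefficients — the default truth being
harvest −0.56, adults 0.19, pair H_o −0.12, density −0.18, years paired
0.28 (fixed scale) and the conditional-scale analogs with pair SD 0.85.
Litter-size and breeder-turnover distributions are config knobs, not claims
of fidelity — no field estimates exist for them in this design.

What the generator does **not** emulate: spatial territory structure, scat
deposition and detection ecology, allele-size stutter or binning artifacts,
population-wide linkage or inbreeding, mtDNA species confirmation (non-target
samples simply never enter), and dispersal beyond the floater pool.  Passing
tests therefore certify the inference machinery under the stated error
model, not robustness to every field artifact.

## Numerical choices and degenerate inputs

* Trio likelihoods use exact sums over the per-locus genotype space
  (k(k+1)/2 states); Mendelian impossibilities yield −inf log-likelihoods,
  and an offspring with no jointly typed loci is an error.
* EM for the IBD simplex cannot fail, so the grid-search fallback exists
  only as an independent test oracle.
* Monomorphic loci contribute zero weight to the moment estimator and are
  dropped (with a warning) from estimated allele-frequency tables.
* Constant responses and perfect separation abort logistic fits with a
  dedicated error; zero-SD covariates abort the z-transformation.
* Quadrature accuracy: 15 vs 40 nodes changes the mixed log-likelihood by
  < 1e-4 at study scale (tested); 21 nodes is the default.
* All randomness flows through numpy Generators; identical seeds give
  bit-identical populations, samples and null distributions.

## Problem sizes used in the test suite

Tests run the study's sampling design at reduced scale (e.g. 4–5 groups over
3–4 years for pipeline identity checks; 200 replicates for fixed-model
recovery, 60 for mixed; 1,000 null iterations) — sizes chosen so the whole
suite completes in well under a minute per file while keeping Monte-Carlo
error far below the tolerances asserted.  The acceptance script uses 500
recovery replicates, 2,000 null iterations and 600 first-degree dyads.

## Known limitations

* The pedigree is per-offspring; conflicting assignments across a litter are
  not reconciled jointly, and multi-generation consistency is not enforced.
* Reconstructed sneaker genotypes are partial (fixed loci only); their
  heterozygosity is computable only over fully fixed loci.
* The reliability score treats replicates as independent given the true
  genotype; systematic artifacts (consistent allele-specific dropout) would
  inflate scores.
* The mixed model supports a single random intercept (mated pair); crossed
  or nested effects (e.g. year within pair) are out of scope.
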