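# packped

Noninvasive-genetics monitoring for pack-living populations: from replicate
PCR allele calls on fecal DNA to consensus genotypes, unique individuals,
pedigrees, pairwise relatedness, and the mate-choice and pup-survival models
used to ask how genetic diversity is maintained in a socially structured,
harvested population such as reintroduced gray wolves.

## Who this is for

Field geneticists and population ecologists who monitor group-living animals
with scat-based microsatellite genotyping and harvest tissue recaptures, and
who need the whole inference chain — genotyping error control, individual
identification, parentage (including unsampled "sneaker" sires), inbreeding
avoidance tests and survival models — as reusable, testable code.  A
synthetic-data generator reproduces the sampling design and error processes,
so every stage can be validated against known truth without field data.

## What it computes

* **Consensus genotyping** — a heterozygote requires the same two alleles in
  ≥ 2 independent PCRs, a homozygote the same single allele in ≥ 3; samples
  amplifying < 5 of 18 loci in the first two PCRs are discarded.  Samples
  mismatching only by a single-locus allelic-dropout pattern (e.g. 102/102
  vs 102/106) are merged as one individual; single-detection genotypes get a
  Bayesian reliability score against a 0.95 threshold.
* **Parentage** — per-offspring trio likelihood
  `P(g_off | g_dam, g_sire)` summed over true-genotype states with
  Hardy–Weinberg priors, Mendelian transmission and a dropout/false-allele
  emission model (rates 0.01/0.01 by default); exclusion fallback tolerating
  two mismatching alleles across 18 loci; sneaker-sire genotypes
  reconstructed from mother–offspring allele constraints.
* **Relatedness** — Queller–Goodnight moment estimator and dyadic maximum
  likelihood over IBD modes (k0, k1, k2), r = k2 + k1/2, fitted by EM on the
  simplex; a random-mating null resamples mated pairs with replacement
  (151 pairs per iteration from 151 male / 167 female pools by default).
* **Population statistics** — observed heterozygosity H_o, yearly allele
  frequencies, genotype-recapture harvest rates, pair-bond durations,
  apparent survival at 15 months (absence = death).
* **Models** — logistic regression of pup survival on z-scored covariates
  (harvest rate, group adults, pair H_o, density, years paired), both fixed
  and with a mated-pair random intercept fitted by adaptive Gauss–Hermite
  quadrature; asymptotic Wald tests; AIC comparison; Welch t-test.

## Worked example

```python
import numpy as np
from packped import pup_survival_analysis, random_mating_null
from packped.genotypes import AlleleFrequencyTable
from packped.simulate import (MIXED_SURVIVAL_COEFFS, generate_allele_frequencies,
                              simulate_survival_dataset)

rng = np.random.default_rng(0)

# pup survival at the study's scale: 83 pair-years, ~357 pups
df = simulate_survival_dataset(rng, pair_re_sd=0.85,
                               coefficients=MIXED_SURVIVAL_COEFFS)
res = pup_survival_analysis(df)
print(res["mixed"])
print(f'AIC mixed - fixed: {res["delta_aic_mixed_vs_fixed"]:+.2f}')
```

```
pup survival (mixed): n=334, llf=-211.319, AIC=436.64, params=7, RE(group) SD=1.021
                coef     se       z  P>|z|
intercept     0.1185 0.1781  0.6652 0.5059
harvest_rate -0.4904 0.1895 -2.5873 0.0097
n_adults      0.0073 0.1877  0.0389 0.9690
pair_ho      -0.1123 0.1805 -0.6220 0.5340
density      -0.2120 0.1926 -1.1008 0.2710
years_paired  0.4160 0.1938  2.1465 0.0318
AIC mixed - fixed: -11.06
```

One replicate of this size recovers the generating truth (harvest −0.61,
years paired 0.26, pair-ID random-intercept SD 0.85) to within its standard
errors; harvest rate is the dominant, significantly negative predictor and
the mixed model beats the fixed one on AIC, as expected when pairs breed
repeatedly.

```python
# random-mating null for mated-pair relatedness
freqs = generate_allele_frequencies(18, 8, rng)
males, females = freqs.sample_genotypes(151, rng), freqs.sample_genotypes(167, rng)
pool = AlleleFrequencyTable.from_genotypes(np.concatenate([males, females]), freqs.loci)
null = random_mating_null(males, females, pool, n_pairs=151, n_iter=1000,
                          seed=1, observed=0.0)
print(null.summary())
```

```
{'estimator': 'qg', 'n_iter': 1000, 'n_pairs': 151, 'mean': -0.0027,
 'median': -0.0022, 'q025': -0.0241, 'q975': 0.0175,
 'observed': 0.0, 'percentile': 0.822}
```

Under random mating among unrelated animals, mean mated-pair relatedness is
0.00; an observed value of 0.00 sits squarely inside the null (two-sided
tail position 0.82), i.e. no evidence that mates are more (or less) related
than chance.

A command-line interface mirrors the pipeline stages:

```bash
packped simulate --seed 1 --out simdata
packped genotype --replicates simdata/replicates.csv \
    --frequencies simdata/allele_frequencies.csv --out geno
packped null --males males.csv --females females.csv --n-pairs 151 \
    --iterations 10000 --seed 1
packped models --survival pup_survival.csv
```

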