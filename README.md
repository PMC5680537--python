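# cfscreen

A performance model for **prenatal cystic fibrosis (CF) screening from
maternal-plasma cell-free DNA**, for biostatisticians and screening-programme
modellers evaluating single-gene cfDNA tests.

Cystic fibrosis is an autosomal recessive disorder (European birth prevalence
≈ 1/2500; carrier frequency ≈ 1/25). Current prenatal screening tests both
parents for carrier status. The alternative modelled here sequences and
counts deduplicated (UMI-tagged) plasma DNA fragments at a panel of targeted
*CFTR* mutation sites and calls a pregnancy screen-positive when the
percentage of mutant fragments reaches a cut-off — no paternal sample needed.

## The model

Plasma cfDNA is a maternal/placental mixture with fetal fraction *ff* (%).
At an informative mutation site the expected mutant-fragment percentage *m*
is determined by the genotypes: a carrier mother contributes (100 − *ff*)/2,
each fetal mutant allele *ff*/2. Hence, with one mutation observed,

- affected fetus: *m* = (100 − *ff*)/2 + *ff*  (55% at *ff* = 10),
- carrier fetus (maternal mutation): (100 − *ff*)/2 + *ff*/2 = 50%,
- carrier fetus (paternal mutation): *ff*/2,
- mother carrier, fetus non-carrier: (100 − *ff*)/2.

When two *different* mutations are seen, only the predominant (always
maternal) site is informative: *m* = 50% exactly if affected, (100 − *ff*)/2
if the fetus is a carrier. Counting *n* fragments, the observed percentage
is Gaussian with sd √(*m*(100 − *m*)/*n*) (an exact-binomial oracle is
included). A result ≥ the cut-off is positive: *c₁* (choice: 51%) with one
mutation found, *c₂* = *c₁* − *ff*/2 with two.

Population performance over a random-mating population with panel coverage
*a* (0.834 for the ACMG-23 panel):

- **DR** = P(affected tail ≥ *c₁*) × *a*² — at most 70%;
- **FPR** = Σ stratum-weight × tail over unaffected strata, including the
  OXX trisomy-7 confined-placental-mosaicism stratum whose mean is shifted
  up by *ff*/6;
- **OAPR** = (DR/FPR) × prevalence odds (1:2499).

A stratified Monte-Carlo simulator draws binomial fragment counts per
genotype stratum and recombines them with analytic weights, validating the
analytic tails and making the ~2 × 10⁻⁵ FPR estimable at desk scale.

## Worked example

```python
from cfscreen import PopulationParams, ScreeningPolicy, screening_performance

pop = PopulationParams()                       # q=1/25, odds 1:2499, a=0.834
policy = ScreeningPolicy(c1=51.0, n=32000)     # 51% cut-off, 32,000 fragments
est = screening_performance(policy, ff=10.0, pop=pop)
print(f"DR {est.dr:.1f}%  FPR {est.fpr:.4f}%  OAPR {est.oapr}")
```

prints

```
DR 69.6%  FPR 0.0019%  OAPR 14:1
```

i.e. 70% of affected pregnancies detected (the panel-coverage ceiling,
0.834²), a false-positive rate rounding to 0.002% (dominated by the rare
OXX-mosaicism carrier stratum at mean 50 + *ff*/6), and 14:1 odds that a
positive result is truly affected — versus 70% / 0.12% / 1:3 for parental
carrier testing (see `examples/carrier_comparison.py`: 42-fold better OAPR,
98% of invasive tests in unaffected pregnancies avoided).

The `examples/` scripts cover each capability (expected means, the
performance grid, the carrier-testing comparison, Monte-Carlo validation),
and a thin CLI wraps the same functions:

```sh
cfscreen table1                      # DR/FPR/OAPR grid, cut-offs 50-52 × ff 2-20
cfscreen distributions --ff 10       # per-genotype Gaussian curve tables
cfscreen compare-carrier             # plasma DNA vs carrier testing
cfscreen simulate --seed 1 --reps 100000   # stratified MC validation
```

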