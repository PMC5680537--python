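# Methods

## Model

A pregnancy's plasma cfDNA is a two-component mixture: maternal DNA with
weight (100 − ff)% and placental (fetal) DNA with weight ff%, the fetal
fraction, treated as known per pregnancy. At a targeted *CFTR* mutation
site, each genome copy contributes fragments in proportion to its mixture
weight, so the expected mutant-fragment percentage is compositional: a
heterozygous mother contributes (100 − ff)/2, each fetal mutant allele
ff/2. All genotype-conditional means in `cfscreen.genotype` follow from
this single rule; percentages (0–100), never proportions, are the canonical
unit, matching how every headline number is quoted.

Counting n deduplicated fragments (UMIs are assumed to remove amplification
noise completely, so counts are binomial in the original molecules), the
observed percentage at a site with mean m is modelled as Gaussian with
standard deviation √(m(100 − m)/n) percent — the binomial sd of a
percentage. Degenerate means (0 or 100) are point masses. The positive
call is **inclusive** (observed ≥ cut-off): this is load-bearing, since a
distribution whose mean sits exactly on the cut-off then has tail ½, which
is what produces the 35% detection rate at ff = 2 (cut-off 51) and the 0.8%
false-positive rate at cut-off 50. No continuity correction is applied;
`tail_prob_binomial` provides the exact binomial tail as an independent
oracle, and at the operating point (n = 32,000, m near 50) the two agree to
a few parts per thousand at any cut-off.

## Classification rule

With one mutation observed in plasma the cut-off is c₁ (default 51%). With
two different mutations observed — possible only when both parents carry
different panel mutations and the fetus inherits the paternal one — only
the predominant site (always the maternal mutation, because maternal DNA
dominates the mixture) is judged, against c₂ = c₁ − ff/2. That choice
places the affected mean (exactly 50% in the two-mutation case, 50 + ff/2
in the one-mutation case) at the same distance from the cut-off in both
branches. Because the Gaussian sd depends weakly on the branch mean
(sd(50 + ff/2) ≠ sd(50)), the two branches' detection rates are identical
only where the tails saturate (ff ≥ 10 at n = 32,000); elsewhere they agree
to within 0.01 percentage points — always equal at the whole-percent
rounding the performance grid uses. The package computes both honestly
rather than forcing the equality.

## Population performance

Parameters (`PopulationParams`), with defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| `carrier_freq` (q) | 1/25 | CF carrier frequency (European populations) |
| `prevalence_odds` | 1/2499 | affected-pregnancy odds; consistent with q²/4 = 1/2500 under random mating |
| `panel_coverage` (a) | 0.834 | fraction of population *CFTR* mutant alleles detectable by the ACMG-23 panel |
| `cpm_trisomy7_prev` | 0.002 | trisomy-7 confined placental mosaicism (CPM) prevalence |
| `cpm_oxx_prev` | 0.001 | the OXX half of CPM: the extra chromosome 7 carries the maternal mutation |
| `p_parental_mutations_differ` | 0.5 | among carrier couples, the chance their mutations differ |

DR = (affected tail above c₁) × a², since an affected fetus needs a
detectable mutation from each parent and the two parental alleles are
independent draws under random mating; the ceiling is 100·a² ≈ 70%.

FPR enumerates every unaffected stratum with non-zero signal, rather than
only the dominant one — a test verifies the sub-dominant strata are
numerically negligible at the operating points instead of assuming it:

| stratum | weight | mean |
|---|---|---|
| carrier fetus, maternal origin | (q/2)·a·(1 − cpm_oxx) | 50 |
| same, with OXX CPM | (q/2)·a·cpm_oxx | 50 + ff/6 |
| mother carrier, fetus non-carrier | (q/2)·a | (100 − ff)/2 |
| carrier fetus, paternal origin | (q/2)·a | ff/2 |
| two mutations seen, fetus carries paternal only | q²·p_differ·(¼)·a² | (100 − ff)/2 vs c₂ |

The OXX CPM stratum exists because a trisomic placenta with two
mutant-bearing chromosome-7 copies contributes two-thirds (not half) of the
fetal fraction in mutant fragments, shifting the carrier mean up by ff/6 —
across the 51% cut-off for ff ≥ 6. Its contribution dominates the 0.002%
FPR at cut-off 51. Two modes are exposed: `tail` (default) integrates the
actual Gaussian tail of the shifted distribution; `conservative` counts the
whole stratum as positive. Both round to 0.002% at ff = 10. The OOX type
(extra chromosome without the mutation) shifts means downwards and is
modelled only through its negligible effect on DR (i.e. not at all).

OAPR = (DR/FPR) × prevalence odds, carried at full precision internally;
display strings follow the grid's conventions (DR to whole percent, "<0.1"
below 0.1; FPR to 0.001%, "<0.001" below 0.0005; odds as x:1 / 1:x, capped
at ">1000:1"). Sub-0.001% FPR cells make the corresponding OAPR values
sensitive to tail treatment; the renderer reports the computed values
without adjustment.

### Carrier-testing comparator

Parental carrier testing is modelled as: DR = a² (both mutations must be on
the panel), FPR = q²·¾ (carrier couples, three-quarters of whose
pregnancies are unaffected), OAPR = 1:3 from the within-couple Mendelian
ratio. Note the comparator's OAPR is *not* derived from the DR/FPR identity
— in the conventional presentation coverage enters the DR but not the
couple-prevalence FPR, so the identity does not apply to this strategy.
`compare_with_carrier_testing` derives the headline comparison (42-fold
OAPR advantage, 98% of invasive tests avoided) from the rounded reported
triples, matching how such comparisons are quoted; the full-precision
estimate is returned alongside.

### Resource arithmetic

Sites are amplified from the same plasma aliquot, so plasma volume is set
by the per-site count: n/2,400 ml (≈ 2,400 haploid genome-equivalents per
ml), i.e. 13.3 ml for n = 32,000; total fragments = panel size × n =
736,000 for the 23-site panel.

## Synthetic cohorts

`sample_pregnancy` / `simulate_cohort` emulate the counting pipeline at the
fragment-count level: parental carrier states at frequency q, mutation
identities drawn from the panel's allele-share distribution plus an
off-panel remainder (so per-allele detectability is a and parental
same/different mutation status emerges from the draw), Mendelian fetal
inheritance, OXX CPM at its prevalence among maternal-origin carrier
fetuses, and Binomial(n, m/100) mutant counts at each detectable site. A
mutation is "found" when its mutant count exceeds a configurable floor
(default 0 — the model has no sequencing-error channel, so any mutant
fragment is real); classification then applies the c₁/c₂ rule to the
predominant site. Fetal fraction is a fixed input per run: the test treats
ff as known, and no population ff distribution is assumed (none is
standard; callers can sweep ff instead).

What the generator deliberately does not emulate: sequencing errors and UMI
collisions, amplification bias (assumed fully corrected), maternal
mosaicism, de-novo mutations (expected means are provided, but their
detection logic is a separate problem), per-site variation in n, and
real-world ff measurement error. Passing tests therefore validate the
statistical model's internal consistency, not assay-level robustness.

`estimate_performance_mc` is the rare-event path: each stratum is simulated
separately at full replicate count and recombined with its analytic prior
weight — chosen over importance sampling for transparency (weights are the
same quantities the analytic FPR uses). Stratum standard errors use the
Agresti–Coull-adjusted rate ((k + 2)/(reps + 4)) so strata whose empirical
rate saturates at 0 or 1 keep an honest non-zero uncertainty; combined SEs
add in quadrature. Affected strata are weighted conditional on being
affected (a²·p_same one-mutation, a²·(1 − p_same) two-mutation, 1 − a²
undetectable with rate 0), so the combined positive rate is the DR itself.
Everything is deterministic given a `numpy` Generator seed; identical seeds
give bit-identical cohorts, estimates and CSVs.

Problem sizes: the validation suite runs 10⁵ replicates per stratum for the
stratified estimates and a 10⁶-pregnancy naive cohort for the
detection-rate cross-check — naive sampling sees ~400 affected pregnancies
per million, ample for DR, while the ~2 × 10⁻⁵ FPR is far below naive
resolution, which is precisely why the stratified path exists.

## Numerical choices and limitations

- Tails via `scipy.stats.norm.sf` / `binom.sf`; no continuity correction
  anywhere (the grid's printed values are reproduced without one).
- The binomial threshold count is ⌈c·n/100⌉ with the inclusive convention.
- `two_mutation_cutoff` rejects c₂ outside (0, 100); fetal fractions are
  validated to (0, 100) exclusive — boundary values are degenerate in the
  mixture model.
- The Gaussian model ignores overdispersion beyond binomial; with UMI
  deduplication this is the intended operating assumption, not a claim
  about any particular assay.
- The bundled panel file's per-mutation shares are synthetic placeholders;
  only their sum (0.834) is consequential, and `read_panel` accepts any
  user panel with the same two-column layout.
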