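# Methods

## The two-step incompatibility test

### Setting

Data are n independent mother–offspring pairs with a dichotomous phenotype
y ∈ {0,1}, per-SNP maternal and offspring genotypes coded as minor-allele
counts {0,1,2} (missing allowed), and optional numeric covariates. At a
bi-allelic locus the Mendelian-consistent mismatched genotype combinations
fall into four classes, M1 = (AA,Aa), M2 = (Aa,AA), M3 = (Aa,aa),
M4 = (aa,Aa); the combinations (AA,aa) and (aa,AA) are impossible under
Mendelian transmission and are treated as genotyping errors. An
incompatibility model is a non-empty subset of {M1..M4} declared high risk;
the eleven candidate models are the four singletons, the six pairs, and the
full set (Model 11).

### Step 1: entropy-based model selection

All entropies are in bits (base-2 logarithm, with 0·log 0 := 0). For case
proportion p, H(D) = −p log₂ p − (1−p) log₂ (1−p). A model's high/low-risk
split yields H(D|MFGI) = H(D|high)·P(high) + H(D|low)·P(low), where an empty
group contributes zero with weight zero, and the information-gain ratio
R = 1 − H(D|MFGI)/H(D) ∈ [0,1]. The candidate model maximises R over the
eleven models; ties are broken towards the fewest risk classes and then the
lowest model id (the most parsimonious choice — since the models are
enumerated singletons first, this equals first-in-enumeration order). When
H(D) = 0 the ratio is defined as 0.

The permutation guard shuffles phenotype labels B times, jointly for all
eleven models within a locus, recording each permutation's maximum ratio
R_b^max; the empirical p-value is the fraction of permuted maxima *strictly*
exceeding the observed R^max (ties count as non-exceedances). An optional
add-one estimator (1+Σ)/(1+B) is available but off by default. Selection
succeeds when the p-value falls below the cutoff τ; otherwise Model 11 is
the analysis model. τ must be ≥ 1/B to be attainable.

*Implementation identity.* Every ratio depends on a permuted label vector
only through the per-class case counts over the five classification classes
(compatible, M1..M4), whose joint permutation distribution is multivariate
hypergeometric. The engine therefore resamples those counts directly
(`numpy`'s multivariate hypergeometric generator) and evaluates all eleven
ratios vectorially from them. This is *exactly* equivalent in distribution
to shuffling labels — one count draw serves all models jointly, preserving
the dependence among the eleven ratios — and is two to three orders of
magnitude faster; a test verifies the two nulls agree.

*Degenerate inputs.* A single-class phenotype, a locus with no mismatched
pairs, or R^max = 0 yields no usable permutation null (a literal application
of the p-value formula would return p = 0 and "select" a meaningless model);
selection is skipped and Model 11 is used, flagged `defaulted`.

*Pooled null for multi-locus scans.* Scanning L loci with a per-locus null
would need B ≥ 1/τ permutations per locus. Instead the scan can pool: for
each of B permutations and each locus the maximum ratio is computed, all
L×B values form one null sample, and each locus's p-value is the fraction of
pooled values strictly exceeding its own observed maximum. This both cuts
computation (B = 20 suffices for hundreds of loci) and folds the scan's
multiplicity into the null. Families excluded at a locus (missing genotype
or Mendelian error) drop out of that locus only; degenerate loci contribute
nothing to the pool and default to Model 11.

### Step 2: likelihood-ratio test

The analysis model codes G_ic ∈ {0,1} per family, and a logistic regression

logit P(Y=1) = β₀ + β_m G_m + β_o G_o + (covariates) + β_ic G_ic

is fitted by maximum likelihood (statsmodels, Newton with an L-BFGS
fallback). H₀: β_ic = 0 is tested by the likelihood-ratio statistic against
the reduced model dropping only G_ic, referred to χ²(1); covariates enter
both fits so the test isolates β_ic. The selection step's effect on the null
distribution is controlled by the permutation guard, not by a df adjustment.
The odds ratio exp(β_ic) is reported with a 95% Wald interval
exp(β̂_ic ± 1.96·SE).

*Collinear G_ic.* If G_ic lies in the reduced design's column span
(constant, or duplicating a covariate), the LRT is identically zero and the
result is returned with statistic 0 and p = 1 (detected by a rank check).

*Separation.* With few cases, complete or quasi-complete separation drives
estimates to the boundary. Such fits are flagged `converged=False` and the
p-value is set to missing rather than fabricated; a Firth-type penalised
fallback is a documented extension point, deliberately not a default, so
that the estimator remains plain maximum likelihood. In simulation
experiments these replicates are excluded from the rejection denominator and
reported separately.

## The simulation engine

One population of N families is generated per experiment and samples are
redrawn from it across replicates:

1. Maternal and paternal genotypes are independent multinomial draws from
   the same law (symmetric mating): Hardy–Weinberg proportions
   ((1−q)², 2q(1−q), q²) for (aa, Aa, AA) given minor-allele frequency q
   (default 0.2), or an explicit (AA, Aa, aa) triple for Hardy–Weinberg
   disequilibrium (default (0.18, 0.47, 0.35)).
2. Offspring receive one allele per parent (heterozygotes transmit either
   with probability ½); paternal genotypes are then discarded to mimic the
   dyad design. Generated data contain no Mendelian errors by construction.
3. The liability z = α₀ + α_m G_m + α_o G_o + α_ic G_ic + ε with
   ε ~ N(0, σ²), α₀ = 0 and σ² = 1 by default, is thresholded at its
   *empirical* (1 − prevalence) quantile (default prevalence 5%), so the
   realised population prevalence matches the target up to rank rounding.
   G_ic is coded by the scenario's generating model.

Nine standard scenarios cover no effects (I), a single main effect of 0.4
(II maternal, III fetal), an incompatibility effect α_ic = 0.4 alongside
main effects (IV: α_m = 0.4; V: α_o = 0.4; VI: both 0.2), and
incompatibility only, parameterised by heritability h² ∈ {0.05, 0.10, 0.15}
(VII–IX). For the latter, with q the population fraction of incompatible
pairs under the generating model, σ_T² = α_ic² q(1−q) + σ² and
h² = 1 − σ²/σ_T² give the unique positive effect size
α_ic = √(h²σ² / ((1−h²) q(1−q))); q is read off the simulated population,
so for composite generating models it is the total incompatible fraction.

Samples are simple random draws of n families without replacement — no
case-control oversampling — so an n = 1000 sample at 5% prevalence carries
≈50 cases. Experiments report the fraction of replicates with LRT p < α
(default 0.05), plus the frequency with which each model ends up as the
analysis model. Per-replicate generators are spawned from a master seed
(`numpy` SeedSequence), making results reproducible and independent of
execution order.

### Desk-scale defaults

The default experiment profile is N = 100,000 with 500–4,000 replicates,
B = 2,000 permutations and τ = 2/B for selection arms — sizes chosen so a
full validation run completes in minutes on one CPU while keeping binomial
Monte-Carlo error near ±0.01 on type-I estimates. The full-scale design
(N = 10⁶, 11,000 replicates, B = 10⁴, τ = 10⁻⁴) is reachable through the
same configuration objects. Note that with one population per experiment,
population-level realisation noise adds to the binomial error; at
N = 100,000 this contributes roughly ±0.005 to rejection-fraction estimates
of small probabilities.

## Case-study-style scanning defaults

For single-locus analyses the defaults are B = 10,000 and τ = 10⁻⁴ (a
strict guard keeps the two-step test's size at the nominal level even when
main effects are present). For multi-SNP scans the defaults are the pooled
null with B = 20 per locus and τ = 0.05 — a deliberately loose cutoff that
maximises true positives at a small, known cost in selection-step type I
error. Input tables are wide TSV (one row per family; `<snp>_m`/`<snp>_o`
column pairs; `cov_*` covariates; missing token `NA`, configurable). Before
scanning, families missing more than 50% of maternal *or* offspring
genotypes are removed; per locus, families with a missing genotype or a
Mendelian-inconsistent pair are excluded from that locus only. Genotype
columns are oriented to count the minor allele using the *maternal* allele
frequency (mothers are population draws; offspring are not independent of
them), with a frequency of exactly 0.5 left unflipped and monomorphic loci
flagged; flipping the coding swaps M1↔M4 and M2↔M3, so orientation matters
for interpreting which model is selected. Raw p-values are reported (a
Bonferroni column is emitted for convenience but drives no decision).

## What the generator does and does not emulate

It reproduces the dyad design's essential structure: Mendelian dependence
between maternal and offspring genotypes, main effects confounded with
incompatibility classes (M1 pairs all have G_m = 2, so a maternal main
effect partially masks an M1 effect), liability-threshold case definition
and rare-disease sampling. It does **not** emulate linkage disequilibrium
between loci, covariate effects, population stratification,
ascertained/case-control sampling, X-linked or multi-allelic loci, or
parent-of-origin effects. Passing simulation tests therefore demonstrate
the statistical machinery's calibration and power under the stated
generating process, not robustness to those real-data complications.

## Known limitations and sensitivities

- **Case count drives everything.** Both the selection step's reliability
  and the LRT's power scale with the number of cases, not families. Under
  population sampling at 5% prevalence, power for a moderate effect
  (α_ic = 0.4) at n = 1000 (~50 cases) is modest (~0.3 for the two-step
  procedure vs ~0.09 for the full-model baseline under a Scenario-IV,
  Model-5 process); a case-control design with a 1:4 ratio at the same n
  roughly doubles it. Heritability-scale effects (h² ≥ 0.10) are detected,
  and the true model selected, nearly always even with ~50 cases.
- **Small-sample LRT.** With ~25 cases (n = 500 at 5% prevalence) the
  χ²(1) reference is slightly anti-conservative and ~4% of null replicates
  hit separation; the separation policy (exclude, flag) keeps the measured
  size near nominal, but alternatives (counting boundary LRTs) would
  measure ~0.067 rather than ~0.05.
- **Permutation resolution.** The empirical p-value has granularity 1/B;
  with the pooled scheme the effective resolution is 1/(L·B) but the null
  mixes loci, so per-locus calibration is approximate by design.
- **Tie-breaking.** With few cases several models can share R^max exactly;
  the parsimony-then-id rule is deterministic but arbitrary where the data
  genuinely cannot distinguish models.
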