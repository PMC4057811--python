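# mfgi — entropy-guided testing of maternal–fetal genotype incompatibility

Diseases of pregnancy (preterm prelabor rupture of membranes, pre-eclampsia,
hemolytic disease of the newborn, …) can arise not from the maternal or the
fetal genome alone but from specific *mismatches* between them — the classic
example being Rh incompatibility, where an Rh-negative mother mounts an
immune response against an Rh-positive fetus. Studies of such effects
genotype mother–offspring pairs and ask, SNP by SNP, whether particular
mismatched genotype combinations raise disease risk.

`mfgi` is a Python library (with a thin command-line interface) for
biostatisticians analysing such mother–offspring dyad data. At a bi-allelic
locus with minor allele A, the Mendelian-consistent mismatched combinations
of maternal and offspring genotypes (G_m, G_o) form four classes:

| class | mother | offspring |
|-------|--------|-----------|
| M1    | AA (2) | Aa (1)    |
| M2    | Aa (1) | AA (2)    |
| M3    | Aa (1) | aa (0)    |
| M4    | aa (0) | Aa (1)    |

An *incompatibility model* declares a non-empty subset of {M1…M4} "high
risk"; eleven biologically plausible subsets are considered (the four
singletons, the six pairs, and the full set — Model 11, which codes
incompatibility whenever the genotypes differ at all). Because the true
mechanism is unknown, the package implements a two-step procedure:

**Step 1 — select the model by information gain.** With case proportion p,
the phenotype entropy is H(D) = −p log₂p − (1−p) log₂(1−p). Each model's
high/low-risk split gives a conditional entropy
H(D|MFGI) = H(D|high)P(high) + H(D|low)P(low), and the information-gain
ratio R = 1 − H(D|MFGI)/H(D) is the fraction of phenotype entropy the model
explains. The model maximising R becomes the analysis model only if a
permutation test supports it: phenotype labels are permuted B times, the
maximum ratio R_b^max over all 11 models is recorded per permutation, and
the empirical p-value (1/B)Σ I(R_b^max > R^max) must fall below a cutoff τ;
otherwise Model 11 is used.

**Step 2 — test the effect by likelihood ratio.** The selected model codes
a binary indicator G_ic in the logistic regression

    logit P(Y = 1 | G_m, G_o) = β₀ + β_m G_m + β_o G_o + β_ic G_ic (+ covariates)

and H₀: β_ic = 0 is tested with a 1-df likelihood-ratio test; exp(β_ic) is
the odds ratio of the incompatible combinations, reported with a 95% Wald CI.

The package also ships the liability-threshold simulation engine used to
validate the procedure: parental genotypes under Hardy–Weinberg equilibrium
or disequilibrium, Mendelian offspring, a latent liability
z = α + α_m G_m + α_o G_o + α_ic G_ic + ε dichotomised at 5% prevalence,
heritability-calibrated effect sizes, and experiments estimating type I
error, power, and the frequency with which the true generating model is
selected.

## A worked example

Simulate a population in which pairs jointly carrying three copies of A
(Model 5 = {M1, M2}) are at elevated risk, draw a study sample of 1000
pairs, and run both steps (`examples/02_entropy_model_selection.py` and
`examples/03_two_step_association_test.py`):

```
Candidate model: 5 (R_max = 0.08229)
Permutation p-value over B=2000: 0.0
Final analysis model: 5 (defaulted: False)
```

Step 1 found that Model 5 explains ~8% of the phenotype entropy in this
sample, and none of 2000 label permutations produced a larger maximum —
so Model 5, the true generating model, becomes the analysis model. Step 2
(here on a sample with a maternal main effect co-present) then quantifies
the effect:

```
Selected model:   1
LRT statistic:    12.286 (1 df)
p-value:          0.0004563
Odds ratio:       7.826 [2.362, 25.923]

Full-model (Model 11) baseline p-value: 0.0412
```

The selected model isolates the informative mismatch class: pairs in that
class have ~7.8 times the odds of disease, with p ≈ 5·10⁻⁴, while the
non-selective Model-11 baseline — which mixes the informative class with
inert ones — only reaches p ≈ 0.04. `examples/` contains five such
narrative scripts, from pair classification to a pooled-null multi-SNP scan;
`docs/methods.md` documents the statistical machinery and its design
choices.

The CLI mirrors the library for shell use:

```
mfgi scan pairs.tsv --out results.tsv --covariates cov_age --pooled-null \
     --permutations 20 --tau 0.05 --seed 1
```

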