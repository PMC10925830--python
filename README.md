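# walleyeped

Parentage-based analysis of reproductive success for inland fish
populations genotyped on amplicon SNP panels — built around the question of
whether longer, older or faster-growing walleye (*Sander vitreus*) females
are more likely to leave surviving age-0 offspring, and how much of the
variation is simply interannual.

The package takes a genotype table (samples × biallelic SNP loci, dosage
0/1/2 with missing calls), a fish metadata table (capture year, life stage,
sex, total length, age), and produces:

1. **Panel QC** — five-stage filtering: locus call rate < 80 %,
   per-locus inbreeding coefficient |F_IS| = |1 − Ho/He| > 0.08, sample
   call rate < 80 %, contamination score > 0.4 (standardized heterozygosity
   excess), duplicate genotypes (> 90 % identity, one kept at random), then
   linkage thinning (one SNP per amplicon; drop one of any pair with a
   standardized index of association r̄_d > 0.25).
2. **Cohorting and parentage** — fall juveniles are assigned to cohorts by
   total length (age-0 ≤ 190 mm; age-1 ≤ 275 mm, previous year's cohort),
   then to candidate mothers and fathers with a per-offspring Bayesian
   posterior over each sex's candidates plus an explicit unsampled-parent
   class, built from multilocus Mendelian-transmission likelihood ratios
   with a genotyping-error model. Assignments are accepted when the
   posterior exceeds 0.90; unsampled mates are recovered by full-sib
   clustering of offspring that share one assigned parent.
3. **Successful-spawner estimation (N_s)** — treating assigned offspring as
   incidence samples and parents as species, Chao2 and first-order
   jackknife richness estimators with standard errors, plus permutation
   accumulation curves.
4. **Reproductive-success models** — success for fish *i* in year *t* is 1
   if at least one accepted age-0 assignment exists. A fish is known alive
   in *t* if sampled or assigned as a parent in *t* or later; remaining
   unknown fish-years are resolved by sequential Bernoulli survival draws
   at the lake's long-term natural mortality rate (19.8 %/yr), repeated
   over many iterations. Each iteration fits sex-specific logistic models
   (`logit P(success) = β₀ + β₁·trait`, traits: total length, age,
   growth-rate percentile) and an eight-model candidate set (null, age,
   year, growth, and their combinations, year categorical) ranked by BIC;
   medians of coefficients, Wald SEs/p-values, Nagelkerke R², odds ratios
   and the per-iteration lowest-BIC tally are reported.

A truth-known simulator (`walleyeped.synthetic`) generates populations,
pedigrees, genotypes and the multi-year survey with the statistical
structure the analysis assumes, so every stage is testable without field
data.

## Worked example

```python
import walleyeped as w

cfg = w.RunConfig(out_dir="demo_run", sim=w.SimConfig(seed=11),
                  n_iter=100, n_perm=50, seed=11)
res = w.run_all(cfg)
```

With the default simulator settings (2000 adults, 300 loci, 19.8 % annual
mortality, a female growth effect of 0.676 log-odds and a strong 2018 year
effect) this prints/writes, in about 20 s:

```
QC: 2331 samples x 300 loci retained
N_s estimates:
 year  s_obs   n  f1  f2  chao  chao_se  jack1  jack1_se
 2017    206 208 144  56 390.3     41.6  349.3       9.4
 2018    393 394 253 111 680.6     48.4  645.4      13.5
 2019    149 146 109  33 327.8     48.2  257.3       8.2
 2020    159 154 110  37 321.5     42.8  268.3       8.4
Female growth model (medians over 100 iterations):
            coef     se  odds_ratio  or_lo95  or_hi95
intercept -1.765  0.113       0.171    0.137    0.214
growth     0.708  0.186       2.030    1.412    2.923
Model selection: females -> growth + year (100/100 iterations, dBIC 7.3);
                 males   -> year only   (100/100 iterations)
```

Reading it: the simulated truth put 476/685/290/288 successful spawners in
2017–2020 — the Chao estimates track the 2018 spike and the estimators'
known downward bias at incomplete detection. The recovered female growth
slope (0.708, true 0.676) says a female at the 100th growth percentile has
about twice the odds (OR ≈ 2.0) of producing a surviving age-0 offspring
as one at the 0th; the BIC tally attributes most explained variation to
year, with growth retained for females only.

The same stages are available as CLI subcommands
(`walleyeped simulate | qc | assign | accumulate | success | report |
run-all`); see `walleyeped --help`.

## Scope notes

The joint sibship/parentage maximum-likelihood engines used in field
studies are replaced here by independent per-offspring Bayesian assignment
plus post-hoc sibship clustering — a documented simplification that keeps
the accept/reject semantics testable (see `docs/methods.md`). Spatial
spawning structure, egg/larval dynamics and mark–recapture abundance
estimation are out of scope.
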