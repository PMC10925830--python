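# Methods

## The estimation problem

In an iteroparous broadcast spawner sampled annually — spawning adults in
spring, age-0/age-1 juveniles in fall — we want to know (a) which adults
produced surviving offspring each year, (b) how many successful spawners
(N_s) there were, and (c) whether parental traits (total length, age,
growth-rate percentile) shift the probability of producing at least one
surviving age-0 offspring, over and above year-to-year environmental
variation. Genotypes from an amplicon SNP panel link offspring to parents;
everything downstream is built on those assignments.

## Panel quality control

Five filtering stages run in a fixed order, single pass (statistics are
computed on the matrix as each stage sees it and earlier stages are never
revisited): locus call rate ≥ 0.80 → |F_IS| ≤ 0.08 → sample call rate
≥ 0.80 → contamination score ≤ 0.4 → duplicate removal; then linkage
thinning (one SNP per amplicon, then pairwise r̄_d ≤ 0.25).

* **F_IS** is estimated as 1 − Ho/He with He = 2p̂(1−p̂) from called
  genotypes, no small-sample correction. Monomorphic loci (He = 0) are
  removed at this stage and flagged: F_IS is undefined for them and they
  carry no parentage information. The sampling SD of F_IS is roughly
  √(1.5/n), so at survey scale (n ≳ 1500 samples) a clean panel loses
  ≲ 2 % of loci to the ±0.08 band, while small panels lose noticeably more
  — a property of the statistic, not a bug.
* **Contamination score** = 1 − E[het]/observed-het over a sample's called
  loci, clamped to [−1, 1]. Read-level allele-balance statistics need raw
  counts that hard genotype calls do not carry; mixed-template samples read
  heterozygous wherever their two templates differ, which this score
  captures. The simulator implements exactly that mixing model.
* **Duplicates**: identity = matching calls / co-called loci; groups are
  connected components of the > 0.90 graph; one member is retained by a
  seeded uniform draw. Pairs with < 20 co-called loci are treated as
  non-duplicates (identity undefined) with a warning.
* **r̄_d** is computed per locus pair as the Pearson correlation of the two
  loci's per-pair absolute dosage differences over all sample pairs
  co-called at both loci. Because dosages are categorical, all pair sums
  reduce to sums over the 3×3 joint genotype table, which makes the
  all-pairs matrix cheap (nine matrix products). Greedy thinning removes
  the lower-call-rate member of the worst pair first (ties: lower
  minor-allele frequency, then lexicographically later id).
* **Idempotence caveat**: re-running QC on its own output removes nothing
  *when the sample set is stable*. If samples were removed, per-locus
  statistics recomputed from the retained matrix shift slightly, and a
  borderline F_IS locus can drift across the cutoff on a second pass. No
  implementation that recomputes statistics from its input can avoid this;
  the invariant is therefore exact only in the stable-sample case, which is
  what the tests assert.

## Cohorting and parentage

Fall juveniles ≤ 190 mm TL are age-0 of the capture year; 190–275 mm are
age-1 and belong to the previous year's cohort; longer fish are excluded
(age-1 vs age-2 cannot be separated reliably by length above that). Age-1
assignments are used only to gauge sampling completeness via the overlap of
parent sets between a cohort's age-0 and age-1 detections (both overlap
denominators — union and age-0 parent count — are reported, since either
convention is defensible).

Assignment is per offspring and per sex. For candidate observed call `po`
and offspring observed call `oo` at a locus with alt frequency p:

    L_par(oo | po) = Σ_t P(t | po) Σ_g T(g | t, p) P(oo | g)

with HWE-prior Bayes posteriors for the candidate's true genotype, the
transmission kernel T (one allele from the parent, the other from the
population), and an error model where an observed call equals the truth
with probability 1 − e (default e = 0.01) and is otherwise an independent
HWE draw — under which the background (unrelated) likelihood is exactly the
HWE probability of the offspring call and missing calls contribute a ratio
of 1. The posterior over {candidates} ∪ {unsampled} uses a uniform prior
1/(n+1); the best candidate is accepted when its posterior exceeds 0.90
strictly. An accepted mother/father pair is additionally scored as a trio
against the one-parent and no-parent alternatives; fish of unknown sex sit
in both candidate sets and the higher posterior wins if one tops both.

This replaces joint full-pedigree sibship/parentage maximum likelihood with
independent per-offspring assignment plus post-hoc full-sib clustering
(pairwise full-sib vs half-sib likelihood ratio given the shared parent;
clusters = connected components of the LR > 1 graph). The simplification
keeps the accept/reject semantics and is fully testable; it gives up joint
consistency constraints across offspring, so its assignment probabilities
are an analogue of, not a replica of, a pedigree engine's. Mate counts per
parent and year count distinct co-parents, sampled or inferred-unsampled.

## Successful-spawner estimation

Each assigned offspring is one incidence sample; each assigned parent a
species. With f1/f2 the parents seen in exactly one/two offspring,
A = (N−1)/N:

* Chao2: S_obs + A·f1²/(2f2); bias-corrected S_obs + A·f1(f1−1)/(2(f2+1))
  when f2 = 0; variance per the incidence-based Chao (1987) formulas with
  the f2 = 0 variant (formulas in the code).
* First-order jackknife: S_obs + f1·A, with the leave-one-sample-out
  variance ((N−1)/N)·Σ_j (s_j − f1/N)², s_j = singletons carried by
  offspring j. (Both estimators and SEs were cross-checked against an
  independent R implementation, vegan::specpool.)

Offspring with zero assigned parents are excluded from the incidence by
default (they carry no parental genotype information; switchable, and both
N conventions can be computed). Accumulation curves average distinct-parent
counts over random offspring orderings with a 95 % permutation envelope.
Calibration note: these estimators equal the truth only when detection is
saturated (every true parent carried by several assigned offspring). When
many true singleton parents exist — typical for a broadcast spawner with
1–2 offspring detected per parent — the jackknife legitimately estimates
more spawners than were detected, and a self-contained bias simulation
(`ns_bias_simulation`) quantifies bias/RMSE under configurable detection.

## Mortality-corrected success models

Success for fish × year is 1 iff ≥ 1 accepted age-0 assignment that year;
only age-3+ fish-years enter; sex comes from the survey or from the
parentage role when the survey recorded it unknown. Growth percentile is
the midrank of the fish's length within the sex- and age-specific reference
distribution at first ageing ((n_less + 0.5·n_equal)/n), held constant for
life; total length is usable only in years the fish was handled.

A fish is known alive in year t if sampled or assigned as a parent in t or
any later year. From the year after the last known-alive year, survival is
drawn Bernoulli(1 − 0.198) sequentially; dead fish-years are excluded from
that iteration. Years before the first encounter are covered by the
backward implication of the known-alive rule, so imputation only runs
forward. The inclusion probability k years past the last encounter is
therefore (1 − 0.198)^k by construction, which the calibration test checks
empirically.

Fits are maximum-likelihood logistic regressions (IRLS via statsmodels GLM,
tolerance 1e-8, ≤ 100 iterations) with Wald SEs and p-values, Nagelkerke
R² = [1 − (L0/L1)^(2/n)]/[1 − L0^(2/n)], BIC = −2logL + k·ln n, odds ratios
exp(β) with 95 % CI exp(β ± 1.96·SE). Complete separation or a
zero-variance covariate flags the iteration's fit, which is dropped from
the medians with a logged count; > 50 % failures aborts with diagnostics.
Medians across iterations are reported for every statistic — including the
p-value, which follows the source convention for this analysis and is a
summary of the iteration distribution, not a combined test. One master
seed spawns independent per-iteration child seeds, so results are
reproducible and invariant to iteration order.

Model selection runs the eight-model candidate set (total length excluded:
it cannot be carried across years), tallies the per-iteration BIC minimizer
(ties to the lower model id, logged), then reruns fresh iterations with the
winner for median coefficients, its BIC weight exp(−ΔBIC/2)/Σ and its
ΔBIC to the runner-up.

## The simulator, and what passing tests do and do not show

`SimConfig` defaults emulate the study design: 2000 adults (the magnitude
of the lake's adult population estimates), ages 3–15, 1:1 sex ratio,
sex-specific von Bertalanffy mean length-at-age (L∞ = 560/480 mm F/M,
k = 0.25, t0 = −0.5) with the growth percentile mapped to a length offset
through the normal quantile at CV 0.08; 19.8 % annual mortality; spring
adult surveys in all but the final year at 0.35 capture probability (~1250
distinct adults genotyped) and fall juvenile surveys at 0.8 (~1100
juveniles); a 300-locus panel with allele frequencies in (0.2, 0.8), 1 %
genotyping error (HWE-redraw model, matching the assignment likelihood),
3 % missingness, 2.5 % contaminated and 6.7 % duplicated samples; female
success log-odds −1.73 + 0.676·percentile + year effect (0, 1.2, 0, 0.2) —
a strong second-year pulse; zero-truncated-Poisson mate counts with mean
1.4 and offspring counts max(m, 1 + Poisson(0.4)) distributed so every
drawn mate fathers at least one offspring (so realized mate counts match
the configured mean). A juvenile missed as age-0 can be captured as age-1
the following fall; a juvenile sampled as age-0 is not re-entered as age-1,
which understates age-1 sample sizes relative to a survey where shed tags
cause re-genotyping — the duplicate-sample mechanism covers that QC path
instead.

What the simulator does **not** model: spatial spawning-site structure,
within-season timing, family-correlated survival, null alleles and
paralogs (F_IS outliers arise only from sampling noise and contamination),
linkage between panel loci, and ageing error. Passing recovery tests
therefore demonstrate that the pipeline's inference is correct when its
model assumptions hold — not that those assumptions hold in any particular
lake.

## Numerical and design choices

* Likelihood tables are precomputed per locus (4×4 observed-call tables,
  -inf log-ratios for Mendelian exclusions at e = 0), so assignment is a
  table-gather over candidates × loci; trio tables are 4×4×4.
* Unsampled-parent prior mass 1/(n_candidates+1): uninformative, exposed in
  configuration.
* Recovery tests at study scale use truth-derived assignments (perfect
  parentage) for the statistical module, isolating it from assignment
  error, which the clean-conditions parentage test covers separately; the
  female model sample is ~950–1100 fish-year rows per iteration at
  n_adults = 900.
* BIC identifiability: at a true growth odds ratio of 2 and ~1000 rows the
  Wald z is ≈ 2.5 while the BIC penalty for one parameter is ln(n) ≈ 6.9,
  so growth+year vs year-only is a coin flip *by design of BIC*. The
  slope-recovery check therefore runs at OR = 2, while the model-selection
  recovery scenario uses a growth log-odds of 1.0, which clears the
  penalty; both choices are fixed in the tests.
* Problem sizes in tests and the acceptance script (150–900 simulated
  adults, 50–300 loci, 100–200 imputation iterations, 10⁴ calibration
  draws) are chosen so each check is statistically decisive at a few
  seconds' cost; the full-scale pipeline run in the README takes ~20 s.

## Known limitations

* Per-offspring assignment can accept a wrong parent when panels are small
  and candidate sets large; the trio score flags incompatible pairs but
  singles are kept if individually accepted.
* The contamination score loses power for contaminant fractions far from
  50 % and for related templates.
* Median-of-iterations p-values have no frequentist guarantee; they are
  reported for comparability with the source convention.
* The overlap diagnostic and N_s estimators assume closed cohorts;
  immigration would bias both.
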