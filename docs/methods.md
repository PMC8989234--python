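# Statistical methods and generator design

This note records the models, algorithms, numerical choices and known
limitations behind `crcpear`. The package reimplements the analysis of a
family-based cohort study of incident colorectal cancer: a carrier model
for a single intronic variant, a battery of resampling defenses, and a
discriminant analysis of 16 promoter CpG sites — exercised throughout on a
synthetic family-cohort generator whose ground truth is known.

## 1. Genotype statistics (`genetics.py`)

**Allele frequencies.** The minor-allele frequency is
`(2·TT + TG) / (2n)`; carriers are `TT + TG`.

**Exact Hardy–Weinberg test.** Conditional on the observed allele counts,
the number of heterozygotes under random mating has the distribution

```
P(n_het | n, n_minor) ∝ 2^{n_het} · n! / (n_AA! · n_het! · n_BB!)
```

normalised over all heterozygote counts with the parity of `n_minor`.
The two-sided p-value is the sum of probabilities no greater than the
observed one (minimum-likelihood convention). Probabilities are evaluated
with `gammaln` in log space, so the test is exact for cohort-sized tables.
The unit tests replay the full enumeration independently on a grid of
tables.

**Pooling decision.** Carriers only, TT-vs-TG indicator in the clustered
proportional-hazards model, unadjusted and sex/age-adjusted; pooling of the
minor-allele homozygotes with the heterozygotes is declared when the
smaller Wald p is at least 0.05. With an empty genotype class or no carrier
events the contrast is not estimable and pooling is forced (flagged).

## 2. Proportional-hazards machinery (`coxph.py`)

**Partial likelihood.** Breslow tie handling by default (the simulated
event times are continuous, so ties are measure-zero); Efron is available
behind a flag. The fitter is Newton–Raphson with step-halving on the
log-likelihood, convergence at score norm `1e-9`, starting from zero. The
linear predictor is max-shifted before exponentiation; the shift cancels in
every ratio used by the score and information and contributes a constant to
the log-likelihood within one fit, so step-halving comparisons are valid.

**Cluster-robust variance.** Score residuals (Therneau–Grambsch form,
cumulative-hazard increments weighted by the subject's risk) are summed
within each pedigree; the sandwich is `I⁻¹ (Gᵀ G) I⁻¹` with `G` the matrix
of pedigree score sums. Singleton clusters reproduce the ordinary robust
variance exactly. The implementation was checked against
`R survival::coxph(..., cluster(pedigree_id), ties = "breslow")` — the
coefficients and robust standard errors agree to six decimals — and the
test suite re-verifies against `lifelines` at every run.

**Proportionality diagnostic.** A supremum (Kolmogorov-type) test on the
standardised cumulative score process: the observed statistic per term is
the maximum of |cumulative score| over event times; its null distribution
is simulated with standard-normal multipliers on the per-event score
increments, including the correction term `Icum(t) I(τ)⁻¹ · (total score)`
that accounts for estimating the coefficients (Lin–Wei–Ying wild
resampling). The reported p is `(exceedances + 1) / (R + 1)`. Under a true
proportional-hazards model the unit suite confirms rejection near the
nominal level.

**Cumulative incidence.** Unadjusted curves are one minus the
Kaplan–Meier estimator with Greenwood standard errors. Adjusted curves fit
a per-group Cox model on the adjustment covariates, accumulate the Breslow
baseline hazard, and directly standardise by averaging the predicted
incidence over the whole cohort's covariate distribution. Baseline
increments and standardisation risks are computed under one shared
max-shift, since only their product is shift-invariant. The delta-method
standard error reflects baseline-hazard uncertainty only.

## 3. Resampling defenses (`resampling.py`)

**Permutation null.** Carrier labels are reassigned to a uniformly random
subset of the observed carrier count; outcomes, covariates and pedigree
structure stay fixed; the fully adjusted clustered model is refitted each
run. Reported: the count of runs with carrier Wald p below the observed
significance level and the smoothed permutation p
`(count + 1) / (runs + 1)`. With ~1.3% expected exceedance, 1000 runs give
a standard deviation of about ±3.6 runs around 13.

**Case-exclusion bootstrap.** For each k, each run deletes k uniformly
chosen incident cases and refits. Retention is the fraction of runs
keeping p < 0.05; the pooled mean hazard ratio and its normal-theory 95%
CI aggregate every run of every k.

## 4. Methylation discriminant analysis (`plsda.py`)

**QC.** Duplicate percent measurements are kept as their mean unless the
pair standard deviation `|d₁ − d₂|/√2` reaches 5 percentage points.

**Transformation.** Each site is rank-inverse-normal transformed with the
Blom offset 3/8 (average ranks for ties; missing values propagate; subjects
with any missing site are excluded from the model).

**Risk standardisation.** Case status is regressed on sex, age, BMI, the
cholesterol ratio, creatinine, smoking, drinking, antiplatelet use and the
measurement-to-diagnosis time interval by logistic regression; the response
residual (observed minus fitted probability) is centred and scaled to unit
variance and serves as the continuous PLS outcome. The fit is accepted
whenever it converges with bounded coefficients and fitted probabilities
not pinned to 0/1 on the wrong side of the outcome — with a rare outcome,
legitimately tiny fitted probabilities must not trigger the fallback. On
genuine separation the adjustment falls back to linear-probability
residuals with a warning.

**PLS1.** NIPALS with X- and y-deflation on column-standardised data;
coefficients `B = W (PᵀW)⁻¹ q`. The test suite checks predictions against
`scikit-learn`'s `PLSRegression` to 1e-8.

**Factor selection.** Leave-one-out PRESS for factor counts 0..8, with the
standardisation recomputed inside every training fold. The van der Voet
test compares each candidate's squared cross-validation residuals with
those of the PRESS-minimising count by sign-flip randomisation of the
paired differences; the chosen model is the smallest count whose two-sided
p exceeds 0.10.

**VIP and V-plot.** Wold's variable importance in projection (the squared
scores sum to the number of sites, 16). The V-plot places each site by its
VIP against the z-scored correlation between the transformed site and the
adjusted outcome; sites with VIP > 1.1 are classified higher-risk
(positive rescaled correlation) or lower-risk (negative).

## 5. Descriptive statistics (`descriptives.py`)

Between-group comparisons use the large-sample z-test on means and
Fisher's exact test on 2×2 tables. Paired changes use the paired t-test
(continuous) and McNemar's test (binary) — chi-square without continuity
correction when at least 10 discordant pairs exist, the exact binomial
otherwise. Odds ratios use the 2×2 cross product with the Woolf interval
(Haldane–Anscombe 0.5 correction on a zero cell, flagged) or logistic
regression when covariates are supplied; the two coincide exactly without
covariates. These are textbook primitives and deliberately delegate to
scipy/statsmodels.

## 6. Synthetic cohort generator (`simulate.py`, `config.py`)

**Pedigrees.** 2532 participants: 439 singletons and 278 families whose
sizes follow a truncated geometric law rescaled to the remaining 2093
members. Families of three or more may extend over two generations
(founder couple, children, occasional in-cohort spouses); latent
out-of-cohort parents connect sibships.

**Genotypes.** Founders draw alleles at minor-allele frequency 0.096 under
Hardy–Weinberg equilibrium; descendants inherit one allele from each
parent (Mendelian transmission by generation depth, vectorised).

**Covariates.** Continuous covariates are family-correlated normals
(intra-class correlation 0.2) clipped at physiologic bounds, with total and
HDL cholesterol correlated at 0.15 and the ratio derived; binary covariates
are probit-thresholded family-correlated normals.

**Survival.** Event times are exponential given the linear predictor
(true carrier log-hazard `log 2.17`, a small age effect); censoring is
uniform over 8.2–29.6 years of follow-up. The baseline rate is calibrated
by bisection so the expected number of observed events is 49.

**Methylation.** A 929-subject subset with 16 incident cases measures 16
sites as `expit(site mean + FΛᵀ + noise + case · shift)`: two latent
factors with loadings giving a mean absolute pairwise correlation above
0.3, noise SD 0.9 on the logit scale, and planted case effects at sites 2
and 13 (protective) and 11 and 12 (deleterious), each scaled to the site's
total logit SD. Measurement-to-event time intervals follow asymmetric
Laplace laws matched to the observed quartiles (cases measured after
diagnosis more often than non-cases).

**Planted-effect scale.** The planted effect multiplier is a calibrated
constant: it was swept once against the generator's own power goals —
recovery of all four planted sites at VIP > 1.1 in at least 90% of seeds
and a two-factor van der Voet selection in at least 80% — and frozen at
1.4 (12 seeds per sweep point; confirmation over 30 fresh seeds gave 90%
two-factor selection and 100% site recovery). Smaller multipliers (0.6–1.0)
leave the PRESS curve too flat: the randomisation test then selects zero
factors in most seeds.

## 7. Reproducibility experiments (`experiments.py`, `scripts/acceptance.py`)

All experiment randomness derives from one base seed through
`derive_seed(base, i) = (base·1000003 + 7919·i + 1) mod 2³¹`. The
acceptance script recomputes eight benchmark quantities; two
(`t5`, `t6`) run on a *screened* cohort — the first seeded cohort whose
full-data carrier Wald p falls in [0.011, 0.015] — emulating analysis of a
dataset selected by the strength of its observed association.

**Known marginality.** The pooled case-exclusion mean hazard ratio (`t6`)
sits slightly below its nominal benchmark of 2.16. This is structural: the
generator's clustered standard error for the carrier term is about 0.29,
a little smaller than the benchmark study's 0.31, so screening on
p ≈ 0.013 selects cohorts with hazard ratios around 2.03–2.20 (expectation
≈ 2.09) rather than ≈ 2.16. The Cox estimates themselves are validated
exactly against R; we report the honest value rather than retune the
generator or reselect seeds.

## 8. Numerical and engineering choices

* Newton with step-halving, score-norm tolerance 1e-9, max 100 iterations.
* Max-shifted linear predictors everywhere `exp(η)` appears; shared shifts
  where absolute (not ratio) quantities are needed.
* Exact HWE in log space via `gammaln`.
* Permutation and bootstrap refits reuse the vectorised Breslow derivative
  code (~30 ms per 2532-subject fit), keeping 1000-run experiments in the
  tens of seconds.
* `numpy.random.Generator` with `SeedSequence.spawn` inside the generator:
  pedigrees, genotypes, covariates, survival and methylation each consume
  an independent stream, so adding draws to one stage never perturbs
  another.
* Text-only outputs: TSV tables (methylation as percent, two decimals) and
  JSON reports.

## 9. Limitations

* The generator plants a proportional-hazards carrier effect; the supremum
  test is exercised for calibration, not for detecting planted
  non-proportionality.
* Adjusted cumulative-incidence standard errors ignore coefficient
  uncertainty (baseline-hazard term only).
* Efron ties are supported for the point estimate and model covariance;
  robust score residuals under Efron use tie-group-averaged denominators,
  an approximation that is exact without ties (the default data are
  tie-free).
* The two-generation pedigree machinery is a structural sketch: depth is
  at most two, and spouses enter the cohort with a fixed small
  probability.
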