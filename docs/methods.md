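# Methods

`cyclevag` implements a longitudinal analysis of the vaginal microbiota
over one menstrual cycle — roughly 61 women sampled at four visits timed
to the follicular (F), ovulatory (O), early-luteal (EL) and late-luteal
(LL) phases — together with a synthetic cohort generator that provides
ground truth for every estimator. This note records the models, the
defaults and the design choices where the design was genuinely open.

## The synthetic cohort generator

**Compositional model.** Each woman is assigned a community state type
(CST) regime from a categorical distribution (defaults: the five classic
regimes at frequencies I 31.6 / II 12.7 / III 38.2 / IV 14.1 / V 3.3 %,
renormalized to sum to 1). For each sample and taxon a latent
log-abundance is

```
latent[w,t,j] = baseline[regime_w, j] + b[w,j] + slope_j * t
              + sum_h c[h,j] * z[w,t,h] + eps[w,t,j]
```

with `b ~ N(0, sigma_b^2)`, `eps ~ N(0, sigma_e^2)`, visit `t` in 1..4.
Compositions are the softmax of the latents (a logistic-normal model —
the natural conjugate of the CLR-based downstream analysis) and counts a
multinomial draw at a lognormal library size (mean 138,000 reads,
CV 0.25). The variance split is controlled by `icc_target`:
`sigma_b^2 = icc_target * latent_total_var`, so the latent intraclass
correlation of every taxon is known exactly. Defaults `icc_target = 0.8`,
`latent_total_var = 1.25` give `sigma_b = 1`, `sigma_e = 0.5` — a strongly
person-specific microbiota, which is the regime the analysis is designed
to detect.

**Regime baselines.** The ~24-taxon default panel puts the dominant
marker species of each *Lactobacillus*-dominated regime ~5 latent-log
units above background (softmax share typically >60%), keeps *L. iners*
and *L. crispatus* present in every regime (their prevalence in healthy
cohorts exceeds 90%), and spreads CST-IV mass over several anaerobes
(*Bifidobacterium vaginale*, *Prevotella*, *Fannyhessea*, *Finegoldia*,
*Anaerococcus*, *Dialister*, ...).

**Hormones.** Serum levels are lognormal around a per-visit profile mean
with a woman-level intercept; the `-(sb^2+sw^2)/2` term makes the
expected level equal the profile, and positivity needs no truncation.
17-beta estradiol (BES17) and LH peak at the ovulatory visit,
progesterone in the luteal visits, prolactin is flat; SDs are on the log
scale (≈ coefficients of variation). The paper-equivalent study gives no
within-woman hormone variances, so these are free, surfaced config
parameters, chosen at typical immunoassay magnitudes and not revisited.

**Injected effects.** `visit_effects` adds a linear latent slope per
visit unit to chosen taxa; `hormone_effects` couples a taxon's latent to
the *within-woman log-scale fluctuation* of a hormone (per 1 SD). Both
are recorded in `GroundTruth` exactly as used, enabling parameter-recovery
tests. On the CLR scale an injected latent slope `s` on one of `D` taxa
appears (for a rare taxon) as approximately `s * (1 - 1/D)` — with the
24-taxon panel a 4% attenuation, well inside the recovery tolerance used
in the tests.

**The study-like effect pattern.** `study_effects()` bundles a default
injected scenario: visit trends in the non-*crispatus* lactobacilli,
streptococci and *Dialister* (±0.15-0.25 latent-log units per visit) and
nine negative hormone-taxa couplings concentrated on 17-beta estradiol
and LH for anaerobe taxa plus one prolactin-*B. vaginale* coupling. All
couplings use one common magnitude, 1.0 latent-log unit per within-woman
hormone SD (about one latent-total-SD). The magnitude is anchored to
detectability: in the emulated study design the reported hormone-taxa
associations were detected at FDR < 0.2 with n = 61 women, so the
injected couplings are sized to be detectable at that threshold under
the same design; the *pattern* (which hormones, which taxa, all
negative) is what the scenario fixes, not per-pair strengths.

**Missingness** is completely at random per (woman, visit) at rate 0.16,
except visit 1, which is never dropped: the self-vs-random procedure
anchors on each woman's first collection. 0.16 makes the expected
retained row count ≈ 212 of 244, matching the QC-passing sample count of
the emulated study design.

**Exchangeable nulls.** Regime membership is itself a persistent
within-woman signal, so `icc_target = 0` alone does not make samples
exchangeable. `null_config()` therefore fixes a single regime, zero ICC
and no injected effects; all type-I-error calibrations use it. This also
defines the scope of the latent-ICC invariant: the one-way ANOVA ICC of
CLR abundances matches `icc_target` only under a single regime.

**What the generator does not emulate:** ASV-level structure, taxonomic
misassignment, batch effects correlated with composition, menses-phase
perturbations, non-CLR-linear hormone responses, or real VALENCIA
reference centroids (tests use synthetic centroids). Passing tests
demonstrate correctness of the estimators under a logistic-normal world,
not the fidelity of any particular biological effect size.

## QC and preprocessing

Samples are removed if input reads < 80,000, post-trimming reads
< 60,000, or a negative control in their library batch carries > 500
reads (reason codes `low_input`, `low_survived`, `contaminated_batch`;
rules checked in that order). Rare taxa are dropped unless they have ≥5
reads in ≥2 samples (inclusive boundaries). Subsampling to a fixed depth
is a without-replacement multivariate-hypergeometric draw from the count
vector — the count-space analogue of subsampling reads.

CLR uses `ln(x + eps) - mean_j ln(x_j + eps)` with `eps` defaulting to
half the minimum nonzero relative abundance of the table (logged in the
output; configurable). Model taxa are filtered at prevalence strictly
> 20% and mean relative abundance strictly > 0.10%.

Covariate adjustment is per-taxon OLS residualization on a cumulative
ladder of ten designs: model 1 none (centering), model 2 + technical
covariates (Qubit_DNA, Qubit_Library, Total_counts), then + Age,
+ sex_less_than_two_days, + Pregnancy_category, + Pill_use,
+ Swab_after_feces, + Bristol_stool_scale, + Swab_morning_or_not,
+ WHR_ranges. Categorical covariates expand to treatment coding with the
most frequent level as reference.

## Diversity and the beta-diversity procedures

Alpha diversity: Shannon H (natural log) and Simpson reported as the
complement `1 - sum p^2` (the raw concentration is also emitted); the
Friedman test compares the four visits over women with complete data.
Beta diversity: Bray-Curtis on relative abundances and Euclidean distance
on technical-covariate-residualized CLR. PCoA is classical MDS (full
eigendecomposition; axes from positive eigenvalues, negative eigenvalues
retained in the report). Covariate screening uses per-visit
Kruskal-Wallis tests (continuous covariates binned by tertiles); each
axis is then residualized only on its significant covariates, and
PERMANOVA (999 permutations, add-one p-value rule) follows up significant
pairs within the corresponding visit.

*Per-phase comparison*: each sample is summarized by the mean (or median)
of its distances to the other samples of its phase; the six phase pairs
are compared with Wilcoxon signed-rank and paired t-tests, paired by
woman, Bonferroni-corrected over the six pairs. The aggregation unit
(per-sample summaries, paired at the woman level) is a choice the source
design leaves open and is recorded in the result metadata.

*Self-vs-random*: Self is each woman's mean pairwise distance among her
own collections; each of the (default 10) Random replicates builds one
pseudo-woman per woman from her first collection plus one
other-woman sample per remaining phase (distinct samples within a
pseudo-woman, focal woman excluded as donor), and compares Self to the
replicate with an unpaired Wilcoxon test, Bonferroni over replicates.
Known limitation: because Self and Random values are built from one
shared pool of samples (the anchor sits in both sides), the unpaired test
is conservative under exchangeability — measured null rejection at
alpha = 0.05 is ~0.005-0.01 rather than 0.05. Type-I error is therefore
controlled, but p-values near the threshold understate evidence; under
the high-ICC defaults the separation is so large that this has no
practical effect.

## Association models

All mixed models are Gaussian random-intercept models fitted by profiled
REML: with one grouping factor the covariance is block diagonal and REML
reduces to a 1-D optimization over `lambda = sigma_b^2/sigma_e^2`, making
each fit cheap enough for permutation loops (the fitter is verified
against statsmodels' MixedLM in the test suite to ~1e-6). Wald p-values
use the normal approximation on beta/SE — deliberately, since
denominator-degrees-of-freedom corrections vary across packages — and the
permutation empirical p-value is always reported alongside as the
calibrated quantity.

*Visit trend* (per taxon, per ladder step):
`taxa_adj ~ visit_number + (1|woman)` with visit numeric 1-4. ICC is
taken from the variance components of the technical-covariate-adjusted
fit. Empirical p: permute the abundance column across all rows (breaking
the repeated-measures structure, as the procedure is defined), refit 1,000
times (200 in the bundled pipeline default), and report the exact
proportion of permutation p-values ≤ observed (0 attainable, resolution
1/n_perm). A within-woman permutation variant exists behind a flag for
sensitivity analysis only. BH-FDR is applied to the asymptotic (not
empirical) p-values within each declared family.

*Consecutive-phase differences*: hormone outliers beyond 4 SD of the
pooled per-hormone mean are blanked first (single pass); differences
between consecutive available visits (gap pairs skipped) of both hormones
and adjusted taxa are rank-inverse-normal transformed
(`Phi^-1(rank/(n+1))`, mid-ranks for ties) and regressed per transition
(F-O, O-EL, EL-LL). Each woman contributes at most one observation per
transition, so a woman-level random intercept is unidentifiable; the
model is OLS per transition with optional HC1 robust errors. Pairs with
fewer than 10 observations are flagged `low_n`.

*Whole-cycle hormone models*:
`hormone ~ visit_number + taxa_adj + (1|woman) + pregnancy_category`,
focal term `taxa_adj`; empirical p permutes the taxa column; BH-FDR at
the declared 0.2 threshold within the hormone × taxa family.

Randomness protocol: one master seed; every permutation stream is derived
by hashing (seed, stage, taxon/hormone/model identifiers), so adding a
taxon never changes another taxon's permutations, and identical inputs +
seed give byte-identical result TSVs.

## CST classification

Nearest-centroid assignment under the Yue-Clayton similarity
`theta = sum(xy) / (sum x^2 + sum y^2 - sum xy)` against a user-supplied
centroid table (published reference centroids are an input, never shipped;
tests use synthetic centroids from the generator's regime baselines).
Sample vocabularies are harmonized to the centroid vocabulary by a rename
map with merge-and-renormalize semantics; samples with > 50% unmapped mass
are flagged unclassifiable. Ties break lexicographically with an explicit
flag. A dominance fallback labels samples by a > 60% (strict) marker
species, else CST-IV. Transition bookkeeping counts label changes between
consecutive available visits and classes women as CH / CH+NA / NO CH /
NO CH+NA by change status and completeness.

## Numerical choices and problem sizes

- REML lambda is optimized on the log scale over e^±10 plus the lambda=0
  boundary; boundary or vanishing-variance fits carry a `singular` flag
  but still report coefficients.
- Empirical p-values use the exact-proportion rule in the association
  layer and the add-one rule in PERMANOVA; both conventions are stated in
  the outputs they accompany.
- The test suite's calibration runs use 200 null cohorts for the
  self-vs-random procedure, 500/300 replicates for Kruskal-Wallis and
  PERMANOVA type-I error, 200 null taxa × 200 permutations for empirical-p
  uniformity, and 100/40 replicates for slope/coupling recovery — sizes
  chosen so the whole suite completes in minutes while keeping Monte-Carlo
  error well inside the asserted bands.
- Library sizes in simulation-heavy tests are reduced (20k-60k reads)
  from the 138k default; at 24 taxa the multinomial noise on CLR values
  is negligible at either depth.
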