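# Methods

## Overview

`telosim` implements a two-timepoint mechanistic cohort simulation. A
population of agents receives demographics, a baseline vertex follicular
density, a daily smoked-cannabis exposure, and item-level responses on a
three-domain Likert shedding instrument (SAHL). A latent oxidative-load
index converts exposure, sex, and diet into a single stress burden, which
drives Week-24 change in density (down) and symptom severity (up). The
Week-24 table is then analyzed with the standard observational battery.

## Generative model

### Marginals

| Variable | Distribution | Defaults | Rationale |
|---|---|---|---|
| age (years) | normal, rounded, clipped | 23.6 ± 3.8, clip [18, 35] | young-adult cohort description; the alternate table parameterization (26 ± 3, 40% female) ships as the `table1` preset |
| sex | Bernoulli(p_female) | 0.5 | stated 50:50 assignment |
| diet (0/1/2) | categorical | (0.35, 0.45, 0.20) | "most agents fair or poor"; exact probabilities unpublished, chosen once |
| density D0 (hairs/cm²) | truncated normal, inverse CDF | 185 ± 28 on [150, 220] | published trichoscopy norms; bounds symmetric about the mean, so the truncated mean is exactly 185 |
| exposure X (g/day) | zero-inflated gamma, capped | p₀ ≈ 0.21, gamma moment-matched, cap 5 | mixture mean 1.07, SD 0.84; p₀ is a free calibration parameter starting from 0.20 (a plausible non-user share consistent with "a realistic mix of non-users and light/moderate/heavy users"; the source never prints it) |
| SAHL items | equicorrelated ordinal | ρ ≈ 0.13, 3 domains × 3 items, 5 levels | see below |

The truncated normal is sampled by inverse CDF (fixed draw count per value);
the capped gamma resamples only draws exceeding the cap (exceedance ≈ 1e-4
at the default parameters), the one sampler whose draw count is data
dependent — determinism for a fixed generator state is tested explicitly.

The source material is internally inconsistent about the exposure mean (0.8
in its baseline table, "0.8–1.3" in one passage, 1.07 with SD 0.84 in
another). The default targets 1.07/0.84 — the only mean–SD pair printed
together.

### SAHL item model

Continuous item score `y_ij = √ρ·T_i + √(1−ρ)·e_ij`, discretized by four
fixed thresholds into levels 1–5. With Var(T)=1 the latent inter-item
correlation is exactly ρ, giving the closed-form continuous Cronbach
α = kρ/(1+(k−1)ρ); discretization attenuates this slightly, and the
calibration tunes ρ so the *discretized* baseline α hits its target. The
item count (3 per domain) is a design choice — never published — selected so
that α ≈ 0.51 is reachable with a plausible ρ (≈ 0.1). Default thresholds
put more mass at low response levels (mild right skew, population baseline
skewness > 0); their common location is a calibration parameter. The total
score is the sum of the three domain means, the only scaling consistent
with equal domain weighting and reported totals in the 6–7.5 range on a
3–15 scale.

At Week 24 the latent severity is shifted (`T24 = T0 + β_S·L + υ`) and items
are regenerated with the *same* thresholds and ρ and fresh item noise. The
item noise SD is fixed on the latent scale, so the Week-24 inter-item
correlation (and hence α) rises with the Week-24 latent variance — an
emergent property, not a separate dial.

### Structural equations

    L_i  = α_x·X_i + α_sex·sex_i + α_diet·(2−diet_i) + ε_i
    D24  = max(0, D0 − β_D·L + η)
    T24  = T0 + β_S·L + υ

All noise is mean-zero normal. ε is *additive*: the source prints the
diet term and the error term juxtaposed without an operator, but describes ε
as a random error term and requires poorer diet to raise the mean burden,
which a multiplicative reading would destroy. Week-24 density is floored at
0 but deliberately not re-truncated to [150, 220]: sub-range values are the
early-miniaturization phenomenon of interest. β_D, β_S ≥ 0 by construction;
the harm directions (density down, severity up) are carried by the explicit
signs.

Exposure strata: non (X=0), light (0 < X ≤ 0.5), moderate (0.5 < X ≤ 1.5),
heavy (X > 1.5). The percentile cut-points behind the published strata are
unpublished; these defaults keep all four strata populated in a typical
n=140 draw and produce a strictly graded adjusted dose-response. They are
config fields.

## Seeding

One master seed is expanded by `SeedSequence.spawn` into seven named
substreams (demographics, density, exposure, baseline items, load noise,
outcome noise, Week-24 items) consumed in fixed order. Noise is always drawn
as standard normals and scaled, so coefficient edits never advance any
stream: the baseline table is bit-identical across structural-coefficient
changes, and calibration can use common random numbers. Identical seed and
config give byte-identical cohort CSVs (floats at 6 significant digits) and
analysis-report JSON.

## Calibration

The free parameters (α_sex, α_diet, σ_ε, β_D, β_S, σ_η, σ_υ, ρ, threshold
location, exposure p₀/shape/scale; α_x ≡ 1 pins the scale) are fitted by
Nelder–Mead on log/logit-transformed coordinates, minimizing a weighted sum
of squared tolerance-scaled residuals between measured and target summary
statistics. Every loss evaluation re-simulates one large cohort with the
same seed (common random numbers), making the surface deterministic. The
shipped `paper_default` preset is the output of this procedure (a first pass
at n_eval = 20,000 refined at n_eval = 100,000; refining at larger n_eval
removes the residual Monte Carlo bias of fitting to one finite realization).
The targets identify the coefficients only up to Monte Carlo error, and any
configuration matching them is an equally valid representation — the source
never prints its coefficient values.

### Jointly unattainable targets

Four published statistics conflict with the others under the stated
structural model; the shipped target weights reflect this (zero or small
weight), and the corresponding acceptance checks are expected to fail
honestly rather than be re-targeted:

1. **Test–retest ICC > 0.52.** The test–retest correlation of a scale with
   reliability α ≈ 0.51 is bounded near 0.51 *even with no true change*;
   reaching the headline correlations (r(X, SAHL₂₄)=0.31, |r(SAHL₂₄, D₂₄)|
   =0.47) forces the Week-24 latent variance to ≈ 2.5× baseline, which caps
   the attainable ICC(2,1) near 0.3. Measured: ≈ 0.31.
2. **Week-24 α = 0.54.** With thresholds and ρ shared across timepoints (as
   specified), the inflated Week-24 latent variance pushes the emergent
   Week-24 α to ≈ 0.70. Matching 0.54 would require shrinking β_S·Var(L),
   destroying the correlation targets.
3. **adjusted R² (SAHL model) = 0.19.** Both Week-24 regressions recover
   exactly the non-ε part of L from the same predictors, so
   R²_sahl/R²_density = (0.31/0.38)² ≈ 0.67 is pinned by the two published
   correlations — incompatible with the published ratio 0.19/0.21 ≈ 0.90.
   With the density model held at 0.21, the SAHL model lands near 0.12
   (population) / 0.11 (mean over n=140 replicates).
4. **Male Week-24 SAHL mean = 6.1** (with female 7.4, a 1.3-point gap). The
   sex effect flows only through L, whose non-exposure variance is capped by
   the density-R² target; the attainable adjusted gap is ≈ 0.75 points. The
   female mean (7.4) is prioritized via the threshold location; the male
   mean lands near 6.65.

These bounds follow from the variance algebra of the single-latent-load
design; they are properties of the published numbers, not of this
implementation.

## Statistical battery

* Pearson r with two-sided p from the t transform (n−2 df).
* OLS via statsmodels; standardized β = B·SD(x)/SD(y); 95% CI from the t
  distribution; adjusted R² = 1−(1−R²)(n−1)/(n−p−1). Rank-deficient designs
  raise a collinearity error naming the offending columns.
* ANCOVA: Type-II factor F by nested model comparison (full vs
  covariates-only), the standard choice for covariate adjustment in
  unbalanced designs; adjusted means are model predictions at covariate
  means; post-hoc pairwise contrasts use the full-model covariance with
  Bonferroni adjustment (chosen over Tukey HSD to keep the brute-force
  oracle exact).
* Psychometrics: Cronbach α by the variance decomposition (n−1 variances);
  ICC(2,1) — two-way random effects, absolute agreement, single measurement
  — from the mean-squares decomposition (the conventional test–retest form;
  ICC(3,1) available behind a parameter). Convergent validity is reported
  *signed* (negative under the model: more severity, less density); the
  published positive 0.47 is treated as a magnitude.
* Diagnostics: residual skewness/excess kurtosis, Brown–Forsythe Levene test
  (median-centered) across exposure strata, 100 normal QQ quantile pairs.
* All tests two-sided. Degenerate inputs (zero-variance columns, empty
  strata) degrade to per-statistic error markers in the report, not crashes.

## Test strategy and problem sizes

Exact estimator properties are verified against independent brute-force
oracles (normal equations, nested-RSS F, covariance-form α, two-way ANOVA
mean squares, exhaustive 720-permutation p). Stochastic properties use one
shared 100,000-agent cohort and 200 replicate n=140 cohorts (the replicate
design mirrors how the published single-cohort statistics scatter; at these
sizes every tolerance is several Monte Carlo SEs wide, and the default suite
runs in a few minutes on one CPU). Property-based tests (hypothesis,
derandomized) cover sampler supports and config validation.

## Limitations

* The simulator reproduces a correlation structure by construction; passing
  tests demonstrate internal consistency and estimator correctness, not any
  biological claim about cannabis and hair shedding.
* Single scalp region, two timepoints, linear dose–response, no
  gene–environment interaction, no confounder structure beyond age/sex/diet.
* The SAHL instrument is synthetic; its item count and thresholds are design
  choices, constrained only by the published summary psychometrics.
* The calibrated coefficients are one point in a non-unique solution set.
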