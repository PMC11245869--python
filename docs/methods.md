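# Methods

This note documents the models, defaults and numerical choices behind
`epiage`, and what the synthetic benchmarks do and do not demonstrate.

## Synthetic cohorts

`epiage.synthetic.simulate_dataset` generates the data structure the
analysis assumes, from one integer seed (all sub-streams are derived
deterministically from it, so identical configs give byte-identical
output).

**Methylome model.** Beta values are logistic-transformed Gaussian
M-values: `β = 1 / (1 + 2^(−M))` with per-probe M-means drawn from a
three-component mixture (45% low ~N(−3,1), 45% high ~N(+3,1), 10%
intermediate ~N(0,1)) mimicking the canonical bimodal methylome, and
per-probe M-scale noise SD in [0.25, 0.6]. Probes carrying planted group
effects draw intermediate means, where beta-scale shifts are feasible.

**Planted effects.**

- *Differential positions*: the configured Δβ (default 0.10, target group
  mean difference on the beta scale) is calibrated numerically — for each
  probe the M-scale shift is solved by Brent root-finding so that the
  Gauss–Hermite expectation of the induced beta difference equals the
  target. Signs alternate ~1:2 hyper:hypo. Empirically the observed mean
  |Δβ| over planted probes at 25/25 is within ±0.02 of the target and
  converges to it at 200/group.
- *Variable positions*: M-scale noise SD multiplied by √ratio (default
  ratio 16) in the deceased group. On the beta scale the observed log2
  variance ratio is slightly compressed by the sigmoid (median ≈ 3.6
  rather than 4), which is what a real array would show too.
- *Regions*: clusters of consecutive probes (default 5 regions × 5 probes
  within 500 bp) share the calibrated mean shift plus an equicorrelated
  within-region random effect (ρ = 0.5), giving the spatial p-value
  autocorrelation the region caller estimates.
- *Bimodal probes*: per-sample two-mode M mixtures (modes ≈ ±2.5),
  exercising the multimodality screen.
- *Cell-composition probes*: a uniform-random reference panel (200 probes ×
  6 blood cell types) linearly mixed with per-sample Dirichlet proportions
  (α = (6, 3, 1.5, 0.8, 2.5, 0.5), granulocyte-dominant) plus β-noise
  SD 0.01. The Dirichlet parameters are a plausible blood composition, not
  an estimate of any study population.
- *Clock CpGs*: betas affine in a latent per-sample aging acceleration
  (`β = b0 + c·accel + noise`), so the bundled toy clock — whose weights
  invert that construction — is exactly affine in the acceleration at zero
  noise and correlates > 0.99 with it at the default probe noise (0.01).
  Default scale: 60 years mean, 5 years per acceleration SD.

**Survival.** Latent event times are exponential with
`log hazard = log(baseline) + slope · acceleration` (defaults: baseline
0.037/year, chosen so roughly half a 50-sample cohort dies within the
16.8-year administrative follow-up; slope 0.75 per acceleration SD). To
honor fixed group sizes, the configured number of deceased subjects is the
set with the smallest latent times (rank-preserving rescale onto the
follow-up window when needed); survivors are censored at follow-up. With
slope 0 this selection is independent of the acceleration, so a Cox fit on
the acceleration is a calibrated null — a property the tests verify. With
positive slope the deceased group is enriched for high acceleration, which
is what drives the planted clock-CpG group difference.

**What the generator does not emulate:** probe-type chemistry differences,
dye bias and background artifacts (upstream normalization is out of scope —
the pipeline ingests betas or intensities), realistic linkage between
clinical covariates and methylation, genome-realistic CpG spacing, and
missing-at-random patterns beyond a uniform missingness fraction. Passing
benchmarks therefore demonstrate the statistical machinery under its own
assumptions, not performance on raw array data.

## QC and filtering

Sample QC keeps samples with mean detection p < 0.05. The probe cascade
drops probes with detection p > 0.01 in *any* sample, on sex chromosomes,
SNP-mapping, or flagged cross-reactive / non-specific / variant-containing
/ masked (flags come from the annotation or from plain probe-id list
files). All rules are independent predicates, so the outcome is
order-stable; the FilterReport reconciles counts exactly.

Beta from intensities is `M / (M + U + offset)` with the conventional
offset 100 (configurable).

**Multimodality screen.** Probes bi-/tri-modal in any sex stratum of the
survived group are removed. No standard library ships a dip test, so
Hartigan's dip statistic is implemented here via iterated greatest-convex-
minorant / least-concave-majorant refinement; p-values come from a
Monte-Carlo uniform null regenerated at each stratum's exact sample size
(default 1000 draws), making the screen exact in level at any n. The dip
cleanly separates planted bimodal probes (dip ≈ 0.18 at n = 25) from
unimodal ones (≈ 0.06) with full power at the default α = 0.05 and
conservative size on Gaussian data. A Gaussian-mixture/BIC alternative
(1–3 components on M-values) is available via `method="gmm"`.

## Estimator engine

One schema serves all linear estimators (age clocks, pace measures,
telomere surrogates, EpiScores, protein surrogates, CRP scores):
coefficient CSV with name/intercept/transform/standardize metadata.
Transforms: identity, or the adult/juvenile age warp
(`x < 0 → (1+a)·e^x − 1; x ≥ 0 → (1+a)·x + a`, adult age a = 20,
continuous at 0). Optional per-probe z-standardization before weighting
(EpiScore convention differs between sources; off by default). Missing
model probes: error, impute from bundled reference means, or cohort-mean
fallback (0.5 when the probe is absent entirely), with the policy recorded
per model. PC-clocks are stored as center/rotation/weights CSV trios.

## Cell deconvolution

Per sample, fractions solve `min ‖R f − β‖` with f ≥ 0 (scipy NNLS); the
sum-to-one constraint is imposed by a heavily weighted augmentation row
(weight 1e4) followed by exact renormalization — exact on noiseless
mixtures, simplex-feasible to machine precision, and with per-fraction MAE
≈ 0.004 at β-noise SD 0.02 (200 probes, 6 types). Fractions, not counts,
are reported; a scale column can convert externally.

## Residual-outcome testing

Defaults follow the published procedure: pooled-cohort IQR fences
(k = 1.5, linear-interpolation quartiles), survivor-only OLS reference
model (sex coded M=1/F=0, complications 0/1), Student (equal-variance)
t-test on the whole-cohort residuals, BH across the battery, flagged at
FDR 5% and 10%. Welch is available (`equal_var=False`).

**Known finite-sample deviation.** Residualizing the full cohort against a
model fit on survivors alone leaves the deceased group's residuals with
prediction error that is *shared* across samples (the reference model's
coefficient error), so they are positively correlated and slightly
over-dispersed. At the default design size (27/23, four fitted
parameters) the procedure's true null rejection rate at α = 0.05 is
≈ 0.064 (Student) and ≈ 0.061 (Welch), measured over 20,000 replicates.
This is a property of the two-stage procedure itself, not of its
implementation; it shrinks with more survivors or fewer covariates. The
benchmark suite reports the measured rate rather than hiding it.

Power benchmark: a +0.5 cohort-SD shift planted on one of 15 clock-like
estimators (estimate ≈ age + 2-year residual noise, so the cohort SD is
dominated by the age span) is recovered at BH q = 0.10 in ≈ 88% of
replicates.

## Matching, survival, correlation

Propensity scores come from an unpenalized logistic fit on standardized
covariates (L2 fallback by flag when separation occurs); greedy 1:1
nearest-neighbour matching proceeds in descending treated score without
replacement, caliper off by default; standardized mean differences use the
pooled-SD denominator. Cox fits use lifelines' Efron-tie partial
likelihood; the pipeline's fully adjusted battery fit (10 covariates,
~23 events) applies a small ridge (penalizer 0.1) for stability, while the
single-covariate API default is exact partial likelihood (verified against
a brute-force likelihood grid to ~1e-4). Constant covariates (e.g. a
no-smoking cohort) are dropped with a warning. Spearman correlation uses
midrank ties and flags zero rank variance.

## Differential methylation calling

- **DMP**: per-probe linear model (intercept, group, covariates; batch as
  dummies; one cell-fraction column dropped to avoid simplex collinearity).
  Robust path: Huber M-estimation (c = 1.345, MAD scale, ≤ 50 IRLS
  iterations, vectorized across probes). Moderation: empirical-Bayes
  moment matching of log-variances via trigamma inversion; the degenerate
  all-equal case returns the common value, a non-finite prior falls back to
  unmoderated with a warning. Δβ is the *raw* group-mean difference
  (deceased − survived) — the call rule (BH p < 0.05 and |Δβ| > 0.05,
  both strict) uses it, while the covariate-adjusted coefficient is also
  reported. With robust+moderated defaults, planted Δβ = 0.10 positions at
  25/25 over 10,000 probes are recovered at ~96% recall with ~2% observed
  FDR.
- **DVP**: absolute deviations from the group mean (median by flag)
  regressed on group — Levene/Brown–Forsythe — with the variance ratio in
  log2 (configurable base; "4-fold variance change" at the threshold 2).
  Zero-variance probes are flagged and excluded from calls.
- **DMR**: comb-p style. Autocorrelation of `z = Φ⁻¹(1−p)` in 50-bp
  distance bins up to 500 bp (bins with < 10 pairs contribute 0;
  correlations clipped to [0, 0.99]); Stouffer–Liptak smoothing within a
  500-bp window; seeds at smoothed p < 0.01 merged across gaps ≤ 500 bp;
  single-probe regions suppressed; region p by correlation-adjusted
  Stouffer–Liptak over the original p-values; Sidak correction
  `1 − (1−p)^(covered/width)` with the covered span summed per chromosome
  (computed via expm1/log1p for tiny p). None of these constants are
  stated by upstream conventions uniformly; all are exposed in config.
- **Enrichment**: one-sided hypergeometric upper tail per GMT set against
  a user-supplied universe.

## Benchmark problem sizes

The acceptance script and test suite use desk-scale sizes chosen to give
stable Monte-Carlo estimates in minutes on one CPU: 2000 null replicates
(type-I), 500 power replicates, 10,000-probe DMP runs, 5 × 2000-probe DVP
replicates plus a 20,000-probe null, 100 DMR null replicates of 1000
probes, 200 Cox coverage replicates. Sub-seeds derive from the single
`--seed` argument.

## Known limitations

- The dip implementation follows the convex-envelope construction with
  Monte-Carlo calibration; its raw statistic may differ from the classical
  tabulated values by small edge conventions (the MC null makes the test
  level-exact regardless, but published critical-value tables should not
  be applied to it).
- The comb-p region caller estimates autocorrelation from the supplied
  p-values themselves; on very sparse panels (probe spacing mostly beyond
  500 bp) the correlation defaults to zero and region p-values reduce to
  plain Stouffer combination.
- `GrimAge`-style composite chaining (sub-models feeding a composite) is
  representable only as pre-computed estimate columns fed back in as model
  inputs; no neural-network age predictors are representable beyond linear
  surrogates of their outputs.
- Third-party coefficient sets are not bundled; the engine loads any
  coefficient file matching the documented schema, and toy fixtures are
  generated by the synthetic module.
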