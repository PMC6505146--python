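# Methods

This note documents the statistical models implemented in `ricegxe`, the
conventions and numerical choices behind them, and what the synthetic-data
generator does and does not emulate.

## Setting

A small breeding program evaluates a few hundred rice lines in replicated
field trials at one location over 3–5 consecutive seasons (years).  Roughly
half of the entries are replaced every year, so the data are unbalanced with
non-random missingness.  The questions the package addresses are (i) how well
the performance of lines in a *future, unobserved* year can be predicted from
marker data and from weather-derived environmental covariates (EC), and
(ii) which weather variables modulate the effects of individual QTL
(QTL-by-environment interaction).

## Environmental covariates

Daily weather (temperature, precipitation, sunshine, humidity, evaporation,
wind) is summarized into 18 covariates per developmental stage.  Stages are
anchored on the year's mean days to 50% flowering (FT): vegetative
`[sowing, FT−35)`, reproductive `[FT−35, FT)`, maturation `[FT, FT+30]`
(the FT day belongs to maturation; the three windows tile the season with no
gap or overlap).  Per-year phenology is the default; per-line staging can be
emulated by calling `compute_stage_ec` with per-line windows.

Aggregators follow the covariate definitions: means (thermal amplitude,
relative sunshine, solar radiation, effective precipitation, degree days,
mean/average/max/min temperature, tank and Piche evaporation, wind run,
minimum relative humidity), sums (hours at 100% relative humidity,
accumulated precipitation, sunshine hours) and day counts (rain days, days
with minimum temperature below 15 °C).  Conventions that the definitions
leave open:

* a *rain day* is any day with precipitation > 0 mm;
* degree days are the mean of (daily mean temperature − 10 °C) **without**
  truncation at zero (a truncating mode is available via a custom
  definition list);
* solar radiation is reconstructed from sunshine hours with the
  Ångström–Prescott formula `Rs = Ra (a + b·n/N)` with FAO-56 default
  coefficients `a = 0.25`, `b = 0.50`; day length `N` and extraterrestrial
  radiation `Ra` come from standard solar geometry at the trial latitude
  (default 33.25° S), and relative sunshine is `100·n/N` with the same `N`;
* effective precipitation is consumed as an input column, not recomputed.

With 3 stages × 18 definitions the EC table has 54 columns per year.
Columns constant across years are dropped (logged); the rest are centered
and scaled to unit sample variance (ddof = 1) over the *training* years, and
the center/scale are stored so an out-of-sample year can be standardized
without leaking its own statistics — every leave-one-year-out evaluation
rebuilds the standardization on the training years only.

## The mixed-model engine

All variance-component models go through one REML engine for

    y = Xβ + Σ_k Z_k u_k + e,   u_k ~ N(0, K_k σ_k²),

with arbitrary known PSD kernels `K_k` (identity for design factors, the
genomic relationship `G = XXᵀ/p` from standardized markers, the
environmental relationship `Ω = WWᵀ/q` from standardized EC, or the
observation-level Hadamard product `[Z_g G Z_gᵀ] ∘ Ω` for the
marker-by-environment interaction; PSD by the Schur product theorem).
Residuals can be homogeneous or grouped (heteroscedastic per environment).

Fitting is average-information REML with step halving and a monotone EM
fallback (`σ² ← σ² + σ⁴/q·(yᵀPC Py − tr(PC))`), so the restricted
log-likelihood never decreases across accepted iterations.  Convergence
requires both a stalled likelihood (relative change < 1e-8) and the
first-order conditions: the scale-free gradient `σ·∂ℓ/∂σ` near zero for
interior components, non-positive gradient for components at the zero
boundary.  Negative estimates are pinned at exactly 0 and the remaining
components re-optimized.  Because the restricted likelihood can be bimodal —
an interior mode plus a better mode with a weakly-determined component on
the boundary — the engine finishes with *boundary probing*: any component
whose estimate is within two average-information standard errors of zero is
pinned at 0 and the profile re-optimized; the better mode is kept.  BLUPs
come from `û_k = σ_k² K_k Z_kᵀ P y` at the final estimates.

**Per-year adjusted means (BLUEs).** Genotype is fixed; block,
row-within-block and column-within-block are random.  Missing phenotypes
are dropped listwise; genotypes left without records are omitted with a
warning.  **Heritability** on a line-mean basis is
`H² = σ_g²/(σ_g² + σ_ε²/r)`; because the BLUE model has genotype fixed, the
genotypic variance comes from refitting the same model with genotype random,
and `r` is the year's median replicate count — a convention the analysis
itself has to choose, since adjusted means and a genotypic variance cannot
come from one model.

**Variance partition.** A single multi-year model fits Year, Genotype,
Genotype×Year, Block (within year), Row and Column (within year and block)
and Residual, all random with identity kernels, intercept fixed; percentages
are 100·σ²/Σσ².

**GWAS.** Per trait-year, each marker is tested in the kinship model
`y = 1μ + x β + u + e`, `u ~ N(0, K σ_G²)` with `K = XXᵀ/p`.  Variance
components are estimated once under the null by an eigen-decomposition of K
and a 1-D search over the variance ratio, then reused for every marker
(the standard two-step approximation); each marker is then a 2-parameter
GLS fit in the rotated space.  The test statistic is `β̂/se(β̂)` with a
per-marker residual scale, referred to t with n−2 df — this reduces
*exactly* to the ordinary regression t-test when `K = I` and `σ_G² = 0`,
and is calibrated under the null (empirical p<0.05 rate 0.050 at 2000
markers).  Monomorphic markers are skipped with score 0.  Significant
markers are declared by Benjamini–Hochberg FDR at α = 0.05.

## Reaction-norm prediction of untested years

Inputs are the stacked per-year BLUEs (two-stage analysis).  Three nested
models:

* **G** — GBLUP for mean line performance.  Fitting `y = μ + g + ε` to
  stacked multi-year records is misspecified when the year main effect is
  large (the profile likelihood then prefers σ_g² = 0); the G model is
  therefore fitted to per-line means over the training years, which is what
  "mean performance" denotes.  A `collapse_g=False` switch keeps stacked
  records, e.g. for likelihood-nesting checks on identical data.
* **G+W** — adds a random year effect with covariance `Ω σ_w²`.
* **G+W+GW** — adds the interaction with the Hadamard kernel
  `[Z_g G Z_gᵀ] ∘ [Z_w Ω Z_wᵀ] σ_gw²`.

Prediction for a new year is the BLUP extension (conditional expectation
under the fitted covariance): the new year's raw EC are standardized with
the training center/scale, the cross-covariance to training year j is
`z_newᵀ z_j / q`, and

    ŷ(l, new) = μ̂ + σ̂_g² G[l, obs] P y + σ̂_w² ω_crossᵀ P y
                + σ̂_gw² (G[l, obs] ∘ ω_cross)ᵀ P y.

Genotyped lines without training phenotypes are predicted through their
genomic relationship with the training lines (their information enters via
`G[l, obs]`); lines absent from G cannot be predicted and raise an error.
Accuracy is the Pearson correlation between predictions and the held-out
year's observed means; degenerate (constant) predictions — all variance
components at the boundary — are scored as r = 0 with a warning.

## Partial least squares

PLS1 by NIPALS on standardized predictors: markers only (PLS-G) or markers
plus the year's EC replicated across lines (PLS-GW).  Coefficients use the
corrected weight transform `R = W (PᵀW)⁻¹`, `b = R qᵀ`, which makes
predictions from coefficients identical to predictions from scores (the
naive `b = W qᵀ` holds only for transformed weights).  The latent-variable
count minimizes RMSEP — the square root of the held-out squared errors
pooled over all 10 folds of a seeded cross-validation — with ties broken
toward fewer components; `max_lv` defaults to `min(15, n − folds, p)`.
Influential covariates are read off the coefficient vector, ranked by
absolute value with signs preserved and name-stable ties.

## QTL-by-EC factorial regression

For each marker surviving the single-environment scan, and one EC at a time,

    y_ij = μ + E_j + x_i(α_q + β_q z_j + a_jq) + G_i + GE_ij,

with fixed year main effects E_j, α_q the QTL effect in the average
environment, β_q the slope per standard deviation of the EC (z standardized
over training years), `a_jq ~ N(0, σ_aq²)` the residual year-specific QTL
effect, `G_i ~ N(0, K σ_G²)` polygenic, and GE the remaining
genotype-by-environment term.  With per-year means there is one observation
per line×year cell, so GE and the residual are confounded; the covariance
structure Σ across years is therefore realized as a line main effect
(common covariance) plus the residual: homogeneous residual for CS,
per-year residual variances for HCS (which constrains Σ_jj ≥ Σ_jj', the
usual variance-component parametrization), and a free symmetric Σ for UN,
fitted by direct REML over a log-Cholesky parametrization (Nelder-Mead,
initialized from per-year residual variances).  UN is attempted only with
≤ 5 environments and ≥ 10 lines per covariance parameter.  Structures are
compared by `BIC = −2ℓ_R + k log n` with k the number of covariance
parameters; with `structure="auto"` the comparison is run once and the
winner reused for all (marker, EC) pairs.  β_q is tested by a Wald z test
at the converged components (no degrees-of-freedom correction; empirical
type-I 0.045–0.047 at the 0.05 level over 1000 null replicates), and
significance across all pairs of one trait is declared by BH-FDR at 0.05.

## Synthetic data

The generator emulates the study conditions end to end: two-ish populations
of ~320 lines (default), 5 years, RCBD with 2 replicates (one block per
replicate, a row×column grid within each block), ~50% line turnover per
year, a downscaled panel of 2000 independent biallelic markers with MAF in
[0.05, 0.5] (out-of-band empirical MAF redrawn), and a 150-day season of
daily weather (sinusoidal seasonal mean, AR(1) noise, year-specific offsets
for temperature, sunshine and rain; precipitation as thinned exponential
events) from which the EC pipeline itself derives the 54 covariates.

Phenotypes follow the generative mirror of the full reaction-norm model:
grand mean + year effect (linear in the standardized EC) + genotypic value
(20 QTL with iid normal effects on standardized dosages) + G×Y deviation
(marker×EC products when slopes are configured, plus iid cell effects) +
block/row/column effects + residual.  The default variance fractions are
the tropical-japonica grain-yield profile: Year 43.2%, Genotype 13.2%,
G×Y 5.1%, Column 0.3%, Row 0.5%, Block 22.7%, Residual 15.0% (residual
adjusted from 15.1 so fractions sum to one).

**Calibration semantics.** Each component's realized *level* variance
(sample variance with ddof = 1 over its own levels) is rescaled to exactly
its target, so `TruthSet.realized_variances` match the targets and REML
recovery is anchored rather than drifting with few levels (3 years give a
year-variance estimator with huge sampling variance otherwise).  Block
effects get a finer treatment because they are the largest design component
and blocks are few: their within-year deviations are scaled to the
within-year mean square (the statistic the nested REML estimator uses) and
their year-averages are drawn with variance σ_b²/B and made orthogonal to
the year effects, so the year stratum stays calibrated.  Without this
anchoring the Year percentage recovery error at 3 years was ±16 points;
with it, ≤ ~2.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: linkage disequilibrium and haplotype
structure (markers are independent, so GWAS hits are exact causal markers
rather than LD proxies), genotyping errors and missing marker data,
non-random line turnover (drops are random, not performance-based),
multi-trait genetic correlations, spatial field trends beyond row/column
effects, and meteorological realism beyond marginal scales (the weather
model produces plausible EC variance, not physically consistent weather).

## Problem sizes and seeds

The verification battery uses: variance-partition recovery at 300 lines ×
3 years × 2 replicates; QTL×EC slope recovery (α = 0.4, β = 0.3) at 300
lines × 4 environments × 20 replicates; reaction-norm component recovery at
300 lines × 4 years, averaged over 3 draws; GWAS null calibration at 200
lines × 2000 markers; Wald type-I at 50 lines × 5 environments × 1000
replicates; prediction-ordering at 120 lines × 4 years × 500 markers × 20
replicates with one rotating held-out year per replicate.  All randomness
descends from a single seed via named sub-streams, so every run is exactly
reproducible.

## Known limitations

* The reaction-norm models are fitted by REML and predicted by BLUP; the
  Bayesian treatment of the same covariance structures (posterior means
  under flat-ish priors) would coincide closely for these Gaussian models
  but is not provided.
* Wald tests use large-sample references (t with n−2 df in the scan, normal
  for the interaction slope); small-sample df corrections
  (Kenward–Roger-style) are out of scope.
* The factorial regression tests one EC at a time; strongly correlated EC
  therefore produce near-identical α/β across pairs and the FDR treats
  them as separate tests.
* QTL are reported per marker; no LD-based merging of hits into intervals.
* The generic REML engine is dense O(n³) per iteration; it is sized for
  trials of a few thousand plots, not for biobank-scale data.
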