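# Methods

## Overview

`thermoresil` quantifies how resilient dairy-sheep milk performance is
to weather fluctuation, and how heritable that resilience is.  The
analysis has two stages:

1. **Reaction norms.** Test-day milk yield is modelled across an air
   temperature (or THI) gradient with a second-degree Legendre
   random-regression model.  Each animal's curve is the population curve
   plus an individual deviation curve; the derivative of the total curve
   at a stated temperature (10 degC for cold stress, 25 degC for heat
   stress) is that animal's *resilience phenotype*, in kg milk per degC.
   Phenotypes are derived separately by calendar season of lambing
   (autumn = September–November lambings, winter = December–February,
   spring = March–May) and for two covariate variants: the value on the
   test day and the mean over the seven preceding calendar days.
2. **Quantitative genetics.** The slope phenotypes (and lifetime milk
   yield) are analysed with pedigree-based univariate and bivariate
   animal models to estimate heritabilities and genetic/phenotypic
   correlations.

Everything runs on synthetic data with known ground truth; the package
contains no field data.

## Weather covariates

THI combines daily mean temperature T (degC) and relative humidity RH
(%):

    THI = T − (0.55 · (1 − RH/100)) · (T − 14.4)

so THI = T in saturated air and the humidity correction vanishes at
14.4 degC.  Records are matched to the nearest weather station by
great-circle distance (planar Euclidean for synthetic coordinates; ties
break on the lowest station id).  The "week preceding" covariate is the
arithmetic mean over the seven calendar days strictly before the test
day — the test day is excluded, reading "preceding" strictly, because
same-day and cumulative exposure are treated as distinct phenotypes; a
`lag_window` option exposes the alternative width.  Records with any
unresolvable weather day are dropped and counted in the run log rather
than interpolated, the conservative choice.

## Data edits and lifetime yield

Three sequential single-pass filters: (i) drop records taken fewer than
42 days after lambing (lambs suckle until day 42); (ii) within each
month-of-lactation group (`floor(dim/30.44)+1`, matching the monthly
recording cadence), drop records deviating more than four sample
standard deviations from the group mean, with group statistics computed
once on the data surviving (i); groups with fewer than three records
are exempt because their SD is undefined or unstable — note that a
group needs ≳ 17 records before a single extreme value *can* exceed
4 SD, since max |z| is bounded by (n−1)/sqrt(n); (iii) drop all records
of animals left with fewer than three records.  Group statistics pool
flocks by default (`sd_within_flock` switches to within-flock).  The
filters are idempotent and only ever remove records.

Lifetime milk yield per animal × lambing season accumulates each
lactation with the Fleischmann test-interval method: the first interval
(lambing to first test) is credited at the first test's daily yield,
interior intervals at the mean of their bounding tests, and a 15-day
tail after the last test at the last yield, capped so the credited
lactation does not exceed 210 days (lactations here last 5–6 months).
The tail convention is a documented simplification of official
recording arithmetic; both tail length and cap are configurable.

## Reaction-norm model

For season × covariate cell the model is

    y = X b + Φ(x) β + Z (Φ(x) a_i) + e,

with fixed effects `X b` (farm, lactation number, lambing year, lambing
month, and 30-day days-in-milk classes; first level of each factor set
to zero), population curve coefficients β on the Legendre basis Φ, and
per-animal deviation coefficient 3-vectors a_i ~ iid N(0, G0) with
unstructured 3×3 G0; residuals are iid.  The basis maps the observed
covariate range [x_min, x_max] onto [−1, 1] and uses orthonormalised
Legendre polynomials (φ_k = sqrt((2k+1)/2) P_k); the constant φ_0 acts
as the model intercept.  The observed range is stored with the fit and
slope queries outside it are refused — a season whose temperatures
never approach 25 degC simply has no heat-stress trait, with a warning.

The random part deliberately carries all three coefficients (intercept,
linear, quadratic) per animal: animal-specific curvature is exactly
what distinguishes a plastic from a stable animal.  Animals are fitted
iid at this stage — genetic structure enters only in stage two, on the
derived phenotypes (a two-stage design).  Consequently the slope
phenotypes are BLUP-shrunken: their dispersion understates the
generating slope SD, and stage-two heritabilities of the derived
phenotypes are attenuated at small scale; the parameter-recovery
experiments therefore validate the genetic machinery on directly
simulated traits instead.

Slopes default to the *total* curve (population + deviation), because
the phenotype means of interest are far from zero, which pure BLUP
deviations cannot produce; `mode="deviation"` is retained (deviation
phenotypes centre near zero by construction).

## Pedigree and REML

The inverse numerator relationship matrix is assembled directly by
Henderson's rules with exact inbreeding coefficients from the
Meuwissen–Luo algorithm; log|A| falls out as the sum of log
Mendelian-sampling variances.  Animal models are

    y = X b + a + e,  a ~ N(0, A σ²_a)            (univariate)
    a ~ N(0, A ⊗ G0), e ~ N(0, I ⊗ R0)           (bivariate)

with unstructured 2×2 G0 and R0; animals recorded for one trait only
contribute reduced residual blocks.  Fixed effects for the phenotype
analyses: farm, first lambing year and month (factors), total number of
lactations and total days milked (covariates).

Estimation is REML.  The log-likelihood is evaluated exactly through
the mixed-model equations with a sparse LU factorisation (symmetric
minimum-degree ordering; the log-determinant of the coefficient matrix
comes from the U diagonal).  Updates are average-information: the AI
matrix is computed exactly from working variates, each costing one
back-solve with the current factorisation; the score vector is obtained
by central finite differences of the exact log-likelihood (two
factorisations per parameter), which is accurate to ~1e-6 here and
avoids the selected-inverse traces that exact analytic scores require.
Steps that would leave the parameter space are halved and projected
back to positive semi-definiteness by eigenvalue clipping (floor 1e-8
of the phenotypic variance), which lets variance components settle on
the zero boundary; a trust region caps steps proposed by a singular AI
matrix, and a scaled-gradient fallback handles directions in its null
space (degenerate data such as a duplicated trait).  Convergence:
relative log-likelihood change < 1e-8 and maximum relative parameter
change < 1e-6, 200-iteration cap; non-convergence raises an error
carrying the likelihood trajectory.  Estimates with σ²_a effectively
zero are flagged as boundary fits.

Standard errors come from the inverse AI matrix with the delta method
for h² = σ²_a/(σ²_a+σ²_e), r_A = σ_a12/sqrt(σ²_a1 σ²_a2) and
r_P = (σ_a12+σ_e12)/sqrt(p_1 p_2).  Significance uses a two-tailed
Student t on estimate/SE with residual degrees of freedom (n − rank X;
the df convention is logged with each p-value), stars at P < 0.01.  The
animal variance is additionally tested by a likelihood-ratio test
against the model without the animal effect, referred to the
0.5·χ²₀ + 0.5·χ²₁ mixture appropriate for a variance on its zero
boundary (identical log-likelihoods give p = 0.5).  Correlations pushed
past ±1 by rounding are clamped with a flag.  No multiple-testing
correction is applied; stars are per estimate.

## Synthetic-data generator

The generator emulates a Mediterranean semi-intensive recording scheme:

* **Pedigree** — discrete generations (default 150/300/450 animals),
  random mating, 12 sires per generation (~2% of males, mirroring a
  realistic sire:dam ratio), sexes drawn 50:50.  Breeding values follow
  the pedigree with Mendelian-sampling variance 0.5·G0·(1−(F_s+F_d)/2).
* **Weather** — daily temperature = annual sinusoid (mean 16.5 degC,
  amplitude 10 degC, peak mid-July) + AR(1) noise (φ = 0.7, innovation
  SD 1.6 degC); RH negatively coupled to temperature (−0.8 %/degC
  around a 65% mean, SD 6), truncated to [0, 100].
* **Recording** — lambing dates September–May with season shares
  0.35/0.49/0.16 (autumn/winter/spring, the ratio of a realistic
  seasonal animal-count split), monthly tests from day 42 to dry-off at
  150–210 days; milk yield = flock effect (SD 0.15 kg) + lambing-year
  effect (SD 0.05) + Wilmink lactation baseline
  (2.2 − 1.0·e^(−0.05·dim) − 0.005·dim, peaking near 1.9 kg) + Legendre
  reaction norm Φ(t)(β + g_i + p_i) + residual (SD 0.30 kg).
* **Reaction-norm truth** — basis over [−2, 34] degC;
  β = (0, 0.0522, −0.0540) chosen so the population slope is
  +0.010 kg/degC at 10 degC and −0.005 at 25 degC, magnitudes typical
  of seasonal resilience phenotypes; total coefficient covariance
  diag(0.35², 0.13², 0.07²), split 30% genetic / 70% permanent
  environment, giving generating slope SDs near 0.013 kg/degC.
* **Direct traits** — scalar phenotypes at unit phenotypic variance
  with requested h² (and r_A, r_P for pairs); the residual covariance is
  derived as r_P − cov_a and validated for admissibility.  One 10-level
  group fixed effect (SD 0.3) is always present.

One RNG stream per sub-generator (pedigree, weather, breeding values,
records, traits) is spawned from the master seed, so enlarging one
stage never perturbs another; a fixed seed reproduces every output byte
for byte.

What the generator does *not* emulate: selection and culling decisions,
heterogeneous flock management trends, seasonal feed changes, missing
or mistyped pedigree links, and recording gaps.  Passing tests
demonstrate that the estimators recover known generating parameters
under a faithful model, not that field data meet the model assumptions.

## Validation experiments and problem sizes

The recovery experiments (`thermoresil.validation`, driven by
`scripts/acceptance.py`) use a three-generation pedigree of
600/1200/1800 animals — all 3,000 non-founders phenotyped — or
1000/2000/3000 (5,000 phenotyped) for the near-boundary low-h² case,
with 10 replicates per setting and per-replicate seeds derived from the
master seed.  Generating values: h² ∈ {0.15, 0.17, 0.03} for
univariate recovery; (h² pair, r_A, r_P) of (0.14/0.30, 0.84, 0.69) for
the resilience–production pair — 0.30 being a typical dairy-sheep
milk-yield heritability for the production-like trait —
(0.15/0.13, 0.51, 0.14) for the between-season pair and
(0.15/0.16, 0.97, 0.93) for the near-duplicate daily/cumulative pair.
The test suite runs the same experiments with 5 replicates.  The
end-to-end check runs the full pipeline on the default configuration
and compares fitted population curves against the generating curve on
the interior 80% of each season's covariate range (basis edges are
data-sparse and noisy).

## Known limitations

* Two-stage estimation ignores the uncertainty of stage-one BLUPs;
  heritabilities of derived slope phenotypes are attenuated relative to
  a joint pedigree random-regression analysis.
* Finite-difference scores cost two likelihood evaluations per
  parameter per iteration; for models far larger than ~10⁴ equations an
  analytic-trace implementation would be preferable.
* The Fleischmann tail convention approximates official lactation
  arithmetic; no AM/PM or supervision corrections are applied.
* Heterogeneous residual variance across the covariate range,
  permanent-environment effects inside the reaction-norm stage, and
  polynomials beyond degree 2 are out of scope.
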