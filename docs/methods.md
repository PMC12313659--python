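# Methods

## Model and procedure

The package treats a region-year panel as the unit of analysis: one row per
(region, year), numeric columns for outcomes (resource levels per 1,000
people), need variables, non-need variables and a socio-economic ranking
variable, plus an optional nonnegative observation weight (default 1, i.e.
the region — not its population — is the unit; population weighting is
available but off, since province-level reporting conventionally weights
provinces equally).

**Fractional ranks.** With normalized weights w and observations sorted
ascending by the ranking variable, unit i receives
r_i = Σ_{j<i} w_j + w_i/2. Ties share the midpoint of the tied group's
cumulative-weight interval, which equals the weighted mean of the ranks the
group would occupy without ties; this is the only tie rule that preserves
the identity Σ w_i r_i = 1/2 exactly, on which the index algebra relies.
A constant ranking variable raises an error: no socio-economic ordering
exists, so the index is meaningless rather than zero.

**Concentration index.** C = 2·cov_w(h, r)/μ with the weighted *population*
covariance (denominator = total weight). The population form is required
for three exact identities used in tests: equality with the convenient
regression slope, the perfect-concentration limit C = (n−1)/n, and the
decomposition adding-up identity. The convenient-regression route fits
2·var_w(r)·h_i/μ on r_i by weighted least squares and takes the slope; it
is retained purely as a second, independently coded route so that the two
can be compared to ≤1e−10 at run time and in the acceptance checks. C is
invariant to any nonzero rescaling of h (the scale cancels between
covariance and mean — including sign changes) but not to translation; both
properties are tested. Bounded-variable corrections (Wagstaff/Erreygers)
and standard errors for C are out of scope.

**Per-year tables.** CI and ISCI tables re-rank regions within each year:
a region's socio-economic position may move across years, and pooling ranks
would conflate growth with redistribution. The decomposition, by contrast,
pools all region-years with a single ranking, consistent with the single
pooled regression it rests on.

**Indirect standardization.** OLS of y on need variables x_j and non-need
controls z_k; ŷˣ_i evaluates the fit at the observed x_i and the sample
means z̄_k (means taken within the fitting sample — per-year when fitting
per-year); ŷᴵˢ_i = y_i − ŷˣ_i + ȳ. Because OLS residuals average zero,
mean(ŷᴵˢ) = mean(y) exactly on the fitting rows, and CI(ŷᴵˢ) coincides
with CI(y) − CI(ŷˣ) — the recentring constant contributes nothing — so the
two candidate readings of the need-standardized index are the same number;
this equivalence is asserted in tests. Per-year fitting is the default for
the yearly ISCI table (each year's ISCI then reflects contemporaneous
need-outcome relationships); a pooled-fit flag applies one coefficient
vector to every year. Missing regressors are handled by listwise deletion:
imputation is the IO layer's job, performed explicitly and logged, never
silently inside a fit.

**Decomposition.** Pooled OLS of the outcome on all need + non-need
determinants with an intercept (no year effects by default, matching the
single-F, single-R² pooled convention; a year-dummies flag adds them as
extra reported rows). Each determinant's contribution is computed as
β_k · GC_k / μ with GC_k = 2·cov_w(x_k, r), which equals the textbook
elasticity × C_k form whenever x̄_k ≠ 0 but stays defined for zero-mean
determinants; C_k itself is reported as NaN in that degenerate case. The
identity Σ_k contribution_k + GC_ε/μ = C holds by linearity of the
covariance for *any* coefficient vector, so it is asserted after every fit
(tolerance 1e−8) as a guard against alignment or bookkeeping bugs rather
than as a property of OLS. Constant determinants cannot enter the design
(they are collinear with the intercept); they are excluded from the fit and
reported with zero contribution and a degenerate flag. Plain OLS standard
errors by default; clustering by region is available but not default, as
the reported F/R² conventions in this literature are unadjusted.

**Contribution rates.** CR_k = |contribution_k| / Σ_k |contribution_k| ×
100, with the contribution's sign carried onto the magnitude in a parallel
signed column. The denominator sums over determinants only by default (the
normalization's definition sums over k); an include-residual flag adds
|GC_ε/μ|, in which case determinant magnitudes total below 100% by exactly
the residual's share. The traditional contribution/C × 100 rates are
provided separately for comparison and raise an explicit error when C = 0
— the failure mode the absolute-sum normalization exists to avoid.

## Data cleaning choices

- **IQR screen:** within variable × year (cross-sectional, the natural
  screen for yearbook typos), fences Q1 − k·IQR and Q3 + k·IQR with k = 1.5
  and linear-interpolation ("type 7") quartiles. Flagged values are
  winsorized to the nearer fence — corrected, not deleted — in a single
  pass. Groups with fewer than 4 values are skipped with a warning.
  A second application is a no-op whenever the quartiles do not interpolate
  through corrected order statistics (always the case for isolated outliers
  in a 31-region cross-section, and tested there; at n = 4 the quartiles
  touch the extremes and re-screening can re-flag).
- **Imputation:** within-region time series only. Linear interpolation on
  the year axis for interior gaps; a neighbor-mean method (mean of the
  nearest earlier and later observed years) as a deterministic stand-in for
  donor-based predictive mean matching, whose donor pools and stochastic
  draw are not reproducible from published descriptions. The log records
  each fill's relative fluctuation against the preceding observed year, so
  the <5% adjacency screen can be applied post hoc. No extrapolation:
  leading/trailing gaps stay missing and are logged.
- **Consistency rules** are report-only: violations of row-wise
  `lhs relation factor·rhs` rules are listed, never auto-corrected.

## Synthetic panel generator

The generator's defaults encode the study design the analysis assumes:
31 regions × 13 years (2009–2021), equal weights.

- **Ranking variable:** log-normal (right-skewed, like per-capita GDP),
  log-scale sd 0.15 per region-year around persistent region effects
  (sd 0.4) and a mild common growth drift (0.05/yr), so per-year re-ranking
  is stable but not frozen — region effects dominate, as in real provincial
  panels.
- **Determinants:** x = 1 + a·(r − ½) + 0.15·ε, a monotone mixture of the
  pooled fractional rank r and standard-normal noise, floored at 0.05 to
  keep levels positive. The mixing weight a is tuned by bisection on the
  *realized* same-draw concentration index until it hits the target
  CI = rank_assoc × 0.3; 0.3 maps the unit association scale onto the
  0.05–0.3 magnitude range typical of provincial determinants. Realized
  indices are recorded in the ground truth; a miss beyond ±0.02 raises a
  calibration warning instead of failing silently.
- **Geographic code:** assigned by reversed terciles of the region effects
  (most developed third = 1, least = 3), reproducing the negative CI such
  east/central/west codings show empirically. It is generated, not
  calibrated.
- **Outcome:** y = α + Σ β_k x_k + trend·t + ε with default α = 2, default
  coefficients of order ±0.2–0.8 across five need and three non-need
  determinants, and Gaussian noise whose sd defaults to 10% of the
  systematic outcome sd — large enough that recovery is a real test, small
  enough that the model is "well specified" in the sense that the residual
  decomposition term should be near zero.

What the generator does *not* emulate: the empirical marginals of real
yearbook covariates, cross-determinant correlation beyond the shared
socio-economic gradient, spatial autocorrelation between neighboring
regions, and measurement error in the ranking variable. Passing recovery
tests therefore demonstrates correctness of the estimators under the
assumed linear model, not robustness to misspecification on real data.

The published 31-province fixture carries only outcome levels for four
years; it supports the descriptive arithmetic (national averages, rise
rates) exactly, but no rank-based analysis, since no ranking variable or
determinants are published at province level.

## Numerical choices and degenerate inputs

- Quantiles: numpy's default linear interpolation (type 7).
- Index arithmetic at full precision; rounding (3 decimals for indices,
  2 for percentages) happens only in the CLI reporting layer.
- Collinearity is detected by matrix rank before fitting and reported with
  the offending column names (QR with column pivoting).
- A constant *outcome* has C = 0 (zero covariance); a constant *ranking*
  variable is an error; a zero-mean outcome makes C undefined and raises.
- Bisection for determinant calibration: 80 iterations on a ∈ [−6, 6],
  monotone by construction, on a fixed noise draw — so generation is fully
  reproducible from the seed.
- Problem sizes in the test and acceptance runs (200 replicates at
  31 × 13, 1,000 random vectors for the dual-route check, a 360-case
  small-n sweep for the concentration-curve oracle) were chosen as the
  smallest sizes at which the Monte-Carlo checks are stable.

## Known limitations

- No inference for C, ISCI or contributions (no analytic or bootstrap
  standard errors); coefficient standard errors are exposed only to
  support recovery diagnostics.
- The ISCI's per-year regressions use 31 observations against up to 15
  regressors on real-shaped data; with that little data per year the
  per-year coefficients are noisy, which is inherent to the design, not to
  the implementation.
- Geographic location enters regressions as a single ordinal code
  (east 1 / central 2 / west 3) by default — one column, one coefficient;
  dummy encoding is configurable at the registry level but changes the
  decomposition's row structure.
- The IQR screen's single-pass convention is deliberate (see above); it is
  not a fixed-point operator on pathological tiny groups.
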