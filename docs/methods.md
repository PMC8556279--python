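# Methods

This note records the models implemented, the defaults and why, what the
synthetic generator does and does not emulate, and the numerical choices
that matter for reproducing results.

## Data model

The unit of analysis is the balanced county × year panel: each row carries
an annual mean PM₂.₅ concentration (μg/m³), on-road CO₂ emissions per km²
(10⁶ t/km² internally; summaries often print 10⁴ t/km²), land-cover
percentages, population density (10³ persons/km²), seasonal mean
temperatures (K) and relative humidities (%), and planar centroid
coordinates in km. Balance is enforced strictly (every county in every
year); physical-range violations warn by default and can be promoted to
errors. Published national tabulations of the study system report 3,107
counties over 2001–2016, i.e. 49,712 records (an introduction-level figure
of 3,017 circulates as well; 3,107 × 16 matches the printed record count
and is used here).

## Spatial weights

Queen contiguity: two polygons are neighbours iff their boundaries share
at least one point. On a square lattice this is the 8-cell Moore
neighbourhood; `lattice_queen` computes it by grid arithmetic and
`queen_contiguity` geometrically (shapely STRtree, snap tolerance 1e-9 of
the typical cell size for round-tripped coordinates). Isolated units are
permitted — their lag is zero — because real county maps contain islands.
Row standardization gives each neighbour of unit *i* weight 1/|N(i)|. The
row-standardized W of a symmetric contiguity is similar to a symmetric
matrix, so its spectrum is real and lies in [−1, 1]; this both guarantees
convergence of the spillover series for |λ| < 1 and supplies exact
log-determinants for the likelihood.

## Spatial panel estimation

All global models are estimated after the within transformation (county
demeaning), which removes the fixed effects and commutes with W applied
per year. For the combined model

    y_t = λ W y_t + X_t β + α + u_t,    u_t = ρ W u_t + ν_t,

the log-likelihood is concentrated over (λ, ρ): for fixed spatial
parameters, β is GLS on the doubly transformed data
(y* = (I−ρW)(I−λW)y, X* = (I−ρW)X) and σ² is the mean squared transformed
residual, with Jacobian terms T·Σᵢ ln(1−λωᵢ) + T·Σᵢ ln(1−ρωᵢ) from the
eigenvalues ωᵢ of W. The optimizer is L-BFGS-B on the stationary interval
(1/ω_min + ε, 1 − ε), restarted from (0,0) and (±0.5, ±0.5); the best
likelihood wins, ties broken toward smaller |λ|+|ρ| (tolerance 1e-8 on
the objective). Estimates within 1e-3 of the boundary raise a convergence
warning. Slope standard errors are conditional-GLS (σ̂²(X*′X*)⁻¹); (λ, ρ)
standard errors come from a numerical Hessian of the concentrated
likelihood. The reported R² is the squared correlation between the
reduced-form fit (I−λW)⁻¹Xβ̂ and the observed (within-transformed)
outcome.

The "sac" variant — lag plus error — is what the analysis chain treats as
its combined model. The textbook Durbin form with WX regressors is not the
default; spatially lagged regressors can be added explicitly as columns if
wanted.

### Diagnostics

- F test for individual effects: pooled OLS vs within SSRs,
  F(n−1, nT−n−p).
- Breusch–Pagan LM for random effects (balanced form), χ²(1).
- Hausman: within vs Swamy–Arora FGLS slopes, χ²(p) with a pseudo-inverse
  guard for near-singular contrast covariances.
- Locally robust LM lag/error on the within-transformed pooled panel, each
  χ²(1) under its null and robust to *local* misspecification of the other
  spatial correlation. Finite-sample form: because demeaning leaves T−1
  free periods per county, σ̂² uses N(T−1) and the trace term uses
  (T−1)·tr(W′W + WW); simulation at n = 100, T = 5 puts empirical size at
  the nominal 5% (the naive NT form over-rejects at ~7.5%). Under a strong
  non-local alternative (e.g. λ = 0.7) the opposite robust statistic still
  rejects above its size — expected, since robustness is only local.

The recommendation tree: no individual/random effects → pooled OLS;
F significant and (BP not, or Hausman significant) → FEM, else REM; then
significant robust LM lag and error jointly upgrade to the combined
spatial model, lag-only to the spatial lag model, error-only to the
spatial error model.

### Impacts

For each regressor, direct = mean diagonal and total = mean row sum of
Σ_{s=0..500} λˢWˢ·β, indirect = total − direct (an exact identity by
construction). With row-standardized W the total has closed form
β/(1−λ); truncation error at 500 terms is below 1e-8 for |λ| ≤ 0.8. The
dense-inverse route (`method="exact"`) exists solely as an independent
oracle. Standard errors for impacts are intentionally not provided.

## GTWR

One WLS fit per observation over its k nearest space–time neighbours,
Gaussian kernel exp(−d²/b²) with d² = φ_S·dS² + φ_T·dT², dS planar
Euclidean (km), dT in years. The k-th neighbour defines b (so it receives
weight e⁻¹ and is included). Under an adaptive bandwidth the kernel is
invariant to joint rescaling of (φ_S, φ_T), so φ_S is fixed at 1 and only
τ = φ_T/φ_S is searched, jointly with k, by leave-one-out CV (each
observation predicted from a local fit excluding itself; ties prefer
smaller k, then smaller τ). Local intercepts absorb county effects — no
explicit α_i inside local fits. A locally singular design falls back to a
ridge jitter of 1e-8 × mean diagonal of X′WX, counted on the results
object. Year-range restriction is first-class (`CountyPanel.restrict_years`),
mirroring analyses that drop early panel years for memory reasons. The
flat-kernel limit (fixed radius → ∞) reproduces pooled OLS and is used as
an oracle in tests; note that *scaling distances* does not flatten an
adaptive kernel — the invariance above — which is why the fixed-radius
override exists.

## Attribution

- Contribution: Con_it = β_it·CO2_it/AP_it·100 with the year-specific CO₂
  value (matching the *it* index); a period-mean switch exists because the
  prose description of the quantity is ambiguous between the two readings.
  Clamping to [0, 100] is median(0, Con, 100), idempotent, and applied
  unconditionally.
- Mortality propagation: MAP_t = MAP_{t−1}(1 + CPD·ΔAP) forward from the
  anchor year and the exact algebraic inverse backward (so a
  forward–backward round trip reproduces the anchor to machine precision).
  CPD defaults to 0.012 per μg/m³, the midpoint of the 0.7%–1.6% range in
  the concentration–mortality literature for annual all-cause mortality.
  Propagation is county-level by default; a national-level option
  propagates the population-weighted national mean concentration and
  redistributes by anchor-year shares. Deaths are kept real-valued
  internally and rounded only for display (integer-rounded yearly tables
  can disagree with their own totals by ±1).
- Mileage conversion: 404 g CO₂ per mile and 1.61 km per mile give
  3.985… billion km per 10⁶ t (displayed as 3.99); the headline slope is
  that factor divided by the total CO₂ impact (e.g. 0.646 → 6.17 billion
  vehicle-km per km² per μg/m³). Computed exactly from the constants and
  rounded only at display, which makes the lower-CI conversion 6.72 rather
  than a sometimes-printed 6.71 (input rounding).

## Synthetic data

Two generating processes, chosen to exercise exactly the estimators built
downstream:

- **constant mode** — the combined spatial panel model itself, solved
  exactly by sparse LU: Gaussian innovations (σ_ν), Gaussian county
  effects (σ_α) fixed over time, spatial parameters (λ, ρ) requiring
  row-standardized weights.
- **varying mode** — smooth coefficient surfaces in (x, y, t): each slope
  oscillates around its base with relative amplitude 0.5 over one spatial
  period across the lattice and one temporal period across the panel,
  plus Gaussian noise. True local coefficients are attached to the panel
  for recovery scoring.

Covariates come in a **realistic** style (log-normal CO₂ per km² around
4×10⁻³ in 10⁶ t/km² — the magnitude observed for U.S. counties — land-cover
shares that sum to ≤ 100%, CONUS-plausible climate fields, slow temporal
drift) and a **standardized** style (iid N(0,1) columns) for parameter
recovery experiments. At realistic magnitudes the within-county variation
of CO₂ is far too small for a desk-scale lattice to identify its
coefficient — which is faithful to why the real analysis needs ~50,000
records — so estimator-validation simulations use the standardized style,
with sizes 15×15 × 8 years (combined-model recovery), 10×10 × 5 years ×
500 replicates (test size/power), and 10×10 × 4 years = 400 observations
(GTWR surface recovery, where the chosen smoothness/noise puts true–
estimated slope correlation at ≈ 0.8). Baseline mortality is Poisson with
county means proportional to population density × concentration,
parameterizable to a national total (e.g. ~54,730).

What the generator does **not** emulate: irregular county polygons and
area heterogeneity, spatially correlated covariate *measurement error*,
atmospheric chemistry, or any real spatial texture of the CONUS. Passing
tests therefore certify the statistical machinery under its own
assumptions, not substantive conclusions about real air quality.

## Known limitations

- Random-effects spatial models, GMM estimators and dynamic panels are out
  of scope; so are impact standard errors.
- The GTWR is O(n²) in memory/time for distances; fine at desk scale
  (≲ 5,000 observations), not engineered for the full 49,712-record case.
- The likelihood is concentrated but the (λ, ρ) surface can be flat when
  both parameters are weakly identified (small T, weak signal); the
  multi-start strategy mitigates but does not eliminate this.
- Linear interpolation of slowly varying covariates between anchor years
  uses nearest-anchor constant extrapolation outside the anchor range,
  with a warning.
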