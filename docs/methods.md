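# Methods

`gtwr-panel` estimates how the association between socioeconomic covariates and
city-level birth rates varies over space and time, and screens birth-rate maps
for clustering and hot/cold spots. This note documents the models, the
numerical choices, and what the synthetic test bed does and does not show.

## The regression model

Each city-year observation i at planar location (u_i, v_i) and year t_i gets
its own coefficient vector:

    y_i = β_0(u_i, v_i, t_i) + Σ_k β_k(u_i, v_i, t_i) x_ik + ε_i

with y the birth rate (births per 1,000 population, ‰) and x the covariates.
The local coefficients at point i are estimated by weighted least squares,

    β̂(i) = (XᵀW_i X)⁻¹ XᵀW_i y,   W_i = diag(w_i1 … w_in),

where the weights decay with the combined squared space-time distance

    d²_ij = λ[(u_i−u_j)² + (v_i−v_j)²] + μ(t_i−t_j)².

Only the ratio τ = μ/λ is identifiable jointly with the bandwidth, so λ ≡ 1.
Setting μ = 0 recovers purely spatial GWR; letting the bandwidth grow recovers
global OLS — the test suite verifies this reduction chain to 1e−6.

**Kernels.** Gaussian `exp(−d²/h²)` (default; weights never vanish, so no
observation is ever isolated) and bisquare `(1−d²/h²)²` inside h, 0 beyond.
Temporal weighting is symmetric in time; a causal past-only variant exists but
is off by default, matching the standard formulation.

**Calibration.** Leave-one-out cross-validation: each observation is
re-predicted with its own weight forced to zero, and the score Σ(y_i−ŷ_(i))²
is minimized by a deterministic golden-section search on log-bandwidth over
[smallest nonzero pairwise distance, 2 × largest pairwise distance]. τ is
searched over the dimensionless grid {0, 0.25, 0.5, 1, 2, 4, 8}; a grid value
is converted to μ by multiplying with (median pairwise spatial distance /
median pairwise temporal distance)², so τ = 1 means spatial and temporal
separation contribute comparably. The conversion matters: coordinates are
km-like (distances of hundreds of units) while year offsets are ≤ 9, so an
unscaled single-digit μ could never make time matter. A bandwidth that leaves
any point underdetermined (possible only with the bisquare kernel) scores
infinity — never silently dropped.

**Diagnostics.** Effective parameters are the hat-matrix trace
tr(S) = Σ_i w_ii·x_iᵀ(XᵀW_iX)⁻¹x_i; adjusted R² = 1 − [RSS/(n−tr S)]/[TSS/(n−1)];
AICc = 2n·ln σ̂ + n·ln 2π + n(n+tr S)/(n−2−tr S) with σ̂² = RSS/n. Singular
local normal matrices get a trace-scaled ridge of 1e−8 before a hard error.

**Non-stationarity screen.** A coefficient is declared spatially/temporally
varying when the interquartile range of its n local estimates strictly exceeds
twice its OLS standard error. Quartiles use linear interpolation (type 7);
the screen's outcome depends on that convention, hence it is pinned. With
exactly zero residual noise the OLS standard errors are zero and the strict
inequality flags everything — the screen presumes a stochastic model, and the
tests exercise it accordingly.

## Spatial statistics

**Weights.** k-nearest (ties broken by unit order), binary distance band, or
inverse distance within a band. When no band is given, the
minimum-spanning-distance rule picks the smallest band under which every city
has ≥ 1 neighbor. Rows are standardized to sum to one for Moran/LISA; Gi*
uses binary band weights with the self-weight included. Units that still end
up neighborless ("isolates", e.g. remote cities under an explicit small band)
are excluded from the statistic with a warning rather than an error.

**Global Moran's I** with expectation −1/(n−1), the normality-assumption
analytic variance, and permutation inference. **Local Moran (LISA)** uses
conditional permutation (the focal value held fixed, neighbors drawn from the
remaining units without replacement) and labels significant units HH/LL/HL/LH
by the signs of the standardized value and its spatial lag. **Gi*** is the
usual z-score of the locally weighted sum including self, categorized at the
two-sided 90/95/99% normal quantiles.

Permutation p-values use the +1 pseudo-p correction,
p = (1 + #extreme)/(1 + n_perm), with two-sided extremity: distance from the
null expectation for global I, absolute value for local statistics. The
default is 999 permutations; LISA applies no multiple-testing correction by
default (an optional Benjamini-Hochberg flag exists), matching common
exploratory practice. The suite verifies a ≤ 7% empirical rejection rate at
nominal α = 0.05 over 500 null replicates.

The two-phase comparison (pre/post-policy) computes Moran's I on each city's
period-mean birth rate by default; a year-stacked alternative is exposed since
either pooling is defensible and sources rarely state which was used.

## The synthetic panel generator

No city-level panel is publicly deposited, so the generator is the test bed:

- **Layout**: cities in a [0, 1000]² km-like planar window, uniform or
  clustered (cluster centers uniform in the inner 80%, Gaussian scatter
  sd 60 km). Geometry is metric but deliberately abstract — no attempt at
  real administrative geography.
- **Covariates**: independent truncated Gaussians matched to the published
  sample means/SDs of the nine indicators (log scales where the analysis
  logs them). Truncation is symmetric at ±3.5 SD so sample means stay on
  target (verified to 3 standard errors at n = 2,860); the urbanization share
  is additionally clamped to (0.01, 0.99). Independence and symmetric
  truncation are simplifications: real covariates are correlated and some
  shares (e.g. science-and-technology expenditure) cannot be negative, so a
  small fraction of synthetic values can be mildly implausible.
- **Truth surfaces**: constant, planar gradient, Gaussian bump, linear time
  ramp, or a space-time product; evaluated exactly and stored per record so
  recovery error is measurable. Default truth places a broad bump on the
  intercept (base 5.25, amplitude 5, scale 300 km), chosen so the response
  mean lands near the published ‰ summary (≈ 10.9).
- **Noise and missingness**: iid Gaussian noise (default 1‰); completely
  random record deletion emulates yearbook exclusions. Responses are floored
  at 0 (birth rates are non-negative); at the default scales the floor is
  essentially never active.
- **Determinism**: one seed sequence split by purpose (layout / covariates /
  noise / missingness), so adding a covariate never changes coordinates.

Passing recovery tests on this generator shows the estimator finds smooth
coefficient fields under clustered layouts and iid noise. It does not show
robustness to covariate collinearity, spatially correlated errors,
measurement error, or real geographic boundary effects.

## Problem sizes and defaults

The bundled recovery study uses 200 cities × 5 years (n = 1,000) with one
spatial-bump coefficient (amplitude 2, length scale 200 km), one temporal ramp
(−0.25/‰ per year), noise sd 0.5‰ — large enough that the CV calibration and
the non-stationarity screen behave as they would at study scale, small enough
to run in seconds. The full end-to-end pipeline default is 150 cities × 10
years with 499 permutations. Report CSVs are rounded to 6 decimals; all
internal arithmetic is full precision, and the two-phase change column is the
exact difference of the phase means before any rounding.

## Known limitations

- Fixed (non-adaptive) bandwidth is the default; adaptive neighbor-count
  bandwidths, mixed/semiparametric and multiscale variants are out of scope.
- No bootstrap or analytic inference on individual local coefficients.
- The golden-section search assumes a roughly unimodal CV profile; on
  pathological profiles it returns the best point evaluated and flags
  convergence in the result.
- Longitude/latitude input is projected with a sinusoidal equal-area mapping,
  adequate for kernel distances over a mid-latitude country but not for
  cartography.
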