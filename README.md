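# gtwr-panel

Spatiotemporal regression and hot-spot analysis for city-level demographic
panels: when birth rates (or any city-year outcome) vary across a country and
a decade, a single global regression only reports average effects. This
package estimates **Geographically and Temporally Weighted Regression (GTWR)**
— a local linear model in which every city-year observation gets its own
coefficient vector — alongside the exploratory spatial statistics used to
motivate it (global and local Moran's I, Getis-Ord Gi\* hot/cold spots). It is
written for demographers and spatial epidemiologists analyzing panels such as
Chinese prefecture-city birth rates against socioeconomic indicators.

## The model

For observation i at location (u_i, v_i) and year t_i,

```
y_i = β₀(u_i, v_i, t_i) + Σ_k β_k(u_i, v_i, t_i) x_ik + ε_i
```

Local coefficients are fit by weighted least squares,
β̂(i) = (XᵀW_iX)⁻¹XᵀW_iy, with kernel weights decaying in the combined
squared space-time distance d² = λ·Δspace² + μ·Δtime². The bandwidth h and
the space-time ratio τ = μ/λ are calibrated by leave-one-out cross-validation
(golden-section search, deterministic). τ = 0 recovers purely spatial GWR;
h → ∞ recovers global OLS. A variable is declared non-stationary when the
interquartile range of its local coefficients exceeds twice its OLS standard
error. Full details and numerical conventions are in
[docs/methods.md](docs/methods.md).

Because real city-level yearbook panels are typically not redistributable,
the package ships a synthetic-panel generator with known, configurable
coefficient surfaces (constant / spatial gradient / Gaussian bump / temporal
ramp), so estimators are validated by parameter recovery against exact truth.

## Worked example

Simulate a 200-city × 5-year panel in which the GDP-per-capita coefficient is
a spatial Gaussian bump (amplitude 2 around a base of −1) and the house-price
coefficient ramps down over time, calibrate the kernel by CV, and compare
GTWR with OLS:

```python
import numpy as np
from gtwrpanel import (simulate_panel, optimize_bandwidth, fit_gtwr, fit_ols,
                       nonstationarity_test)
from gtwrpanel.synthetic import SyntheticConfig, SurfaceSpec, COVARIATE_SCALES

surfaces = {
    "intercept": SurfaceSpec(kind="constant", base_value=10.0),
    "pgdp": SurfaceSpec(kind="gaussian_bump", base_value=-1.0, amplitude=2.0,
                        center=(600.0, 400.0), length_scale=200.0),
    "hp": SurfaceSpec(kind="linear_time", base_value=0.6, time_slope=-0.25),
}
config = SyntheticConfig(
    n_cities=200, years=tuple(range(2012, 2017)), layout="clustered", n_clusters=8,
    coefficient_surfaces=surfaces,
    covariate_scales={k: COVARIATE_SCALES[k] for k in ("pgdp", "hp")},
    noise_sd=0.5, seed=7,
)
panel = simulate_panel(config)
search = optimize_bandwidth(panel)
fit = fit_gtwr(panel, search.kernel)
ols = fit_ols(panel)
print(f"bandwidth h = {search.kernel.bandwidth:.1f}, tau = {search.kernel.tau:.0f}")
print(f"adjusted R2: GTWR {fit.adjusted_r2:.3f} vs OLS {ols.adjusted_r2:.3f}")
rmse = np.sqrt(np.mean((fit.coefficients["pgdp"] - panel.truth["beta_pgdp"])**2))
print(f"pgdp coefficient RMSE vs truth: {rmse:.3f}")
print(nonstationarity_test(fit, ols).round(3))
```

Output:

```
bandwidth h = 98.5, tau = 42010
adjusted R2: GTWR 0.976 vs OLS 0.006
pgdp coefficient RMSE vs truth: 0.233
           iqr_gtwr  two_se_ols  nonstationary
intercept     3.029       3.499          False
pgdp          0.920       0.361           True
hp            0.548       0.401           True
```

Reading it: CV selected a ~100 km bandwidth with strong temporal weighting
(τ is large because coordinates are in km while year offsets are single
digits). GTWR explains almost all response variance while OLS — forced to a
single national coefficient — explains almost none, since the true effects
vary over space and time. The local GDP coefficient tracks its true surface
to 0.23 RMSE (the surface spans 2 units), and the IQR-vs-2SE screen flags
exactly the two genuinely varying coefficients while leaving the constant
intercept unflagged.

## Command line

```sh
gtwr-panel simulate --out panel.csv --n-cities 286 --seed 1
gtwr-panel autocorr panel.csv --out moran_by_year.csv
gtwr-panel hotspots panel.csv --year 2017 --out-prefix hs2017
gtwr-panel fit-gtwr panel.csv --out fit.csv --diagnostics diag.json
gtwr-panel report fit.csv --out-dir reports/
gtwr-panel run-all config.json --out-dir results/
```

`run-all` executes the whole chain — transforms, annual and two-phase Moran's
I, LISA and Gi\* maps, OLS baseline, CV bandwidth search, GTWR, the
non-stationarity screen and all report tables — and writes a manifest JSON
from which the run is bit-for-bit reproducible.

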