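# Methods

## Model and assumptions

Edge degradation of above-ground biomass is modelled per sub-region as a
single asymptotic (von Bertalanffy) curve in distance-to-edge,
b(d) = θ₁ − θ₂·exp(−d·θ₃), fitted by unweighted nonlinear least squares to
every forest pixel in the tile. The model assumes one homogeneous edge
response per tile (θ constant within a sub-region), isotropic edges (only
distance matters, not direction or the type of adjacent non-forest), and
additive residual noise. Distance is the exact Euclidean centre-to-centre
distance from a forest pixel to the nearest non-forest pixel, computed on
the full grid *before* tiling so tile boundaries never create phantom
edges. Pixels outside the raster are neither forest nor non-forest: the map
border never generates an edge, and forest pixels closer to the border than
to any mapped non-forest pixel are flagged as carrying a lower-bound
distance rather than dropped.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| pixel_size_km | 0.465 | km | 465 m land-cover/biomass grid; pixel area 21.6 ha |
| forest classes | {1,…,5} | IGBP codes | the five forest types (≥60% tree cover, ≥5 m) |
| tile area | 10,000 (pipeline demo: ~2,162) | km² | one edge model per tile; the demo value gives 100-pixel tiles |
| min_forest_pixels | 500 | pixels | below this a 3-parameter nonlinear fit is unstable; tile flagged skipped |
| edge_offset_km | 0.232 | km | half a pixel: the mapped edge can sit anywhere within the edge pixel, so M is evaluated at d = 0.232 rather than 0 |
| p | 90 | % | edge-area threshold: A(90) bounds the pixels modelled below 90% of the asymptote |
| carbon fraction | 0.47 | – | IPCC tropical-forest conversion from biomass to carbon |
| Tukey c, scale | 4.685, normalized MAD | – | standard 95%-efficiency bisquare tuning |
| IRLS tol / max iter | 1e-6 / 50 | – | coefficient-change convergence |
| NLS tol / max iter | 1e-8 / 200 | – | relative residual change |

## Numerical choices

* **Initialization.** θ₁⁰ = mean biomass in the top distance quartile,
  θ₂⁰ = max(θ₁⁰ − bottom-quartile mean, 1), θ₃⁰ = 1 km⁻¹, with a
  multi-start ladder θ₃⁰ ∈ {0.25, 0.5, 1, 2, 4} if the first start fails.
  Unconverged tiles carry `converged=False` and are excluded from metrics,
  maps and covariate tables (counted in the manifest), never silently
  replaced.
* **Degenerate inputs.** Fits require ≥10 samples at ≥3 distinct
  distances; constant biomass converges with θ̂₂ ≈ 0 (no edge effect);
  θ̂₂ < 0 (biomass higher at the edge) reports M = 0 with an
  `inverse-effect` flag, honouring the [0, 1] bound on magnitude.
* **Clamps and caps.** M is clamped to [0, 1] and A(p) capped at the
  maximum observed distance, both flagged. A(p) uses the definitional
  inversion of b(d) — evaluating the fitted curve at A(p) returns exactly
  p% of θ₁ — and does not incorporate the 0.232 km offset, which concerns
  the edge position, not the threshold crossing.
* **R².** Approximate, 1 − SSE/SST on the fitted samples, clamped at 0.
  For robust fits, R² is computed on the weighted response and equals OLS
  R² when all weights are 1.
* **Robust scale degeneracy.** When OLS residuals of a covariate fit have
  MAD < 10⁻⁹·sd(y) (an essentially exact linear relationship) the bisquare
  standardization is meaningless; the fit returns the OLS solution with
  unit weights instead of weights driven by rounding noise.
* **Subset selection.** The full robust model's weights are frozen; every
  subset up to k_max (≤20 candidates, exhaustive) is scored by BIC under
  weighted least squares with those weights,
  BIC = n·ln(Σwᵢeᵢ²/n) + k·ln(n); the winner is refitted robustly with
  refreshed weights. Ties break toward fewer predictors, then
  lexicographically — fully deterministic.
* **Edge area and binning.** Membership is strict d < A(90). The
  missing-biomass profile bins distance at whole pixel widths starting at
  one pixel (the minimum possible distance); the last bin absorbs the tail
  so per-bin deficits always sum exactly to the aggregate. "Directly
  adjacent to non-forest" means d < 1.5 pixel widths, covering both rook
  and diagonal adjacency.
* **Representative curve.** The sub-region minimizing Euclidean distance
  to the weighted mean in standardized (M, A(90)) space, weighted by forest
  pixel count (the weighting is exposed as a parameter since other choices
  are defensible); ties go to the smallest id.
* **Unit chain.** Carbon totals are Mg C ha⁻¹ × ha pixel⁻¹ × pixel count,
  reported in Pg (10⁹ Mg), with all intermediates retained in the summary
  so every percentage can be recomputed from the stored totals.

## The synthetic generator

Masks are all-forest grids minus axis-aligned rectangular clearings and
1-pixel random-walk tendrils, mixing smooth and convoluted edges; defaults
(200×200 pixels, 5 clearings of 8–30 pixels, 3 tendrils) leave interior
pixels several km from any edge so that A(90) ≈ 1.6 km (true θ =
(300, 150, 1)) is well inside the observed distance range. Biomass is the
model evaluated at the true distance field plus Gaussian noise truncated at
zero (no residual model is prescribed for the real data; truncated Gaussian
is the simplest non-negative choice), default sd = 30 Mg ha⁻¹ = 10% of θ₁.
θ₁ = 300 Mg ha⁻¹ matches dense tropical moist forest; θ₂/θ₁ = 0.5 and
θ₃ = 1 km⁻¹ put the magnitude (M ≈ 0.40) and scale (A(90) ≈ 1.6 km) in the
upper-middle of the ranges seen across real tropical sub-regions.
Covariate studies draw six predictors from fixed plausible distributions
(latitude, elevation, precipitation, soil water capacity, dry-season
length, a cropland-anthrome proportion) and plant a linear response with
optional gross outliers (±10 response-sd shifts, indices recorded).

What the generator does **not** emulate: spatial autocorrelation of biomass
beyond the distance trend, land-cover classification error, within-tile
heterogeneity of θ, correlated or non-Gaussian covariates. Passing tests
therefore demonstrate that the estimators recover known parameters under
the model's own assumptions — not that those assumptions hold for any
particular real landscape.

## Problem sizes

The default test battery uses 100–200 pixel square landscapes (the
end-to-end demo: 200×200 pixels, four 100-pixel tiles), 20-tile recovery
ensembles at 120×120, and 50-replicate covariate selections at n = 300 —
sizes chosen so the whole suite runs in seconds while every distance field
still spans many multiples of 1/θ₃.

## Known limitations

* Inputs must already be co-registered in an equal-area frame; there is no
  reprojection or resampling, and raster I/O is plain TIFF with a JSON
  sidecar (pixel size, nodata), not CRS-tagged GeoTIFF.
* Tiling is a fixed square grid; tiles are not forest-area-equalized.
* No uncertainty intervals on θ, M or A(p); responses are regressed
  untransformed.
* Carbon accounting covers above-ground biomass only — no below-ground or
  soil carbon.
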