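# forestedge

Biomass in fragmented tropical forests declines toward the forest edge, but
carbon inventories built from land-cover type alone (IPCC Tier-1-style
accounting) assign every forest pixel the interior density and miss that
degradation. `forestedge` is a pipeline for quantifying the edge effect from
co-registered land-cover and biomass rasters and converting it into
edge-aware carbon-stock estimates. It is aimed at landscape ecologists and
carbon-accounting analysts working with moderate-resolution (~500 m)
remote-sensing products.

## The model

For every fixed-area sub-region (default ~10,000 km² tiles, configurable),
each forest pixel (IGBP land-cover classes 1–5) gets the exact Euclidean
centre-to-centre distance *d* (km) to the nearest non-forest pixel, and
biomass density *b* (Mg ha⁻¹) is regressed on *d* with the von Bertalanffy
asymptotic model

    b(d) = θ₁ − θ₂ · exp(−d·θ₃)

where θ₁ is the asymptotic (interior) biomass, θ₁ − θ₂ the density at the
theoretical edge, and θ₃ (km⁻¹) the recovery rate. Each fit is summarized
by

* **magnitude** M = θ₂·exp(−0.232·θ₃)/θ₁ ∈ [0, 1], the proportional biomass
  reduction at the edge (the 0.232 km offset is half a 465 m pixel, the
  positional uncertainty of the mapped edge), and
* **scale** A(p) = ln(θ₂ / ((1 − p/100)·θ₁)) / θ₃, the distance at which
  biomass reaches p% of the asymptote (default p = 90), floored at 0 and
  capped at the maximum observed distance.

Sub-region metrics are regressed on physical/human covariates (dry-season
length, elevation, anthrome proportions, …) with Tukey-bisquare robust
regression and exhaustive BIC-guided subset selection. Finally, over the
A(90) "edge area" (pixels with d < A(90)), three carbon totals are compared
after applying the 0.47 tropical carbon fraction: the modelled total b(d),
the uniform-interior total 0.9·θ₁, and the empirical raster total. Their
difference is the "missing biomass" carbon deficit hidden by uniform
accounting.

Because the pantropical input rasters are large external downloads, the
package ships a synthetic-landscape generator (fragmented masks, biomass
simulated forward from the model plus noise, precipitation stacks, covariate
tables with planted effects) so the entire pipeline is testable end to end
against known ground truth.

## Worked example

Run the full synthetic pipeline (200×200 pixels of 465 m, four sub-regions,
true θ = (300, 150, 1), 10% noise):

```bash
forest-edges all --seed 7 --tile-area-km2 2162.25 --out demo
```

which prints a manifest ending in

```
"carbon": {
    "carbon_fraction": 0.47,
    "n_edge_pixels": 1702,
    "mean_modelled_mgc_ha": 111.65,
    "mean_uniform_mgc_ha": 126.81,
    "deficit_pg": 0.000558,
    "overestimate_pct": 11.96,
    "model_vs_empirical_pct": -0.060,
    "edge_area_fraction": 0.045,
    "first_pixel_adjacent_fraction": 0.333
}
```

and writes `demo/edge_fits.csv`, whose first row is

```
id,theta1,theta2,theta3,converged,M,A90,R2,n_pixels
0,299.85,150.54,1.011,True,0.3971,1.596,0.242,8995
```

Reading this: the fit recovered the generating parameters (θ̂₁ = 299.85 vs
300, M̂ = 0.397 vs the true 0.3966, Â(90) = 1.60 km vs ln 5 = 1.61 km);
biomass at the edge is ~40% below the interior plateau and takes ~1.6 km to
recover to 90% of it. Assuming uniform interior biomass across the edge
area would overstate its carbon stock by ~12% (`overestimate_pct`), a
deficit of 5.6×10⁻⁴ Pg C on this small landscape; the modelled and
empirical totals agree to 0.06%. A third of edge-area pixels touch
non-forest directly, but the remaining deficit extends several pixels
inward (`demo/missing_biomass_profile.csv` bins it by distance).

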