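"""Edge-aware carbon-stock accounting.

Above-ground biomass converts to carbon with a fixed carbon fraction (0.47,
the IPCC value for tropical forest).  The "edge area" of each sub-region is
the set of forest pixels closer to the edge than the fitted A(90) scale —
i.e. where the model predicts less than 90% of the asymptotic (interior)
biomass.  Over that area three totals are compared:

* modelled  — b(d) evaluated per pixel from its sub-region's fit;
* uniform   — every edge pixel assigned the interior density 0.9 * theta1
              (the naive Tier-1-style assumption);
* empirical — the observed biomass raster.

The uniform-minus-modelled difference is the carbon deficit the uniform
assumption hides; the modelled-vs-empirical comparison checks the model.
Totals follow the chain Mg C ha^-1 x ha pixel^-1 x pixel count, reported in
Pg (1 Pg = 1e9 Mg).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .edge_model import EdgeFit, EdgeMetrics, predict
from .raster import DistanceField, SubRegion

IPCC_TROPICAL_CARBON_FRACTION = 0.47
#: per-pixel area (ha) of a 465 m grid: 0.465 km squared x 100 ha / km^2
DEFAULT_PIXEL_AREA_HA = 21.466


@dataclass
class CarbonSummary:
    carbon_fraction: float
    pixel_area_ha: float
    n_edge_pixels: float
    mean_modelled_mgc_ha: float
    mean_uniform_mgc_ha: float
    mean_empirical_mgc_ha: float
    total_modelled_pg: float
    total_uniform_pg: float
    total_empirical_pg: float
    deficit_pg: float              # uniform - modelled
    overestimate_pct: float        # (uniform - modelled) / uniform * 100
    model_vs_empirical_pct: float  # (modelled - empirical) / empirical * 100
    edge_area_fraction: float      # edge pixels / forest pixels
    first_pixel_adjacent_fraction: float  # edge pixels directly adjacent to non-forest


def to_carbon(biomass, carbon_fraction: float = IPCC_TROPICAL_CARBON_FRACTION):
    """Convert above-ground biomass (Mg ha^-1) to carbon density (Mg C ha^-1)."""
    b = np.asarray(biomass, dtype=float)
    if np.nanmin(b, initial=0.0) < 0:
        raise ValueError("biomass must be non-negative")
    return b * carbon_fraction


def _total_pg(mean_density: float, pixel_area_ha: float, n_pixels: float) -> float:
    return mean_density * pixel_area_ha * n_pixels * 1e-9


def summary_from_densities(
    mean_modelled_mgc_ha: float,
    mean_uniform_mgc_ha: float,
    mean_empirical_mgc_ha: float,
    pixel_area_ha: float = DEFAULT_PIXEL_AREA_HA,
    n_pixels: float = 1e9,
    carbon_fraction: float = IPCC_TROPICAL_CARBON_FRACTION,
    edge_area_fraction: float = float("nan"),
    first_pixel_adjacent_fraction: float = float("nan"),
) -> CarbonSummary:
    """Assemble a CarbonSummary from mean edge-area carbon densities.

    This is the dimensional arithmetic at the end of the accounting chain,
    usable directly when densities come from an external inventory table.
    """
    tot_mod = _total_pg(mean_modelled_mgc_ha, pixel_area_ha, n_pixels)
    tot_uni = _total_pg(mean_uniform_mgc_ha, pixel_area_ha, n_pixels)
    tot_emp = _total_pg(mean_empirical_mgc_ha, pixel_area_ha, n_pixels)
    return CarbonSummary(
        carbon_fraction=carbon_fraction,
        pixel_area_ha=pixel_area_ha,
        n_edge_pixels=n_pixels,
        mean_modelled_mgc_ha=mean_modelled_mgc_ha,
        mean_uniform_mgc_ha=mean_uniform_mgc_ha,
        mean_empirical_mgc_ha=mean_empirical_mgc_ha,
        total_modelled_pg=tot_mod,
        total_uniform_pg=tot_uni,
        total_empirical_pg=tot_emp,
        deficit_pg=tot_uni - tot_mod,
        overestimate_pct=(tot_uni - tot_mod) / tot_uni * 100.0 if tot_uni else 0.0,
        model_vs_empirical_pct=(tot_mod - tot_emp) / tot_emp * 100.0 if tot_emp else 0.0,
        edge_area_fraction=edge_area_fraction,
        first_pixel_adjacent_fraction=first_pixel_adjacent_fraction,
    )


def edge_area_pixels(
    distances: DistanceField,
    tiles: list[SubRegion],
    fits: dict[int, EdgeFit],
    metrics: dict[int, EdgeMetrics],
) -> np.ndarray:
    """Boolean raster of edge-area membership: forest pixels with d < A(90)
    of their sub-region's fit (strict inequality).  Sub-regions without a
    converged fit, or with A(90) = 0, contribute no pixels.
    """
    out = np.zeros(distances.distance_km.shape, dtype=bool)
    d = distances.distance_km
    for t in tiles:
        fit = fits.get(t.id)
        if fit is None or not fit.converged or t.id not in metrics:
            continue
        a = metrics[t.id].scale_km
        if a <= 0:
            continue
        win = t.window
        out[win] = np.isfinite(d[win]) & (d[win] < a)
    return out


def _per_pixel_densities(edge_mask, distances, biomass, tiles, fits, carbon_fraction):
    """Carbon density triples (modelled, uniform, empirical) for every
    edge-area pixel, in raster-flattened order."""
    d = distances.distance_km
    b = np.asarray(biomass, dtype=float)
    modelled = []
    uniform = []
    empirical = []
    dist = []
    for t in tiles:
        win = t.window
        sel = edge_mask[win]
        if not sel.any():
            continue
        fit = fits.get(t.id)
        if fit is None or not fit.converged:
            raise ValueError(
                f"edge pixels present in sub-region {t.id} but no converged fit supplied"
            )
        dd = d[win][sel]
        modelled.append(predict(fit.theta1, fit.theta2, fit.theta3, dd) * carbon_fraction)
        uniform.append(np.full(dd.size, 0.9 * fit.theta1 * carbon_fraction))
        empirical.append(b[win][sel] * carbon_fraction)
        dist.append(dd)
    if not modelled:
        raise ValueError("edge-pixel set is empty")
    return (np.concatenate(modelled), np.concatenate(uniform),
            np.concatenate(empirical), np.concatenate(dist))


def carbon_totals(
    edge_mask: np.ndarray,
    distances: DistanceField,
    biomass: np.ndarray,
    tiles: list[SubRegion],
    fits: dict[int, EdgeFit],
    carbon_fraction: float = IPCC_TROPICAL_CARBON_FRACTION,
    pixel_area_ha: float = DEFAULT_PIXEL_AREA_HA,
    n_forest_pixels: int | None = None,
) -> CarbonSummary:
    """Modelled / uniform / empirical carbon totals over the edge area."""
    mod, uni, emp, dd = _per_pixel_densities(
        edge_mask, distances, biomass, tiles, fits, carbon_fraction
    )
    n = mod.size
    if n_forest_pixels is None:
        n_forest_pixels = int(np.isfinite(distances.distance_km).sum())
    # pixels directly adjacent to non-forest: nearest centre within 1.5 pixel
    # widths covers both rook and diagonal adjacency
    adjacent = float((dd < 1.5 * distances.pixel_size_km).mean())
    # empirical mean ignores missing biomass pixels
    emp_ok = emp[np.isfinite(emp)]
    return summary_from_densities(
        mean_modelled_mgc_ha=float(mod.mean()),
        mean_uniform_mgc_ha=float(uni.mean()),
        mean_empirical_mgc_ha=float(emp_ok.mean()) if emp_ok.size else float("nan"),
        pixel_area_ha=pixel_area_ha,
        n_pixels=n,
        carbon_fraction=carbon_fraction,
        edge_area_fraction=n / n_forest_pixels if n_forest_pixels else float("nan"),
        first_pixel_adjacent_fraction=adjacent,
    )


def missing_biomass_profile(
    edge_mask: np.ndarray,
    distances: DistanceField,
    tiles: list[SubRegion],
    fits: dict[int, EdgeFit],
    n_bins: int = 10,
    carbon_fraction: float = IPCC_TROPICAL_CARBON_FRACTION,
    pixel_area_ha: float = DEFAULT_PIXEL_AREA_HA,
) -> pd.DataFrame:
    """Missing-biomass (uniform - modelled) deficit binned by distance.

    Bin edges are multiples of the pixel width starting at one pixel (the
    closest possible distance); the last bin is extended to include every
    remaining edge pixel, so the per-bin deficits always sum to the aggregate
    deficit.  Columns: bin_lo_km, bin_hi_km, n_pixels, mean_modelled_mgc_ha,
    mean_uniform_mgc_ha, deficit_pg, deficit_share, first_bin_fraction.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be at least 1")
    mod, uni, dd = _profile_inputs(edge_mask, distances, tiles, fits, carbon_fraction)
    px = distances.pixel_size_km
    # bin edges at whole pixel widths starting at the minimum possible
    # distance (one pixel); final edge stretched past the farthest pixel
    edges = px * np.arange(1, n_bins + 1, dtype=float)
    edges = np.append(edges, max(float(dd.max()) + px, edges[-1] + px))
    idx = np.clip(np.digitize(dd, edges) - 1, 0, n_bins - 1)

    deficit_px = (uni - mod) * pixel_area_ha * 1e-9
    total_deficit = float(deficit_px.sum())
    rows = []
    for k in range(n_bins):
        sel = idx == k
        n = int(sel.sum())
        rows.append(
            {
                "bin_lo_km": edges[k],
                "bin_hi_km": edges[k + 1],
                "n_pixels": n,
                "mean_modelled_mgc_ha": float(mod[sel].mean()) if n else np.nan,
                "mean_uniform_mgc_ha": float(uni[sel].mean()) if n else np.nan,
                "deficit_pg": float(deficit_px[sel].sum()),
                "deficit_share": float(deficit_px[sel].sum()) / total_deficit if total_deficit else 0.0,
            }
        )
    df = pd.DataFrame(rows)
    df["first_bin_fraction"] = df.loc[0, "n_pixels"] / df["n_pixels"].sum()
    return df


def _profile_inputs(edge_mask, distances, tiles, fits, carbon_fraction):
    """Per-edge-pixel modelled and uniform densities plus distances (the
    empirical raster is not needed for the deficit profile)."""
    d = distances.distance_km
    mod, uni, dist = [], [], []
    for t in tiles:
        win = t.window
        sel = edge_mask[win]
        if not sel.any():
            continue
        fit = fits.get(t.id)
        if fit is None or not fit.converged:
            raise ValueError(
                f"edge pixels present in sub-region {t.id} but no converged fit supplied"
            )
        dd = d[win][sel]
        mod.append(predict(fit.theta1, fit.theta2, fit.theta3, dd) * carbon_fraction)
        uni.append(np.full(dd.size, 0.9 * fit.theta1 * carbon_fraction))
        dist.append(dd)
    if not mod:
        raise ValueError("edge-pixel set is empty")
    return np.concatenate(mod), np.concatenate(uni), np.concatenate(dist)
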