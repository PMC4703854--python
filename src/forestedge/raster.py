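"""Land-cover masking, distance-to-edge, and sub-region tiling.

The landscape is a pair of co-registered rasters in an equal-area frame: an
integer land-cover raster (IGBP-style codes, classes 1-5 = forest) and an
above-ground biomass raster in Mg ha^-1 with NaN marking non-forest / missing
pixels.  Every forest pixel is assigned the Euclidean centre-to-centre
distance (km) to the nearest non-forest pixel, and the grid is partitioned
into fixed-area square sub-regions inside which one edge model is fitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

#: IGBP land-cover codes treated as forest: evergreen needleleaf (1),
#: evergreen broadleaf (2), deciduous needleleaf (3), deciduous broadleaf (4),
#: mixed forest (5).
DEFAULT_FOREST_CLASSES = frozenset({1, 2, 3, 4, 5})

#: Default pixel edge length in km (465 m pixels).
DEFAULT_PIXEL_SIZE_KM = 0.465


@dataclass
class LandscapeGrid:
    """Co-registered land-cover and biomass rasters.

    Pixel area in hectares is ``pixel_size_km**2 * 100``.
    """

    land_cover: np.ndarray
    biomass: np.ndarray
    pixel_size_km: float = DEFAULT_PIXEL_SIZE_KM
    crs: str = "synthetic-equal-area"

    def __post_init__(self) -> None:
        self.land_cover = np.asarray(self.land_cover)
        self.biomass = np.asarray(self.biomass, dtype=float)
        if self.land_cover.shape != self.biomass.shape:
            raise ValueError(
                "land cover and biomass rasters must be co-registered: shapes "
                f"{self.land_cover.shape} vs {self.biomass.shape}"
            )
        if self.pixel_size_km <= 0:
            raise ValueError("pixel_size_km must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.land_cover.shape

    @property
    def pixel_area_ha(self) -> float:
        return self.pixel_size_km**2 * 100.0


@dataclass
class DistanceField:
    """Per-forest-pixel Euclidean distance to the nearest non-forest centre.

    ``distance_km`` is NaN on non-forest pixels.  ``boundary_lower_bound``
    flags forest pixels whose nearest true edge may lie off-raster (the raster
    border is closer than the nearest mapped non-forest pixel), where the
    stored distance is only a lower bound.
    """

    distance_km: np.ndarray
    pixel_size_km: float
    boundary_lower_bound: np.ndarray
    max_observed_km: float


@dataclass
class SubRegion:
    """A rectangular tile of the grid (half-open pixel window)."""

    id: int
    row_start: int
    row_stop: int
    col_start: int
    col_stop: int
    forest_pixels: int = 0
    skipped: bool = False

    @property
    def window(self) -> tuple[slice, slice]:
        return (slice(self.row_start, self.row_stop), slice(self.col_start, self.col_stop))

    def area_km2(self, pixel_size_km: float) -> float:
        n = (self.row_stop - self.row_start) * (self.col_stop - self.col_start)
        return n * pixel_size_km**2


def make_forest_mask(land_cover: np.ndarray, forest_classes=DEFAULT_FOREST_CLASSES) -> np.ndarray:
    """Boolean forest mask: True where the land-cover code is a forest class."""
    if not forest_classes:
        raise ValueError("forest class set must be non-empty")
    return np.isin(np.asarray(land_cover), sorted(forest_classes))


def distance_to_edge(mask: np.ndarray, pixel_size_km: float = DEFAULT_PIXEL_SIZE_KM) -> DistanceField:
    """Exact Euclidean distance (km) from each forest pixel centre to the
    nearest non-forest pixel centre.

    Pixels outside the raster are neither forest nor non-forest, so the map
    border never creates an edge; forest pixels closer to the border than to
    any mapped non-forest pixel are flagged (their distance is a lower bound).

    Raises ``ValueError`` if the mask is all-forest (no edge present).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.all():
        raise ValueError("no edge present: mask contains no non-forest pixel")

    d = ndimage.distance_transform_edt(mask) * pixel_size_km
    distance = np.where(mask, d, np.nan)

    rows, cols = mask.shape
    i = np.arange(rows)[:, None]
    j = np.arange(cols)[None, :]
    # centre-to-centre distance to the nearest hypothetical off-raster cell
    border_km = (np.minimum.reduce([i, rows - 1 - i] ) + 1) * pixel_size_km
    border_km = np.minimum(border_km, (np.minimum(j, cols - 1 - j) + 1) * pixel_size_km)
    lower_bound = mask & (border_km < distance)

    max_obs = float(np.nanmax(distance)) if mask.any() else 0.0
    return DistanceField(
        distance_km=distance,
        pixel_size_km=pixel_size_km,
        boundary_lower_bound=lower_bound,
        max_observed_km=max_obs,
    )


def brute_force_distance(mask: np.ndarray, pixel_size_km: float = DEFAULT_PIXEL_SIZE_KM) -> np.ndarray:
    """O(n^2) reference nearest-non-forest-centre search (small rasters only).

    Exists as an independent check of :func:`distance_to_edge`; NaN on
    non-forest pixels.
    """
    mask = np.asarray(mask, dtype=bool)
    nf = np.argwhere(~mask)
    if nf.size == 0:
        raise ValueError("no edge present: mask contains no non-forest pixel")
    out = np.full(mask.shape, np.nan)
    for r, c in np.argwhere(mask):
        dd = (nf[:, 0] - r) ** 2 + (nf[:, 1] - c) ** 2
        out[r, c] = math.sqrt(dd.min()) * pixel_size_km
    return out


def tile_subregions(
    forest_mask: np.ndarray,
    pixel_size_km: float = DEFAULT_PIXEL_SIZE_KM,
    target_area_km2: float = 10_000.0,
    min_forest_pixels: int = 500,
) -> list[SubRegion]:
    """Partition the grid into square tiles of about ``target_area_km2``.

    The tile edge is ``sqrt(target_area)`` rounded to whole pixels; edge tiles
    absorb the remainder.  Tiles with fewer than ``min_forest_pixels`` forest
    pixels are flagged ``skipped`` (excluded from fitting, never dropped from
    the partition).
    """
    forest_mask = np.asarray(forest_mask, dtype=bool)
    pixel_area = pixel_size_km**2
    if target_area_km2 < 100 * pixel_area:
        raise ValueError("target area must cover at least 100 pixels")
    edge_px = max(1, round(math.sqrt(target_area_km2) / pixel_size_km))
    rows, cols = forest_mask.shape

    row_edges = list(range(0, rows, edge_px)) + [rows]
    col_edges = list(range(0, cols, edge_px)) + [cols]
    # merge a trailing sliver (< half a tile) into the previous tile
    if len(row_edges) > 2 and row_edges[-1] - row_edges[-2] < edge_px / 2:
        row_edges.pop(-2)
    if len(col_edges) > 2 and col_edges[-1] - col_edges[-2] < edge_px / 2:
        col_edges.pop(-2)

    tiles: list[SubRegion] = []
    tid = 0
    for r0, r1 in zip(row_edges[:-1], row_edges[1:]):
        for c0, c1 in zip(col_edges[:-1], col_edges[1:]):
            count = int(forest_mask[r0:r1, c0:c1].sum())
            tiles.append(
                SubRegion(
                    id=tid,
                    row_start=r0,
                    row_stop=r1,
                    col_start=c0,
                    col_stop=c1,
                    forest_pixels=count,
                    skipped=count < min_forest_pixels,
                )
            )
            tid += 1
    return tiles


def subregion_membership(shape: tuple[int, int], tiles: list[SubRegion]) -> np.ndarray:
    """Integer raster mapping every pixel to its sub-region id."""
    out = np.full(shape, -1, dtype=int)
    for t in tiles:
        out[t.window] = t.id
    if (out < 0).any():
        raise ValueError("sub-regions do not cover the grid")
    return out


def extract_fit_inputs(
    tile: SubRegion, distances: DistanceField, biomass: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (distance, biomass) samples for one sub-region.

    One pair per forest pixel with non-missing biomass.  A tile with zero
    usable pairs is reclassified as skipped and empty arrays are returned.
    """
    if tile.skipped:
        raise ValueError(f"sub-region {tile.id} is flagged skipped")
    d = distances.distance_km[tile.window]
    b = np.asarray(biomass, dtype=float)[tile.window]
    ok = np.isfinite(d) & np.isfinite(b)
    if not ok.any():
        tile.skipped = True
        return np.empty(0), np.empty(0)
    return d[ok].ravel(), b[ok].ravel()
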