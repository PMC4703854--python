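"""Synthetic fragmented landscapes with known edge-effect parameters.

Real inputs to this kind of analysis are a pantropical biomass product and a
MODIS-style land-cover map.  This module emulates them at desk scale: a
forest/non-forest mosaic with rectangular clearings plus random-walk
"tendrils" (a mix of smooth and convoluted edges), a biomass field generated
forward from the asymptotic edge model b(d) = theta1 - theta2 exp(-d theta3)
plus truncated Gaussian noise, a 12-month precipitation stack, and a
covariate table with planted linear effects for exercising the robust
regression stage.  Every generator is a pure function of (scenario, seed).

Non-forest biomass carries NaN as the missing-value sentinel — a reserved
value, not zero — so it can never silently enter a fit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import DEFAULT_PIXEL_SIZE_KM, DistanceField

#: NaN marks non-forest / missing biomass everywhere in the package.
BIOMASS_NODATA = float("nan")


@dataclass(frozen=True)
class SyntheticScenario:
    """Ground truth for one synthetic landscape.

    Defaults give a 200 x 200 grid of 465 m pixels (~8,650 km^2) with
    clearings covering roughly a quarter of the area, interior pixels several
    km from any edge (max distance comfortably above 3/theta3, so A(90) is
    detectable), theta = (300, 150, 1): a 300 Mg ha^-1 interior plateau —
    typical of dense tropical moist forest — halved at the theoretical edge,
    recovering on a ~1 km scale.  noise_sd defaults to 10% of theta1.
    """

    rows: int = 200
    cols: int = 200
    pixel_size_km: float = DEFAULT_PIXEL_SIZE_KM
    theta1: float = 300.0
    theta2: float = 150.0
    theta3: float = 1.0
    noise_sd: float = 30.0
    n_clearings: int = 5
    clearing_size: tuple[int, int] = (8, 30)
    n_tendrils: int = 3
    tendril_length: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 8 or self.cols < 8:
            raise ValueError("grid must be at least 8 x 8")
        if self.theta1 <= 0:
            raise ValueError("theta1 must be positive")
        if not 0 <= self.theta2 < self.theta1:
            raise ValueError("theta2 must satisfy 0 <= theta2 < theta1")
        if self.theta3 <= 0:
            raise ValueError("theta3 must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticScenario":
        d = json.loads(text)
        if "clearing_size" in d:
            d["clearing_size"] = tuple(d["clearing_size"])
        return cls(**d)


def _rng(scenario: SyntheticScenario, stream: int) -> np.random.Generator:
    # independent derived stream per generator stage
    return np.random.default_rng(np.random.SeedSequence([int(scenario.seed), stream]))


def generate_mask(scenario: SyntheticScenario) -> np.ndarray:
    """Forest mask with rectangular clearings and random-walk tendrils.

    True = forest.  Raises ``ValueError`` for degenerate scenarios: no
    non-forest features requested (no edge would exist) or clearings wiping
    out the forest entirely.
    """
    if scenario.n_clearings == 0 and scenario.n_tendrils == 0:
        raise ValueError(
            "degenerate scenario: zero non-forest patches requested, no edge would exist"
        )
    rng = _rng(scenario, 1)
    mask = np.ones((scenario.rows, scenario.cols), dtype=bool)
    lo, hi = scenario.clearing_size
    for _ in range(scenario.n_clearings):
        h = int(rng.integers(lo, hi + 1))
        w = int(rng.integers(lo, hi + 1))
        r = int(rng.integers(0, max(scenario.rows - h, 1)))
        c = int(rng.integers(0, max(scenario.cols - w, 1)))
        mask[r : r + h, c : c + w] = False
    steps = np.array([(0, 1), (0, -1), (1, 0), (-1, 0)])
    for _ in range(scenario.n_tendrils):
        r = int(rng.integers(0, scenario.rows))
        c = int(rng.integers(0, scenario.cols))
        for _ in range(scenario.tendril_length):
            mask[r, c] = False
            dr, dc = steps[rng.integers(0, 4)]
            r = int(np.clip(r + dr, 0, scenario.rows - 1))
            c = int(np.clip(c + dc, 0, scenario.cols - 1))
    if mask.all():
        raise ValueError("degenerate scenario: no non-forest pixel was generated")
    if not mask.any():
        raise ValueError("degenerate scenario: clearings removed every forest pixel")
    return mask


def generate_biomass(
    mask: np.ndarray,
    distances: DistanceField,
    scenario: SyntheticScenario,
) -> np.ndarray:
    """Biomass raster (Mg ha^-1) simulated forward from the edge model.

    Forest pixels get theta1 - theta2 exp(-d theta3) + N(0, noise_sd),
    truncated at zero; non-forest pixels get NaN.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != distances.distance_km.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match distance field "
            f"{distances.distance_km.shape}"
        )
    rng = _rng(scenario, 2)
    d = distances.distance_km
    b = scenario.theta1 - scenario.theta2 * np.exp(-d * scenario.theta3)
    if scenario.noise_sd > 0:
        b = b + rng.normal(0.0, scenario.noise_sd, size=b.shape)
    b = np.clip(b, 0.0, None)
    return np.where(mask, b, BIOMASS_NODATA)


def generate_precip_stack(
    rows: int,
    cols: int,
    monthly_means_mm,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """12-layer monthly precipitation stack (mm), shape (12, rows, cols).

    Each layer is its monthly mean plus optional Gaussian noise, clipped at
    zero.  Exactly 12 non-negative monthly means are required.
    """
    means = np.asarray(monthly_means_mm, dtype=float)
    if means.shape != (12,):
        raise ValueError(f"exactly 12 monthly means required, got {means.size}")
    if (means < 0).any():
        raise ValueError("monthly means must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    stack = np.broadcast_to(means[:, None, None], (12, rows, cols)).astype(float).copy()
    if noise_sd > 0:
        stack += rng.normal(0.0, noise_sd, size=stack.shape)
    return np.clip(stack, 0.0, None)


# predictor columns of the synthetic covariate study, with their sampling
# distributions (units follow the real covariates they emulate)
_COVARIATE_SPECS = {
    "latitude": lambda rng, n: rng.uniform(-23.0, 23.0, n),          # degrees
    "elevation": lambda rng, n: rng.gamma(2.0, 300.0, n),            # m
    "precipitation": lambda rng, n: rng.normal(1800.0, 400.0, n),    # mm / yr
    "soil_water_capacity": lambda rng, n: rng.uniform(50.0, 250.0, n),  # mm
    "dry_season_length": lambda rng, n: rng.integers(0, 9, n).astype(float),  # months
    "anthrome_cropland": lambda rng, n: np.clip(rng.normal(0.2, 0.25, n), 0.0, 1.0),
}


def generate_covariate_study(
    n_subregions: int,
    coefficients: dict[str, float],
    noise_sd: float = 1.0,
    outlier_fraction: float = 0.0,
    intercept: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Covariate table with a planted linear response, for testing the
    robust-regression stage against known ground truth.

    response = intercept + sum_j coef_j * x_j + N(0, noise_sd); a recorded
    ``outlier_fraction`` of rows additionally receive a gross +/- shift of
    ten response standard deviations.  Returns ``(table, outlier_row_index)``;
    the table holds all predictor columns plus ``response``.
    """
    if n_subregions < 10:
        raise ValueError("need at least 10 sub-regions")
    if not 0.0 <= outlier_fraction <= 0.3:
        raise ValueError("outlier_fraction must lie in [0, 0.3]")
    unknown = set(coefficients) - set(_COVARIATE_SPECS)
    if unknown:
        raise ValueError(f"unknown predictors: {sorted(unknown)}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4]))
    cols = {name: fn(rng, n_subregions) for name, fn in _COVARIATE_SPECS.items()}
    table = pd.DataFrame(cols)
    y = np.full(n_subregions, float(intercept))
    for name, coef in coefficients.items():
        y = y + coef * table[name].to_numpy()
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, n_subregions)
    n_out = int(round(outlier_fraction * n_subregions))
    out_idx = rng.choice(n_subregions, size=n_out, replace=False) if n_out else np.empty(0, int)
    if n_out:
        shift = 10.0 * max(float(np.std(y)), noise_sd, 1.0)
        y[out_idx] += rng.choice([-1.0, 1.0], n_out) * shift
    table["response"] = y
    return table, np.sort(out_idx)
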