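"""Asymptotic biomass-distance regression and edge-effect statistics.

Within each sub-region, biomass density b (Mg ha^-1) is modelled against
distance to the forest edge d (km) with the von Bertalanffy asymptotic form

    b(d) = theta1 - theta2 * exp(-d * theta3)

where theta1 is the asymptotic (interior) biomass, theta1 - theta2 the
density at the theoretical edge (d = 0), and theta3 (km^-1) the rate at
which the asymptote is approached.  Two summary statistics follow:

* magnitude  M = theta2 * exp(-offset * theta3) / theta1, the proportional
  biomass reduction at the edge (offset 0.232 km = half a 465 m pixel,
  because the mapped edge position is uncertain within the edge pixel);
  bounded in [0, 1].
* scale  A(p), the distance at which biomass reaches p% of the asymptote:
  A(p) = ln(theta2 / ((1 - p/100) * theta1)) / theta3, floored at 0 when the
  edge density already exceeds the threshold and capped at the maximum
  observed distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

DEFAULT_EDGE_OFFSET_KM = 0.232
DEFAULT_SCALE_PERCENT = 90.0

#: rate multi-start ladder (km^-1) used when the quartile-based start fails
THETA3_STARTS = (0.25, 0.5, 1.0, 2.0, 4.0)


@dataclass
class EdgeFit:
    theta1: float
    theta2: float
    theta3: float
    converged: bool
    n_pixels: int
    residual_variance: float
    r_squared: float
    max_observed_km: float
    message: str = ""


@dataclass
class EdgeMetrics:
    magnitude: float
    scale_km: float
    p: float = DEFAULT_SCALE_PERCENT
    edge_offset_km: float = DEFAULT_EDGE_OFFSET_KM
    flags: list[str] = field(default_factory=list)


def predict(theta1: float, theta2: float, theta3: float, d) -> np.ndarray:
    """Evaluate b(d) = theta1 - theta2 * exp(-d * theta3)."""
    return theta1 - theta2 * np.exp(-np.asarray(d, dtype=float) * theta3)


def _initial_guess(d: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """theta1 start = mean biomass in the far-distance quartile; theta2 start
    = that minus the near-quartile mean, floored at 1 Mg ha^-1."""
    q1, q3 = np.quantile(d, [0.25, 0.75])
    far = b[d >= q3]
    near = b[d <= q1]
    t1 = float(far.mean()) if far.size else float(b.mean())
    t2 = max(t1 - (float(near.mean()) if near.size else t1), 1.0)
    return t1, t2


def fit_edge_model(
    d: np.ndarray,
    b: np.ndarray,
    ftol: float = 1e-8,
    max_iter: int = 200,
) -> EdgeFit:
    """Nonlinear least-squares fit of the asymptotic model to (d, b) samples.

    Requires >= 10 samples spanning >= 3 distinct distances.  Starts from a
    quartile-based guess with theta3 = 1 km^-1 and, on failure, retries over a
    small theta3 ladder.  Non-convergence is reported via ``converged=False``
    (never a silent fallback).  theta2 may come out negative (biomass higher
    at the edge); that is flagged downstream, not here.
    """
    d = np.asarray(d, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if d.size != b.size:
        raise ValueError("distance and biomass sample arrays differ in length")
    if d.size < 10:
        raise ValueError(f"need >= 10 samples, got {d.size}")
    if np.unique(d).size < 3:
        raise ValueError("need >= 3 distinct distances for a 3-parameter fit")

    t1_0, t2_0 = _initial_guess(d, b)

    def residuals(theta):
        return predict(*theta, d) - b

    best = None
    for t3_0 in (1.0,) + tuple(t for t in THETA3_STARTS if t != 1.0):
        try:
            res = least_squares(
                residuals,
                x0=[t1_0, t2_0, t3_0],
                method="lm",
                ftol=ftol,
                xtol=1e-10,
                max_nfev=max_iter * 4,
            )
        except Exception:  # singular Jacobian etc. -> try next start
            continue
        if best is None or res.cost < best.cost:
            best = res
        if res.success and t3_0 == 1.0:
            break

    n = d.size
    if best is None:
        return EdgeFit(np.nan, np.nan, np.nan, False, n, np.nan, 0.0,
                       float(d.max()), "optimizer failed from every start")

    t1, t2, t3 = (float(v) for v in best.x)
    sse = float(2 * best.cost)
    sst = float(((b - b.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    r2 = min(max(r2, 0.0), 1.0)
    converged = bool(best.success) and t1 > 0 and t3 > 0
    return EdgeFit(
        theta1=t1,
        theta2=t2,
        theta3=t3,
        converged=converged,
        n_pixels=n,
        residual_variance=sse / max(n - 3, 1),
        r_squared=r2,
        max_observed_km=float(d.max()),
        message=best.message,
    )


def magnitude(fit: EdgeFit, edge_offset_km: float = DEFAULT_EDGE_OFFSET_KM) -> tuple[float, list[str]]:
    """Magnitude M = theta2 * exp(-offset * theta3) / theta1, clamped to [0, 1].

    Returns ``(M, flags)``; flags record clamping and inverse edge effects
    (theta2 < 0, i.e. biomass increasing toward the edge -> M = 0).
    """
    if not fit.converged:
        raise ValueError("magnitude requires a converged fit")
    if fit.theta1 <= 0:
        raise ValueError("invalid fit: theta1 must be positive")
    flags: list[str] = []
    m = fit.theta2 * math.exp(-edge_offset_km * fit.theta3) / fit.theta1
    if fit.theta2 < 0:
        flags.append("inverse-effect")
    if m < 0.0:
        m = 0.0
        if "inverse-effect" not in flags:
            flags.append("clamped")
    elif m > 1.0:
        m = 1.0
        flags.append("clamped")
    return m, flags


def scale(fit: EdgeFit, p: float = DEFAULT_SCALE_PERCENT) -> tuple[float, list[str]]:
    """Scale A(p): distance (km) at which b(d) reaches p% of the asymptote.

    A(p) = ln(theta2 / ((1 - p/100) * theta1)) / theta3; 0 when the edge
    density already exceeds the threshold; capped at the maximum observed
    distance (flag ``capped-at-max-distance``).
    """
    if not fit.converged:
        raise ValueError("scale requires a converged fit")
    if not 0.0 < p < 100.0:
        raise ValueError(f"p must lie in (0, 100), got {p}")
    flags: list[str] = []
    threshold = (1.0 - p / 100.0) * fit.theta1
    if fit.theta2 <= threshold:
        return 0.0, flags
    a = math.log(fit.theta2 / threshold) / fit.theta3
    if a > fit.max_observed_km:
        a = fit.max_observed_km
        flags.append("capped-at-max-distance")
    return a, flags


def edge_metrics(
    fit: EdgeFit,
    p: float = DEFAULT_SCALE_PERCENT,
    edge_offset_km: float = DEFAULT_EDGE_OFFSET_KM,
) -> EdgeMetrics:
    """Magnitude and scale for one converged fit, with quality flags."""
    m, mflags = magnitude(fit, edge_offset_km)
    a, aflags = scale(fit, p)
    return EdgeMetrics(magnitude=m, scale_km=a, p=p, edge_offset_km=edge_offset_km,
                       flags=mflags + aflags)


def select_representative(
    metrics: dict[int, EdgeMetrics],
    weights: dict[int, float] | None = None,
) -> int:
    """Sub-region whose (M, A(p)) lies closest to the weighted average.

    Distances are Euclidean in standardized (M, A) space (weighted mean and
    weighted standard deviation; a zero-spread axis contributes nothing).
    Ties break to the smallest id.  Default weights are uniform; the pipeline
    weights by forest pixel count.
    """
    if not metrics:
        raise ValueError("no converged fits to select from")
    ids = sorted(metrics)
    w = np.array([1.0 if weights is None else weights[i] for i in ids], dtype=float)
    if w.sum() <= 0:
        raise ValueError("weights must have positive total")
    w = w / w.sum()
    x = np.array([[metrics[i].magnitude, metrics[i].scale_km] for i in ids])
    mean = w @ x
    sd = np.sqrt(w @ (x - mean) ** 2)
    sd[sd == 0] = 1.0  # degenerate axis: all values equal, distance 0 anyway
    dist = np.sqrt((((x - mean) / sd) ** 2).sum(axis=1))
    return ids[int(np.argmin(dist))]  # argmin takes first minimum -> smallest id
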