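"""Statistical models scoring frame-to-frame assignment hypotheses.

Each assignment type (appear, disappear, migrate, divide) is scored by a
joint log-likelihood assembled from univariate densities of single-cell
observables: displacement of the observed position from a predicted one
(half-normal), relative area deviation (normal), migration rotation angle
(normal, axial), the "snapping" angle between daughter major axes at
division (normal, axial), and the inter-daughter distance (half-normal).

Six named configurations compose these models:

====== ============================================================
NN      nearest neighbour: zero motion and growth assumed
FO      first order: extrapolate each cell's own past velocity/growth
FO+O    FO plus orientation (rotation + division snapping angle)
FO+G    FO plus colony-informed growth model
FO+DD   FO plus division-distance model
FO+G+O+DD  the composite of all models
====== ============================================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, NamedTuple, Sequence, Tuple

import numpy as np

from .datamodel import Detection

LOG_SQRT_2_OVER_PI = 0.5 * math.log(2.0 / math.pi)
LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# univariate densities
# ---------------------------------------------------------------------------

def halfnormal_logpdf(x: float, sigma: float) -> float:
    """Log-density of the half-normal distribution with scale ``sigma``."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if x < 0:
        raise ValueError("half-normal support is x >= 0")
    return LOG_SQRT_2_OVER_PI - math.log(sigma) - 0.5 * (x / sigma) ** 2


def normal_logpdf(x: float, mu: float, sigma: float) -> float:
    """Log-density of the normal distribution N(mu, sigma²)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    z = (x - mu) / sigma
    return -LOG_SQRT_2PI - math.log(sigma) - 0.5 * z * z


def axial_difference(a: float, b: float) -> float:
    """Minimal axial (direction-free) angle between two major axes, in [0, π/2].

    A segmented rod has no head/tail, so orientations are equivalent mod π
    and a flip must not be penalized.
    """
    d = abs(a - b) % math.pi
    return min(d, math.pi - d)


class KernelDensityModel:
    """Optional scorer: a 1-D kernel density estimate fit on harvested
    feature samples (e.g. from a reference lineage forest)."""

    def __init__(self, samples: Sequence[float]):
        from scipy.stats import gaussian_kde

        self._kde = gaussian_kde(np.asarray(samples, dtype=float))

    def logpdf(self, x: float) -> float:
        return float(np.log(np.maximum(self._kde(x), 1e-300))[0])


# ---------------------------------------------------------------------------
# parameters and configurations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParams:
    """Numeric parameters of the assignment models.

    Scales adjust with the imaging interval Δt (minutes per processed
    frame): displacement diffusively as σ_move·√Δt, growth exponentially as
    exp(colony_rate·Δt).
    """

    dt: float = 1.0                 # minutes per processed frame
    sigma_move: float = 5.0         # px per sqrt(min)
    sigma_area: float = 0.1         # relative deviation of observed vs predicted area
    sigma_area_growth: float = 0.1  # sd of the area ratio in the G model
    sigma_angle: float = 0.3        # rad, migration rotation
    mu_div_angle: float = 0.0       # rad, snapping angle between daughter axes
    sigma_div_angle: float = 0.3    # rad
    sigma_div_dist: float = 8.0     # px, inter-daughter distance scale
    colony_rate: float = 0.0        # per-minute colony area growth rate
    lambda_appear: float = -20.0    # log-penalty
    lambda_disappear: float = -20.0
    r_max: float = 40.0             # candidate radius in px (per frame pair)
    d_div_max: float | None = None  # max inter-daughter distance; None -> r_max
    growth_clip: Tuple[float, float] = (0.5, 4.0)

    def __post_init__(self) -> None:
        for name in ("sigma_move", "sigma_area", "sigma_area_growth",
                     "sigma_angle", "sigma_div_angle", "sigma_div_dist"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def div_distance_limit(self) -> float:
        return self.r_max if self.d_div_max is None else self.d_div_max

    @property
    def default_growth(self) -> float:
        """Growth-factor prior for cells without history."""
        return math.exp(self.colony_rate * self.dt)


_CONFIG_FLAGS: Dict[str, Tuple[bool, bool, bool, bool]] = {
    # (first_order, orientation, growth, div_distance)
    "NN": (False, False, False, False),
    "FO": (True, False, False, False),
    "FO+O": (True, True, False, False),
    "FO+G": (True, False, True, False),
    "FO+DD": (True, False, False, True),
    "FO+G+O+DD": (True, True, True, True),
}
_ALIASES = {"FO+O+G+DD": "FO+G+O+DD"}

CONFIG_NAMES = tuple(_CONFIG_FLAGS)


@dataclass(frozen=True)
class TrackingConfig:
    name: str
    use_first_order: bool
    use_orientation: bool
    use_growth: bool
    use_div_distance: bool
    params: ModelParams

    def __post_init__(self) -> None:
        flags = _CONFIG_FLAGS.get(self.name)
        if flags is not None and flags != (
            self.use_first_order,
            self.use_orientation,
            self.use_growth,
            self.use_div_distance,
        ):
            raise ValueError(f"flags inconsistent with configuration name {self.name}")


def make_config(
    name: str,
    dt: float = 1.0,
    colony_rate: float = 0.0,
    **overrides: object,
) -> TrackingConfig:
    """Build one of the named tracking configurations for an imaging
    interval of ``dt`` minutes.

    The candidate radius defaults to 40·√Δt px unless overridden; all other
    ``ModelParams`` fields may be overridden by keyword.
    """
    canonical = _ALIASES.get(name, name)
    if canonical not in _CONFIG_FLAGS:
        raise ValueError(
            f"unknown tracking configuration {name!r}; choose from {CONFIG_NAMES}"
        )
    fo, o, g, dd = _CONFIG_FLAGS[canonical]
    kwargs = dict(dt=dt, colony_rate=colony_rate)
    if "r_max" not in overrides:
        kwargs["r_max"] = 40.0 * math.sqrt(dt)
    kwargs.update(overrides)  # type: ignore[arg-type]
    params = ModelParams(**kwargs)  # type: ignore[arg-type]
    return TrackingConfig(canonical, fo, o, g, dd, params)


# ---------------------------------------------------------------------------
# per-cell history features and prediction
# ---------------------------------------------------------------------------

class CellHistory(NamedTuple):
    """Self-learned temporal features of one cell within one CLT hypothesis."""

    vx: float  # px/min
    vy: float
    growth: float  # area factor per processed interval


def root_history(params: ModelParams) -> CellHistory:
    """History prior for a cell without a past: zero velocity, colony growth."""
    return CellHistory(0.0, 0.0, params.default_growth)


def predict(
    config: TrackingConfig, det: Detection, history: CellHistory
) -> Tuple[float, float, float]:
    """Predicted (x, y, area) of a cell one processed interval ahead.

    NN assumes zero motion and growth; FO extrapolates the cell's own past
    velocity and growth factor.
    """
    if not config.use_first_order:
        return (det.x, det.y, det.area)
    dt = config.params.dt
    return (det.x + history.vx * dt, det.y + history.vy * dt, det.area * history.growth)


# ---------------------------------------------------------------------------
# assignment scorers
# ---------------------------------------------------------------------------

def score_migration(
    config: TrackingConfig,
    src: Detection,
    history: CellHistory,
    tgt: Detection,
) -> float:
    p = config.params
    xh, yh, ah = predict(config, src, history)
    dist = math.hypot(tgt.x - xh, tgt.y - yh)
    score = halfnormal_logpdf(dist, p.sigma_move * math.sqrt(p.dt))
    score += normal_logpdf(tgt.area / ah, 1.0, p.sigma_area)
    if config.use_orientation:
        rot = axial_difference(src.orientation, tgt.orientation)
        score += normal_logpdf(rot, 0.0, p.sigma_angle)
    if config.use_growth:
        score += normal_logpdf(
            tgt.area / src.area, math.exp(p.colony_rate * p.dt), p.sigma_area_growth
        )
    return score


def score_division(
    config: TrackingConfig,
    src: Detection,
    history: CellHistory,
    tgt1: Detection,
    tgt2: Detection,
) -> float:
    """Log-score of ``src`` dividing into the unordered pair (tgt1, tgt2)."""
    p = config.params
    xh, yh, ah = predict(config, src, history)
    mx, my = (tgt1.x + tgt2.x) / 2.0, (tgt1.y + tgt2.y) / 2.0
    score = halfnormal_logpdf(math.hypot(mx - xh, my - yh), p.sigma_move * math.sqrt(p.dt))
    score += normal_logpdf((tgt1.area + tgt2.area) / ah, 1.0, p.sigma_area)
    if config.use_orientation:
        snap = axial_difference(tgt1.orientation, tgt2.orientation)
        score += normal_logpdf(snap, p.mu_div_angle, p.sigma_div_angle)
    if config.use_div_distance:
        sep = math.hypot(tgt1.x - tgt2.x, tgt1.y - tgt2.y)
        score += halfnormal_logpdf(sep, p.sigma_div_dist)
    return score


def score_appear(config: TrackingConfig, tgt: Detection) -> float:
    return config.params.lambda_appear


def score_disappear(config: TrackingConfig, src: Detection) -> float:
    return config.params.lambda_disappear
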