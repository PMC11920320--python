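"""Point-source reaction-diffusion model and diffusion-coefficient estimator.

Tumor cell density u(x, t) in 3-D obeys the linearized Fisher-Kolmogorov
equation with a Dirac point source,

    u_t = D * Laplacian(u) + rho * u,    u(x, 0) = C0 * delta(x),

whose radially symmetric solution is the exponentially amplified Gaussian

    u(r, t) = C0 / (8 * (pi*D*t)**1.5) * exp(rho*t - r**2 / (4*D*t)).

Setting u = u* (the smallest detectable density) gives the detectable
radius

    r*^2 = 4*D*rho*t^2 - 4*D*t * ln(8*u*/C0 * (pi*D*t)**1.5),

and for large t the log term is negligible, so r* ~ 2*sqrt(D*rho)*t: the
radius grows linearly at the Fisher-KPP front speed v = 2*sqrt(D*rho).
Inverting the asymptote yields the per-timepoint estimator

    D ~ r*^2 / (4 * rho * t^2).

The estimator is applied to each observed (t, r) pair; the per-line summary
is the mean D-bar, sample sd, and coefficient of variation CV = sd/D-bar.
CV < 50 % is the model-validity criterion: it certifies that D stayed
close to constant over the measurement window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InputError, NotYetDetectableError

__all__ = [
    "DetectionThreshold",
    "DiffusionSummary",
    "PointSourceModel",
    "RadiusSeries",
    "detectable_radius_squared",
    "estimate_diffusion",
    "fit_radius_linear",
    "point_source_density",
    "volume_to_radius",
]

D_TIER_THRESHOLDS: tuple[float, float, float] = (8e-3, 1e-3, 3e-4)
TIER_LABELS: tuple[str, ...] = ("High", "Medium high", "Medium", "Low")
CV_VALIDITY_CUTOFF = 0.5


@dataclass(frozen=True)
class PointSourceModel:
    """Constant-coefficient point-source model parameters."""

    D: float  # mm^2/day
    rho: float  # 1/day
    C0: float = 1.0  # cells at the source

    def __post_init__(self):
        if self.D <= 0 or self.rho <= 0 or self.C0 <= 0:
            raise InputError("D, rho and C0 must all be positive")


@dataclass(frozen=True)
class DetectionThreshold:
    """Detectable density u*, stored as the ratio u*/C0 (1/mm^3)."""

    ratio: float

    def __post_init__(self):
        if self.ratio <= 0:
            raise InputError("u*/C0 must be positive")


@dataclass(frozen=True)
class RadiusSeries:
    """Observed tumor radii (mm) at strictly increasing times (days > 0)."""

    cell_line_id: str
    times: np.ndarray
    radii: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        radii = np.asarray(self.radii, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "radii", radii)
        if times.ndim != 1 or times.shape != radii.shape:
            raise InputError("times and radii must be 1-D and equal length")
        if np.any(times <= 0):
            raise InputError(f"{self.cell_line_id}: times must be strictly positive")
        if np.any(np.diff(times) <= 0):
            raise InputError(f"{self.cell_line_id}: times must be strictly increasing")
        if np.any(radii < 0):
            raise InputError(f"{self.cell_line_id}: radii must be non-negative")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class DiffusionSummary:
    """Per-timepoint diffusion estimates and their dispersion summary."""

    cell_line_id: str
    per_timepoint_D: np.ndarray  # mm^2/day
    D_bar: float
    sd: float
    cv: float
    valid: bool
    t_range: tuple[float, float]
    tier: str


def volume_to_radius(volume):
    """Radius (mm) of a sphere of the given volume (mm^3)."""
    volume = np.asarray(volume, dtype=float)
    if np.any(volume < 0):
        raise InputError("volume must be non-negative")
    out = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    return out if out.ndim else float(out)


def point_source_density(model: PointSourceModel, r, t: float):
    """Cell density u(r, t) of the point-source solution (cells/mm^3)."""
    if t <= 0:
        raise InputError("the point-source solution requires t > 0")
    r = np.asarray(r, dtype=float)
    out = (
        model.C0
        / (8.0 * (np.pi * model.D * t) ** 1.5)
        * np.exp(model.rho * t - r**2 / (4.0 * model.D * t))
    )
    return out if out.ndim else float(out)


def detectable_radius_squared(
    model: PointSourceModel, threshold: DetectionThreshold, t: float
) -> float:
    """Squared detectable radius r*^2 (mm^2) at time ``t``.

    Raises :class:`NotYetDetectableError` while the expression is negative,
    i.e. before the peak density has reached the detection threshold.
    """
    if t <= 0:
        raise InputError("detectable radius requires t > 0")
    D, rho = model.D, model.rho
    r2 = 4.0 * D * rho * t**2 - 4.0 * D * t * np.log(
        8.0 * threshold.ratio * (np.pi * D * t) ** 1.5
    )
    if r2 < 0:
        raise NotYetDetectableError(
            f"tumor not yet detectable at t = {t:g} days (r*^2 = {r2:.4g} mm^2)", t
        )
    return float(r2)


def estimate_diffusion(
    series: RadiusSeries,
    rho: float,
    cv_cutoff: float = CV_VALIDITY_CUTOFF,
    tier_thresholds: tuple[float, float, float] = D_TIER_THRESHOLDS,
) -> DiffusionSummary:
    """Per-timepoint diffusion coefficients D_i = r_i^2 / (4*rho*t_i^2).

    ``rho`` should be the line's weighted-average in vitro proliferation
    rate.  Returns mean, sample sd (n-1 denominator), CV and the
    CV < ``cv_cutoff`` validity flag.
    """
    if rho <= 0:
        raise InputError(f"rho must be positive, got {rho}")
    if len(series) < 2:
        raise InputError(
            f"{series.cell_line_id}: at least 2 timepoints are needed for an sd"
        )
    d = series.radii**2 / (4.0 * rho * series.times**2)
    d_bar = float(np.mean(d))
    if d_bar <= 0:
        raise InputError(f"{series.cell_line_id}: all radii are zero")
    sd = float(np.std(d, ddof=1))
    cv = sd / d_bar
    tier = TIER_LABELS[-1]
    for bound, label in zip(tier_thresholds, TIER_LABELS):
        if d_bar >= bound:
            tier = label
            break
    return DiffusionSummary(
        cell_line_id=series.cell_line_id,
        per_timepoint_D=d,
        D_bar=d_bar,
        sd=sd,
        cv=cv,
        valid=cv < cv_cutoff,
        t_range=(float(series.times[0]), float(series.times[-1])),
        tier=tier,
    )


def fit_radius_linear(series: RadiusSeries) -> tuple[float, float, float]:
    """OLS line through (t, r): returns (slope mm/day, intercept mm, R^2).

    The slope is the front speed v; under the asymptotic law v = 2*sqrt(D*rho),
    so slope**2 / (4*rho) is an alternative (cross-check) estimate of D.
    """
    if len(series) < 2:
        raise InputError(f"{series.cell_line_id}: at least 2 points required")
    if np.ptp(series.times) == 0:
        raise InputError(f"{series.cell_line_id}: identical times, singular design")
    res = stats.linregress(series.times, series.radii)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
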