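"""Power-law (allometric) tumor-growth model.

In vivo tumor volume is modelled by the autonomous ODE

    dV/dt = alpha * V**beta,    V(t0) = V0,

whose solution for beta != 1 is

    V(t) = [V0**(1-beta) + alpha*(1-beta)*(t-t0)] ** (1/(1-beta)).

``alpha`` (units mm^{3(1-beta)}/day) measures the growth rate and ``beta``
is the dimensionless scale exponent.  For beta < 1 growth is sublinear and
finite for all time; for beta > 1 the solution blows up at
T* = V0**(1-beta) / (alpha*(beta-1)).

The module fits (alpha, beta) to observed volume series by unweighted
Levenberg-Marquardt least squares started at (0.9, 0.9), classifies each
line into a growth tier by alpha, and assigns each fitted beta to the
nearest of the characteristic allometric clusters {2/3, 3/4, 5/6}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    BlowUpDomainError,
    InputError,
    UnsupportedExponentError,
)

__all__ = [
    "BETA_CLUSTERS",
    "FitConfig",
    "PowerLawFit",
    "TumorVolumeSeries",
    "assign_beta_cluster",
    "classify_growth_tier",
    "fit_power_law",
    "power_law_solution",
]

#: characteristic allometric scale exponents around which fitted betas cluster
BETA_CLUSTERS: tuple[float, ...] = (2.0 / 3.0, 3.0 / 4.0, 5.0 / 6.0)

TIER_LABELS: tuple[str, ...] = ("High", "Medium high", "Medium", "Low")

_BETA_GUARD = 1e-6  # half-width of the excluded neighbourhood of beta = 1


@dataclass(frozen=True)
class TumorVolumeSeries:
    """Observed tumor volumes (mm^3) at strictly increasing times (days)."""

    cell_line_id: str
    times: np.ndarray
    volumes: np.ndarray
    t0: float = 0.0
    v0: float = 0.0

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        volumes = np.asarray(self.volumes, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "volumes", volumes)
        if times.ndim != 1 or times.shape != volumes.shape:
            raise InputError("times and volumes must be 1-D and equal length")
        if times.size and np.any(np.diff(times) <= 0):
            raise InputError(f"{self.cell_line_id}: times must be strictly increasing")
        if np.any(volumes < 0):
            raise InputError(f"{self.cell_line_id}: volumes must be non-negative")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class FitConfig:
    """Least-squares settings; defaults reproduce the published procedure."""

    seed_alpha: float = 0.9
    seed_beta: float = 0.9
    max_iterations: int = 5000
    tolerance: float = 1e-12
    #: strictly decreasing alpha breakpoints separating High / Medium high /
    #: Medium / Low growth tiers
    tier_thresholds: tuple[float, float, float] = (0.80, 0.30, 0.15)

    def __post_init__(self):
        t = self.tier_thresholds
        if not (t[0] > t[1] > t[2] > 0):
            raise InputError("tier_thresholds must be strictly decreasing and positive")


@dataclass(frozen=True)
class PowerLawFit:
    """Fitted power-law parameters and diagnostics for one cell line."""

    cell_line_id: str
    alpha: float
    beta: float
    r_squared: float
    tier: str
    beta_cluster: float
    converged: bool
    n_points: int
    message: str = ""


def power_law_solution(alpha, beta, v0, t0, t):
    """Volume at time(s) ``t`` of the power-law growth solution.

    Parameters are scalars; ``t`` may be a scalar or array of days.
    Raises :class:`UnsupportedExponentError` at beta = 1 (the exponential
    limit is deliberately outside the model domain) and
    :class:`BlowUpDomainError` when beta > 1 and ``t`` reaches past the
    finite-time blow-up T*.
    """
    beta = float(beta)
    if abs(beta - 1.0) < _BETA_GUARD:
        raise UnsupportedExponentError("beta = 1 is not supported (exponential regime)")
    t = np.asarray(t, dtype=float)
    one_m_b = 1.0 - beta
    bracket = v0 ** one_m_b + alpha * one_m_b * (t - t0)
    if beta > 1.0:
        if np.any(bracket <= 0):
            t_star = t0 + v0 ** one_m_b / (alpha * (beta - 1.0))
            raise BlowUpDomainError(
                f"power-law solution blows up at t* = {t_star:.6g} days", t_star
            )
        return bracket ** (1.0 / one_m_b)
    # beta < 1: bracket < 0 only for t < t0; clip the pre-history to zero volume
    out = np.where(bracket > 0, np.maximum(bracket, 0.0) ** (1.0 / one_m_b), 0.0)
    return out if out.ndim else float(out)


def classify_growth_tier(
    alpha: float,
    thresholds: tuple[float, float, float] = FitConfig.tier_thresholds,
) -> str:
    """Growth tier of a fitted alpha; lower bounds are inclusive."""
    if not alpha > 0:
        raise InputError(f"alpha must be positive, got {alpha}")
    for bound, label in zip(thresholds, TIER_LABELS):
        if alpha >= bound:
            return label
    return TIER_LABELS[-1]


def assign_beta_cluster(beta: float, clusters: tuple[float, ...] = BETA_CLUSTERS) -> float:
    """Nearest allometric cluster to ``beta``; ties go to the smaller value."""
    if not 0.0 < beta < 1.0:
        raise InputError(f"beta must lie in (0, 1), got {beta}")
    # sorted clusters + stable argmin give the smaller value on exact ties
    ordered = sorted(clusters)
    dists = [abs(beta - c) for c in ordered]
    return ordered[int(np.argmin(dists))]


def _model(t, alpha, beta):
    """Eq.-2 model with V0 = 0, t0 = 0, guarded for the LM search.

    The optimizer explores (alpha, beta) freely: near beta = 1 the exponent
    is perturbed off the removable singularity, and a negative bracket
    (possible while iterates wander above beta = 1) is floored so residuals
    stay finite.
    """
    if abs(beta - 1.0) < _BETA_GUARD:
        beta = 1.0 + np.sign(beta - 1.0 or 1.0) * 1e-4
    one_m_b = 1.0 - beta
    bracket = np.maximum(alpha * one_m_b * t, 1e-12)
    return bracket ** (1.0 / one_m_b)


def fit_power_law(series: TumorVolumeSeries, config: FitConfig = FitConfig()) -> PowerLawFit:
    """Fit (alpha, beta) of the power-law solution to one volume series.

    Unconstrained Levenberg-Marquardt on the summed squared volume
    residuals, started at ``(config.seed_alpha, config.seed_beta)``.
    Non-convergence or an implausible optimum (alpha <= 0 or beta outside
    (0, 1.5)) is reported via ``converged=False`` rather than an exception.
    """
    if len(series) < 3:
        raise InputError(
            f"{series.cell_line_id}: at least 3 points are needed for a 2-parameter fit"
        )
    positive = series.volumes[series.volumes > 0]
    if np.unique(positive).size < 2:
        raise InputError(
            f"{series.cell_line_id}: need at least 2 distinct positive volumes"
        )

    t = series.times - series.t0
    v = series.volumes
    converged = True
    message = ""
    try:
        popt, _ = curve_fit(
            _model,
            t,
            v,
            p0=(config.seed_alpha, config.seed_beta),
            method="lm",
            maxfev=config.max_iterations,
            ftol=config.tolerance,
            xtol=config.tolerance,
        )
        alpha, beta = map(float, popt)
    except RuntimeError as exc:  # maxfev exhausted
        converged = False
        message = str(exc)
        alpha, beta = config.seed_alpha, config.seed_beta

    if converged and not (alpha > 0 and 0.0 < beta < 1.5):
        converged = False
        message = f"implausible optimum alpha={alpha:.4g}, beta={beta:.4g}"

    pred = _model(t, alpha, beta)
    ss_res = float(np.sum((v - pred) ** 2))
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    tier = classify_growth_tier(alpha, config.tier_thresholds) if alpha > 0 else ""
    cluster = assign_beta_cluster(beta) if 0.0 < beta < 1.0 else float("nan")
    return PowerLawFit(
        cell_line_id=series.cell_line_id,
        alpha=alpha,
        beta=beta,
        r_squared=r_squared,
        tier=tier,
        beta_cluster=cluster,
        converged=converged,
        n_points=len(series),
        message=message,
    )
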