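"""Logistic model of in vitro confluence growth.

Confluence N (percent of covered dish area) follows the logistic ODE

    dN/dt = rho * N * (1 - N/k),    N(0) = N0 != 0,

with carrying capacity fixed at k = 100 % and solution

    N(t) = k*N0*exp(rho*t) / (k + N0*(exp(rho*t) - 1)).

Cultures are seeded at nominal 5 % or 10 % confluence; each (cell line,
condition) pair is fitted for its own rate rho (1/day), pooling all
replicate observations into one residual vector.  The sample-size-weighted
average of the two condition rates,

    rho_w = (rho5*n5 + rho10*n10) / (n5 + n10),

is the per-line proliferation rate used by the diffusion estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import DegenerateFitError, InputError

__all__ = [
    "ConfluenceSeries",
    "LogisticFit",
    "LogisticFitConfig",
    "WeightedRate",
    "fit_logistic",
    "logistic_solution",
    "weighted_average_rate",
]

RHO_TIER_THRESHOLDS: tuple[float, float, float] = (1.70, 1.49, 1.20)
TIER_LABELS: tuple[str, ...] = ("High", "Medium high", "Medium", "Low")

HOURS_PER_DAY = 24.0


def normalize_condition(condition) -> int:
    """Canonical seeding condition: the integer 5 or 10."""
    cond = str(condition).rstrip("%")
    try:
        value = int(float(cond))
    except ValueError:
        raise InputError(f"unrecognized seeding condition {condition!r}") from None
    if value not in (5, 10):
        raise InputError(f"seeding condition must be 5% or 10%, got {condition!r}")
    return value


@dataclass(frozen=True)
class ConfluenceSeries:
    """One replicate's confluence trace; times already in days."""

    cell_line_id: str
    condition: int  # 5 or 10 (% of dish area at seeding)
    replicate: int
    times: np.ndarray  # days
    confluence: np.ndarray  # percent

    def __post_init__(self):
        object.__setattr__(self, "condition", normalize_condition(self.condition))
        times = np.asarray(self.times, dtype=float)
        conf = np.asarray(self.confluence, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "confluence", conf)
        if times.ndim != 1 or times.shape != conf.shape:
            raise InputError("times and confluence must be 1-D and equal length")
        if times.size == 0:
            raise InputError(f"{self.cell_line_id}: empty confluence series")
        if np.any(np.diff(times) <= 0):
            raise InputError(f"{self.cell_line_id}: times must be strictly increasing")
        if np.any((conf < 0) | (conf > 100)):
            raise InputError(f"{self.cell_line_id}: confluence must lie in [0, 100]")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class LogisticFitConfig:
    """How the logistic rate is estimated."""

    k: float = 100.0
    seed_rho: float = 1.0
    max_iterations: int = 5000
    #: "nominal" pins N0 at the seeding density (5 or 10); "first" uses the
    #: mean of each group's first observations; "fit" estimates N0 jointly
    n0_mode: str = "nominal"
    tier_thresholds: tuple[float, float, float] = RHO_TIER_THRESHOLDS


@dataclass(frozen=True)
class LogisticFit:
    cell_line_id: str
    condition: int
    rho: float
    n0: float
    k: float
    r_squared: float
    n_replicates: int


@dataclass(frozen=True)
class WeightedRate:
    cell_line_id: str
    rho5: float
    n5: int
    rho10: float
    n10: int
    weighted_average: float
    tier: str


def logistic_solution(rho, n0, k, t):
    """Confluence at time(s) ``t`` days for logistic growth from ``n0``."""
    if k <= 0:
        raise InputError(f"carrying capacity must be positive, got {k}")
    if n0 <= 0 or n0 > k:
        raise InputError(f"N0 must lie in (0, k], got {n0}")
    t = np.asarray(t, dtype=float)
    # algebraically identical to k*N0*e^{rho t} / (k + N0*(e^{rho t}-1)) but
    # immune to exp overflow for large rho*t
    out = k / (1.0 + (k / n0 - 1.0) * np.exp(-rho * t))
    return out if out.ndim else float(out)


def fit_logistic(
    replicates: Iterable[ConfluenceSeries],
    config: LogisticFitConfig = LogisticFitConfig(),
) -> LogisticFit:
    """Fit one rate rho to all replicates of a (cell line, condition) group.

    Replicate points are pooled into a single residual vector, so the
    estimate uses every observation and is invariant to replicate order.
    """
    group = list(replicates)
    if not group:
        raise InputError("no replicate series supplied")
    ids = {s.cell_line_id for s in group}
    conditions = {s.condition for s in group}
    if len(ids) > 1 or len(conditions) > 1:
        raise InputError(f"replicates mix cell lines/conditions: {ids}, {conditions}")
    (cell_line,) = ids
    (condition,) = conditions

    t = np.concatenate([s.times for s in group])
    y = np.concatenate([s.confluence for s in group])
    if len(t) < 3:
        raise InputError(f"{cell_line}: at least 3 pooled points required")
    if np.ptp(y) == 0:
        raise DegenerateFitError(f"{cell_line} {condition}%: all observations identical")

    k = config.k
    if config.n0_mode == "nominal":
        n0 = float(condition)
    elif config.n0_mode == "first":
        n0 = float(np.mean([s.confluence[0] for s in group]))
    elif config.n0_mode == "fit":
        n0 = None
    else:
        raise InputError(f"unknown n0_mode {config.n0_mode!r}")

    if n0 is None:
        popt, _ = curve_fit(
            lambda tt, rho, n0_: logistic_solution(rho, max(n0_, 1e-6), k, tt),
            t,
            y,
            p0=(config.seed_rho, float(condition)),
            method="lm",
            maxfev=config.max_iterations,
        )
        rho, n0 = float(popt[0]), float(popt[1])
    else:
        popt, _ = curve_fit(
            lambda tt, rho: logistic_solution(rho, n0, k, tt),
            t,
            y,
            p0=(config.seed_rho,),
            method="lm",
            maxfev=config.max_iterations,
        )
        rho = float(popt[0])

    pred = logistic_solution(rho, n0, k, t)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot
    return LogisticFit(
        cell_line_id=cell_line,
        condition=condition,
        rho=rho,
        n0=float(n0),
        k=k,
        r_squared=r_squared,
        n_replicates=len(group),
    )


def weighted_average_rate(
    rho5: float,
    n5: int,
    rho10: float,
    n10: int,
    cell_line_id: str = "",
    tier_thresholds: Sequence[float] = RHO_TIER_THRESHOLDS,
) -> WeightedRate:
    """Replicate-count-weighted mean of the 5 % and 10 % seeding rates."""
    if n5 < 1 or n10 < 1:
        raise InputError("replicate counts must be at least 1 in each condition")
    weighted = (rho5 * n5 + rho10 * n10) / (n5 + n10)
    tier = TIER_LABELS[-1]
    for bound, label in zip(tier_thresholds, TIER_LABELS):
        if weighted >= bound:
            tier = label
            break
    return WeightedRate(
        cell_line_id=cell_line_id,
        rho5=rho5,
        n5=int(n5),
        rho10=rho10,
        n10=int(n10),
        weighted_average=float(weighted),
        tier=tier,
    )
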