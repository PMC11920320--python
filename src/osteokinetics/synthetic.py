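"""Synthetic cell-line panels with known ground truth.

The published growth/confluence curves behind the reference panel are
digitized figures and are not machine-readable, so every downstream stage
of this package is exercised against simulated panels instead: sublinear
power-law volume trajectories, sigmoid confluence curves saturating at
100 %, and linearly growing detectable radii, all generated from known
parameters so that recovery can be checked exactly.

Noise models (the source data report none, so these are the minimal
structures respecting positivity and bounds):

* volumes  — multiplicative lognormal, ``V * exp(eps)`` with
  ``eps ~ N(0, volume_sigma^2)`` (volumes span three orders of magnitude);
* confluence — additive Gaussian in percentage points, clipped to
  [0.1, 100] (the 0.1 floor keeps post-noise confluence positive).

All generators are deterministic under a fixed :class:`NoiseSpec` seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .diffusion import DetectionThreshold, PointSourceModel, detectable_radius_squared
from .errors import InputError, UnsupportedExponentError
from .growth import TumorVolumeSeries, power_law_solution
from .proliferation import (
    HOURS_PER_DAY,
    ConfluenceSeries,
    logistic_solution,
    normalize_condition,
)

__all__ = [
    "GroundTruth",
    "NoiseSpec",
    "PanelData",
    "reference_truth_panel",
    "simulate_confluence_series",
    "simulate_panel",
    "simulate_radius_series",
    "simulate_volume_series",
]


@dataclass(frozen=True)
class GroundTruth:
    """True kinetic parameters of one simulated cell line.

    ``alpha = 0`` (no growth) is tolerated as an explicit degenerate case;
    ``beta > 1`` (finite-time blow-up) only with ``allow_blow_up=True``.
    """

    cell_line_id: str
    alpha: float  # mm^{3(1-beta)}/day
    beta: float  # dimensionless scale exponent
    rho5: float  # 1/day, 5 % seeding
    rho10: float  # 1/day, 10 % seeding
    D: float  # mm^2/day
    n5: int = 4
    n10: int = 2
    t_appearance: float = 5.0  # day of first detectable tumor
    allow_blow_up: bool = False

    def __post_init__(self):
        if self.alpha < 0:
            raise InputError("alpha must be non-negative")
        if self.beta <= 0:
            raise InputError("beta must be positive")
        if self.beta == 1.0:
            raise UnsupportedExponentError("beta = 1 is outside the model domain")
        if self.beta > 1.0 and not self.allow_blow_up:
            raise InputError("beta > 1 (blow-up regime) requires allow_blow_up=True")
        if self.rho5 <= 0 or self.rho10 <= 0:
            raise InputError("proliferation rates must be positive")
        if self.D <= 0:
            raise InputError("diffusion coefficient must be positive")
        if self.n5 < 1 or self.n10 < 1:
            raise InputError("replicate counts must be at least 1")
        if self.t_appearance < 0:
            raise InputError("appearance time must be non-negative")

    @property
    def rho_weighted(self) -> float:
        return (self.rho5 * self.n5 + self.rho10 * self.n10) / (self.n5 + self.n10)


@dataclass(frozen=True)
class NoiseSpec:
    """Observation-noise magnitudes and the RNG seed."""

    volume_sigma: float = 0.05  # lognormal sd (dimensionless)
    confluence_sigma: float = 2.0  # additive sd (percentage points)
    seed: int = 0

    def __post_init__(self):
        if self.volume_sigma < 0 or self.confluence_sigma < 0:
            raise InputError("noise sigmas must be non-negative")


def _check_times(times: np.ndarray, minimum: float = 0.0) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise InputError("times must be non-empty")
    if np.any(times < minimum):
        raise InputError(f"times must be >= {minimum}")
    if np.any(np.diff(times) <= 0):
        raise InputError("times must be strictly increasing")
    return times


def simulate_volume_series(
    truth: GroundTruth,
    times,
    noise: NoiseSpec = NoiseSpec(),
    rng: np.random.Generator | None = None,
) -> TumorVolumeSeries:
    """Power-law volume trajectory (t0 = 0, V0 = 0) with lognormal noise."""
    times = _check_times(times, minimum=0.0)
    values = np.asarray(
        power_law_solution(truth.alpha, truth.beta, 0.0, 0.0, times), dtype=float
    )
    if noise.volume_sigma > 0:
        rng = np.random.default_rng(noise.seed) if rng is None else rng
        values = values * np.exp(rng.normal(0.0, noise.volume_sigma, size=times.size))
    return TumorVolumeSeries(truth.cell_line_id, times, values)


def simulate_confluence_series(
    truth: GroundTruth,
    condition,
    times_hours,
    noise: NoiseSpec = NoiseSpec(),
    replicate: int = 0,
    rng: np.random.Generator | None = None,
) -> ConfluenceSeries:
    """Logistic confluence trace at 5 % or 10 % seeding, times in hours."""
    condition = normalize_condition(condition)
    hours = _check_times(times_hours, minimum=0.0)
    days = hours / HOURS_PER_DAY
    rho = truth.rho5 if condition == 5 else truth.rho10
    values = np.asarray(logistic_solution(rho, float(condition), 100.0, days))
    if noise.confluence_sigma > 0:
        rng = np.random.default_rng(noise.seed) if rng is None else rng
        values = values + rng.normal(0.0, noise.confluence_sigma, size=days.size)
        values = np.clip(values, 0.1, 100.0)
    return ConfluenceSeries(truth.cell_line_id, condition, replicate, days, values)


def simulate_radius_series(
    truth: GroundTruth,
    times,
    mode: str = "asymptotic",
    u_star_over_C0: float = 1e-3,
    rho: float | None = None,
):
    """Detectable-radius trajectory from the point-source model.

    ``asymptotic`` returns the exactly linear front r = 2*sqrt(D*rho)*t;
    ``exact`` evaluates the full detectable-radius law, which needs the
    detection ratio u*/C0 and raises while the tumor is still undetectable.
    ``rho`` defaults to the truth's replicate-weighted proliferation rate.
    """
    from .diffusion import RadiusSeries  # local import keeps module load light

    times = _check_times(times, minimum=np.finfo(float).tiny)
    rho = truth.rho_weighted if rho is None else float(rho)
    if mode == "asymptotic":
        radii = 2.0 * np.sqrt(truth.D * rho) * times
    elif mode == "exact":
        if not 0.0 < u_star_over_C0 < 1.0:
            raise InputError("u*/C0 must lie in (0, 1)")
        model = PointSourceModel(D=truth.D, rho=rho, C0=1.0)
        threshold = DetectionThreshold(ratio=u_star_over_C0)
        radii = np.sqrt(
            [detectable_radius_squared(model, threshold, t) for t in times]
        )
    else:
        raise InputError(f"unknown radius mode {mode!r}")
    return RadiusSeries(truth.cell_line_id, times, radii)


@dataclass(frozen=True)
class PanelData:
    """Bundle of simulated panel tables, mirroring the on-disk CSV schemas."""

    volumes: pd.DataFrame  # cell_line, time_days, volume_mm3
    confluence: pd.DataFrame  # cell_line, condition, replicate, time_hours, confluence_pct
    levels: pd.DataFrame  # cell_line, TL, CL, IL, ML, PL
    ground_truth: pd.DataFrame  # cell_line, alpha, beta, rho5, rho10, D

    def write_csvs(self, directory) -> dict[str, Path]:
        from . import io  # deferred to avoid an import cycle

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [
            ("volumes", self.volumes),
            ("confluence", self.confluence),
            ("levels", self.levels),
            ("ground_truth", self.ground_truth),
        ]:
            paths[name] = io.write_csv(df, directory / f"{name}.csv")
        return paths


def _volume_time_grid(truth: GroundTruth, n_points: int, target_volume: float) -> np.ndarray:
    """Observation days: from appearance until the tumor reaches ~target volume.

    Fast-growing lines get short windows and slow lines long ones, which is
    how real measurement campaigns end up sampling (windows clipped to the
    3-172-day span seen in practice).
    """
    if truth.alpha == 0:
        t_end = 172.0
    else:
        t_end = target_volume ** (1.0 - truth.beta) / (truth.alpha * (1.0 - truth.beta))
    t_start = max(truth.t_appearance, 3.0)
    t_end = float(np.clip(t_end, t_start + 10.0, 172.0))
    return np.linspace(t_start, t_end, n_points)


def _monotone_levels(
    values: np.ndarray, n_levels: int, jitter: float, rng: np.random.Generator
) -> np.ndarray:
    """Integer scores 1..n_levels, monotone in ``values`` up to bounded jitter.

    Equal-width binning of the raw value range (not rank quartiles) keeps
    the score approximately linear in the value, so Pearson correlations
    against the raw parameter stay high even for skewed parameter spreads.
    """
    values = np.asarray(values, dtype=float)
    span = np.ptp(values)
    if span == 0:
        scaled = np.full(values.shape, (1.0 + n_levels) / 2.0)
    else:
        scaled = 1.0 + (n_levels - 1.0) * (values - values.min()) / span
    if jitter > 0:
        scaled = scaled + rng.uniform(-jitter, jitter, size=values.shape)
    return np.clip(np.round(scaled), 1, n_levels).astype(int)


def simulate_panel(
    panel_spec: list[GroundTruth],
    noise: NoiseSpec = NoiseSpec(),
    n_volume_points: int = 12,
    confluence_hours: np.ndarray | None = None,
    target_volume: float = 1000.0,
) -> PanelData:
    """Simulate a full multi-line panel: volumes, confluence, phenotype levels.

    One volume series per line, ``n5``/``n10`` replicate confluence series
    per seeding condition, and ordinal phenotype levels constructed monotone
    in the growth rate (TL, CL, IL, ML in alpha; PL in the weighted
    proliferation rate) so that panel correlations carry signal.
    Deterministic for a fixed ``noise.seed``.
    """
    if not panel_spec:
        raise InputError("panel_spec must contain at least one cell line")
    ids = [t.cell_line_id for t in panel_spec]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InputError(f"duplicate cell line ids: {dupes}")

    rng = np.random.default_rng(noise.seed)
    if confluence_hours is None:
        confluence_hours = np.arange(0.0, 121.0, 3.0)

    vol_rows, conf_rows = [], []
    for truth in panel_spec:
        days = _volume_time_grid(truth, n_volume_points, target_volume)
        vol = simulate_volume_series(truth, days, noise, rng=rng)
        vol_rows.append(
            pd.DataFrame(
                {
                    "cell_line": truth.cell_line_id,
                    "time_days": vol.times,
                    "volume_mm3": vol.volumes,
                }
            )
        )
        for condition, n_reps in ((5, truth.n5), (10, truth.n10)):
            for rep in range(n_reps):
                conf = simulate_confluence_series(
                    truth, condition, confluence_hours, noise, replicate=rep, rng=rng
                )
                conf_rows.append(
                    pd.DataFrame(
                        {
                            "cell_line": truth.cell_line_id,
                            "condition": condition,
                            "replicate": rep,
                            "time_hours": conf.times * HOURS_PER_DAY,
                            "confluence_pct": conf.confluence,
                        }
                    )
                )

    alphas = np.array([t.alpha for t in panel_spec])
    rhos = np.array([t.rho_weighted for t in panel_spec])
    levels = pd.DataFrame(
        {
            "cell_line": ids,
            # TL/PL jitter is bounded at 0.2 level-units so quantization plus
            # jitter cannot erase the designed monotone signal; the secondary
            # assay scores are deliberately noisier
            "TL": _monotone_levels(alphas, 4, 0.2, rng),
            "CL": _monotone_levels(alphas, 4, 0.75, rng),
            "IL": _monotone_levels(alphas, 4, 0.75, rng),
            "ML": _monotone_levels(alphas, 4, 0.75, rng),
            "PL": _monotone_levels(rhos, 3, 0.2, rng),
        }
    )
    ground_truth = pd.DataFrame(
        {
            "cell_line": ids,
            "alpha": [t.alpha for t in panel_spec],
            "beta": [t.beta for t in panel_spec],
            "rho5": [t.rho5 for t in panel_spec],
            "rho10": [t.rho10 for t in panel_spec],
            "D": [t.D for t in panel_spec],
        }
    )
    return PanelData(
        volumes=pd.concat(vol_rows, ignore_index=True),
        confluence=pd.concat(conf_rows, ignore_index=True),
        levels=levels,
        ground_truth=ground_truth,
    )


def reference_truth_panel() -> list[GroundTruth]:
    """Ground truths emulating the published 17-line osteosarcoma panel.

    Joins the reference growth, proliferation and diffusion tables on cell
    line, taking the published first measurement day as the appearance time.
    """
    from . import reference

    growth = reference.growth_parameters().set_index("cell_line")
    prolif = reference.proliferation_rates().set_index("cell_line")
    diff = reference.diffusion_estimates().set_index("cell_line")
    panel = []
    for line in growth.index:
        if line not in prolif.index or line not in diff.index:
            continue
        panel.append(
            GroundTruth(
                cell_line_id=line,
                alpha=float(growth.loc[line, "alpha"]),
                beta=float(growth.loc[line, "beta"]),
                rho5=float(prolif.loc[line, "rho5"]),
                rho10=float(prolif.loc[line, "rho10"]),
                n5=int(prolif.loc[line, "n5"]),
                n10=int(prolif.loc[line, "n10"]),
                D=float(diff.loc[line, "D_bar"]),
                t_appearance=float(diff.loc[line, "t_first"]),
            )
        )
    return panel
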