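"""CSV schemas, configuration, run logging and the pipeline driver.

Fixed input schemas (UTF-8, comma-separated, decimal point):

* ``volumes``      — cell_line, time_days, volume_mm3
* ``confluence``   — cell_line, condition, replicate, time_hours, confluence_pct
* ``levels``       — cell_line, TL, CL, IL, ML, PL
* ``ground_truth`` — cell_line, alpha, beta, rho5, rho10, D

Confluence times are recorded in hours and converted to days at ingest so
all rates downstream are per day.  Outputs are written in full precision
by default; report mode rounds to 4 decimals to mirror the published
tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffusion as diffusion_mod
from . import growth as growth_mod
from . import proliferation as prolif_mod
from .errors import (
    InputError,
    OsteokineticsError,
    ParseError,
    PipelineError,
)
from .panel import build_panel, correlation_matrix

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "RunLog",
    "SCHEMAS",
    "read_timeseries_csv",
    "run_pipeline",
    "write_csv",
]

logger = logging.getLogger(__name__)

SCHEMAS: dict[str, list[str]] = {
    "volumes": ["cell_line", "time_days", "volume_mm3"],
    "confluence": ["cell_line", "condition", "replicate", "time_hours", "confluence_pct"],
    "levels": ["cell_line", "TL", "CL", "IL", "ML", "PL"],
    "ground_truth": ["cell_line", "alpha", "beta", "rho5", "rho10", "D"],
}


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the pipeline; round-trips losslessly through YAML."""

    seed: int = 0
    # power-law fit
    seed_alpha: float = 0.9
    seed_beta: float = 0.9
    max_iterations: int = 5000
    tolerance: float = 1e-12
    alpha_tier_thresholds: tuple[float, float, float] = (0.80, 0.30, 0.15)
    # logistic fit
    n0_mode: str = "nominal"
    rho_tier_thresholds: tuple[float, float, float] = (1.70, 1.49, 1.20)
    # diffusion
    d_tier_thresholds: tuple[float, float, float] = (8e-3, 1e-3, 3e-4)
    cv_validity_cutoff: float = 0.5
    # correlation
    correlation_method: str = "pearson"
    # synthetic noise (used by the simulate CLI path)
    volume_sigma: float = 0.05
    confluence_sigma: float = 2.0

    def __post_init__(self):
        for name in ("alpha_tier_thresholds", "rho_tier_thresholds", "d_tier_thresholds"):
            t = tuple(float(x) for x in getattr(self, name))
            object.__setattr__(self, name, t)
            if not (t[0] > t[1] > t[2] > 0):
                raise InputError(f"{name} must be strictly decreasing and positive")
        if self.cv_validity_cutoff <= 0:
            raise InputError("cv_validity_cutoff must be positive")

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class RunLog:
    """Ordered stage events; every dropped record or failed fit appears once."""

    config_digest: str = ""
    events: list[dict] = field(default_factory=list)

    def record(self, stage: str, level: str, message: str) -> None:
        self.events.append(
            {"timestamp": time.time(), "stage": stage, "level": level, "message": message}
        )
        getattr(logger, level, logger.info)("[%s] %s", stage, message)

    def warnings(self) -> list[dict]:
        return [e for e in self.events if e["level"] == "warning"]

    def write_json(self, path) -> Path:
        # timestamps are dropped on serialization so fixed-seed runs produce
        # byte-identical output trees
        path = Path(path)
        stable = [{k: e[k] for k in ("stage", "level", "message")} for e in self.events]
        path.write_text(
            json.dumps({"config": self.config_digest, "events": stable}, indent=2) + "\n"
        )
        return path


def _validate_numeric(df: pd.DataFrame, column: str, path) -> np.ndarray:
    values = pd.to_numeric(df[column], errors="coerce")
    bad = values.isna() & df[column].notna() | df[column].isna()
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2  # 1-based, after header
        raise ParseError(f"{path}: non-numeric value in column {column!r}", row)
    return values.to_numpy(dtype=float)


def read_timeseries_csv(path, schema: str) -> pd.DataFrame:
    """Read and validate one of the fixed input schemas.

    Returns a typed DataFrame with rows sorted per series; confluence gains
    a ``time_days`` column (hours / 24).  Violations raise
    :class:`ParseError` carrying the 1-based file row.
    """
    if schema not in SCHEMAS:
        raise InputError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    expected = SCHEMAS[schema]
    if list(df.columns) != expected:
        raise ParseError(
            f"{path}: header {list(df.columns)} does not match schema "
            f"{schema!r} ({expected})"
        )

    out = pd.DataFrame({"cell_line": df["cell_line"].astype(str)})
    for column in expected[1:]:
        out[column] = _validate_numeric(df, column, path)

    if schema == "volumes":
        if (out["volume_mm3"] < 0).any():
            row = int(np.flatnonzero(out["volume_mm3"] < 0)[0]) + 2
            raise ParseError(f"{path}: negative volume", row)
        keys = out[["cell_line", "time_days"]]
        sort_cols = ["cell_line", "time_days"]
    elif schema == "confluence":
        bad = ~out["condition"].isin([5, 10])
        if bad.any():
            raise ParseError(
                f"{path}: condition must be 5 or 10", int(np.flatnonzero(bad)[0]) + 2
            )
        bad = (out["confluence_pct"] < 0) | (out["confluence_pct"] > 100)
        if bad.any():
            raise ParseError(
                f"{path}: confluence outside [0, 100]", int(np.flatnonzero(bad)[0]) + 2
            )
        out["time_days"] = out["time_hours"] / prolif_mod.HOURS_PER_DAY
        keys = out[["cell_line", "condition", "replicate", "time_hours"]]
        sort_cols = ["cell_line", "condition", "replicate", "time_hours"]
    elif schema == "levels":
        keys = out[["cell_line"]]
        sort_cols = ["cell_line"]
    else:  # ground_truth
        keys = out[["cell_line"]]
        sort_cols = ["cell_line"]

    dup = keys.duplicated()
    if dup.any():
        raise ParseError(f"{path}: duplicate key", int(np.flatnonzero(dup)[0]) + 2)
    return out.sort_values(sort_cols, kind="stable").reset_index(drop=True)


def write_csv(df: pd.DataFrame, path, report_mode: bool = False) -> Path:
    """Write a DataFrame; report mode rounds floats to 4 decimals."""
    path = Path(path)
    if report_mode:
        df = df.copy()
        for col in df.select_dtypes(include=[float]).columns:
            df[col] = df[col].round(4)
    df.to_csv(path, index=False, lineterminator="\n")
    return path


@dataclass
class PipelineResult:
    growth_fits: pd.DataFrame
    proliferation_fits: pd.DataFrame
    diffusion: pd.DataFrame
    panel: pd.DataFrame
    correlation: pd.DataFrame
    run_log: RunLog

    def write_csvs(self, directory, report_mode: bool = False) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("growth_fits", "proliferation_fits", "diffusion", "panel"):
            paths[name] = write_csv(getattr(self, name), directory / f"{name}.csv", report_mode)
        corr_path = directory / "correlation.csv"
        self.correlation.to_csv(corr_path, index=True, lineterminator="\n")
        paths["correlation"] = corr_path
        paths["run_log"] = self.run_log.write_json(directory / "run_log.json")
        return paths


def _fit_growth_stage(volumes: pd.DataFrame, config: PipelineConfig, log: RunLog) -> pd.DataFrame:
    fit_config = growth_mod.FitConfig(
        seed_alpha=config.seed_alpha,
        seed_beta=config.seed_beta,
        max_iterations=config.max_iterations,
        tolerance=config.tolerance,
        tier_thresholds=config.alpha_tier_thresholds,
    )
    rows = []
    for line, group in volumes.groupby("cell_line", sort=True):
        try:
            series = growth_mod.TumorVolumeSeries(
                line, group["time_days"].to_numpy(), group["volume_mm3"].to_numpy()
            )
            fit = growth_mod.fit_power_law(series, fit_config)
        except OsteokineticsError as exc:
            log.record("growth", "warning", f"{line}: skipped ({exc})")
            continue
        if not fit.converged:
            log.record("growth", "warning", f"{line}: fit did not converge ({fit.message})")
        rows.append(
            {
                "cell_line": line,
                "alpha": fit.alpha,
                "beta": fit.beta,
                "r_squared": fit.r_squared,
                "tier": fit.tier,
                "beta_cluster": fit.beta_cluster,
                "n_points": fit.n_points,
                "converged": fit.converged,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "cell_line", "alpha", "beta", "r_squared", "tier",
            "beta_cluster", "n_points", "converged",
        ],
    )
    log.record("growth", "info", f"fitted {len(df)} cell line(s)")
    return df


def _fit_proliferation_stage(
    confluence: pd.DataFrame, config: PipelineConfig, log: RunLog
) -> pd.DataFrame:
    fit_config = prolif_mod.LogisticFitConfig(
        n0_mode=config.n0_mode, tier_thresholds=config.rho_tier_thresholds
    )
    rows = []
    for line, group in confluence.groupby("cell_line", sort=True):
        fits: dict[int, prolif_mod.LogisticFit] = {}
        for condition, sub in group.groupby("condition"):
            replicates = [
                prolif_mod.ConfluenceSeries(
                    line,
                    int(condition),
                    int(rep),
                    rep_group["time_days"].to_numpy(),
                    rep_group["confluence_pct"].to_numpy(),
                )
                for rep, rep_group in sub.groupby("replicate")
            ]
            try:
                fits[int(condition)] = prolif_mod.fit_logistic(replicates, fit_config)
            except OsteokineticsError as exc:
                log.record("proliferation", "warning", f"{line} {condition}%: {exc}")
        if set(fits) != {5, 10}:
            log.record(
                "proliferation", "warning", f"{line}: missing a seeding condition, dropped"
            )
            continue
        weighted = prolif_mod.weighted_average_rate(
            fits[5].rho,
            fits[5].n_replicates,
            fits[10].rho,
            fits[10].n_replicates,
            cell_line_id=line,
            tier_thresholds=config.rho_tier_thresholds,
        )
        rows.append(
            {
                "cell_line": line,
                "rho5": fits[5].rho,
                "n5": fits[5].n_replicates,
                "r2_5": fits[5].r_squared,
                "rho10": fits[10].rho,
                "n10": fits[10].n_replicates,
                "r2_10": fits[10].r_squared,
                "weighted_average": weighted.weighted_average,
                "tier": weighted.tier,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "cell_line", "rho5", "n5", "r2_5", "rho10", "n10", "r2_10",
            "weighted_average", "tier",
        ],
    )
    log.record("proliferation", "info", f"fitted {len(df)} cell line(s)")
    return df


def _diffusion_stage(
    volumes: pd.DataFrame,
    proliferation_fits: pd.DataFrame,
    config: PipelineConfig,
    log: RunLog,
) -> pd.DataFrame:
    rates = proliferation_fits.set_index("cell_line")["weighted_average"]
    rows = []
    for line, group in volumes.groupby("cell_line", sort=True):
        if line not in rates.index:
            log.record("diffusion", "warning", f"{line}: no proliferation rate, skipped")
            continue
        group = group[group["time_days"] > 0]  # injection day excluded (t = 0)
        try:
            series = diffusion_mod.RadiusSeries(
                line,
                group["time_days"].to_numpy(),
                diffusion_mod.volume_to_radius(group["volume_mm3"].to_numpy()),
            )
            summary = diffusion_mod.estimate_diffusion(
                series,
                float(rates[line]),
                cv_cutoff=config.cv_validity_cutoff,
                tier_thresholds=config.d_tier_thresholds,
            )
        except OsteokineticsError as exc:
            log.record("diffusion", "warning", f"{line}: skipped ({exc})")
            continue
        rows.append(
            {
                "cell_line": line,
                "t_first": summary.t_range[0],
                "t_last": summary.t_range[1],
                "D_bar": summary.D_bar,
                "sd": summary.sd,
                "cv": summary.cv,
                "valid": summary.valid,
                "tier": summary.tier,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["cell_line", "t_first", "t_last", "D_bar", "sd", "cv", "valid", "tier"],
    )
    log.record("diffusion", "info", f"estimated D for {len(df)} cell line(s)")
    return df


def run_pipeline(
    config: PipelineConfig,
    volumes_path,
    confluence_path,
    levels_path=None,
) -> PipelineResult:
    """Run every stage: growth fits, logistic rates, diffusion, panel, correlation.

    Per-line failures never abort the run; they are logged and the line is
    excluded downstream.  Raises :class:`PipelineError` only when no cell
    line at all could be fitted.
    """
    log = RunLog(config_digest=config.digest())
    volumes = read_timeseries_csv(volumes_path, "volumes")
    confluence = read_timeseries_csv(confluence_path, "confluence")
    levels = read_timeseries_csv(levels_path, "levels") if levels_path else None

    growth_fits = _fit_growth_stage(volumes, config, log)
    proliferation_fits = _fit_proliferation_stage(confluence, config, log)
    if growth_fits.empty and proliferation_fits.empty:
        raise PipelineError("no cell line produced a usable fit")
    diffusion = _diffusion_stage(volumes, proliferation_fits, config, log)

    panel = pd.DataFrame()
    correlation = pd.DataFrame()
    if levels is not None:
        usable_growth = growth_fits[growth_fits["converged"]]
        try:
            panel = build_panel(usable_growth, proliferation_fits, diffusion, levels)
            correlation = correlation_matrix(panel, method=config.correlation_method).matrix
        except OsteokineticsError as exc:
            log.record("panel", "warning", f"panel stage skipped: {exc}")
    log.record("pipeline", "info", "done")
    return PipelineResult(
        growth_fits=growth_fits,
        proliferation_fits=proliferation_fits,
        diffusion=diffusion,
        panel=panel,
        correlation=correlation,
        run_log=log,
    )
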