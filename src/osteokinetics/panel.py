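"""Join fitted kinetics to phenotype levels and correlate.

One row per cell line: fitted power-law (alpha, beta), weighted logistic
rate rho, mean diffusion coefficient D-bar, and the ordinal phenotype
scores (TL tumorigenicity, CL colony formation, IL invasion, ML migration,
PL proliferation).  Lines missing any source table are dropped (listwise
deletion) with a warning.  The panel's pairwise correlation matrix (Pearson
by default, Spearman optional) summarizes how the model parameters track
the experimental phenotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, UndefinedCorrelationError

__all__ = ["CorrelationMatrix", "build_panel", "correlation_matrix", "PANEL_VARIABLES"]

logger = logging.getLogger(__name__)

#: canonical variable order of the joined panel
PANEL_VARIABLES: tuple[str, ...] = (
    "alpha",
    "beta",
    "rho",
    "D_bar",
    "TL",
    "CL",
    "IL",
    "ML",
    "PL",
)


@dataclass(frozen=True)
class CorrelationMatrix:
    variables: tuple[str, ...]
    matrix: pd.DataFrame
    method: str


def build_panel(
    growth_fits: pd.DataFrame,
    proliferation_fits: pd.DataFrame,
    diffusion_summaries: pd.DataFrame,
    levels: pd.DataFrame,
) -> pd.DataFrame:
    """Inner-join the three fit tables and the phenotype levels on cell line.

    Expects the pipeline CSV schemas: ``growth_fits`` with alpha/beta,
    ``proliferation_fits`` with weighted_average, ``diffusion_summaries``
    with D_bar, ``levels`` with any subset of TL/CL/IL/ML/PL.  Lines absent
    from any input are dropped with a logged warning; an empty join raises.
    """
    frames = {
        "growth": growth_fits[["cell_line", "alpha", "beta"]],
        "proliferation": proliferation_fits[["cell_line", "weighted_average"]].rename(
            columns={"weighted_average": "rho"}
        ),
        "diffusion": diffusion_summaries[["cell_line", "D_bar"]],
        "levels": levels,
    }
    panel = None
    for name, frame in frames.items():
        if frame["cell_line"].duplicated().any():
            raise InputError(f"{name} table has duplicate cell lines")
        panel = frame if panel is None else panel.merge(frame, on="cell_line", how="inner")
    if panel.empty:
        raise InputError("panel join is empty: no cell line appears in all inputs")

    all_lines = set().union(*(set(f["cell_line"]) for f in frames.values()))
    dropped = sorted(all_lines - set(panel["cell_line"]))
    if dropped:
        logger.warning(
            "dropped %d cell line(s) missing from at least one input: %s",
            len(dropped),
            ", ".join(dropped),
        )
    return panel.reset_index(drop=True)


def correlation_matrix(
    panel: pd.DataFrame,
    variables: tuple[str, ...] = PANEL_VARIABLES,
    method: str = "pearson",
) -> CorrelationMatrix:
    """Pairwise correlations among the panel variables.

    Raises :class:`UndefinedCorrelationError` naming any constant column,
    and requires at least 3 records.
    """
    if method not in ("pearson", "spearman"):
        raise InputError(f"unsupported correlation method {method!r}")
    variables = tuple(v for v in variables if v in panel.columns)
    if len(panel) < 3:
        raise InputError("at least 3 panel records are required")
    data = panel[list(variables)].astype(float)
    for col in variables:
        if np.ptp(data[col].to_numpy()) == 0:
            raise UndefinedCorrelationError(
                f"column {col!r} is constant; its correlations are undefined", col
            )
    matrix = data.corr(method=method)
    return CorrelationMatrix(variables=variables, matrix=matrix, method=method)
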