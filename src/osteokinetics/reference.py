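"""Published kinetic-parameter panel for human osteosarcoma cell lines.

The in vivo growth curves and in vitro confluence curves behind these
numbers come from the Lauvrak osteosarcoma cell-line characterization
(Lauvrak et al., Br J Cancer 109:2228-2236, 2013); the kinetic parameters
below are the published model-based estimates for that panel: power-law
growth parameters (alpha, beta), logistic proliferation rates at 5 % and
10 % seeding with replicate counts, point-source diffusion summaries, and
ordinal phenotype scores.

These tables serve two purposes:

* realistic defaults for the synthetic-data generator (the simulated
  panels emulate exactly these parameter ranges), and
* arithmetic-consistency checks: the weighted-average rates, the CV
  column, the CV < 50 % validity rule, the beta-cluster memberships and
  the rate-vs-proliferation-score correlation are all recomputable from
  the printed columns.

Only the tumorigenicity (TL) and proliferation (PL) phenotype scores are
included; the remaining assay scores of the source panel are not carried
here.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "beta_cluster_groups",
    "diffusion_estimates",
    "growth_parameters",
    "phenotype_scores",
    "proliferation_rates",
]

# cell_line, alpha, beta, r_squared_pct, tier  (ordered by decreasing alpha)
_GROWTH = [
    ("HOS", 2.1797, 0.5300, 99.79, "High"),
    ("OHS", 1.1640, 0.6696, 99.00, "High"),
    ("OSA", 1.1353, 0.7198, 99.61, "High"),
    ("HOS-143B", 0.8803, 0.8649, 99.99, "High"),
    ("HOS-MNNG", 0.8598, 0.8555, 99.99, "High"),
    ("MHM", 0.8137, 0.8633, 99.99, "High"),
    ("HAL", 0.4663, 0.8530, 98.92, "Medium high"),
    ("IOR/OS9", 0.4351, 0.8134, 99.09, "Medium high"),
    ("ZK-58", 0.3742, 0.8781, 99.80, "Medium high"),
    ("Cal-72", 0.3021, 0.8562, 99.67, "Medium high"),
    ("Saos-2", 0.2573, 0.7161, 99.38, "Medium"),
    ("G-292", 0.2016, 0.8619, 99.14, "Medium"),
    ("KPD", 0.1668, 0.8704, 99.82, "Medium"),
    ("IOR/OS14", 0.1576, 0.7687, 96.66, "Medium"),
    ("IOR/OS15", 0.1251, 0.6742, 99.69, "Low"),
    ("U2OS", 0.1000, 0.8419, 99.15, "Low"),
    ("MG-63", 0.0801, 0.8377, 99.53, "Low"),
]

# cell_line, rho5, n5, r2_5_pct, rho10, n10, r2_10_pct, weighted_average, tier
# (ordered by decreasing weighted average)
_PROLIFERATION = [
    ("OSA", 1.77, 4, 93.57, 2.88, 2, 97.33, 2.14, "High"),
    ("MHM", 1.75, 3, 96.81, 2.54, 2, 98.08, 2.07, "High"),
    ("U2OS", 1.92, 4, 98.92, 2.16, 2, 98.78, 2.00, "High"),
    ("HOS-143B", 1.77, 6, 97.52, 1.97, 3, 95.11, 1.84, "High"),
    ("IOR/OS15", 1.59, 2, 99.20, 1.89, 2, 96.61, 1.74, "High"),
    ("Cal-72", 1.45, 3, 98.44, 1.67, 2, 97.13, 1.54, "Medium high"),
    ("IOR/OS18", 1.52, 4, 96.93, 1.54, 2, 96.98, 1.53, "Medium high"),
    ("IOR/OS10", 1.48, 6, 97.38, 1.65, 2, 97.88, 1.53, "Medium high"),
    ("HOS", 1.48, 8, 95.57, 1.58, 2, 95.76, 1.50, "Medium high"),
    ("OHS", 1.44, 7, 99.63, 1.60, 3, 99.68, 1.49, "Medium high"),
    ("IOR/SARG", 1.32, 3, 99.57, 1.65, 3, 99.70, 1.48, "Medium"),
    ("MG-63", 1.50, 8, 92.35, 1.43, 3, 91.99, 1.48, "Medium"),
    ("Saos-2", 1.25, 4, 97.64, 1.86, 2, 97.05, 1.45, "Medium"),
    ("HOS-MNNG", 1.37, 6, 98.04, 1.43, 3, 97.19, 1.39, "Medium"),
    ("ZK-58", 1.17, 2, 98.56, 1.36, 2, 97.59, 1.26, "Medium"),
    ("IOR/OS14", 1.02, 3, 95.23, 1.15, 3, 90.99, 1.09, "Low"),
    ("HAL", 0.87, 4, 99.12, 1.22, 4, 99.61, 1.05, "Low"),
    ("IOR/OS9", 0.93, 6, 99.36, 1.29, 2, 99.30, 1.02, "Low"),
    ("KPD", 0.88, 6, 99.74, 1.00, 3, 99.42, 0.92, "Low"),
    ("IOR/MOS", 0.78, 2, 99.64, 1.04, 2, 98.65, 0.91, "Low"),
    ("G-292", 0.37, 4, 95.71, 0.43, 2, 93.50, 0.39, "Low"),
]

# cell_line, t_first, t_last (days), D_bar (mm^2/day), sd, cv_pct, tier
# (ordered by decreasing D_bar)
_DIFFUSION = [
    ("HOS", 11, 28, 1.19e-2, 2.37e-3, 20, "High"),
    ("HOS-MNNG", 8, 21, 1.03e-2, 3.92e-3, 38, "High"),
    ("OHS", 3, 28, 9.67e-3, 7.44e-4, 8, "High"),
    ("OSA", 7, 22, 9.26e-3, 9.88e-4, 11, "High"),
    ("HOS-143B", 8, 21, 8.35e-3, 3.55e-3, 42, "High"),
    ("HAL", 7, 28, 5.96e-3, 3.15e-3, 53, "Medium high"),
    ("MHM", 4, 24, 5.92e-3, 2.68e-3, 45, "Medium high"),
    ("Cal-72", 7, 34, 3.95e-3, 1.22e-3, 31, "Medium high"),
    ("KPD", 7, 55, 3.33e-3, 9.31e-4, 28, "Medium high"),
    ("G-292", 18, 69, 2.99e-3, 1.33e-3, 44, "Medium high"),
    ("IOR/OS9", 16, 48, 2.88e-3, 1.89e-3, 66, "Medium high"),
    ("ZK-58", 7, 45, 1.66e-3, 4.54e-4, 27, "Medium high"),
    ("Saos-2", 15, 90, 9.39e-4, 7.30e-5, 8, "Medium"),
    ("IOR/OS14", 13, 116, 5.55e-4, 1.78e-4, 32, "Medium"),
    ("IOR/OS15", 11, 129, 1.78e-4, 4.41e-5, 25, "Low"),
    ("U2OS", 36, 129, 1.34e-4, 4.85e-5, 36, "Low"),
    ("MG-63", 23, 172, 5.01e-5, 1.57e-5, 31, "Low"),
]

# cell_line, rho (weighted average, as summarized in the joined panel),
# TL (tumorigenicity, 1-4), PL (proliferation score, 1-3)
_PHENOTYPE = [
    ("HOS", 1.50, 4, 3),
    ("OSA", 2.14, 4, 3),
    ("HOS-143B", 1.84, 4, 3),
    ("HOS-MNNG", 1.39, 4, 2),
    ("MHM", 2.07, 4, 3),
    ("OHS", 1.49, 4, 2),
    ("Cal-72", 1.54, 3, 2),
    ("HAL", 1.05, 3, 1),
    ("IOR/OS9", 1.02, 3, 1),
    ("ZK-58", 1.26, 3, 2),
    ("KPD", 0.92, 2, 1),
    ("G-292", 0.39, 2, 1),
    ("Saos-2", 1.45, 2, 2),
    ("IOR/OS14", 1.09, 2, 2),
    ("MG-63", 1.48, 1, 3),
    ("IOR/OS15", 1.74, 1, 3),
    ("U2OS", 2.00, 1, 3),
]

# published grouping of fitted scale exponents around allometric clusters
_BETA_GROUPS = {
    2.0 / 3.0: ("HOS", "OHS", "IOR/OS15"),
    3.0 / 4.0: ("OSA", "Saos-2", "IOR/OS14"),
    5.0 / 6.0: (
        "MHM",
        "G-292",
        "Cal-72",
        "HOS-MNNG",
        "HAL",
        "U2OS",
        "MG-63",
        "IOR/OS9",
        "ZK-58",
        "KPD",
        "HOS-143B",
    ),
}


def growth_parameters() -> pd.DataFrame:
    """Power-law fits (alpha, beta, R^2 %) for the 17 in vivo lines."""
    return pd.DataFrame(
        _GROWTH, columns=["cell_line", "alpha", "beta", "r_squared_pct", "tier"]
    )


def proliferation_rates() -> pd.DataFrame:
    """Logistic rates per seeding condition for the 21 in vitro lines."""
    return pd.DataFrame(
        _PROLIFERATION,
        columns=[
            "cell_line",
            "rho5",
            "n5",
            "r2_5_pct",
            "rho10",
            "n10",
            "r2_10_pct",
            "weighted_average",
            "tier",
        ],
    )


def diffusion_estimates() -> pd.DataFrame:
    """Diffusion summaries (D-bar, sd, CV %) for the 17 in vivo lines."""
    return pd.DataFrame(
        _DIFFUSION,
        columns=["cell_line", "t_first", "t_last", "D_bar", "sd", "cv_pct", "tier"],
    )


def phenotype_scores() -> pd.DataFrame:
    """Weighted rates joined to ordinal tumorigenicity/proliferation scores."""
    return pd.DataFrame(_PHENOTYPE, columns=["cell_line", "rho", "TL", "PL"])


def beta_cluster_groups() -> dict[float, tuple[str, ...]]:
    """Published cell-line membership of the {2/3, 3/4, 5/6} beta clusters."""
    return dict(_BETA_GROUPS)
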