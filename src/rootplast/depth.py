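"""Vertical summaries of absorptive fine roots per plot.

The central statistic is the weighted mean rooting depth — the vertical
centre of gravity of the absorptive fine-root mass:

    depth = sum_i(M_i * midpoint_i) / sum_i(M_i)

where M_i is the absorptive mass of stratum i and midpoint_i is the
stratum's centre depth (2.5, 7.5, 12.5, 17.5 and 25 cm for the default
0-5/5-10/10-15/15-20/20-30 cm strata).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_STRATA, stratum_midpoints, stratum_thicknesses
from .errors import GapError, UndefinedIndexError, ValidationError
from .processing import PLOT_KEY

PROFILE_COLUMNS = PLOT_KEY + ["total_mass", "weighted_mean_depth_cm"]


def weighted_mean_depth(
    mass_by_stratum: Sequence[float],
    strata_bounds_cm: Sequence[tuple[float, float]] = DEFAULT_STRATA,
) -> float:
    """Mass-weighted mean of stratum midpoints, cm.

    Raises :class:`UndefinedIndexError` when all masses are zero — the
    statistic has no value for an empty profile, and silently returning 0
    (a depth above the soil surface) would corrupt downstream means.
    """
    masses = np.asarray(mass_by_stratum, dtype=float)
    if len(masses) != len(strata_bounds_cm):
        raise ValidationError(
            f"expected {len(strata_bounds_cm)} masses, got {len(masses)}"
        )
    if (masses < 0).any():
        raise ValidationError("stratum masses must be non-negative")
    total = masses.sum()
    if total == 0.0:
        raise UndefinedIndexError("weighted mean depth undefined for all-zero masses")
    mids = np.asarray(stratum_midpoints(strata_bounds_cm))
    # the exact value lies in [first midpoint, last midpoint]; clip the
    # floating-point roundoff so the bound holds verbatim
    return float(np.clip(masses @ mids / total, mids[0], mids[-1]))


def profile_from_densities(
    plot_densities: pd.DataFrame,
    strata_bounds_cm: Sequence[tuple[float, float]] = DEFAULT_STRATA,
    density_column: str = "absorptive_density",
) -> dict:
    """Depth profile of a single plot from its per-stratum densities.

    Converts density to mass per unit ground area (density x stratum
    thickness); the areal constant cancels in the weighted mean.  The
    bottom stratum is twice as thick as the others by default, so this
    thickness weighting matters: dropping it would bias the mean shallow.
    """
    n_strata = len(strata_bounds_cm)
    seen = sorted(plot_densities["stratum_index"])
    if seen != list(range(n_strata)):
        raise GapError(
            f"plot {plot_densities['plot_id'].iloc[0]}: "
            f"expected strata {list(range(n_strata))}, found {seen}"
        )
    ordered = plot_densities.sort_values("stratum_index")
    thickness = np.asarray(stratum_thicknesses(strata_bounds_cm))
    masses = ordered[density_column].to_numpy() * thickness
    first = ordered.iloc[0]
    return {
        "plot_id": first["plot_id"],
        "species_code": first["species_code"],
        "treatment": first["treatment"],
        "block": first["block"],
        "total_mass": float(masses.sum()),
        "weighted_mean_depth_cm": weighted_mean_depth(masses, strata_bounds_cm),
    }


def profiles_from_density_table(
    densities: pd.DataFrame,
    strata_bounds_cm: Sequence[tuple[float, float]] = DEFAULT_STRATA,
    density_column: str = "absorptive_density",
) -> pd.DataFrame:
    """Per-plot depth profiles for a whole density table."""
    rows = [
        profile_from_densities(grp, strata_bounds_cm, density_column)
        for _, grp in densities.groupby("plot_id", sort=True)
    ]
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)
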