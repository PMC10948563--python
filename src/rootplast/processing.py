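"""Raw core processing: fragment allocation, pooling, and densities.

Field protocol being reproduced: roots from the three cores of a plot are
pooled by depth stratum; short (< 1 cm) absorptive-category fragments are
picked from boxes covering a fixed fraction of the sorting-tray area
(10% by default), so their total mass is the tray pick divided by that
fraction; the fragment total is then allocated to the absorptive and dead
fractions in proportion to their sorted masses.  Density of each fraction
is dry mass over skeletal soil volume (mg cm^-3).
"""

from __future__ import annotations

import pandas as pd

from .errors import GapError, ValidationError
from .synthetic import STRATUM_SAMPLE_COLUMNS

PLOT_KEY = ["plot_id", "species_code", "treatment", "block"]

DENSITY_COLUMNS = PLOT_KEY + [
    "stratum_index",
    "absorptive_density", "transportive_density", "coarse_density", "dead_density",
]


def allocate_fragments(
    absorptive_mass: float,
    dead_mass: float,
    fragment_tray_mass: float,
    tray_fraction: float = 0.10,
) -> tuple[float, float]:
    """Scale the tray-subsample fragment mass up and split it.

    ``fragment_tray_mass / tray_fraction`` is the total fragment mass of
    the sample; it is divided between the absorptive and dead fractions in
    proportion to their sorted masses.  When both sorted masses are zero
    all fragment mass goes to the absorptive fraction, since fragments are
    by definition absorptive-category material.

    Returns the adjusted (absorptive, dead) masses in mg.
    """
    if absorptive_mass < 0 or dead_mass < 0 or fragment_tray_mass < 0:
        raise ValidationError("fragment allocation requires non-negative masses")
    if not (0.0 < tray_fraction <= 1.0):
        raise ValidationError("tray_fraction must lie in (0, 1]")
    total_fragments = fragment_tray_mass / tray_fraction
    pool = absorptive_mass + dead_mass
    if pool == 0.0:
        return absorptive_mass + total_fragments, dead_mass
    share = absorptive_mass / pool
    return (
        absorptive_mass + total_fragments * share,
        dead_mass + total_fragments * (1.0 - share),
    )


def _require_columns(samples: pd.DataFrame) -> None:
    missing = [c for c in STRATUM_SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValidationError(f"stratum-sample table missing columns: {missing}")


def pool_by_plot_depth(samples: pd.DataFrame) -> pd.DataFrame:
    """Sum fraction masses and soil volumes over the cores of each plot.

    Output has one row per plot x stratum with ``core_id`` set to the
    sentinel ``"pooled"``.  Raises :class:`GapError` if any plot lacks a
    stratum that other plots have.
    """
    _require_columns(samples)
    if samples.empty:
        raise ValidationError("no stratum samples to pool")

    all_strata = sorted(samples["stratum_index"].unique())
    gaps = []
    for plot_id, grp in samples.groupby("plot_id", sort=True):
        have = set(grp["stratum_index"])
        for s in all_strata:
            if s not in have:
                gaps.append((plot_id, s))
    if gaps:
        listing = ", ".join(f"{p}:stratum {s}" for p, s in gaps)
        raise GapError(f"missing plot/stratum combinations: {listing}")

    mass_cols = [
        "absorptive_mass", "transportive_mass", "coarse_mass", "dead_mass",
        "fragment_tray_mass", "soil_volume",
    ]
    pooled = (
        samples.groupby(PLOT_KEY + ["stratum_index"], sort=True, as_index=False)[
            mass_cols
        ].sum()
    )
    pooled["core_id"] = "pooled"
    return pooled[STRATUM_SAMPLE_COLUMNS]


def compute_density(pooled: pd.DataFrame, tray_fraction: float = 0.10) -> pd.DataFrame:
    """Fragment-adjusted fraction densities (mg cm^-3) per plot x stratum.

    The transportive and coarse fractions pass through unadjusted: the
    fragment rule concerns only absorptive and dead material.
    """
    _require_columns(pooled)
    if (pooled["soil_volume"] <= 0).any():
        bad = pooled.loc[pooled["soil_volume"] <= 0, "plot_id"].tolist()
        raise ValidationError(f"non-positive soil volume for plots: {bad}")

    adjusted = pooled.apply(
        lambda row: allocate_fragments(
            row["absorptive_mass"], row["dead_mass"],
            row["fragment_tray_mass"], tray_fraction,
        ),
        axis=1, result_type="expand",
    )
    out = pooled[PLOT_KEY + ["stratum_index"]].copy()
    vol = pooled["soil_volume"]
    out["absorptive_density"] = adjusted[0] / vol
    out["transportive_density"] = pooled["transportive_mass"] / vol
    out["coarse_density"] = pooled["coarse_mass"] / vol
    out["dead_density"] = adjusted[1] / vol
    return out[DENSITY_COLUMNS].reset_index(drop=True)


def process_samples(samples: pd.DataFrame, tray_fraction: float = 0.10) -> pd.DataFrame:
    """Pool cores by plot and depth, then compute fraction densities."""
    return compute_density(pool_by_plot_depth(samples), tray_fraction)
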