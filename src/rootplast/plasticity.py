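"""Plasticity and variability indices for a trait measured under two
water-availability treatments.

Four indices are computed per species:

* ``cv_total`` — total phenotypic variability: sample SD / mean over all
  plot-level values, mixing within- and between-treatment variation.
* ``cv_means`` — SD of the two treatment means / mean of the treatment
  means; isolates between-treatment variation.
* ``pi_v`` — plasticity index: (max treatment mean - min treatment mean)
  / max treatment mean, in [0, 1].
* ``pi_cv_ratio`` — PI:CV, the share of total phenotypic variability
  attributable to the treatment; 1 means all variation is acclimation.

Traits may be masses (mg), densities (mg cm^-3) or rooting depth (cm);
the indices are dimensionless and unit-agnostic, but negative trait
values are rejected.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedIndexError, ValidationError

INDEX_NAMES = ("pi_v", "cv_total", "cv_means", "pi_cv_ratio")

INDEX_TABLE_COLUMNS = [
    "species_code", "trait_name", "cv_total", "cv_means", "pi_v", "pi_cv_ratio",
    "mean_high", "mean_low", "n_high", "n_low",
]


def cv_total(values: Sequence[float]) -> float:
    """Sample coefficient of variation (SD with n-1 denominator / mean)."""
    arr = np.asarray(values, dtype=float)
    if len(arr) < 2:
        raise ValidationError("cv_total needs at least two values")
    mean = arr.mean()
    if mean <= 0:
        raise UndefinedIndexError(f"cv_total undefined for mean {mean}")
    return float(arr.std(ddof=1) / mean)


def pi_v(mean_high: float, mean_low: float) -> float:
    """(max - min) / max of the two treatment means."""
    if mean_high < 0 or mean_low < 0:
        raise ValidationError("treatment means must be non-negative")
    hi, lo = max(mean_high, mean_low), min(mean_high, mean_low)
    if hi == 0:
        raise UndefinedIndexError("pi_v undefined when both treatment means are 0")
    return (hi - lo) / hi


def cv_means(mean_high: float, mean_low: float) -> float:
    """Sample SD of the two treatment means over their mean.

    For two values this equals sqrt(2) * |m1 - m2| / (m1 + m2).
    """
    if mean_high < 0 or mean_low < 0:
        raise ValidationError("treatment means must be non-negative")
    centre = (mean_high + mean_low) / 2.0
    if centre <= 0:
        raise UndefinedIndexError("cv_means undefined for zero mean of means")
    sd = abs(mean_high - mean_low) / math.sqrt(2.0)
    return sd / centre


def pi_cv_ratio(pi_value: float, cv_value: float) -> float:
    """PI:CV — treatment-driven share of total phenotypic variability."""
    if cv_value <= 0:
        raise UndefinedIndexError("pi_cv_ratio undefined for cv_total <= 0")
    return pi_value / cv_value


def percent_change(mean_reference: float, mean_other: float) -> float:
    """Signed percent change from the reference mean to the other mean."""
    if mean_reference <= 0:
        raise UndefinedIndexError("percent change undefined for zero reference")
    return 100.0 * (mean_other - mean_reference) / mean_reference


def compute_index(
    index_name: str, high_values: np.ndarray, low_values: np.ndarray
) -> float:
    """One named index from raw plot values of the two treatment arms."""
    mh = float(np.mean(high_values))
    ml = float(np.mean(low_values))
    if index_name == "pi_v":
        return pi_v(mh, ml)
    if index_name == "cv_means":
        return cv_means(mh, ml)
    if index_name == "cv_total":
        return cv_total(np.concatenate([high_values, low_values]))
    if index_name == "pi_cv_ratio":
        return pi_cv_ratio(
            pi_v(mh, ml), cv_total(np.concatenate([high_values, low_values]))
        )
    raise ValidationError(f"unknown index {index_name!r}; choose from {INDEX_NAMES}")


def species_indices(
    trait_values: pd.DataFrame,
    trait_name: str,
    value_column: str = "value",
    expected_n_per_arm: int | None = None,
) -> pd.DataFrame:
    """All four indices per species from a tidy plot-level trait table.

    Parameters
    ----------
    trait_values:
        Columns ``species_code``, ``treatment`` (high/low) and
        ``value_column``; one row per plot.
    expected_n_per_arm:
        If given, a warning is emitted for any species x arm with fewer
        plots (missing plots reduce n, they are not imputed).
    """
    if (trait_values[value_column] < 0).any():
        raise ValidationError("negative trait values are not supported")
    rows = []
    for code, grp in trait_values.groupby("species_code", sort=True):
        hi = grp.loc[grp["treatment"] == "high", value_column].to_numpy(float)
        lo = grp.loc[grp["treatment"] == "low", value_column].to_numpy(float)
        if len(hi) == 0 or len(lo) == 0:
            raise ValidationError(f"species {code}: empty treatment arm")
        if expected_n_per_arm is not None and (
            len(hi) < expected_n_per_arm or len(lo) < expected_n_per_arm
        ):
            warnings.warn(
                f"species {code}: fewer plots than expected "
                f"({len(hi)} high, {len(lo)} low)", stacklevel=2,
            )
        mh, ml = float(hi.mean()), float(lo.mean())
        cv_t = cv_total(np.concatenate([hi, lo]))
        piv = pi_v(mh, ml)
        rows.append({
            "species_code": code, "trait_name": trait_name,
            "cv_total": cv_t, "cv_means": cv_means(mh, ml),
            "pi_v": piv, "pi_cv_ratio": pi_cv_ratio(piv, cv_t),
            "mean_high": mh, "mean_low": ml,
            "n_high": len(hi), "n_low": len(lo),
        })
    return pd.DataFrame(rows, columns=INDEX_TABLE_COLUMNS)


def stratum_trait_table(
    densities: pd.DataFrame,
    stratum_index: int = 0,
    density_column: str = "absorptive_density",
) -> pd.DataFrame:
    """Plot-level trait table for one stratum's density (tidy: one row/plot)."""
    sub = densities[densities["stratum_index"] == stratum_index]
    if sub.empty:
        raise ValidationError(f"no records for stratum {stratum_index}")
    out = sub[["plot_id", "species_code", "treatment", "block"]].copy()
    out["value"] = sub[density_column].to_numpy()
    return out.reset_index(drop=True)


def depth_trait_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """Plot-level trait table for weighted mean rooting depth."""
    out = profiles[["plot_id", "species_code", "treatment", "block"]].copy()
    out["value"] = profiles["weighted_mean_depth_cm"].to_numpy()
    return out.reset_index(drop=True)
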