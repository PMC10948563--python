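"""Bootstrap populations of species-level plasticity and their regression
on aboveground woody biomass.

For each species, plots are resampled with replacement *within each
treatment arm*; the treatment means and the chosen plasticity index are
recomputed per iteration, building a bootstrap population of index values
(1000 per species by default, 6000 points across six species).  Each
iteration is paired with the mean biomass of an independently resampled
set of the species' plots, and the pooled point cloud is fit by ordinary
least squares: index ~ biomass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ValidationError
from .plasticity import INDEX_NAMES, compute_index, species_indices

BOOT_TABLE_COLUMNS = ["species_code", "iteration", "index_value", "biomass_value"]


@dataclass(frozen=True)
class BootstrapConfig:
    """Settings for one bootstrap population build."""

    index_name: str = "pi_v"
    trait_name: str = "trait"
    n_iterations_per_species: int = 1000
    seed: int = 0
    paired_biomass: str = "resampled"  # or "fixed": un-resampled species mean

    def __post_init__(self) -> None:
        if self.n_iterations_per_species < 1:
            raise ValidationError("n_iterations_per_species must be >= 1")
        if self.index_name not in INDEX_NAMES:
            raise ValidationError(
                f"unknown index {self.index_name!r}; choose from {INDEX_NAMES}"
            )
        if self.paired_biomass not in ("resampled", "fixed"):
            raise ValidationError("paired_biomass must be 'resampled' or 'fixed'")


@dataclass
class BootstrapRegressionResult:
    """OLS fit of a bootstrap plasticity population against biomass."""

    index_name: str
    trait_name: str
    slope: float
    intercept: float
    r_squared: float
    slope_ci_95: tuple[float, float]
    n_points: int
    species_centroids: pd.DataFrame = field(repr=False)
    seed: int = 0

    def summary_row(self) -> dict:
        return {
            "index_name": self.index_name, "trait_name": self.trait_name,
            "slope": self.slope, "intercept": self.intercept,
            "r_squared": self.r_squared,
            "slope_ci_low": self.slope_ci_95[0],
            "slope_ci_high": self.slope_ci_95[1],
            "n_points": self.n_points, "seed": self.seed,
        }


def bootstrap_index(
    trait_values: pd.DataFrame,
    plot_biomass: pd.DataFrame,
    config: BootstrapConfig,
    value_column: str = "value",
) -> pd.DataFrame:
    """Bootstrap table of (species, iteration, index_value, biomass_value).

    ``trait_values`` is the tidy plot-level table produced by the
    plasticity module helpers; ``plot_biomass`` must carry ``plot_id``,
    ``species_code`` and ``biomass_g`` for every plot of every species.
    Resampling is stratified by treatment so no iteration has an empty
    arm (the plasticity index would be undefined).
    """
    rng = np.random.default_rng(config.seed)
    n_iter = config.n_iterations_per_species
    rows: list[pd.DataFrame] = []
    for code, grp in trait_values.groupby("species_code", sort=True):
        hi = grp.loc[grp["treatment"] == "high", value_column].to_numpy(float)
        lo = grp.loc[grp["treatment"] == "low", value_column].to_numpy(float)
        if len(hi) == 0 or len(lo) == 0:
            raise ValidationError(f"species {code}: empty treatment arm")
        bm = plot_biomass.loc[
            plot_biomass["species_code"] == code, "biomass_g"
        ].to_numpy(float)
        missing = set(grp["plot_id"]) - set(
            plot_biomass.loc[plot_biomass["species_code"] == code, "plot_id"]
        )
        if len(bm) == 0 or missing:
            raise ValidationError(f"species {code}: biomass missing for {missing}")

        idx_hi = rng.integers(0, len(hi), size=(n_iter, len(hi)))
        idx_lo = rng.integers(0, len(lo), size=(n_iter, len(lo)))
        idx_bm = rng.integers(0, len(bm), size=(n_iter, len(bm)))
        index_values = np.array([
            compute_index(config.index_name, hi[idx_hi[i]], lo[idx_lo[i]])
            for i in range(n_iter)
        ])
        if config.paired_biomass == "resampled":
            biomass_values = bm[idx_bm].mean(axis=1)
        else:
            biomass_values = np.full(n_iter, bm.mean())
        rows.append(pd.DataFrame({
            "species_code": code,
            "iteration": np.arange(n_iter),
            "index_value": index_values,
            "biomass_value": biomass_values,
        }))
    return pd.concat(rows, ignore_index=True)[BOOT_TABLE_COLUMNS]


def regress_plasticity_on_biomass(
    boot_table: pd.DataFrame,
    trait_values: pd.DataFrame | None = None,
    plot_biomass: pd.DataFrame | None = None,
    config: BootstrapConfig | None = None,
) -> BootstrapRegressionResult:
    """Unweighted OLS of bootstrap index values on biomass.

    Species centroids (the un-resampled point-estimate index paired with
    the plain species-mean biomass) are attached when the raw tables are
    supplied; they are diagnostic anchors and play no role in the fit.
    """
    if boot_table.empty:
        raise ValidationError("empty bootstrap table")
    x = boot_table["biomass_value"].to_numpy(float)
    y = boot_table["index_value"].to_numpy(float)
    if np.ptp(x) == 0.0:
        raise ValidationError("constant biomass: regression design is rank-deficient")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)

    centroids = pd.DataFrame(columns=["species_code", "biomass_g", "index_value"])
    index_name = config.index_name if config else "index"
    trait_name = config.trait_name if config else "trait"
    if trait_values is not None and plot_biomass is not None and config is not None:
        point = species_indices(trait_values, config.trait_name)
        bm_mean = plot_biomass.groupby("species_code")["biomass_g"].mean()
        centroids = pd.DataFrame({
            "species_code": point["species_code"],
            "biomass_g": point["species_code"].map(bm_mean).to_numpy(),
            "index_value": point[config.index_name].to_numpy(),
        })

    return BootstrapRegressionResult(
        index_name=index_name,
        trait_name=trait_name,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        slope_ci_95=(float(ci[1][0]), float(ci[1][1])),
        n_points=len(boot_table),
        species_centroids=centroids,
        seed=config.seed if config else 0,
    )


def plot_regression(result: BootstrapRegressionResult, boot_table: pd.DataFrame,
                    path: str) -> None:
    """Scatter of bootstrap points with the fitted line and centroids."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(boot_table["biomass_value"], boot_table["index_value"],
               s=4, alpha=0.15, color="grey", rasterized=True)
    xs = np.linspace(boot_table["biomass_value"].min(),
                     boot_table["biomass_value"].max(), 50)
    ax.plot(xs, result.intercept + result.slope * xs, color="black")
    for _, row in result.species_centroids.iterrows():
        ax.annotate(row["species_code"], (row["biomass_g"], row["index_value"]),
                    fontsize=9, fontweight="bold")
    ax.set_xlabel("aboveground woody biomass (g)")
    ax.set_ylabel(f"{result.index_name} ({result.trait_name})")
    ax.set_title(f"R² = {result.r_squared:.2f}, slope = {result.slope:.2e}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
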