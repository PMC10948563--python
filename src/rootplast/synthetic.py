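"""Synthetic soil-core generator for the blocked water-availability trial.

Emulates the sampling design — ``n_blocks`` replicate blocks, each holding
one monoculture plot per species x water treatment, three cores per plot,
five depth strata per core — and the statistical structure of root-density
data: log-normal multiplicative variation at the block, plot and core
levels around a deterministic species x depth x treatment mean.

All randomness flows through a single :class:`numpy.random.Generator`
seeded from ``config.seed``, so a given configuration always produces a
byte-identical dataset.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import SimulationConfig, stratum_midpoints

STRATUM_SAMPLE_COLUMNS = [
    "block", "plot_id", "species_code", "treatment", "core_id", "stratum_index",
    "absorptive_mass", "transportive_mass", "coarse_mass", "dead_mass",
    "fragment_tray_mass", "soil_volume",
]

PLOT_BIOMASS_COLUMNS = ["plot_id", "species_code", "treatment", "block", "biomass_g"]


def expected_absorptive_density(
    config: SimulationConfig, species_code: str, stratum_index: int, treatment: str
) -> float:
    """Noise-free mean absorptive density (mg cm^-3) for one design cell.

    The generator draws log-normally *around* this value (median
    parameterisation), so with all noise SDs at zero every core reproduces
    it exactly.
    """
    sp = {p.species_code: p for p in config.species_params}[species_code]
    mid = stratum_midpoints(config.strata_bounds_cm)[stratum_index]
    density = sp.surface_density_median * math.exp(-sp.depth_decay_rate * mid)
    if treatment == "high":
        density *= sp.treatment_multiplier_by_stratum[stratum_index]
    return density


def generate_dataset(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one full experiment.

    Returns
    -------
    stratum_samples:
        One row per block x species x treatment x core x stratum with the
        five sorted fraction masses (mg) and the skeletal soil volume (cm^3).
        The ``fragment_tray_mass`` column holds the mass picked from the
        tray-area subsample (i.e. already scaled *down* by
        ``fragment_tray_fraction``); downstream processing multiplies it
        back up.
    plot_biomass:
        One row per plot with aboveground woody biomass in g.
    """
    rng = np.random.default_rng(config.seed)
    mids = stratum_midpoints(config.strata_bounds_cm)
    n_strata = config.n_strata
    volumes = [config.core_stratum_volume(s) for s in range(n_strata)]

    rows: list[dict] = []
    biomass_rows: list[dict] = []
    for b in range(1, config.n_blocks + 1):
        block = f"B{b}"
        block_eff = math.exp(rng.normal(0.0, config.block_effect_sd))
        for sp in config.species_params:
            for treatment in ("high", "low"):
                plot_id = f"{block}-{sp.species_code}-{treatment}"
                plot_eff = math.exp(rng.normal(0.0, config.plot_noise_sd))
                sigma_bm = math.sqrt(math.log(1.0 + sp.biomass_cv**2))
                biomass = sp.biomass_median * math.exp(rng.normal(0.0, sigma_bm))
                biomass_rows.append({
                    "plot_id": plot_id, "species_code": sp.species_code,
                    "treatment": treatment, "block": block, "biomass_g": biomass,
                })
                for c in range(1, config.n_cores_per_plot + 1):
                    core_id = f"C{c}"
                    for s in range(n_strata):
                        mean = sp.surface_density_median * math.exp(
                            -sp.depth_decay_rate * mids[s]
                        )
                        if treatment == "high":
                            mean *= sp.treatment_multiplier_by_stratum[s]
                        mean *= block_eff * plot_eff
                        noise = math.exp(rng.normal(0.0, config.core_noise_sd))
                        noise_dead = math.exp(rng.normal(0.0, config.core_noise_sd))
                        noise_tr = math.exp(rng.normal(0.0, config.core_noise_sd))
                        noise_co = math.exp(rng.normal(0.0, config.core_noise_sd))
                        absorptive = mean * noise * volumes[s]
                        dead = (
                            mean * sp.dead_fraction_by_stratum[s]
                            * noise_dead * volumes[s]
                        )
                        transportive = (
                            mean * config.transportive_ratio * noise_tr * volumes[s]
                        )
                        coarse = mean * config.coarse_ratio * noise_co * volumes[s]
                        fragment_tray = (
                            config.fragment_mass_fraction
                            * (absorptive + dead)
                            * config.fragment_tray_fraction
                        )
                        rows.append({
                            "block": block, "plot_id": plot_id,
                            "species_code": sp.species_code,
                            "treatment": treatment, "core_id": core_id,
                            "stratum_index": s,
                            "absorptive_mass": absorptive,
                            "transportive_mass": transportive,
                            "coarse_mass": coarse,
                            "dead_mass": dead,
                            "fragment_tray_mass": fragment_tray,
                            "soil_volume": volumes[s],
                        })

    samples = pd.DataFrame(rows, columns=STRATUM_SAMPLE_COLUMNS)
    biomass_df = pd.DataFrame(biomass_rows, columns=PLOT_BIOMASS_COLUMNS)
    return samples, biomass_df
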