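import pytest

from rootplast.config import DEFAULT_SPECIES_PARAMS, SimulationConfig, SpeciesParams
from rootplast.synthetic import generate_dataset


def make_config(
    multipliers=None,
    block_sd=0.15,
    plot_sd=0.20,
    core_sd=0.25,
    seed=0,
    **kwargs,
):
    """Build a SimulationConfig, optionally overriding one species' treatment
    multipliers (dict species_code -> 5-tuple) and the noise SDs."""
    species = []
    for sp in DEFAULT_SPECIES_PARAMS:
        mult = sp.treatment_multiplier_by_stratum
        if multipliers and sp.species_code in multipliers:
            mult = tuple(multipliers[sp.species_code])
        species.append(SpeciesParams(
            sp.species_code, sp.surface_density_median, sp.depth_decay_rate,
            mult, sp.dead_fraction_by_stratum, sp.biomass_median, sp.biomass_cv,
        ))
    return SimulationConfig(
        species_params=tuple(species),
        block_effect_sd=block_sd, plot_noise_sd=plot_sd, core_noise_sd=core_sd,
        seed=seed, **kwargs,
    )


def noise_free_config(multipliers=None, seed=0, **kwargs):
    return make_config(multipliers, block_sd=0.0, plot_sd=0.0, core_sd=0.0,
                       seed=seed, **kwargs)


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded default experiment shared across read-only tests."""
    samples, biomass = generate_dataset(SimulationConfig(seed=7))
    return samples, biomass
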