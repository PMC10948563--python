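# rootplast

Analysis machinery for **fine-root acclimation to growing-season water
availability** in blocked tree-monoculture field experiments, for root
ecologists and forest scientists working with soil-core data.

The experimental template is a common-garden trial: six temperate tree
species (*Betula papyrifera* Bp, *Quercus rubra* Qr, *Acer saccharum* As,
*Larix laricina* Ll, *Pinus strobus* Ps, *Picea glauca* Pg) grown in
monoculture plots across four replicate blocks, each plot receiving either
a high (irrigated) or low (rainfall-excluded) water treatment. Three soil
cores per plot are split into five depth strata (0–5, 5–10, 10–15, 15–20,
20–30 cm) and hand-sorted into absorptive fine roots, transportive fine
roots, coarse roots, dead roots, and short root fragments.

## What it computes

**Core processing.** Fragments are picked from a fixed fraction of the
sorting-tray area (10% by default), so their total mass is the tray pick
divided by that fraction; the total is allocated to the absorptive and dead
fractions in proportion to their sorted masses. Cores are pooled by plot
and stratum, and each fraction's density is dry mass over skeletal soil
volume (mg cm⁻³).

**Weighted mean rooting depth** — the vertical centre of gravity of the
absorptive fine roots:

```
depth = Σᵢ Mᵢ · midᵢ / Σᵢ Mᵢ
```

with `Mᵢ` the absorptive mass of stratum *i* and `midᵢ` its centre depth
(2.5, 7.5, 12.5, 17.5, 25 cm).

**Plasticity indices**, per species and trait, with treatment means
`m_high`, `m_low` over the replicate plots:

| index | definition | reads as |
|---|---|---|
| PIv | (max − min) / max of the treatment means | plasticity, in [0, 1] |
| CV | SD / mean over all plot values | total phenotypic variability |
| CVm | SD of the two treatment means / their mean | between-treatment variability |
| PI:CV | PIv / CV | share of variability due to acclimation (1 = all of it) |

**Bootstrap regression.** Per species, plots are resampled with replacement
within each treatment arm and the index recomputed, building a population
of 1000 index values per species (6000 points over six species); each is
paired with the mean biomass of an independently resampled set of that
species' plots, and the pooled cloud is fit by OLS: index ~ aboveground
woody biomass.

**Mixed-model ANOVA.** Absorptive density is modelled on the log(x+1)
scale with species × soil depth × water treatment fixed effects and
block/plot random intercepts; dead-root density is ×10-rounded to counts
and fit as Poisson; rooting depth is Box-Cox transformed with species ×
treatment effects. Type-III tables and per-species high-vs-low contrasts
are extracted.

A **synthetic-data generator** reproduces the design (48 plots × 3 cores ×
5 strata) with log-normal block/plot/core variation around species-specific
depth-decaying density profiles, so the full pipeline is testable without
field data.

## Worked example

```python
from rootplast.config import SimulationConfig
from rootplast.synthetic import generate_dataset
from rootplast import processing, plasticity
from rootplast.bootstrap import (BootstrapConfig, bootstrap_index,
                                 regress_plasticity_on_biomass)

cfg = SimulationConfig(seed=1)
samples, biomass = generate_dataset(cfg)
densities = processing.process_samples(samples, cfg.fragment_tray_fraction)

topsoil = plasticity.stratum_trait_table(densities, stratum_index=0)
print(plasticity.species_indices(topsoil, "topsoil_absorptive_density")
      [["species_code", "pi_v", "cv_total", "cv_means", "pi_cv_ratio"]]
      .round(3).to_string(index=False))

bcfg = BootstrapConfig(index_name="pi_v", trait_name="topsoil_absorptive_density",
                       n_iterations_per_species=1000, seed=1)
boot = bootstrap_index(topsoil, biomass, bcfg)
reg = regress_plasticity_on_biomass(boot, topsoil, biomass, bcfg)
print(f"slope = {reg.slope:.3e} per g, R^2 = {reg.r_squared:.3f}")
```

prints

```
species_code  pi_v  cv_total  cv_means  pi_cv_ratio
          As 0.382     0.319     0.333        1.195
          Bp 0.070     0.167     0.051        0.418
          Ll 0.062     0.244     0.045        0.254
          Pg 0.441     0.398     0.400        1.107
          Ps 0.013     0.171     0.009        0.074
          Qr 0.197     0.157     0.154        1.256
slope = -4.093e-05 per g, R^2 = 0.345
```

The two slow-growing, late-successional species (As, Pg) show the highest
topsoil plasticity (PIv 0.38 and 0.44) and the regression slope against
aboveground woody biomass is negative: the smaller a species' aboveground
stature, the more it shifts absorptive fine-root density in the top 5 cm
between water treatments. Running the same regression on weighted mean
rooting depth gives a positive slope — the fast growers acclimate by
moving the whole profile instead.

The same pipeline is available from the shell:

```bash
rootplast simulate --seed 1 --out samples.csv --biomass-out biomass.csv
rootplast process samples.csv --out densities.csv
rootplast profile densities.csv --out profiles.csv
rootplast plasticity densities.csv profiles.csv
rootplast run-all --seed 1 --outdir results/
```

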