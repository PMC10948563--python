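"""Experiment-design constants and simulation configuration.

The design mirrors a blocked common-garden water-availability trial:
six tree species grown in monoculture plots, four replicate blocks,
each block holding one plot per species x water treatment (high = weekly
irrigation, low = partial rainfall exclusion), sampled with three soil
cores per plot split into five depth strata down to 30 cm.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

from .errors import ValidationError

SPECIES_CODES = ("Bp", "Qr", "As", "Ll", "Ps", "Pg")
SPECIES_NAMES = {
    "Bp": "Betula papyrifera",
    "Qr": "Quercus rubra",
    "As": "Acer saccharum",
    "Ll": "Larix laricina",
    "Ps": "Pinus strobus",
    "Pg": "Picea glauca",
}
TREATMENTS = ("high", "low")

#: default depth strata (top, bottom) in cm below the mineral-soil surface
DEFAULT_STRATA = ((0.0, 5.0), (5.0, 10.0), (10.0, 15.0), (15.0, 20.0), (20.0, 30.0))


def stratum_midpoints(strata: Sequence[tuple[float, float]]) -> list[float]:
    """Centre depth of each stratum, cm (2.5, 7.5, 12.5, 17.5, 25 by default)."""
    return [(top + bottom) / 2.0 for top, bottom in strata]


def stratum_thicknesses(strata: Sequence[tuple[float, float]]) -> list[float]:
    return [bottom - top for top, bottom in strata]


def validate_strata(strata: Sequence[tuple[float, float]]) -> None:
    """Strata must be contiguous, non-overlapping and increasing in depth."""
    if not strata:
        raise ValidationError("at least one depth stratum is required")
    prev_bottom = None
    for i, (top, bottom) in enumerate(strata):
        if bottom <= top:
            raise ValidationError(f"stratum {i}: bottom {bottom} <= top {top}")
        if prev_bottom is not None and not math.isclose(top, prev_bottom):
            raise ValidationError(
                f"stratum {i}: top {top} does not meet previous bottom {prev_bottom}"
            )
        prev_bottom = bottom


@dataclass(frozen=True)
class SpeciesParams:
    """Data-generating parameters for one species.

    Parameters
    ----------
    species_code:
        Two-letter species label (Bp, Qr, As, Ll, Ps, Pg).
    surface_density_median:
        Median absorptive fine-root density (mg cm^-3) in the top stratum
        under the low-water arm.
    depth_decay_rate:
        Exponential decline of density per cm of depth (evaluated at the
        stratum midpoint).
    treatment_multiplier_by_stratum:
        High-water density divided by low-water density, per stratum.
        Values > 1 concentrate roots where watered; a declining gradient
        shifts the high-water profile shallower than the low-water one.
    dead_fraction_by_stratum:
        Dead-root (necromass) density as a fraction of the live absorptive
        density mean, per stratum.
    biomass_median:
        Median aboveground woody biomass per plot, g.
    biomass_cv:
        Coefficient of variation of plot biomass (log-normal).
    """

    species_code: str
    surface_density_median: float
    depth_decay_rate: float
    treatment_multiplier_by_stratum: tuple[float, ...]
    dead_fraction_by_stratum: tuple[float, ...]
    biomass_median: float
    biomass_cv: float

    def __post_init__(self) -> None:
        if self.surface_density_median <= 0:
            raise ValidationError(f"{self.species_code}: surface density must be > 0")
        if self.depth_decay_rate <= 0:
            raise ValidationError(f"{self.species_code}: decay rate must be > 0")
        if self.biomass_median <= 0 or self.biomass_cv < 0:
            raise ValidationError(f"{self.species_code}: invalid biomass parameters")
        if any(m <= 0 for m in self.treatment_multiplier_by_stratum):
            raise ValidationError(
                f"{self.species_code}: treatment multipliers must be > 0"
            )
        if any(not (0.0 <= d <= 1.0) for d in self.dead_fraction_by_stratum):
            raise ValidationError(
                f"{self.species_code}: dead fractions must lie in [0, 1]"
            )


# Illustrative defaults. Conifers carry higher densities than broadleaves and
# all species decline steeply with depth; the slower-growing, late-successional
# species (As, Pg) get the large topsoil treatment multipliers while the
# fast-growing, early-successional species (Bp, Ll) get the depth-gradient
# shifts, so the synthetic data reproduce the qualitative
# plasticity-versus-biomass patterns of the study system.
DEFAULT_SPECIES_PARAMS: tuple[SpeciesParams, ...] = (
    SpeciesParams("Bp", 6.0, 0.08, (1.10, 1.00, 0.80, 0.60, 0.40),
                  (0.18, 0.18, 0.20, 0.20, 0.22), 6000.0, 0.25),
    SpeciesParams("Qr", 5.0, 0.09, (1.20, 1.05, 0.95, 0.85, 0.80),
                  (0.18, 0.18, 0.20, 0.20, 0.22), 2500.0, 0.25),
    SpeciesParams("As", 4.5, 0.10, (1.65, 1.30, 1.25, 1.25, 1.25),
                  (0.18, 0.18, 0.20, 0.20, 0.22), 1200.0, 0.25),
    SpeciesParams("Ll", 9.0, 0.10, (1.15, 1.00, 0.75, 0.55, 0.35),
                  (0.32, 0.32, 0.34, 0.34, 0.36), 5000.0, 0.25),
    SpeciesParams("Ps", 10.0, 0.12, (1.30, 1.10, 1.00, 0.95, 0.90),
                  (0.32, 0.32, 0.34, 0.34, 0.36), 2000.0, 0.25),
    SpeciesParams("Pg", 11.0, 0.15, (1.90, 1.40, 1.30, 1.30, 1.35),
                  (0.32, 0.32, 0.34, 0.34, 0.36), 900.0, 0.25),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Full configuration of the synthetic field experiment."""

    species_params: tuple[SpeciesParams, ...] = DEFAULT_SPECIES_PARAMS
    n_blocks: int = 4
    n_cores_per_plot: int = 3
    strata_bounds_cm: tuple[tuple[float, float], ...] = DEFAULT_STRATA
    block_effect_sd: float = 0.15
    plot_noise_sd: float = 0.20
    core_noise_sd: float = 0.25
    fragment_tray_fraction: float = 0.10
    fragment_mass_fraction: float = 0.15
    transportive_ratio: float = 0.25
    coarse_ratio: float = 0.60
    core_diameter_cm: float = 5.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.n_cores_per_plot < 1:
            raise ValidationError("block and core counts must be >= 1")
        validate_strata(self.strata_bounds_cm)
        n_strata = len(self.strata_bounds_cm)
        for sp in self.species_params:
            if len(sp.treatment_multiplier_by_stratum) != n_strata:
                raise ValidationError(
                    f"{sp.species_code}: expected {n_strata} treatment multipliers"
                )
            if len(sp.dead_fraction_by_stratum) != n_strata:
                raise ValidationError(
                    f"{sp.species_code}: expected {n_strata} dead fractions"
                )
        for name in ("block_effect_sd", "plot_noise_sd", "core_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (0.0 < self.fragment_tray_fraction <= 1.0):
            raise ValidationError("fragment_tray_fraction must lie in (0, 1]")
        if self.fragment_mass_fraction < 0:
            raise ValidationError("fragment_mass_fraction must be >= 0")
        if self.transportive_ratio < 0 or self.coarse_ratio < 0:
            raise ValidationError("fraction ratios must be >= 0")
        if self.core_diameter_cm <= 0:
            raise ValidationError("core diameter must be > 0")

    @property
    def species_codes(self) -> tuple[str, ...]:
        return tuple(sp.species_code for sp in self.species_params)

    @property
    def n_strata(self) -> int:
        return len(self.strata_bounds_cm)

    def core_stratum_volume(self, stratum_index: int) -> float:
        """Skeletal volume of one core section, cm^3 (cylinder model)."""
        top, bottom = self.strata_bounds_cm[stratum_index]
        radius = self.core_diameter_cm / 2.0
        return math.pi * radius**2 * (bottom - top)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["strata_bounds_cm"] = [list(b) for b in self.strata_bounds_cm]
        d["species_params"] = [asdict(sp) for sp in self.species_params]
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        if "species_params" in data:
            data["species_params"] = tuple(
                SpeciesParams(
                    species_code=sp["species_code"],
                    surface_density_median=float(sp["surface_density_median"]),
                    depth_decay_rate=float(sp["depth_decay_rate"]),
                    treatment_multiplier_by_stratum=tuple(
                        float(x) for x in sp["treatment_multiplier_by_stratum"]
                    ),
                    dead_fraction_by_stratum=tuple(
                        float(x) for x in sp["dead_fraction_by_stratum"]
                    ),
                    biomass_median=float(sp["biomass_median"]),
                    biomass_cv=float(sp["biomass_cv"]),
                )
                for sp in data["species_params"]
            )
        if "strata_bounds_cm" in data:
            data["strata_bounds_cm"] = tuple(
                (float(t), float(b)) for t, b in data["strata_bounds_cm"]
            )
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
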