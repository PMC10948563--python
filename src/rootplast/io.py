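"""CSV schemas and validated readers/writers.

All interchange is plain CSV with fixed units: masses in mg, soil volume
in cm^3, densities in mg cm^-3, depths in cm, biomass in g.  Every table
written by the pipeline gets a ``<name>.meta.json`` sidecar carrying the
package version, the run seed and a configuration hash; no timestamps
are written, so reruns with the same seed are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__
from .config import SPECIES_CODES, TREATMENTS
from .errors import ValidationError
from .synthetic import PLOT_BIOMASS_COLUMNS, STRATUM_SAMPLE_COLUMNS

_MASS_COLUMNS = [
    "absorptive_mass", "transportive_mass", "coarse_mass", "dead_mass",
    "fragment_tray_mass",
]


def read_stratum_samples(
    path: str | Path,
    allowed_species: tuple[str, ...] = SPECIES_CODES,
    n_strata: int = 5,
) -> pd.DataFrame:
    """Read and validate a stratum-sample CSV.

    Row-level violations are reported with 1-based file line numbers
    (header is line 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: no records (empty file)") from None
    missing = [c for c in STRATUM_SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if df.empty:
        raise ValidationError(f"{path}: no records")

    errors: list[str] = []
    for i, row in df.iterrows():
        line = i + 2  # header occupies line 1
        if row["species_code"] not in allowed_species:
            errors.append(f"line {line}: unknown species code "
                          f"{row['species_code']!r}")
        if row["treatment"] not in TREATMENTS:
            errors.append(f"line {line}: treatment {row['treatment']!r} "
                          f"not in {TREATMENTS}")
        if not (0 <= row["stratum_index"] < n_strata):
            errors.append(f"line {line}: stratum_index {row['stratum_index']} "
                          f"outside 0..{n_strata - 1}")
        for col in _MASS_COLUMNS:
            if row[col] < 0:
                errors.append(f"line {line}: negative mass in {col}")
        if row["soil_volume"] <= 0:
            errors.append(f"line {line}: non-positive soil_volume")
    if errors:
        raise ValidationError(f"{path}: " + "; ".join(errors[:20]))
    return df[STRATUM_SAMPLE_COLUMNS]


def read_plot_biomass(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: no records (empty file)") from None
    missing = [c for c in PLOT_BIOMASS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if df.empty:
        raise ValidationError(f"{path}: no records")
    bad = df.index[df["biomass_g"] <= 0]
    if len(bad):
        raise ValidationError(
            f"{path}: non-positive biomass on lines {[i + 2 for i in bad[:10]]}"
        )
    return df[PLOT_BIOMASS_COLUMNS]


def write_table(df: pd.DataFrame, path: str | Path,
                seed: int | None = None,
                config_hash: str | None = None) -> None:
    """Write a CSV plus its metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    meta = {"version": __version__, "seed": seed, "config_hash": config_hash,
            "rows": len(df), "columns": list(df.columns)}
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2) + "\n"
    )


def read_table(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: no records (empty file)") from None
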