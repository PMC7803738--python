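"""File formats, configuration parsing and run manifests.

All tables are UTF-8 CSV with a header row and '.' decimal separator;
lengths are mm, angles degrees, wavelengths nm.  Every pipeline output
directory receives exactly one ``run_manifest.json`` recording the command,
a digest of the effective configuration, the master seed and the package
version, so that identical manifests imply bit-identical deterministic
outputs.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidParameterError
from .forward import SimulationConfig, SphereGeometry
from .optics import Layer, LayerStack, OpticalProperties

MEASUREMENT_COLUMNS = ("wavelength_nm", "Rd", "Tt", "Td")
RESULT_COLUMNS = (
    "wavelength_nm", "mu_a_mm", "mu_s_mm", "g", "mu_s_prime_mm",
    "residual", "iterations", "converged", "seed",
)


def package_version() -> str:
    try:
        return version("imctissue")
    except PackageNotFoundError:  # pragma: no cover - editable edge case
        return "unknown"


def read_measurement_csv(path) -> pd.DataFrame:
    """Read a measurement table, checking the schema by column name."""
    df = pd.read_csv(path)
    for col in MEASUREMENT_COLUMNS:
        if col not in df.columns:
            raise InvalidParameterError(f"measurement file {path} is missing column {col!r}")
    return df


def write_csv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def parse_wavelength_grid(spec: str) -> np.ndarray:
    """Parse a start:stop:step grid in nm, inclusive of stop when aligned."""
    try:
        start, stop, step = (float(tok) for tok in spec.split(":"))
    except ValueError as exc:
        raise InvalidParameterError(f"bad wavelength grid {spec!r}; expected start:stop:step") from exc
    if step <= 0 or stop < start:
        raise InvalidParameterError(f"bad wavelength grid {spec!r}")
    n = int(round((stop - start) / step))
    grid = start + step * np.arange(n + 1)
    return grid[grid <= stop + 1e-9]


def geometry_from_dict(d: dict) -> SphereGeometry:
    return SphereGeometry(**{k: d[k] for k in (
        "beam_diameter", "sample_port_diameter", "reference_port_diameter",
        "lateral_extent", "collimation_half_angle",
    ) if k in d})


def stack_from_dict(d: dict) -> LayerStack:
    layers = tuple(
        Layer(
            thickness=la["thickness"],
            props=OpticalProperties(
                mu_a=la.get("mu_a", 0.0),
                mu_s=la.get("mu_s", 0.0),
                g=la.get("g", 0.0),
                n=la.get("n", 1.0),
            ),
        )
        for la in d["layers"]
    )
    return LayerStack(layers, ambient_n=d.get("ambient_n", 1.0))


def simulation_from_dict(d: dict) -> SimulationConfig:
    return SimulationConfig(**{k: d[k] for k in (
        "n_photons", "seed", "roulette_threshold", "roulette_survival",
    ) if k in d})


def read_config_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def write_manifest(out_dir, command: str, config: dict, master_seed: int) -> Path:
    """Write the single run manifest of an output directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config_hash": config_hash(config),
        "master_seed": int(master_seed),
        "package_version": package_version(),
        "written_utc": datetime.now(timezone.utc).isoformat(),
    }
    path = out / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
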