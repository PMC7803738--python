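"""Ground-truth tissue spectra and synthetic measurement sets.

No public measurement data exist for the heated-ear experiment, so this
module is the study's stand-in data source: it generates per-wavelength
ground-truth optical properties from a parametric chromophore model and
forward-simulates them into noisy integrating-sphere measurement tables.

The absorption model is a flat baseline plus Gaussian bands in wavelength:
hemoglobin bands (oxy/deoxy mixed by an oxygen-saturation fraction) dominate
400-950 nm and water bands dominate 1150-1650 nm.  Scattering follows a
power law mu_s(lambda) = a * (lambda/500 nm)^-b and the anisotropy factor is
a clipped linear trend.  Three shipped presets encode the 25/36/60 C states:
heating deoxygenates the blood (Soret band 417 -> 426 nm, the 545/575 nm
oxyhemoglobin double band collapsing to a single 557 nm band, a deoxy band
near 905 nm appearing), blue-shifts the water bands (1192 -> 1184 nm and
1454 -> 1449 -> 1441 nm), concentrates chromophores by shrinkage, steepens
the scattering power law and slightly lowers g.

Band amplitudes and widths are package design choices (documented in
docs/methods.md); only the band centers and the qualitative orderings carry
over from the reported temperature responses.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidParameterError
from .forward import SimulationConfig, SphereGeometry, simulate_measurements
from .optics import LayerStack, OpticalProperties, sandwich, with_tissue

__all__ = [
    "ChromophoreBand",
    "TissueSpectrumModel",
    "TemperaturePreset",
    "PRESET_NAMES",
    "REPLICATES_PER_PRESET",
    "load_preset",
    "evaluate_truth",
    "generate_measurement_set",
]

#: Wavelength range (nm) over which the band models are considered valid.
WAVELENGTH_RANGE = (380.0, 1700.0)
#: Reference wavelength (nm) of the scattering power law.
SCATTER_REFERENCE_NM = 500.0
#: Shipped presets.
PRESET_NAMES = ("25C", "36C", "60C")
#: Replicate structure of the emulated study (sets per temperature).
REPLICATES_PER_PRESET = {"25C": 12, "36C": 10, "60C": 10}

_PRESET_FILES = {"25C": "t25c.yaml", "36C": "t36c.yaml", "60C": "t60c.yaml"}


@dataclass(frozen=True)
class ChromophoreBand:
    """A Gaussian absorption band: center (nm), width (Gaussian sigma, nm), amplitude (mm^-1)."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        lo, hi = WAVELENGTH_RANGE
        if not (lo <= self.center <= hi):
            raise InvalidParameterError(f"band center {self.center} nm outside {WAVELENGTH_RANGE}")
        if not self.width > 0.0:
            raise InvalidParameterError("band width must be > 0")
        if not self.amplitude >= 0.0:
            raise InvalidParameterError("band amplitude must be >= 0")

    def __call__(self, wavelengths: np.ndarray) -> np.ndarray:
        d = (np.asarray(wavelengths, dtype=float) - self.center) / self.width
        return self.amplitude * np.exp(-0.5 * d * d)


@dataclass(frozen=True)
class TissueSpectrumModel:
    """Parametric ground-truth spectra of the tissue layer."""

    hemoglobin_bands_oxy: tuple[ChromophoreBand, ...] = ()
    hemoglobin_bands_deoxy: tuple[ChromophoreBand, ...] = ()
    water_bands: tuple[ChromophoreBand, ...] = ()
    oxygen_saturation: float = 0.95
    blood_amplitude_scale: float = 1.0
    water_amplitude_scale: float = 1.0
    scatter_a: float = 15.0
    scatter_b: float = 1.1
    g0: float = 0.92
    g_slope: float = 0.0
    baseline_mu_a: float = 0.1
    n: float = 1.4

    def __post_init__(self) -> None:
        if not (0.0 <= self.oxygen_saturation <= 1.0):
            raise InvalidParameterError("oxygen_saturation must lie in [0, 1]")
        if not self.scatter_a > 0.0:
            raise InvalidParameterError("scatter_a must be > 0")
        if not self.baseline_mu_a >= 0.0:
            raise InvalidParameterError("baseline_mu_a must be >= 0")
        object.__setattr__(self, "hemoglobin_bands_oxy", tuple(self.hemoglobin_bands_oxy))
        object.__setattr__(self, "hemoglobin_bands_deoxy", tuple(self.hemoglobin_bands_deoxy))
        object.__setattr__(self, "water_bands", tuple(self.water_bands))

    def mu_a(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        out = np.full(wl.shape, self.baseline_mu_a)
        s = self.oxygen_saturation
        for band in self.hemoglobin_bands_oxy:
            out = out + self.blood_amplitude_scale * s * band(wl)
        for band in self.hemoglobin_bands_deoxy:
            out = out + self.blood_amplitude_scale * (1.0 - s) * band(wl)
        for band in self.water_bands:
            out = out + self.water_amplitude_scale * band(wl)
        return out

    def mu_s(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        return self.scatter_a * (wl / SCATTER_REFERENCE_NM) ** (-self.scatter_b)

    def g(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        return np.clip(self.g0 + self.g_slope * (wl - SCATTER_REFERENCE_NM), 1e-3, 0.999)

    def to_dict(self) -> dict:
        def bands(bs):
            return [{"center": b.center, "width": b.width, "amplitude": b.amplitude} for b in bs]

        return {
            "hemoglobin_bands_oxy": bands(self.hemoglobin_bands_oxy),
            "hemoglobin_bands_deoxy": bands(self.hemoglobin_bands_deoxy),
            "water_bands": bands(self.water_bands),
            "oxygen_saturation": self.oxygen_saturation,
            "blood_amplitude_scale": self.blood_amplitude_scale,
            "water_amplitude_scale": self.water_amplitude_scale,
            "scatter_a": self.scatter_a,
            "scatter_b": self.scatter_b,
            "g0": self.g0,
            "g_slope": self.g_slope,
            "baseline_mu_a": self.baseline_mu_a,
            "n": self.n,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TissueSpectrumModel":
        def bands(key):
            return tuple(ChromophoreBand(**b) for b in d.get(key, []))

        kwargs = {k: d[k] for k in (
            "oxygen_saturation", "blood_amplitude_scale", "water_amplitude_scale",
            "scatter_a", "scatter_b", "g0", "g_slope", "baseline_mu_a", "n",
        ) if k in d}
        return cls(
            hemoglobin_bands_oxy=bands("hemoglobin_bands_oxy"),
            hemoglobin_bands_deoxy=bands("hemoglobin_bands_deoxy"),
            water_bands=bands("water_bands"),
            **kwargs,
        )


@dataclass(frozen=True)
class TemperaturePreset:
    """A named temperature state with its ground-truth spectrum model."""

    label: str
    model: TissueSpectrumModel


def load_preset(name: str) -> TemperaturePreset:
    """Load one of the shipped temperature presets ('25C', '36C', '60C')."""
    if name not in _PRESET_FILES:
        raise InvalidParameterError(f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}")
    ref = importlib.resources.files("imctissue.presets") / _PRESET_FILES[name]
    data = yaml.safe_load(ref.read_text())
    label = data.pop("label", name)
    return TemperaturePreset(label=label, model=TissueSpectrumModel.from_dict(data))


def save_preset(preset: TemperaturePreset, path) -> None:
    """Serialize a preset to YAML."""
    payload = {"label": preset.label, **preset.model.to_dict()}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def _check_grid(wavelengths: np.ndarray) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    lo, hi = WAVELENGTH_RANGE
    if wl.size == 0 or wl.min() < lo or wl.max() > hi:
        raise InvalidParameterError(f"wavelength grid must lie within {WAVELENGTH_RANGE} nm")
    if wl.size > 1 and not np.all(np.diff(wl) > 0):
        raise InvalidParameterError("wavelength grid must be strictly increasing")
    return wl


def evaluate_truth(preset: TemperaturePreset, wavelengths) -> pd.DataFrame:
    """Ground-truth per-wavelength optical properties of a preset.

    Returns a table with columns wavelength_nm, mu_a_mm, mu_s_mm, g,
    mu_s_prime_mm, n.
    """
    wl = _check_grid(wavelengths)
    m = preset.model
    mu_a = m.mu_a(wl)
    mu_s = m.mu_s(wl)
    g = m.g(wl)
    return pd.DataFrame(
        {
            "wavelength_nm": wl,
            "mu_a_mm": mu_a,
            "mu_s_mm": mu_s,
            "g": g,
            "mu_s_prime_mm": mu_s * (1.0 - g),
            "n": m.n,
        }
    )


def _kernel_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def generate_measurement_set(
    preset: TemperaturePreset,
    wavelengths,
    geom: SphereGeometry | None = None,
    stack_template: LayerStack | None = None,
    cfg: SimulationConfig | None = None,
    noise_cv: float = 0.01,
    seed: int = 0,
    replicate: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Forward-simulate a preset into one noisy measurement table.

    Per wavelength the ground truth is forward-simulated (with a seed fanned
    out from ``seed`` per (replicate, wavelength)), then independent
    multiplicative Gaussian noise (1 + eps), eps ~ N(0, noise_cv^2), is
    applied to Rd, Tt and Td, results are clipped to [0, 1] and Td <= Tt is
    restored before Tc = Tt - Td is recomputed.

    Returns ``(measurements, truth)``; recovery scoring must only ever read
    the truth table.
    """
    if noise_cv < 0.0:
        raise InvalidParameterError("noise_cv must be >= 0")
    geom = geom or SphereGeometry()
    cfg = cfg or SimulationConfig()
    truth = evaluate_truth(preset, wavelengths)
    if stack_template is None:
        stack_template = sandwich(OpticalProperties(0.1, 10.0, 0.9, preset.model.n))
    # splittable counter scheme: every (replicate, wavelength) gets its own stream
    noise_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2, replicate)))
    rows = []
    for i, row in truth.iterrows():
        props = OpticalProperties(row.mu_a_mm, row.mu_s_mm, row.g, preset.model.n)
        stack = with_tissue(stack_template, props)
        wcfg = SimulationConfig(
            n_photons=cfg.n_photons,
            seed=_kernel_seed(np.random.SeedSequence(entropy=seed, spawn_key=(1, replicate, i))),
            roulette_threshold=cfg.roulette_threshold,
            roulette_survival=cfg.roulette_survival,
        )
        meas = simulate_measurements(stack, geom, wcfg)
        rd, tt, td = meas.Rd, meas.Tt, meas.Td
        if noise_cv > 0.0:
            eps = noise_rng.normal(0.0, noise_cv, size=3)
            rd = float(np.clip(rd * (1.0 + eps[0]), 0.0, 1.0))
            tt = float(np.clip(tt * (1.0 + eps[1]), 0.0, 1.0))
            td = float(np.clip(td * (1.0 + eps[2]), 0.0, 1.0))
            td = min(td, tt)
        rows.append(
            {
                "wavelength_nm": row.wavelength_nm,
                "Rd": rd,
                "Tt": tt,
                "Td": td,
                "Tc": tt - td,
                "se_Rd": meas.se_Rd,
                "se_Tt": meas.se_Tt,
                "se_Td": meas.se_Td,
                "n_photons": meas.n_photons,
                "seed": meas.seed,
            }
        )
    return pd.DataFrame(rows), truth


def default_stack(preset: TemperaturePreset, tissue_thickness: float = 0.3) -> LayerStack:
    """The reference sapphire/tissue/sapphire stack for a preset."""
    return sandwich(
        OpticalProperties(0.1, 10.0, 0.9, preset.model.n),
        tissue_thickness=tissue_thickness,
    )
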