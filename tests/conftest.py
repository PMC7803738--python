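import numpy as np
import pytest

from imctissue.forward import SimulationConfig, SphereGeometry, simulate_measurements
from imctissue.optics import Layer, LayerStack, OpticalProperties, sandwich


@pytest.fixture(scope="session")
def geometry() -> SphereGeometry:
    return SphereGeometry()


@pytest.fixture(scope="session")
def ear_stack() -> LayerStack:
    """Reference sapphire / tissue / sapphire stack with mid-range tissue."""
    return sandwich(OpticalProperties(0.1, 10.0, 0.9, 1.4))


def bare_slab(mu_a: float, mu_s: float, g: float, thickness: float = 0.3) -> LayerStack:
    """Single index-matched slab in air (no interfaces)."""
    return LayerStack((Layer(thickness, OpticalProperties(mu_a, mu_s, g, 1.0)),), ambient_n=1.0)


@pytest.fixture(scope="session")
def ear_measurement(ear_stack, geometry):
    return simulate_measurements(ear_stack, geometry, SimulationConfig(n_photons=100_000, seed=7))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
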