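"""Shared physical primitives for layered photon transport.

The sample modelled throughout the package is a slab stack illuminated at
normal incidence: in the reference configuration a thin piece of tissue is
sandwiched between two sapphire windows and surrounded by air.  This module
holds the optical-property containers for such stacks plus the two
single-photon primitives the transport kernel is built on:

* sampling of the scattering-angle cosine from the Henyey-Greenstein (HG)
  phase function,
* unpolarized Fresnel reflection / Snell refraction at a planar index step.

All lengths are millimetres and all attenuation coefficients mm^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import InvalidParameterError

#: Refractive index of sapphire; dispersion over 400-1650 nm is < 2% and ignored.
SAPPHIRE_N = 1.76
#: Default refractive index of soft tissue.
TISSUE_N_DEFAULT = 1.4


@dataclass(frozen=True)
class OpticalProperties:
    """Single-wavelength optical properties of a homogeneous medium.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, mm^-1.
    mu_s : float
        Scattering coefficient, mm^-1.
    g : float
        Scattering anisotropy factor (mean cosine of the HG deflection
        angle), in (-1, 1).
    n : float
        Refractive index, >= 1.
    """

    mu_a: float
    mu_s: float
    g: float
    n: float = TISSUE_N_DEFAULT

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mu_a) and self.mu_a >= 0.0):
            raise InvalidParameterError(f"mu_a must be finite and >= 0, got {self.mu_a}")
        if not (math.isfinite(self.mu_s) and self.mu_s >= 0.0):
            raise InvalidParameterError(f"mu_s must be finite and >= 0, got {self.mu_s}")
        if not (-1.0 < self.g < 1.0):
            raise InvalidParameterError(f"g must lie in (-1, 1), got {self.g}")
        if not (math.isfinite(self.n) and self.n >= 1.0):
            raise InvalidParameterError(f"n must be finite and >= 1, got {self.n}")

    @property
    def mu_t(self) -> float:
        """Total attenuation coefficient mu_a + mu_s, mm^-1."""
        return self.mu_a + self.mu_s

    @property
    def mu_s_prime(self) -> float:
        """Reduced scattering coefficient mu_s * (1 - g), mm^-1."""
        return self.mu_s * (1.0 - self.g)


@dataclass(frozen=True)
class Layer:
    """A slab of finite thickness (mm) with homogeneous optical properties."""

    thickness: float
    props: OpticalProperties

    def __post_init__(self) -> None:
        if not (math.isfinite(self.thickness) and self.thickness > 0.0):
            raise InvalidParameterError(f"layer thickness must be > 0, got {self.thickness}")


@dataclass(frozen=True)
class LayerStack:
    """Ordered slabs from top (illuminated side) to bottom, in ambient medium.

    The reference arrangement has exactly three layers
    (sapphire window / tissue / sapphire window) but any number >= 1 is
    accepted.
    """

    layers: tuple[Layer, ...]
    ambient_n: float = 1.0

    def __post_init__(self) -> None:
        if len(self.layers) < 1:
            raise InvalidParameterError("a LayerStack needs at least one layer")
        if not (math.isfinite(self.ambient_n) and self.ambient_n >= 1.0):
            raise InvalidParameterError(f"ambient_n must be >= 1, got {self.ambient_n}")
        object.__setattr__(self, "layers", tuple(self.layers))

    @property
    def total_thickness(self) -> float:
        return sum(layer.thickness for layer in self.layers)

    def boundaries(self) -> np.ndarray:
        """z coordinates of the layer interfaces, z=0 at the illuminated face."""
        return np.concatenate([[0.0], np.cumsum([la.thickness for la in self.layers])])


def window_layer(thickness: float = 1.0, n: float = SAPPHIRE_N) -> Layer:
    """A clear (non-scattering, non-absorbing) refractive window slab."""
    return Layer(thickness, OpticalProperties(0.0, 0.0, 0.0, n))


def sandwich(
    tissue: OpticalProperties,
    tissue_thickness: float = 0.3,
    window_thickness: float = 1.0,
    window_n: float = SAPPHIRE_N,
    ambient_n: float = 1.0,
) -> LayerStack:
    """Build the reference window/tissue/window stack."""
    win = window_layer(window_thickness, window_n)
    return LayerStack((win, Layer(tissue_thickness, tissue), win), ambient_n)


def with_tissue(stack: LayerStack, tissue: OpticalProperties, tissue_index: int | None = None) -> LayerStack:
    """Return a copy of ``stack`` with the tissue layer's properties replaced.

    ``tissue_index`` defaults to the middle layer, matching the
    window/tissue/window arrangement.
    """
    idx = len(stack.layers) // 2 if tissue_index is None else tissue_index
    layers = list(stack.layers)
    layers[idx] = Layer(layers[idx].thickness, tissue)
    return LayerStack(tuple(layers), stack.ambient_n)


# ---------------------------------------------------------------------------
# Henyey-Greenstein sampling
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _hg_cosine(g: float, u: float) -> float:
    # Inverse-CDF of p(cos) = (1-g^2) / (2 (1+g^2-2 g cos)^{3/2})
    if g == 0.0:
        return 2.0 * u - 1.0
    t = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    c = (1.0 + g * g - t * t) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


def sample_hg_cosine(g: float, u):
    """Map uniform deviates ``u`` in [0, 1) to HG scattering-angle cosines.

    Uses the closed-form inverse CDF of the Henyey-Greenstein density with
    mean cosine ``g``; for g = 0 this reduces to the isotropic cos = 2u - 1.
    Accepts a scalar or an array of deviates.
    """
    if not (-1.0 < g < 1.0):
        raise InvalidParameterError(f"anisotropy g must lie in (-1, 1), got {g}")
    u_arr = np.asarray(u, dtype=np.float64)
    if np.any((u_arr < 0.0) | (u_arr >= 1.0)):
        raise InvalidParameterError("uniform deviates must lie in [0, 1)")
    if g == 0.0:
        out = 2.0 * u_arr - 1.0
    else:
        t = (1.0 - g * g) / (1.0 - g + 2.0 * g * u_arr)
        out = np.clip((1.0 + g * g - t * t) / (2.0 * g), -1.0, 1.0)
    if np.isscalar(u) or u_arr.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Fresnel / Snell boundary handling
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _fresnel(n_in: float, n_out: float, cos_i: float):
    # Returns (unpolarized reflectance, cosine of the refracted angle).
    # Under total internal reflection the reflectance is exactly 1 and the
    # returned cosine is meaningless (0.0).
    if cos_i > 1.0:
        cos_i = 1.0
    if n_in == n_out:
        return 0.0, cos_i
    sin_i2 = 1.0 - cos_i * cos_i
    if sin_i2 < 0.0:
        sin_i2 = 0.0
    ratio = n_in / n_out
    sin_t2 = ratio * ratio * sin_i2
    if sin_t2 >= 1.0:
        return 1.0, 0.0
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (n_in * cos_i - n_out * cos_t) / (n_in * cos_i + n_out * cos_t)
    rp = (n_in * cos_t - n_out * cos_i) / (n_in * cos_t + n_out * cos_i)
    r = 0.5 * (rs * rs + rp * rp)
    if r > 1.0:
        r = 1.0
    return r, cos_t


def fresnel_reflectance(n_in: float, n_out: float, cos_incident: float) -> tuple[float, float]:
    """Unpolarized Fresnel reflectance at a planar index step.

    Returns ``(R, cos_t)`` where ``R`` is the reflection probability in
    [0, 1] and ``cos_t`` the cosine of the refracted angle from Snell's law.
    Under total internal reflection ``R`` is exactly 1 and ``cos_t`` is NaN.
    """
    if not (n_in >= 1.0 and n_out >= 1.0):
        raise InvalidParameterError("refractive indices must be >= 1")
    if not (0.0 <= cos_incident <= 1.0):
        raise InvalidParameterError(f"cos_incident must lie in [0, 1], got {cos_incident}")
    r, cos_t = _fresnel(n_in, n_out, cos_incident)
    if r == 1.0 and n_in > n_out:
        return 1.0, float("nan")
    return r, cos_t
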