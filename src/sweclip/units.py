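"""Conversions among Young's modulus, shear modulus, and shear-wave velocity.

Under the standard soft-tissue assumptions (incompressible, locally
isotropic, density rho), the elastic moduli and the shear-wave speed c are
linked by

    E = 3 * mu          (Young's modulus vs. shear modulus, kPa)
    mu = rho * c**2     (so  c = sqrt(1000 * E / (3 * rho))  with E in kPa)

With the default rho = 1000 kg/m^3 this reduces to ``c = sqrt(E_kPa / 3)``
in m/s. SWV is the recommended reporting unit for muscle, where the modulus
assumptions are weakest; these helpers convert the device's kPa output
accordingly. NaN inputs propagate (missing statistics stay missing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TissueConstants",
    "DEFAULT_TISSUE",
    "young_to_shear",
    "shear_to_young",
    "young_to_swv",
    "swv_to_young",
]


@dataclass(frozen=True)
class TissueConstants:
    """Tissue density in kg/m^3 (1000 is the standard soft-tissue value)."""

    rho: float = 1000.0

    def __post_init__(self):
        if not np.isfinite(self.rho) or self.rho <= 0:
            raise ValueError("density must be positive and finite")


DEFAULT_TISSUE = TissueConstants()


def _validated(x, name):
    arr = np.asarray(x, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValueError(f"{name} must be non-negative")
    return arr


def _scalar_or_array(result, template):
    return float(result) if np.isscalar(template) or np.ndim(template) == 0 else result


def young_to_shear(E):
    """Young's modulus (kPa) -> shear modulus (kPa): mu = E / 3."""
    E = _validated(E, "Young's modulus")
    return _scalar_or_array(E / 3.0, E)


def shear_to_young(mu):
    """Shear modulus (kPa) -> Young's modulus (kPa): E = 3 * mu."""
    mu = _validated(mu, "shear modulus")
    return _scalar_or_array(3.0 * mu, mu)


def young_to_swv(E, const: TissueConstants = DEFAULT_TISSUE):
    """Young's modulus (kPa) -> shear-wave velocity (m/s)."""
    E = _validated(E, "Young's modulus")
    return _scalar_or_array(np.sqrt(1000.0 * E / (3.0 * const.rho)), E)


def swv_to_young(c, const: TissueConstants = DEFAULT_TISSUE):
    """Shear-wave velocity (m/s) -> Young's modulus (kPa)."""
    c = _validated(c, "shear-wave velocity")
    return _scalar_or_array(3.0 * const.rho * np.square(c) / 1000.0, c)
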