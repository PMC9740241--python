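"""Density -> isotropic elastoplastic material mapping.

Power laws in apparent density (g/cm^3):

    E(rho)       = modulus_coeff * rho ** modulus_exponent     [MPa]
    sigma_y(rho) = yield_coeff   * rho ** yield_exponent       [MPa]

with floors E_min / sigma_min so zero-density elements keep a tiny positive
stiffness and the global stiffness matrix stays positive definite.  The
default coefficients are implementation choices in the range of published
density-property fits for human femoral bone, not values transcribed from a
specific source; they are configurable through the run config.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .meshing import TetMesh

__all__ = ["MaterialLaw", "MaterialField", "map_materials", "DEFAULT_LAW"]


@dataclass(frozen=True)
class MaterialLaw:
    modulus_coeff_mpa: float = 6950.0
    modulus_exponent: float = 1.49
    yield_coeff_mpa: float = 105.0
    yield_exponent: float = 1.93
    poisson_ratio: float = 0.3
    e_min_mpa: float = 1.0
    sigma_min_mpa: float = 0.1

    def __post_init__(self) -> None:
        if self.modulus_coeff_mpa < 0 or self.yield_coeff_mpa < 0:
            raise ValueError("coefficients must be >= 0")
        if self.modulus_exponent < 0 or self.yield_exponent < 0:
            raise ValueError("exponents must be >= 0")
        if not (self.e_min_mpa > 0 and self.sigma_min_mpa > 0):
            raise ValueError("floors must be > 0")
        if not (0 <= self.poisson_ratio < 0.5):
            raise ValueError("poisson ratio must be in [0, 0.5)")


DEFAULT_LAW = MaterialLaw()


@dataclass
class MaterialField:
    youngs_modulus_mpa: np.ndarray  # per element
    yield_stress_mpa: np.ndarray  # per element
    poisson_ratio: float

    def __post_init__(self) -> None:
        if len(self.youngs_modulus_mpa) != len(self.yield_stress_mpa):
            raise ValueError("E and sigma_y must have equal length")


def map_materials(mesh: TetMesh, law: MaterialLaw = DEFAULT_LAW) -> MaterialField:
    """Evaluate the power laws per element with floors applied."""
    rho = np.asarray(mesh.element_density_mg_cm3, dtype=float)
    if np.any(rho < 0):
        raise ValueError("element densities must be >= 0")
    rho_g = rho / 1000.0  # mg/cm^3 -> g/cm^3
    E = np.maximum(law.modulus_coeff_mpa * rho_g**law.modulus_exponent, law.e_min_mpa)
    sy = np.maximum(law.yield_coeff_mpa * rho_g**law.yield_exponent, law.sigma_min_mpa)
    return MaterialField(youngs_modulus_mpa=E, yield_stress_mpa=sy, poisson_ratio=law.poisson_ratio)
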