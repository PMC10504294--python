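"""Physical constants and fluid defaults used throughout the package (SI units)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Boltzmann constant, J/K (2019 SI exact value).
K_BOLTZMANN = 1.380649e-23

#: Default absolute temperature for the aqueous simulations, K.
DEFAULT_TEMPERATURE = 298.0

#: Density of water at room temperature, kg/m^3.
WATER_DENSITY = 1000.0

#: Dynamic viscosity of water at room temperature, Pa*s.
WATER_VISCOSITY = 1.0e-3


@dataclass(frozen=True)
class PhysicalConstants:
    """Thermal environment for Brownian forcing.

    Attributes
    ----------
    k_B : Boltzmann constant in J/K.
    temperature : absolute temperature in K; must be positive.
    """

    k_B: float = K_BOLTZMANN
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid parameters entering the momentum balance.

    Attributes
    ----------
    density : fluid density rho, kg/m^3.
    dynamic_viscosity : mu, Pa*s.
    body_force : volumetric force density F, N/m^3 (defaults to zero).
    """

    density: float = WATER_DENSITY
    dynamic_viscosity: float = WATER_VISCOSITY
    body_force: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")
        if self.dynamic_viscosity <= 0:
            raise ValueError(
                f"dynamic_viscosity must be positive, got {self.dynamic_viscosity}"
            )

    @property
    def kinematic_viscosity(self) -> float:
        return self.dynamic_viscosity / self.density

    def body_force_array(self) -> np.ndarray:
        return np.asarray(self.body_force, dtype=float)


WATER = FluidProperties()
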