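"""Physical constants and unit conversions.

Canonical internal units are Å (length), ns (time) and kcal/mol (energy).
All conversions to reporting units (cm/s for permeability, molar for
concentration) happen through the factors defined here, never inline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Boltzmann constant, kcal/mol/K.
K_B = 1.987204e-3

#: 1 Å/ns expressed in cm/s.
ANG_PER_NS_TO_CM_PER_S = 10.0

#: 1 mol/L expressed in molecules per Å³.
MOLAR_TO_PER_ANG3 = 6.022140857e-4

#: Molarity of pure water (mol/L); used to convert water counts to volume.
PURE_WATER_MOLARITY = 55.345

#: Boltzmann constant in erg/K (cgs), for the Stokes-Einstein prefactor.
K_B_CGS = 1.380649e-16

#: One dalton in grams.
DALTON_G = 1.66053906660e-24


@dataclass(frozen=True)
class ThermoConstants:
    """Temperature and derived thermodynamic factors.

    Parameters
    ----------
    T : float
        Absolute temperature in K. Must be positive.
    """

    T: float = 298.0
    k_B: float = field(default=K_B, init=False)

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"temperature must be positive, got {self.T}")

    @property
    def kBT(self) -> float:
        """Thermal energy k_B*T in kcal/mol."""
        return self.k_B * self.T

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/(k_B*T) in mol/kcal."""
        return 1.0 / self.kBT
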