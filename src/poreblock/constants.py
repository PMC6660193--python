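"""Physical constants and the unit conventions used package-wide.

Conventions (fixed across all modules):

* voltage in mV, depolarization positive;
* time in seconds for wash-in/wash-out time courses, milliseconds for
  voltage-step traces (converted at module boundaries);
* toxin concentration in uM inside rate equations, dissociation constants
  reported in nM (``K_D [nM] = 1000 * k_off [s^-1] / k_on [uM^-1 s^-1]``);
* external K+ concentration in mM;
* energies in kJ/mol, with kT-unit conversion through RT.

An effective valence ``z`` multiplying ``F*V/(R*T)`` is positive when the
rate (or equilibrium constant) grows with depolarization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """Faraday constant, gas constant and absolute temperature.

    Defaults give RT/F = 25.693 mV and RT = 2.479 kJ/mol at 298.15 K.
    The recording temperature is the only knob users normally touch.
    """

    faraday: float = 96485.33212331  # C mol^-1
    gas_constant: float = 8.31446261815324  # J mol^-1 K^-1
    temperature: float = 298.15  # K

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if self.faraday <= 0 or self.gas_constant <= 0:
            raise ValueError("faraday and gas_constant must be positive")

    @property
    def thermal_voltage_mv(self) -> float:
        """RT/F in millivolts (~25.693 mV at 298.15 K)."""
        return 1e3 * self.gas_constant * self.temperature / self.faraday

    @property
    def rt_kj_per_mol(self) -> float:
        """RT in kJ/mol (~2.479 kJ/mol at 298.15 K); 1 kT unit == RT per mole."""
        return self.gas_constant * self.temperature / 1e3

    def boltzmann_factor(self, z: float, v_mv: float) -> float:
        """exp(z*F*V/RT) for an effective valence ``z`` and voltage in mV."""
        return math.exp(z * v_mv / self.thermal_voltage_mv)


DEFAULT_CONSTANTS = PhysicalConstants()
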