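"""Physical constants and unit conventions.

The package works throughout in the MD-native unit system:
energies in kcal/mol, lengths in Å, times in ps (trajectory time
stamps in ns), masses in amu, temperatures in K.
"""

#: Boltzmann constant in kcal/mol/K (7 significant digits).
KB_KCAL_PER_MOL_K: float = 1.987204e-3

#: Conversion of (kcal/mol/Å)/amu to acceleration in Å/ps².
#: 1 kcal/mol = 4184 J/mol; amu = 1e-3 kg/mol; Å = 1e-10 m; ps = 1e-12 s.
KCAL_PER_MOL_ACCEL: float = 418.4

#: Default simulation temperature (K) of the CPR study conditions.
DEFAULT_TEMPERATURE: float = 310.0


def kbt(temperature: float) -> float:
    """Thermal energy k_B·T in kcal/mol (≈ 0.6160332 at 310 K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL_PER_MOL_K * temperature
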