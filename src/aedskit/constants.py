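"""Physical constants and unit conventions.

Units throughout the package: energies in kJ/mol, lengths in nm,
times in ps, temperatures in K.
"""

#: Molar gas constant in kJ mol^-1 K^-1.
GAS_CONSTANT: float = 0.0083145

#: Default simulation temperature (K).
DEFAULT_TEMPERATURE: float = 300.0


def rt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy R*T in kJ/mol at the given temperature."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return GAS_CONSTANT * temperature
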