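"""Physical constants and campaign-wide defaults.

Energies are kJ/mol, distances nm, angles radians (degrees only at I/O
boundaries), temperatures K, times ps.
"""

#: Boltzmann constant in kJ mol^-1 K^-1 (fixed so printed thermal energies reproduce).
KB = 0.0083144621

#: Default simulation temperature (K) for the membrane system.
DEFAULT_TEMPERATURE = 310.0


def kt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B*T in kJ/mol (2.58 kJ/mol at 310 K)."""
    return KB * temperature
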