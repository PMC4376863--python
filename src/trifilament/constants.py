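"""Physical constants and unit conventions.

Units used throughout the package: nanometres (nm), piconewtons (pN),
seconds (s), kelvin (K).  Stress is reported in nN/um^2 (numerically equal
to kPa).  Sarcomere lengths at the protocol level are in micrometres (um);
half-sarcomere lengths at the chain level are in nm.
"""

#: Boltzmann constant in pN nm / K.
KB = 1.380649e-2

#: Default absolute temperature (room-temperature myofibril experiments).
DEFAULT_TEMPERATURE = 293.15


def kbt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B * T in pN nm."""
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0 K, got {temperature}")
    return KB * temperature
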