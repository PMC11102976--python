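"""Physical constants (SI units)."""

FARADAY = 96485.3329
"""Faraday constant, C/mol (A·s/mol)."""

GAS_CONSTANT = 8.3144598
"""Universal gas constant, J/(mol·K)."""

LITRE_PER_CUBIC_MICRON = 1e-15
"""Volume conversion: 1 µm³ = 1e-15 L."""
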