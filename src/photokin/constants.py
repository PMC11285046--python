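"""Physical constants (CODATA 2018 exact values) used throughout the package."""

PLANCK_H = 6.62607015e-34
"""Planck constant, J s."""

SPEED_OF_LIGHT = 2.99792458e8
"""Speed of light in vacuum, m s^-1."""

AVOGADRO = 6.02214076e23
"""Avogadro constant, mol^-1."""

NM_TO_M = 1e-9
"""Metres per nanometre."""


def photon_energy(wavelength_nm: float) -> float:
    """Energy of one photon at the given vacuum wavelength, in joules."""
    if wavelength_nm <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength_nm} nm")
    return PLANCK_H * SPEED_OF_LIGHT / (wavelength_nm * NM_TO_M)
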