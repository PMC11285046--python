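"""Two-component decomposition of a photostationary-state spectrum.

At the PSS the sample is an unknown mixture of the two isomers; given both
pure absorbance spectra, the mole fraction follows from one-parameter linear
least squares on Abs_obs = c * Abs_A + (1 - c) * Abs_B.
"""

import numpy as np

from photokin import Spectrum, decompose_mixture
from photokin.synthetic import make_toy_switch

system = make_toy_switch()
c_tot = 4e-5  # M

# pure-isomer absorbance spectra at the sample concentration (1 cm path)
abs_A = Spectrum(system.eps_A.wavelengths, system.eps_A.values * c_tot)
abs_B = Spectrum(system.eps_B.wavelengths, system.eps_B.values * c_tot)

# a synthetic PSS spectrum: 4% stable isomer, 96% metastable, plus noise
rng = np.random.default_rng(0)
mix = 0.04 * abs_A.values + 0.96 * abs_B.values
observed = Spectrum(abs_A.wavelengths, mix + rng.normal(0, 0.002, mix.size))

c, resid = decompose_mixture(observed, abs_A, abs_B, fit_range=(280.0, 500.0))
print(f"recovered stable-isomer mole fraction: {c:.4f} (truth 0.0400)")
print(f"residual norm: {resid:.4f}")
print("-> with reliable pure spectra the PSS composition follows directly from")
print("   the spectrum, without NMR or chromatographic separation.")
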