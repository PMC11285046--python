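"""Determine quantum yields from a noisy absorbance time series.

Generates a synthetic in-operando record with known ground truth
(Phi = 0.16 / 0.38), fits the yield pair by Levenberg-Marquardt least
squares and propagates a 2% power uncertainty into the final error bars.
"""

from photokin import PowerResult, determine_quantum_yields
from photokin.synthetic import default_experiment

exp = default_experiment(noise_sd=0.002, seed=1)
power = PowerResult(mean_power=1.0e-3, std_power=0.02e-3, n_samples=100)

res = determine_quantum_yields(
    exp.series.times,
    exp.series.at_wavelength(340.0),
    exp.system,
    exp.source,
    exp.geometry,
    exp.initial_state,
    power=power,
)

print(f"true yields:    {exp.true_phis.phi_AB:.3f} / {exp.true_phis.phi_BA:.3f}")
print(f"fitted forward: {res.phi_AB:.4f}  (fit SE {res.se_AB:.4f}, "
      f"total +/- {res.delta_phi_AB:.4f})")
print(f"fitted backward: {res.phi_BA:.4f}  (fit SE {res.se_BA:.4f}, "
      f"total +/- {res.delta_phi_BA:.4f})")
print(f"RSS = {res.rss:.3g} over {res.n_points} points")
print("-> the total uncertainty is dominated by the power term: it comes from")
print("   refitting at the power limits P -/+ dP, not from the fit covariance.")
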