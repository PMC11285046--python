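# Methods

## The model

`photokin` treats a molecular photoswitch as a two-state system: a stable
isomer A (for azobenzene, *trans*) and a metastable isomer B (*cis*).  Under
irradiation with photon flux q₀ (photons s⁻¹) the two interconvert
photochemically with quantum yields Φ_A→B and Φ_B→A, while B relaxes
thermally to A with first-order rate constant k_B→A.

With Abs_tot = ([A]ε_A(λ) + [B]ε_B(λ))·l the decadic absorbance along the
irradiation path l (cm), the monochromatic rate equation is

    d[A]/dt = (q₀ / (N_A·V)) · (1 − 10^(−Abs_tot))/Abs_tot
              · (Φ_B→A·[B]ε_B·l − Φ_A→B·[A]ε_A·l)  +  k_B→A·[B]
    d[B]/dt = −d[A]/dt

The factor (1 − 10^(−Abs_tot)) is the fraction of incident photons absorbed
by the solution; each species captures photons in proportion to its share
Abs_X/Abs_tot of the total absorbance, so the expression is exactly the
composition of "photons absorbed per species" with the yield balance.  Note
the path length appears in *both* the exponent and the denominator: only
then is the expression the exact photon bookkeeping for any l (the two
readings coincide at l = 1 cm, the usual cuvette).  As Abs_tot → 0 the
factor (1 − 10^(−x))/x tends to ln 10; the implementation switches to a
three-term series below x = 10⁻⁶, which is seamless to machine precision.

For an LED with non-negligible bandwidth the photochemical term is averaged
over the source's photon-normalised spectral distribution f(λ) (trapezoid
quadrature on the emission grid restricted to where both ε spectra are
defined).  The thermal term is included in the polychromatic rate as well,
for consistency with the monochromatic form; `include_thermal=False` gives
the purely photochemical variant.

Total concentration is conserved *exactly*: the integrator propagates [A]
alone and reconstructs [B] = c_tot − [A].  Integration uses SciPy's
stiff-capable LSODA with rtol 10⁻⁸ and atol 10⁻¹² M by default.

Assumptions inherited from the experimental design: the sample is
well-stirred (spatially uniform concentrations, no inner-filter gradient),
quantum yields are wavelength-independent within one fit (wavelength
dependence is characterised by separate fits per LED), there is no
photodegradation channel, and probing is perpendicular to irradiation, so
the absorbance that drives the photochemistry uses `path_irradiation` while
reported model absorbance uses `path_probe` (both default to 1 cm).

## Photon flux from thermopile power

The radiant power is measured directly with a calibrated thermopile rather
than by actinometry:

1. **Baseline.** A polynomial (degree 0–3, default 1) is fitted to the
   LED-off samples — before switch-on and, when recorded, after switch-off —
   and subtracted from the whole trace.  A degree-d baseline annihilates any
   degree-≤d drift exactly.
2. **Averaging.** Mean and sample standard deviation of the on-segment after
   discarding the first `settle_time` (default 5 s) to skip the thermopile's
   thermal rise.  The reported uncertainty is the on-segment sample standard
   deviation (not the standard error of the mean): it is meant to represent
   the "lower and upper power limits" the detector actually records.
3. **Transmission loss.** Powers are measured bare and through the cuvette
   assembly; the loss at the sample is taken as a configurable fraction
   (default ½) of the total loss: P_sample = (1−f)·P_bare + f·P_through,
   uncertainties combined in quadrature with the same weights.
4. **Pooling.** Repeated determinations are combined by inverse-variance
   weighting, w_i = 1/σ_i², with combined uncertainty √(1/Σw).
5. **Conversion.** Monochromatic: q₀ = P·λ/(hc).  Polychromatic: the
   measured relative emission g(λ) is treated as power-basis (CCD
   spectrometers calibrated in irradiance report power density), converted
   per-wavelength to a photon-rate density φ(λ) ∝ g(λ)·λ and scaled so that
   ∫φ·(hc/λ)dλ equals the measured power; then q₀ = ∫φ dλ and f = φ/q₀.
   Users whose spectra are already photon counts can set
   `emission_in_photon_basis=True`.

Physical constants are the CODATA exact values (h = 6.62607015×10⁻³⁴ J s,
c = 2.99792458×10⁸ m s⁻¹, N_A = 6.02214076×10²³ mol⁻¹), kept in one module.

## The fit and its uncertainty budget

(Φ_A→B, Φ_B→A) are estimated by minimising the residual sum of squares
between the measured absorbance and the modelled absorbance, by
Levenberg–Marquardt as implemented in lmfit, with the yields bounded to
[0, 1] and initialised at (0.3, 0.3).  By default the fit uses the
absorbance at the irradiation wavelength — the most conversion-sensitive
single probe — and residuals are unweighted in absorbance; per-point σ
weighting and joint multi-wavelength fitting are available.  Standard errors
come from the linearised covariance (JᵀJ)⁻¹·s² at the optimum.  The initial
composition defaults to 100% A (a relaxed sample), with the total
concentration either supplied or read off the first spectrum; a free initial
fraction is available for partially converted samples.

The fit standard errors do not see the dominant experimental error, the LED
power.  It is propagated by refitting with the photon flux rebuilt from
P − ΔP and P + ΔP (ΔP = `bound_multiple` × the power uncertainty, default
multiple 1).  Because the yields scale roughly inversely with the assumed
flux, the low-power refit gives the *upper* yield values; the implementation
therefore takes the per-yield minimum and maximum over the two refits,
widens each by that refit's own fit standard error, and reports

    ΔΦ = max(|Φ − Φ_min|, |Φ − Φ_max|)

per yield.  This guarantees Φ_min ≤ Φ ≤ Φ_max.  With ΔP = 0 and noiseless
data the bounds collapse onto the central fit.

Replicates are pooled with inverse-variance weights w_i = 1/ΔΦ_i² and
reported with the weighted sample standard deviation
√(Σwᵢ(Φᵢ−Φ̄)² / (((n−1)/n)·Σwᵢ)); both that spread and the per-replicate ΔΦ
are kept, since they answer different questions (between-run scatter versus
single-run error).

An identifiability guard refuses to fit dark data (q₀ = 0) and attaches a
warning when one species does not absorb the excitation light, since the
corresponding yield is then unconstrained.

## Duty-cycled irradiation clock

In-operando acquisition alternates LED-on periods with brief probe
measurements during which the LED is off.  The rate equations assume
continuous illumination, so time series are interpreted on the cumulative
LED-on clock: `effective_irradiation_times` subtracts the per-cycle
acquisition dead time (i-th spectrum: t_i − i·dead_time).  The correction is
on by default in the CLI (`--no-duty-cycle-correction` disables it) and is
the identity when no dead time is configured.

## Mixture decomposition

A photostationary-state spectrum is decomposed as
Abs_obs = c·Abs_A + (1−c)·Abs_B, with c the mole fraction of A and both pure
spectra taken at the sample's total concentration — the only reading that is
dimensionally and stoichiometrically consistent.  The one-parameter linear
least-squares problem is solved in closed form (exact and unconditionally
stable; no iteration), c is clipped to [0, 1], and near-identical pure
spectra raise a degeneracy error.  The fit range is a required user
parameter: the informative window depends on the switch, so no default is
imposed.  Interpolation everywhere is linear with no smoothing —
assumption-free and exactly invertible on grid nodes; wavelength grids from
different instruments are reconciled by intersecting ranges and
interpolating.

## What the synthetic generator emulates

The generator reproduces the reference experiment's conditions so that every
pipeline stage is testable without instruments:

| quantity | default | rationale |
| --- | --- | --- |
| ε spectra | Gaussian bands; stable isomer: 22 000 M⁻¹cm⁻¹ at 320 nm (σ 30 nm) + 450 at 440 nm; metastable: 8 000 at 240, 5 000 at 280, 1 250 at 440 nm | azobenzene-like band structure and ordering |
| k_B→A | 7.2×10⁻⁷ s⁻¹ | thermal *cis*→*trans* rate at 20 °C |
| true Φ | (0.16, 0.38) | forward/backward yields at 340 nm |
| geometry | 3.00 mL, 1 cm × 1 cm, 20 °C | standard cuvette experiment |
| source | 1 mW at 340 nm → q₀ ≈ 1.71×10¹⁵ s⁻¹ | fibre-coupled LED scale |
| schedule | 1 h, one spectrum per 30 s (121 points) | in-operando protocol |
| start | 100% A at c₀ ≈ 4.1×10⁻⁵ M (Abs₃₂₀ ≈ 0.9) | π→π* absorbance in the 0.8–1.0 window |
| absorbance noise | σ = 0.002, homoscedastic Gaussian | typical CCD spectrometer scatter; a shot-noise-like heteroscedastic option exists but is off by default |
| power log | polynomial drift + step + Gaussian noise (2% of the power where a noisy condition is wanted) | thermopile behaviour under ambient drift |

Under these conditions the toy switch reaches a ≈96% metastable
photostationary state at 340 nm, consistent with the behaviour the band
ordering implies.

What the generator does *not* emulate: dark current and stray light,
wavelength-dependent detector noise, LED output drift during irradiation,
and photodegradation.  Passing tests therefore demonstrate the correctness
of the estimator and of the uncertainty protocol under the stated noise
model, not robustness to instrument systematics.

## Numerical choices and problem sizes

- ODE tolerances rtol 10⁻⁸ / atol 10⁻¹² M; analytic series for the
  absorbed-fraction factor below Abs_tot = 10⁻⁶.
- Photostationary state by bracketed root finding (Brent) on the metastable
  fraction in [0, 1], xtol 10⁻¹⁴; degenerate all-A/all-B cases handled
  before bracketing.  With k_B→A > 0 the stationary point depends on the
  total concentration, which is therefore a parameter (default 10⁻⁵ M).
- Emission profiles are truncated below 10⁻⁴ of peak intensity and
  photon-normalised to unit trapezoid integral (tolerance 10⁻⁹).
- The validation suite runs the stochastic-coverage study at 200 seeded
  repetitions (three fits each) and the replicate-averaging Monte Carlo at
  1 000 draws; the noise-averaging check uses 10⁴ replicates of a single
  time point.  These sizes give comfortable margins on the binomial /
  law-of-large-numbers bounds they assert.

## Known limitations

- Two states only; no sequential or parallel multi-photoproduct schemes.
- Quantum yields are treated as wavelength-independent within a single fit.
- ε spectra and k_B→A are fixed inputs, never co-fitted; errors in them
  propagate unexamined into Φ.
- The power-basis assumption for emission spectra is a convention, not a
  measurement; it matters only for broad LEDs.
- The transmission-loss split between the two cuvette faces is a geometric
  approximation controlled by `loss_fraction_at_sample`.
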