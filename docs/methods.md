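# Methods

## Physical model

All analyses concern the longitudinal magnetization of a spin-1/2
ensemble under two competing processes: relaxation toward an equilibrium
level with a single time constant T (a true thermal T₁, a DNP build-up
constant T^DNP, or a liquid-state T₁ after dissolution), and consumption
by RF sampling, where each excitation of flip angle α leaves a fraction
cos α of the longitudinal component and yields a recorded signal
proportional to sin α.

Between pulses,

    dM/dt = (M_eq − M) / T,

and with pulses applied at an average rate N = NX/TR the *observed*
mono-exponential rate of any recorded series is

    1/T_obs = 1/T − N·ln cos α            (ln cos α ≤ 0).

Inverting this relation gives the corrections applied after fitting:

    T     = T_obs / (1 + N·T_obs·ln cos α)
    S_inf = S_inf_obs · (1 − N·T·ln cos α)

These hold identically for recoveries (equilibrium M_eq > 0, fitted as
S_inf_obs·(1 − e^(−t/T_obs))) and decays (M_eq = 0, fitted as
S0·e^(−t/T_obs)). In the relaxation-free limit (hyperpolarized solid,
train of pulses over seconds) the observed decay reduces to a geometric
series with τ = −1/(N·ln cos α), which is the basis of the flip-angle
calibration α = arccos(e^(−1/(τN))).

The corrections assume the continuous-rate limit — pulses frequent and
weak relative to T. The discrete-pulse simulator (below) quantifies the
approximation: over α ∈ [0.3°, 5°] and N·T ∈ [5, 500] the corrected
constants agree with the discrete truth to better than 0.5%, which is the
tolerance the test suite enforces. The denominator of the T-correction
must stay positive; when sampling is too aggressive
(N·T_obs·|ln cos α| ≥ 1) the correction is undefined and the package
raises an error naming the offending product rather than returning a
negative time constant.

### Validity guard for the flip-angle calibration

The arccos formula assumes the polarization does not relax appreciably
during the train. If a caller supplies the sample's T₁ and the fitted
τ exceeds T₁/10, a warning is emitted that the recovered angle is biased
low. Angles are degrees at every interface and radians internally.

## Thermal polarization and field calibration

Thermal equilibrium polarization of a spin-1/2 nucleus is
P^TP = tanh(ħγB₀/2k_BT), computed with CODATA constants and the magnitude
of the gyromagnetic ratio (negative-γ nuclei such as ¹⁵N are stored
signed but always enter formulas as |γ|, so polarizations and frequencies
are positive). Polarization is a dimensionless fraction everywhere
internally; ppm and % conversions happen only at reporting boundaries.

The field is calibrated from a reference resonance — in practice the
⁶³Cu signal of the NMR coil itself — as B₀ = ν/(γ/2π), using the
effective coil constant 11.319 MHz/T. The registry ships ¹H, ¹³C, ¹⁵N,
⁶³Cu and an effective electron entry (28.034 GHz/T, derived from the
observed electron frequency at the calibrated field; stored as a
configurable constant, not asserted as the free-electron value) and is
extensible from config.

## Enhancement conventions

The enhancement formula normalizes by the scan-count ratio NS^TP/NS^HP.
Whether a spectrometer stores the *sum* or the *average* of NS scans is
vendor-dependent, and the two conventions differ by exactly that ratio.
The `ns_convention` flag (`summed`, the default, applies the ratio;
`averaged` drops it) makes the choice explicit. The default reproduces
the as-printed arithmetic of the reference worked examples; users whose
spectra are scan-averaged should select `averaged`, otherwise the
polarization is off by exactly NS^TP/NS^HP. Back-extrapolated P(0) values
are labelled estimates throughout: the sample traverses varying, mostly
much lower fields during transfer, so using the measurement-field T₁ is
a deliberate, stated simplification.

## Fitting choices

* Models: two free parameters each — (S0, τ) for decays, (S_inf, T) for
  recoveries with zero signal assumed at t = 0 (magnetization is
  saturated with a pulse train before monitoring). No baseline offset by
  default.
* Initialization is deterministic and seed-free: amplitude from the
  first/largest sample, rate from an ordinary least-squares line through
  the log of the (positive) samples, then nonlinear refinement
  (lmfit/least-squares). Unweighted residuals.
* Degenerate inputs (constant series, wrong-model trends, unresolvable
  time constants where the data never bend over) raise a `FitFailure`
  carrying diagnostics; fits never silently succeed.
* Leading low-SNR points of a recovery can be excluded with
  `skip_first=k` (the solid-state thermal-recovery protocol discards the
  first six points).
* The time origin is the first excitation after saturation (or after
  microwave-on); input CSV series must be on that clock.

## The synthetic-data generator

`synthetic_data` is a forward simulator, not a fixture: it realizes the
discrete-pulse process exactly (piecewise-exponential relaxation between
pulses spaced TX apart at the start of each TR block; instantaneous
cos α losses; one recorded FID per block, the first by default — the
recorded/unrecorded distinction matters because all NX excitations
consume polarization while only one is stored; the choice of first vs
last recorded pulse is configurable and numerically negligible at
TX ≪ T). Noise is additive Gaussian on the recorded integrals — the
pipeline consumes integrals only, so no FID-level noise model is needed —
and every stochastic output requires an explicit seed; equal seeds give
bit-identical outputs.

Default generator conditions mirror the standard ¹³C-pyruvate protocol:
pulse-train calibration at NX = 49, TR = 1 s, TX = 217 µs; build-up
sampling at ~0.7° every minute; liquid-state decay sampling at 5° every
3 s; five-run reproducibility tables with the protocol's observed means
(T^DNP ≈ 1032 s, t_trans ≈ 19 s, P ≈ 38%, T₁ ≈ 92 s, 58.9 mM) and
inter-run coefficients of variation (2.1%–15%). Inter-run variability is
log-normal so that positive quantities stay positive. No noise level for
single-spectrum integrals is part of the protocol; the signal-to-noise
ratio of simulated measurements is a free parameter (the end-to-end
tests use noiseless and SNR-50 conditions).

What the simulator does *not* emulate: the microscopic DNP mechanism
(solid effect / cross effect lineshapes), spectrometer raw data,
field-profile-resolved relaxation during transfer, and systematic
baseline/phase errors of real spectra. Passing tests therefore certify
the *analysis* — fitting, corrections, normalization conventions,
statistics — against a known ground truth, not the physics of
polarization transfer itself.

Lorentzian spectra are provided to exercise integration-window
conventions (e.g. ±1 ppm windows at 9.4 T, ±2 ppm at 1 T): the numerical
integral over a ±HWHM window recovers 50% of the line area, and ≥98%
once the window exceeds ~10 FWHM.

## Sweep analysis

Operating-point selectors return members of the measured grid (no
interpolation, no smoothing by default; an optional odd-window moving
average is available for noisy sweeps). The frequency sweep has a
positive and a negative lobe; the recommended operating point is the
positive-lobe maximum. Power and position use a threshold rule — the
smallest power, or the lowest (coldest) position, whose response reaches
a stated fraction of the maximum, 0.9 by default. The fraction is a
parameter because the choice of where on a slowly declining plateau to
operate is a judgment call (lower power heats the sample less); ties
break toward the lower setting for the same reason.

## Statistics

Multi-run summaries use the sample standard deviation (n−1 denominator)
and c_v = SD/mean·100%, which reproduces the reference five-run table's
printed spreads (e.g. build-up constant 1032 ± 21.7 s, c_v 2.1%). With a
single run SD and c_v are reported as unavailable rather than zero.

## Problem sizes

The test suite and acceptance script run on the protocol's native scales
throughout — ten-second pulse trains (490 excitations), 24 h recoveries
at 256 excitations/hour, 60-point decay series, 100-seed noise ensembles
— since the discrete-pulse simulation of a full experiment takes
milliseconds; nothing is scaled down.

## Known limitations

* Only spin-1/2; no Brillouin function for higher spins, no electron
  polarization model.
* Mono-exponential models only; bi-exponential or stretched dynamics and
  spectral-diffusion build-up models are out of scope.
* The solid-state thermal-recovery correction is reported as the formula
  yields it; with very long T_obs (hours) and slow sampling the
  continuous-rate assumption is at its weakest, and independently
  published values for that experiment differ from the formula's output
  by more than the formula's own uncertainty.
* P(0) back-extrapolation ignores the transfer field profile by design.
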