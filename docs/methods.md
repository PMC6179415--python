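# Methods

## Scope

`myofluor` implements the analysis chain for time-resolved
autofluorescence and diffuse-reflectance monitoring of an isolated
perfused (Langendorff) heart subjected to a three-phase perfusion
protocol: baseline with oxygenated buffer (0–180 s), an insult phase
(180–630 s; deoxygenated buffer, glucose-free buffer, or oxygenated
buffer for controls) and reperfusion (630–1530 s), sampled every 5 s.
Because no measured dataset is distributed with the package, a
synthetic-data generator produces all raw inputs with known ground
truth; every estimator is validated against that truth.

## TCSPC decay model

Photon-arrival histograms (default 1024 bins spanning the 50 ns
repetition period of a 20 MHz pulsed laser) are modelled as a
bi-exponential decay

I(t) = a1·exp(−t/τ1) + a2·exp(−t/τ2),

with amplitudes a1, a2 (counts at t = 0) and lifetimes τ1 ≤ τ2 (ns).
Derived metrics are the intensity-weighted mean lifetime

τ_mean = (a1·τ1² + a2·τ2²) / (a1·τ1 + a2·τ2)

and the fast-component amplitude fraction α1 = a1/(a1+a2). τ_mean is
bounded by the component lifetimes, increases with τ2 and decreases
with a1; these invariants are property-tested.

**Incomplete decay.** At a 50 ns period a 3.5 ns component has not fully
decayed between pulses, so fluorescence from preceding pulses wraps into
the measured window. Summing the pulse train in closed form multiplies
each component by 1/(1 − e^(−T/τ)) and makes the model periodic; the
model is then *circularly* convolved with the IRF over the period (FFT,
O(n log n)). This is exact, unlike truncated multi-pulse summation, and
is verified against brute-force summation over 200 pulses to < 1e−9
relative error. An exact single-bin (delta) IRF bypasses the FFT so
that noiseless tail bins carry no round-off.

**Background and afterpulsing.** A constant per-bin background models
dark counts and stray light. Detector afterpulsing is modelled as a
uniform additive component with amplitude p × (total modeled
fluorescence counts)/n_bins — the standard TCSPC treatment of the
count-correlated uniform floor. Both default to fixed calibration
values (0) and can be fitted on request (`fit_background`,
`fit_afterpulse`).

## Fitting

The fit minimises the Neyman chi-square
χ² = Σ_k (I(t_k) − I_model(t_k))² / max(I(t_k), 1);
the per-bin variance is estimated by the observed count, and the
max(·, 1) clamp keeps zero-count bins finite while preserving the
weighting elsewhere (excluding zero bins entirely is available as
`zero_policy="exclude"`; a sensitivity test covers both).

The amplitudes (and the background, if fitted) enter the model
linearly, so they are profiled out by non-negative least squares
(`scipy.optimize.nnls`) at every evaluation of the nonlinear
parameters — variable projection. The outer problem over (τ1, τ2)
(plus the afterpulse probability when fitted) is solved with bounded
trust-region least squares (`scipy.optimize.least_squares`, bounds
τ ∈ [0.01, 20] ns, tight tolerances 1e−12) from a fixed four-point
multi-start grid (τ1, τ2) ∈ {0.3, 0.8} × {2.5, 4.0} ns. The multi-start
grid removes sensitivity to local minima without introducing any
randomness: identical inputs give bit-identical fits. After
optimisation the components are reordered to the canonical τ1 ≤ τ2
(ties broken by larger amplitude first). Fits below a configurable
photon minimum (default 1000 counts) are refused outright rather than
returned with meaningless uncertainty; non-converged optimizer states
are flagged, never silently accepted.

No IRF temporal-shift (color shift) parameter is fitted by default; the
simulated IRF lives on the same grid as the histograms, so a shift
parameter is unidentifiable from synthetic data. The fitted range is
the full period.

Noiseless model histograms are inverted to their generating parameters
within 1e−4 relative error across a sweep of ≥ 100 parameter sets, and
the optimizer's χ² minimum is checked against an exhaustive 20³ lattice
over (τ1, τ2, α1) on a small histogram.

## IRF recovery from reference dyes

Each channel's IRF is recovered from the measured decay M(t) of a
reference fluorophore with a known short mono-exponential lifetime
τ_ref ≈ 0.2 ns (DAPI-like for UV excitation, erythrosin-B-like for blue
excitation). Because M = IRF ⊛ exp(−t/τ_ref), the deconvolution has the
closed form F(t) = M(t) + τ_ref·dM/dt. Two discretisations are
provided:

- `method="central"` (default): periodic central differences, the
  direct transcription of the closed form. Recovers a 0.25 ns-FWHM
  Gaussian IRF from a noiseless 10⁶-count measurement with normalized
  RMSE ≈ 0.9% (< 2%).
- `method="discrete"`: the sampled exponential kernel is geometric, so
  F_k ∝ M_k − e^(−Δt/τ_ref)·M_{k−1} deconvolves it *exactly*. The
  central-difference variant carries an O(Δt²) bias near the IRF peak
  that, while small (< 1% of peak), exceeds Poisson error bands at 10⁶
  counts; the discrete variant is used wherever machine-accurate
  round-trip reconvolution is asserted.

Negative excursions (noise amplified by the derivative) are clamped to
zero and the result renormalized; an optional Savitzky-Golay window
(default 5 bins, order 2) smooths M first, which measurably reduces
reconstruction error on shot-noise-limited references.

## Reflectance metrics

Tissue absorbance is A(λ) = −log10(I(λ)/I0(λ)) with I the tissue
spectrum and I0 the white-reference spectrum (interpolated to the
sample grid; zero-intensity bins are masked with a warning). The
sign-flipped variant (`sign_convention="as_printed"`) is provided; the
default is chosen so absorber bands appear as *maxima*, which is the
internally consistent reading of the oxy-myoglobin double peak at
~544/578 nm. Two ratio metrics, evaluated at exact wavelengths by
linear interpolation:

- **Oxygenation**: A(578)/A(600). 578 and 600 nm are where the
  oxy-minus-deoxy difference spectrum is largest in the visible band;
  `difference_spectrum` locates such extrema by prominence-thresholded
  peak finding.
- **Cytochrome c state**: A(502)/A(550). Reduced cytochrome c absorbs
  at 550 nm; 502 nm is insensitive to oxygenation and anchors the
  ratio. The ratio falls as cytochrome c becomes reduced.

Both ratios are scale-invariant in absorbance, hence insensitive to
overall attenuation. No spectral smoothing is applied before ratio
extraction by default.

## Protocol time courses

Per-channel intensities (total histogram counts per acquisition) are
normalized to the mean of the first 60 s of baseline. The optical redox
ratio RR = I_CH2/(I_CH2 + I_CH3) is computed from the
baseline-normalized intensities by default (raw intensities optional);
it is invariant to common rescaling of the two channels. Phases are
labelled with half-open intervals [0, 180), [180, 630), [630, end].
Group curves are across-heart means with sample SD (n−1), aligned by
nearest-time matching within 2.5 s; missing acquisitions simply reduce
n at that time point — gaps are never interpolated.

Transition kinetics are summarised by the 10–90% transition time within
a phase window: the initial level is the first sample of the window,
the plateau is the median of the final 20% of the window (robust to
drift), and the 10%/90% crossings of the excursion are located by
linear interpolation. A saturating exponential of constant τ yields
τ·ln 9 by construction, which the tests verify. Flat or non-monotone
windows raise an explicit no-transition error.

## Synthetic data generator

The generator emulates the study conditions, not any measured record:

- **Decay regimes.** Channel baselines use the control averages of the
  instrument's channels: CH2 (NAD(P)H) α1 = 0.87, τ1 = 0.82 ns,
  τ2 = 3.47 ns; CH3 α1 = 0.88, τ1 = 0.77, τ2 = 3.08; CH4 (FAD)
  α1 = 0.89, τ1 = 0.83, τ2 = 3.05. CH1 (collagen band, low signal) is
  set to a mean lifetime near 1.7 ns with a reduced photon budget.
- **Photon budget.** 10⁶ expected counts per 1 s acquisition in CH2
  (typical of TCSPC at 20 MHz with tens-of-µW excitation), scaled
  0.3–0.8× for the dimmer channels; per-bin counts are independent
  Poisson draws from the periodic reconvolution model. `counts_scale`
  reduces every budget for quick runs.
- **IRF.** Gaussian, default FWHM 0.25 ns — the scale of the laser
  pulse width plus detector transit-time spread.
- **Trajectories.** Each parameter follows a delayed saturating
  exponential: flat at baseline, relaxing to an insult plateau after
  the 180 s switch plus a 120 s solution-transport delay, and back
  after the 630 s switch plus delay. Hypoxia defaults: CH2 intensity
  ×1.35 and CH4 ×0.75 at plateau, CH2/CH3 τ1 down and α1 up with τ2 up,
  CH4 α1 down (mean lifetime up); insult time constant 45 s and
  reperfusion 120 s, so recovery is slower than onset. Glucose
  depletion: slow CH2/CH3 intensity decline (τ = 300 s, longer than the
  insult phase, hence no plateau within it), flat CH4, mild CH3
  lifetime changes. Controls are flat. The plateaus and time constants
  encode only the qualitative orderings of the modelled physiology;
  they are configurable and not asserted as quantitative truth.
- **Reflectance.** Gaussian chromophore templates (oxy-myoglobin
  544/578 nm, deoxy-myoglobin 560 nm, reduced cytochrome c 550 nm) over
  a flat pseudo-isosbestic floor of 0.2 absorbance, mixed by an
  oxygenated fraction (1 → 0.05 during hypoxia) and a reduced-
  cytochrome fraction (0 → 0.9); the white reference is a smooth
  lamp-like curve and the sample is the reference attenuated by
  10^(−A) with 0.5% multiplicative noise.
- **Variability.** Per-heart offsets drawn once per heart: log-normal
  intensity factor (5% SD), additive lifetime offset (0.02 ns SD) and
  α1 offset (0.01 SD); 1% multiplicative acquisition-to-acquisition
  intensity jitter on top of shot noise.
- **Seeding.** Counter-based: every (heart, time point, channel) draw
  derives its generator from `SeedSequence(seed, spawn_key=(heart,
  purpose, time, channel))`, so identical seeds give bit-identical
  datasets and any subset can be regenerated independently.

What the generator does *not* emulate: cardiac motion, probe-distance
drift, detector dead time and pile-up, wavelength-dependent scattering,
spectrally varying instrument throughput, or biochemically calibrated
extinction spectra. Passing tests therefore demonstrate correctness of
the estimators under the stated noise model, not robustness to every
artefact of real measurements.

## Problem sizes in the shipped analyses

The analysis drivers and end-to-end tests run the full 306-point,
15-heart protocol at a reduced photon budget (10⁵ counts per CH2
acquisition) with 256 time bins, and fit decays on a stride of every
10th–30th acquisition; these sizes keep a complete run to minutes on a
single core while leaving all qualitative conclusions unchanged. The
parameter-recovery and self-inversion studies use the full 1024-bin,
10⁶-count configuration.

## Known limitations

- The afterpulse term is proportional to modeled fluorescence, not to
  the measured count rate, and ignores dead-time distortion.
- The central-difference IRF reconstruction carries an O(Δt²) bias near
  sharp peaks (see above); use `method="discrete"` when the reference
  lifetime is trusted exactly.
- χ² with Neyman weights is biased low for bins with very few counts;
  at the photon budgets used here the effect is negligible, but fits of
  very dim histograms should use the photon minimum rather than trust
  reduced-χ².
- Group alignment assumes a shared nominal 5 s clock; systematic clock
  drift between hearts is not modelled or corrected.
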