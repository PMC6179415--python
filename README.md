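# myofluor

Analysis pipeline for time-resolved autofluorescence and
diffuse-reflectance monitoring of isolated perfused (Langendorff)
hearts. It is written for biophotonics groups who record NAD(P)H/FAD
autofluorescence with time-correlated single photon counting (TCSPC)
and visible reflectance spectra while a heart undergoes a
baseline → insult → reperfusion perfusion protocol, and who need the
whole chain — decay fitting, redox and oxygenation metrics, group
statistics — as tested, scriptable code.

## What it computes

**Fluorescence decays.** Each photon-arrival histogram (1024 bins over
a 50 ns repetition period) is fitted with a bi-exponential model

I(t) = a₁e^(−t/τ₁) + a₂e^(−t/τ₂)

brought to periodic steady state (each component scaled by
1/(1 − e^(−T/τ)) to account for incomplete decay between pulses),
circularly convolved with the instrument response function (IRF), plus
background and a uniform afterpulsing term. The fit minimises the
Neyman chi-square χ² = Σ (I(t_k) − I_model(t_k))²/max(I(t_k), 1) with a
deterministic multi-start bounded least-squares routine. Reported per
fit: the intensity-weighted mean lifetime
τ_mean = (a₁τ₁² + a₂τ₂²)/(a₁τ₁ + a₂τ₂), the fast fraction
α₁ = a₁/(a₁+a₂), and χ². The IRF of each channel is recovered from the
decay of a ~200 ps reference dye via the closed form
F(t) = M(t) + τ_ref·dM/dt.

**Reflectance.** Tissue absorbance A(λ) = −log₁₀(I/I₀) against a white
reference, with two ratio metrics: A(578)/A(600) for myoglobin
oxygenation and A(502)/A(550) for the cytochrome c oxidation state.

**Protocol time courses.** Intensities normalized to the first minute
of baseline, the optical redox ratio RR = I_CH2/(I_CH2 + I_CH3)
(≈ NAD(P)H/(NAD(P)H + FAD)), phase labels for the 180 s/630 s solution
switches, across-heart mean ± SD curves, and 10–90% transition times.

**Synthetic data.** A generator produces full multi-heart datasets
(TCSPC histograms + reflectance spectra every 5 s, with ground truth)
for control, hypoxia and glucose-depletion scenarios, used by the test
suite and the analysis scripts. See `docs/methods.md` for the model
details and defaults.

## Worked example

```python
import numpy as np
from myofluor import BiExpParams, fit_decay, tau_mean
from myofluor.simulate import simulate_irf, simulate_decay_histogram

truth = BiExpParams(a1=0.87, a2=0.13, tau1=0.82, tau2=3.47)  # NAD(P)H channel
irf = simulate_irf(fwhm_ns=0.25)
hist = simulate_decay_histogram(truth, irf, total_counts=1e6, rng=42)
fit = fit_decay(hist, irf)
print(f"tau_mean = {fit.tau_mean:.3f} ns (truth {tau_mean(truth):.3f})")
print(f"alpha1   = {fit.alpha1:.3f}")
```

prints

```
tau_mean = 1.836 ns (truth 1.847)
alpha1   = 0.867
```

i.e. at 10⁶ photons the fitter recovers the mean lifetime of the
control-regime NAD(P)H decay to ~0.6% and the fast fraction to ~0.003.

The numbered drivers under `analysis/` run the full study on synthetic
data and write tables under `results/` (bulky intermediates under
`scratch/`):

```sh
python analysis/01_simulate_protocols.py   # 15 hearts, 3 groups, ground truth
python analysis/02_fit_control_decays.py   # control lifetime table
python analysis/03_reflectance_metrics.py  # absorbance peaks & ratio sweep
python analysis/04_protocol_timecourses.py # group curves & transition times
```

The last driver reports, for the hypoxia group, a CH2 (NAD(P)H)
intensity plateau of ~1.35× baseline with CH4 (FAD) at ~0.75×, a redox
ratio rising from 0.50 to ~0.60 during the insult, and a reperfusion
10–90% transition (~244 s) slower than the insult transition (~101 s),
while control curves stay flat.

A `myofluor` command-line interface wraps the same library
(`simulate`, `fit-decay`, `reflectance`, `protocol`, `config`); run
`myofluor --help`.

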