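# fcskit

A toolkit for dual-color **fluorescence correlation spectroscopy (FCS)**
and **fluorescence cross-correlation spectroscopy (FCCS)**: simulation of
two-channel confocal photon streams, multi-tau correlation, diffusion-model
fitting, observation-volume calibration on standard dyes, and a
cross-correlation-ratio statistic that classifies a labeled protein
population as monomeric or oligomeric.

It is written for single-molecule biophysicists who need a transparent,
testable implementation of the full FCS/FCCS chain — for instance to read
out the oligomeric state of a protein such as α-synuclein from cells
co-expressing a GFP- and an RFP-tagged copy: co-diffusing (oligomeric)
molecules carry both labels and raise the cross-correlation amplitude,
while a monomeric population stays at the spectral-crosstalk baseline.
Because raw photon data from such experiments are rarely shareable, the
package ships a stochastic simulator that generates photon streams with
known ground truth, so every estimator can be validated end to end.

## Model

For molecules diffusing through a 3D Gaussian detection volume with
lateral radius `r0`, structure parameter `w = z0/r0` and effective volume
`V_eff = π^{3/2} r0² z0`, the autocorrelation of the detected intensity is

    G(τ) = [1 + T_R e^{−τ/τ_R}/(1−T_R)] · (1/N) ·
           (1 + τ/τ_D)^{−1} · (1 + τ/(w² τ_D))^{−1/2}

with `N = ⟨C⟩·V_eff` (amplitude ↔ concentration) and `τ_D = r0²/4D`
(decay ↔ mobility); `T_R`, `τ_R` describe triplet blinking. The anomalous
variant substitutes `(τ/τ_D)^α`, with `α < 1` reporting subdiffusion in
crowded cytosol. The volume is calibrated on a standard dye of known D
(R6G, 414 µm²/s; R640, 470 µm²/s for the red channel). The FCCS ratio is
`100·G_cross(0)/G_auto(0)` from fitted amplitudes, and a cohort of
per-cell ratios is called oligomeric when a one-sided Welch test finds it
elevated above a free-fluorophore baseline cohort (p < 0.05).

See `docs/methods.md` for estimator details, numerical choices, and what
the simulator does and does not emulate.

## Worked example

```python
from fcskit import (ObservationVolume, analyze_measurement, fccs_ratio,
                    simulate_photon_stream, two_color_config)

cfg = two_color_config(n_green_only=155, n_red_only=155, n_dual=155,
                       D=25.0, dt=40e-6, duration=8.0, seed=8)
stream = simulate_photon_stream(cfg)                  # 2-channel counts
volume = ObservationVolume(cfg.detection.r0, cfg.detection.w)
m = analyze_measurement(stream, volume)               # correlate + fit
print(fccs_ratio(m))
```

Running `python examples/04_fccs_ratio.py` (the same computation) prints:

```
auto amplitudes:  green 1/N = 0.488, red 1/N = 0.505
cross amplitude:  0.242
bound fractions:  green 47.9%, red 49.6%
FCCS ratio = 49.6% (min_amplitude convention; truth: 50% dual-labeled)
```

One third of the molecules carry both labels, i.e. half of each color's
labeled pool is in dual-labeled complexes — and the fitted ratio reads
exactly that 50% bound fraction back out. The `examples/` directory walks
through each capability: simulation, correlation + fitting (recovering
D = 25 µm²/s and the occupancy N from photons alone), dye calibration,
the FCCS ratio, cohort classification, and the end-to-end pipeline.
A thin CLI mirrors the pipeline stages
(`fcskit simulate | correlate | calibrate | fit | fccs | pipeline |
report`).

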