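# Methods

## Scope

`fcskit` implements the quantitative core of a dual-color fluorescence
correlation spectroscopy (FCS/FCCS) workflow: a stochastic photon-stream
simulator, auto-/cross-correlators, diffusion-model fitting,
observation-volume calibration on standard dyes, and a cross-correlation
ratio statistic with a baseline-referenced monomeric/oligomeric
classification. The simulator exists so that every stage of the analysis
can be validated against known ground truth without access to raw
instrument data.

## Physical model

**Detection.** The confocal molecular detection function (MDF) is the
standard 3D Gaussian, `W(x, y, z) = exp(-2(x²+y²)/r0² - 2z²/z0²)`, with
lateral 1/e² radius `r0` and axial radius `z0 = w·r0` (`w` the structure
parameter). The effective volume is `V_eff = π^{3/2} r0² z0`; with this
definition the autocorrelation amplitude of a single freely diffusing
species is exactly `1/(⟨C⟩·V_eff)`.

**Correlation models.** The free-diffusion autocorrelation is

    G(τ) = [1 + T_R·e^{-τ/τ_R}/(1-T_R)] · (1/N) ·
           (1 + τ/τ_D)^{-1} · (1 + τ/(w²τ_D))^{-1/2}

with `N = ⟨C⟩V_eff`, diffusion time `τ_D = r0²/(4D)`, and a triplet
(dark-state) prefactor with fraction `T_R` and relaxation time `τ_R`. The
anomalous model replaces `τ/τ_D` by `(τ/τ_D)^α` in both diffusion factors;
`α = 1` recovers the free model identically. For fractional Brownian
motion — a Gaussian process with `MSD(t) = 6Γt^α` — this anomalous form is
the exact correlation function (Gaussian propagator inserted into the
Gaussian MDF), so the simulator and the fit model are mutually consistent
by construction, not by approximation.

**Simulation.** Molecules perform independent random walks in a cubic
periodic box. Brownian steps are i.i.d. Gaussian with per-axis variance
`2D·dt`; anomalous paths are per-axis fractional Gaussian noise generated
by circulant embedding (Davies–Harte), which reproduces the fGn
autocovariance exactly (verified against the closed form in the tests).
Triplet blinking is a per-molecule two-state Markov chain on the `dt` grid
with rates `k_dark = T_R/τ_R`, `k_bright = (1-T_R)/τ_R`, giving
equilibrium dark occupancy `T_R` and telegraph correlation time `τ_R`.
Expected counts per bin are `Σ brightness·W(position)·on_state·dt` plus
background; detected counts are Poisson. Green→red spectral crosstalk with
probability κ is applied as a Poisson-rate transfer before the draw, which
is distributionally identical to rerouting each photon by an independent
Bernoulli trial (Poisson splitting). A separate per-photon rerouting
utility couples the rerouted photon sets across κ values (shared
uniforms), enabling strict-monotonicity checks.

Defaults mirror a typical acquisition: 60 s duration, 1 µs integration
step, `r0 = 0.2` µm, `w = 5`, calibration-dye presets R6G
(D = 414 µm²/s, green) and R640 (D = 470 µm²/s, red), and a cytosolic-GFP
preset at 25 µm²/s. All are free parameters.

## Estimators

**Correlators.** The direct correlator is the exact `O(N·K)` reference
with symmetric normalization: fluctuations are taken about the means of
the overlapping head/tail windows, which is robust to slow drift and
coincides with global-mean normalization for stationary input. The
multi-tau correlator evaluates lags 1..m (default m = 16) at the native
bin width and, per stage, rebins by two and evaluates lags m/2+1..m, so
every multi-tau point *equals* the direct correlator applied to the
correspondingly rebinned traces (asserted to 1e-10 in the tests). The
lag-zero point is excluded (shot-noise dominated).

**Errors.** `estimate_errors` reports the full-trace curve with per-lag
standard errors from the spread of segment-wise curves (default 10
segments). The full-trace G is used, not the segment mean: the symmetric
estimator has a finite-length bias that scales as 1/duration, so
averaging segment curves would multiply that bias by the segment count.

**Fitting.** Bounded weighted least squares (lmfit, trust-region
reflective) on an amplitude parameterization `A = 1/N`, which remains
well-conditioned for near-zero cross-correlation curves. Weights are
1/sd from segment errors (unweighted fallback when absent, recorded in
the result). Bounds: `τ_D` within the fitted lag range ×10, `T_R ≤ 0.8`,
`τ_R` in [0.1, 100] µs, `α` in [0.2, 2], `w` in [2, 10] when floated.
Initial guesses come from the first post-triplet lag (amplitude) and the
half-amplitude lag (`τ_D`). If a solution sits on a bound, up to three
jittered restarts are tried and the best reduced χ² kept. Non-convergence
is flagged, never silent. An optional additive baseline offset is
available for instrument-style baselines but off by default. Triplet
parameters are only floated on request: they are weakly identified, and
the recovery tolerances in the tests (±0.1 absolute on `T_R`, factor 2 on
`τ_R`) reflect that.

**Calibration.** Dye fits float `w`; sample fits freeze the calibrated
volume. Floating `w` (or `w` and `α`) on low-SNR cell curves is
degenerate, so the split follows the usual practice: high-SNR dye curve
determines the geometry once, `r0 = sqrt(4·D_ref·τ_D)`, `z0 = w·r0`.
A `w` pinned at its bounds flags the calibration ill-conditioned.

**FCCS ratio.** Amplitudes are taken from fitted `N` (triplet- and
noise-corrected), never from the raw first-lag G. Bound fractions are
`G_x(0)/G_red(0)` and `G_x(0)/G_green(0)`; the reported ratio divides by
the *smaller* auto amplitude by default (`min_amplitude` convention,
i.e. the larger bound fraction) because instruments print a single
"FCCS ratio (%)" without fixing the denominator — the convention is
recorded in every result, and `green_auto`/`red_auto` are selectable. No
crosstalk correction is applied to the ratio by default (control
baselines in real data are visibly uncorrected); the measured κ can be
used for an explicit correction upstream if desired.

**Classification.** A cohort of per-cell ratios is called oligomeric only
if a one-sided Welch test finds it elevated above the free-fluorophore
baseline cohort at tier * or better (p < 0.05); at or below baseline is
monomeric by the sidedness of the test; fewer than three cells on either
side is indeterminate. The baseline is an empirical distribution, not a
fixed constant, because control baselines drift between sessions. The
diffusion-coefficient fit can be attached as corroborating evidence but
never decides the call. Two-group comparisons use Welch's unequal-variance
t-test (two-tailed), mapped to tiers: ns (p ≥ 0.10), trend `#`
(0.05 ≤ p < 0.10), `*` < 0.05, `**` < 0.01, `***` < 0.001.

## What the simulator does and does not emulate

It reproduces the statistical structure the analysis relies on: Poisson
photon detection over a diffusing-emitter intensity process, correct
amplitude–concentration and decay–mobility relations, triplet shoulders,
anomalous-exponent signatures, dual-label cross-correlation, spectral
crosstalk and uncorrelated background. It does not model optical
aberrations or a non-Gaussian point-spread function, photobleaching,
detector afterpulsing or dead time, or scanning modes. Passing recovery
tests therefore demonstrates correctness of the estimators and fits under
the stated model, not robustness to instrument artifacts outside it.

**Finite-box artifact.** The periodic simulation box is a closed system:
total particle number is conserved, which depresses the correlation tail
by about 1/M (M = particles in the box) until the slowest concentration
mode, wavenumber 2π/L, has relaxed at `t_box = (L/2π)²/D` (generalized
`((L/2π)²/Γ)^{1/α}` for fBm). With the default box (L = 6·z0) this bump
sits near the axial shoulder that determines `w` and the subdiffusive
tail that determines `α`. Recovery and calibration studies therefore cap
the fitted lag range at `t_box/2` — an artifact domain with no analogue
in an open sample, where the reservoir restores Poisson number
statistics. This is a property of the validation geometry, not of the
estimators.

## Validation studies and problem sizes

`fcskit.studies` holds the simulation-recovery experiments used by the
test suite and by `scripts/acceptance.py`. Sizes are chosen so the whole
suite runs on one CPU in well under half an hour while leaving clear
statistical margin: traces of 2–10 s (rather than full 60 s acquisitions),
5 seeds per condition (3 for the FCCS mixtures), compact geometries
(`w = 2–3`, 155–620 particles, occupancies N ≈ 1–2, specific count rates
~100 kHz). Specifically:

- **D/N recovery** at D ∈ {25, 100, 414} µm²/s (6–10 s traces): median
  fitted D and N within 10% of truth.
- **α recovery** at α ∈ {0.7, 1.0} (fBm, 8–9 s traces): medians within
  ±0.1, the separation needed to distinguish crowded (α ≈ 0.75) from
  free (α ≈ 0.95) intracellular diffusion.
- **Calibration round trip** on a simulated R6G measurement (4 s): median
  r0 within 5%, V_eff within 15%.
- **Composition readout**: bound fraction within 5 points of the true
  dual-labeled fraction at f ∈ {0, 0.5, 1}; crosstalk
  κ ∈ {0, 0.05, 0.1, 0.2} strictly inflates the f = 0 baseline.
- **Classification calibration**: disjoint random partitions of a
  20-cell null pool (same generator for "sample" and "baseline") yield
  oligomeric calls in ≤ 10% of 100 replicates — each partition is a valid
  two-sample null comparison, making this an empirical level check
  without simulating 100 independent cohorts. A high-dual-fraction cohort
  versus the null pool separates at tier * or better.

Cohort simulations add per-cell lognormal expression jitter (σ = 0.15 in
log space) and 12% green→red crosstalk, which keeps the free-fluorophore
baseline ratio well above zero, as in real controls.

## Numerical choices

- Brownian/photon kernels are numba-compiled; increments are generated in
  float32 by numpy's SFC64 generator (seeded; bit-reproducible for a
  given config + seed, single-threaded).
- The MDF is truncated where `2q > 24` (`W < 4·10⁻¹¹`).
- fGn circulant eigenvalues are clipped at zero; a materially negative
  eigenvalue (beyond 1e-8 relative) raises instead of silently biasing.
- Expected counts per bin are guarded at 10⁶ (saturation would otherwise
  silently break the Poisson draw).
- Multi-tau stages stop when the maximum lag reaches a tenth of the trace
  (configurable) or the rebinned trace gets shorter than 2m bins.
- Fits require ≥ 8 lags spanning ≥ 2 decades; degenerate curves raise.

## Known limitations

- The closed-box tail artifact above: validation fits must stay below the
  box mixing time, or the box must be made much larger than 6·z0.
- `w` is weakly identified even for dye curves; calibrations near the
  w-bounds are flagged rather than silently accepted.
- Triplet parameters trade against each other at short lags; only
  order-of-magnitude recovery of `τ_R` should be expected.
- The cross-correlation fit shares no parameters with the autos; for
  very low cross amplitudes its diffusion time is unconstrained (the
  amplitude, which is what the ratio uses, remains well-behaved).
- Concentrations derive from the free-fit amplitude (the anomalous-fit
  amplitude differs negligibly at these noise levels but is not used).
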