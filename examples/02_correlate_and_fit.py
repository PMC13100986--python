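"""Correlate a simulated stream and fit the free-diffusion model.

The autocorrelation amplitude reads the mean number of molecules in the
effective volume (hence concentration); the decay time tau_D reads the
diffusion coefficient through D = r0^2 / (4 tau_D).
"""

from fcskit import (DetectionSpec, ObservationVolume, SimConfig, SpeciesSpec,
                    bin_photons, estimate_errors, fit_correlation,
                    simulate_photon_stream)

det = DetectionSpec(r0=0.25, w=2.0)
species = SpeciesSpec("green_only", n_particles=310, D=25.0,
                      brightness_green=150e3)
cfg = SimConfig(species=[species], detection=det, box_side=6 * det.z0,
                dt=40e-6, duration=6.0, seed=3)
stream = simulate_photon_stream(cfg)

trace = bin_photons(stream, cfg.dt)
curve = estimate_errors(trace.channel(0), trace.channel(0), n_segments=10)
volume = ObservationVolume(det.r0, det.w)
fit = fit_correlation(curve, "free3d", volume)

n_true = 310 * volume.V_eff / cfg.box_side**3
print(f"curve: {curve.lags.size} logarithmic lags, "
      f"{curve.lags[0] * 1e6:.0f} us .. {curve.lags[-1]:.2f} s")
print(f"fitted N  = {fit.params['N']:.2f} molecules in V_eff "
      f"(simulation truth {n_true:.2f})")
print(f"fitted D  = {fit.D:.1f} um^2/s (simulation truth 25.0)")
print(f"=> concentration {fit.concentration_nM:.1f} nM in "
      f"V_eff = {volume.V_eff:.3f} fL")
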