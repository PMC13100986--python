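"""Simulation-recovery studies validating the full analysis chain.

Each study simulates photon streams with known ground truth, runs the
standard pipeline (bin -> multi-tau correlate with segment errors -> fit),
and reports recovered vs true quantities. They serve three audiences: the
test suite (tolerance assertions), the acceptance script (numeric report),
and users wanting a template for their own parameter regimes.

Problem sizes (trace lengths of a few seconds, a handful of seeds, compact
w = 2-3 geometries) are chosen so every study runs in seconds-to-minutes on
one CPU while leaving comfortable statistical margin against its tolerance;
they are deliberately smaller than a full 60 s acquisition protocol. All
sizes are overridable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import calibrate_volume
from .correlate import bin_photons, estimate_errors
from .fccs import (FCCSMeasurement, analyze_measurement, classify_state,
                   compare_groups, fccs_ratio)
from .models import (FitOptions, ObservationVolume, fit_correlation)
from .simulate import (DetectionSpec, SimConfig, SpeciesSpec, TripletSpec,
                       dye_config, reroute_crosstalk, simulate_photon_stream,
                       two_color_config)

_BRIGHT = 150e3     # peak counts/s per molecule: ~100 kHz specific rate


def _run_seed(base_seed: int, idx: int) -> int:
    return (base_seed * 10007 + 7919 * idx + 1) % (2**31 - 1)


def _n_eff(n_particles: int, det: DetectionSpec, box_side: float) -> float:
    vol = ObservationVolume(det.r0, det.w)
    return n_particles * vol.V_eff / box_side**3


def _single_species_curve(cfg: SimConfig, n_segments: int = 10):
    stream = simulate_photon_stream(cfg)
    trace = bin_photons(stream, cfg.dt)
    return estimate_errors(trace.channel(0), trace.channel(0),
                           n_segments=n_segments)


def _box_mixing_time(cfg: SimConfig) -> float:
    """Relaxation time of the slowest concentration mode of the periodic box.

    The simulation volume is a closed system: total particle number is
    conserved, which depresses the correlation tail by ~1/M until the
    longest-wavelength concentration mode (wavenumber 2 pi / L) has
    relaxed. Recovery fits are therefore restricted to lags below half
    this time — an artifact domain with no analogue in an open sample.
    """
    sp = cfg.species[0]
    g = sp.transport_coefficient
    return ((cfg.box_side / (2.0 * np.pi)) ** 2 / g) ** (1.0 / sp.alpha)


# ---------------------------------------------------------------------------
# Brownian parameter recovery: D and N from single-species streams
# ---------------------------------------------------------------------------

#: per-D simulation geometry: lateral radius, step, trace length
RECOVERY_CONDITIONS = {
    25.0: dict(r0=0.25, dt=40e-6, duration=10.0),
    100.0: dict(r0=0.25, dt=8e-6, duration=8.0),
    414.0: dict(r0=0.40, dt=8e-6, duration=6.0),
}


def recovery_study(D_values: Sequence[float] = (25.0, 100.0, 414.0),
                   n_seeds: int = 5, seed: int = 0, w: float = 2.0,
                   n_particles: int = 310) -> pd.DataFrame:
    """Recover D and N from simulated single-species streams.

    One row per (D, seed): true and fitted diffusion coefficient and mean
    occupancy N = <C> V_eff from a free-diffusion fit with the true
    (known) observation volume held fixed.
    """
    rows = []
    for d_true in D_values:
        cond = RECOVERY_CONDITIONS[float(d_true)]
        det = DetectionSpec(r0=cond["r0"], w=w)
        box = 6.0 * det.z0
        vol = ObservationVolume(det.r0, det.w)
        n_true = _n_eff(n_particles, det, box)
        sp = SpeciesSpec("green_only", n_particles=n_particles, D=d_true,
                         brightness_green=_BRIGHT)
        for i in range(n_seeds):
            cfg = SimConfig(species=[sp], detection=det, box_side=box,
                            dt=cond["dt"], duration=cond["duration"],
                            seed=_run_seed(seed, hash((d_true, i)) % 10000))
            curve = _single_species_curve(cfg)
            cap = max(0.5 * _box_mixing_time(cfg), 110.0 * cfg.dt)
            fit = fit_correlation(curve, "free3d", vol,
                                  FitOptions(max_lag=cap))
            rows.append(dict(D_true=d_true, seed=i, converged=fit.converged,
                             D_fit=fit.D, N_true=n_true,
                             N_fit=fit.params["N"],
                             tau_D_fit=fit.params["tau_D"]))
    return pd.DataFrame(rows)


def amplitude_law_study(n_eff_values: Sequence[float] = (1.0, 5.0, 20.0),
                        n_seeds: int = 3, seed: int = 0) -> pd.DataFrame:
    """Check the amplitude law 1/G(0) = <C> V_eff across occupancies."""
    det = DetectionSpec(r0=0.25, w=2.0)
    box = 6.0 * det.z0
    vol = ObservationVolume(det.r0, det.w)
    per_particle = vol.V_eff / box**3
    durations = {1.0: 8.0, 5.0: 6.0, 20.0: 3.0}
    rows = []
    for n_eff in n_eff_values:
        n_part = int(round(n_eff / per_particle))
        n_true = n_part * per_particle
        sp = SpeciesSpec("green_only", n_particles=n_part, D=25.0,
                         brightness_green=_BRIGHT)
        for i in range(n_seeds):
            cfg = SimConfig(species=[sp], detection=det, box_side=box,
                            dt=40e-6, duration=durations.get(n_eff, 6.0),
                            seed=_run_seed(seed, hash((n_eff, i)) % 10000))
            curve = _single_species_curve(cfg)
            fit = fit_correlation(curve, "free3d", vol)
            rows.append(dict(N_true=n_true, seed=i, N_fit=fit.params["N"],
                             converged=fit.converged))
    return pd.DataFrame(rows)


def background_dilution_study(background: float = 100e3, seed: int = 0,
                              n_seeds: int = 2) -> pd.DataFrame:
    """Uncorrelated background B dilutes the amplitude by (S/(S+B))^2."""
    det = DetectionSpec(r0=0.25, w=2.0)
    box = 6.0 * det.z0
    vol = ObservationVolume(det.r0, det.w)
    sp = SpeciesSpec("green_only", n_particles=310, D=25.0,
                     brightness_green=_BRIGHT)
    rows = []
    for i in range(n_seeds):
        amps = {}
        rates = {}
        for label, bg in (("clean", 0.0), ("background", background)):
            d = DetectionSpec(r0=det.r0, w=det.w, background_green=bg)
            cfg = SimConfig(species=[sp], detection=d, box_side=box,
                            dt=40e-6, duration=6.0, seed=_run_seed(seed, i))
            stream = simulate_photon_stream(cfg)
            trace = bin_photons(stream, cfg.dt)
            rates[label] = trace.counts[:, 0].mean() / cfg.dt
            curve = estimate_errors(trace.channel(0), trace.channel(0), 10)
            amps[label] = fit_correlation(curve, "free3d", vol).amplitude
        s = rates["clean"]
        expected = (s / (s + background)) ** 2
        rows.append(dict(seed=i, amp_clean=amps["clean"],
                         amp_background=amps["background"],
                         observed_factor=amps["background"] / amps["clean"],
                         expected_factor=expected))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# anomalous-exponent recovery (fractional Brownian motion)
# ---------------------------------------------------------------------------

ANOMALOUS_CONDITIONS = {
    0.7: dict(Gamma=5.0, r0=0.30, dt=30e-6, duration=9.0),
    1.0: dict(Gamma=25.0, r0=0.25, dt=40e-6, duration=8.0),
}


def anomalous_recovery_study(alpha_values: Sequence[float] = (0.7, 1.0),
                             n_seeds: int = 5, seed: int = 0,
                             n_particles: int = 233) -> pd.DataFrame:
    """Recover the anomalous exponent alpha from fBm simulations.

    Subdiffusive (alpha = 0.7) and Brownian (alpha = 1.0) regimes; the fit
    floats alpha with the true volume fixed. Distinguishing these regimes
    is what separates crowded (alpha ~ 0.75) from free (alpha ~ 0.95)
    intracellular diffusion in practice.
    """
    rows = []
    for alpha in alpha_values:
        cond = ANOMALOUS_CONDITIONS[float(alpha)]
        det = DetectionSpec(r0=cond["r0"], w=2.0)
        box = 6.0 * det.z0
        vol = ObservationVolume(det.r0, det.w)
        mobility = (dict(D=cond["Gamma"]) if alpha == 1.0
                    else dict(Gamma=cond["Gamma"], alpha=alpha))
        sp = SpeciesSpec("green_only", n_particles=n_particles,
                         brightness_green=_BRIGHT, **mobility)
        for i in range(n_seeds):
            cfg = SimConfig(species=[sp], detection=det, box_side=box,
                            dt=cond["dt"], duration=cond["duration"],
                            seed=_run_seed(seed, hash((alpha, i)) % 10000))
            curve = _single_species_curve(cfg, n_segments=5)
            fit = fit_correlation(
                curve, "anomalous", vol,
                FitOptions(max_lag=0.5 * _box_mixing_time(cfg)))
            rows.append(dict(alpha_true=alpha, seed=i,
                             alpha_fit=fit.params["alpha"],
                             D_app=fit.D, converged=fit.converged))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# observation-volume calibration round trip
# ---------------------------------------------------------------------------

def calibration_study(n_seeds: int = 5, seed: int = 0, r0_true: float = 0.30,
                      w_true: float = 3.0, dye: str = "R6G",
                      duration: float = 4.0) -> pd.DataFrame:
    """Simulate a standard dye at known geometry; calibrate and compare.

    The dye's literature D (R6G 414 um^2/s) is both the simulation truth
    and the calibration reference, mirroring the real protocol where only
    D_ref is known and (r0, w, V_eff) are inferred. The fitted lag range
    is capped below the periodic box's concentration-mixing time
    L^2/(4 pi^2 D) — a closed-system artifact of the simulation volume
    with no analogue in an open sample.
    """
    vol_true = ObservationVolume(r0_true, w_true)
    rows = []
    for i in range(n_seeds):
        cfg = dye_config(dye, r0=r0_true, w=w_true, n_particles=349,
                         brightness=250e3, duration=duration,
                         seed=_run_seed(seed, i))
        t_box = cfg.box_side**2 / (4.0 * np.pi**2 * cfg.species[0].D)
        stream = simulate_photon_stream(cfg)
        trace = bin_photons(stream, cfg.dt)
        curve = estimate_errors(trace.channel(0), trace.channel(0), 8)
        cal = calibrate_volume(curve, cfg.species[0].D,
                               FitOptions(max_lag=0.5 * t_box))
        rows.append(dict(seed=i, r0_true=r0_true, r0_fit=cal.r0,
                         w_true=w_true, w_fit=cal.w,
                         V_eff_true=vol_true.V_eff, V_eff_fit=cal.V_eff,
                         ill_conditioned=cal.ill_conditioned))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FCCS: bound fraction vs dual-labeled composition; crosstalk; cohorts
# ---------------------------------------------------------------------------

_FCCS_DET = DetectionSpec(r0=0.25, w=2.0)
_FCCS_TOTAL = 310          # labeled molecules per color (N_eff ~ 2)


def _mixture_cfg(f_dual: float, seed: int, duration: float = 8.0,
                 crosstalk: float = 0.0, total: int = _FCCS_TOTAL,
                 total_red: Optional[int] = None) -> SimConfig:
    n_dual = int(round(f_dual * total))
    tr = total if total_red is None else total_red
    det = DetectionSpec(r0=_FCCS_DET.r0, w=_FCCS_DET.w,
                        crosstalk_g_to_r=crosstalk)
    return two_color_config(
        n_green_only=total - n_dual, n_red_only=tr - n_dual, n_dual=n_dual,
        D=25.0, detection=det, brightness=_BRIGHT, dt=40e-6,
        duration=duration, seed=seed)


def mixture_ratio_study(f_values: Sequence[float] = (0.0, 0.5, 1.0),
                        n_seeds: int = 3, seed: int = 0,
                        duration: float = 8.0) -> pd.DataFrame:
    """Bound fraction vs true dual-labeled fraction f, matched volumes.

    With equal green/red totals, no crosstalk and one shared volume, the
    fitted bound fraction G_cross(0)/G_auto(0) equals f.
    """
    vol = ObservationVolume(_FCCS_DET.r0, _FCCS_DET.w)
    rows = []
    for f in f_values:
        for i in range(n_seeds):
            cfg = _mixture_cfg(f, _run_seed(seed, hash((f, i)) % 10000),
                               duration)
            stream = simulate_photon_stream(cfg)
            m = analyze_measurement(stream, vol)
            r = fccs_ratio(m)
            rows.append(dict(f_true=f, seed=i, valid=r.valid,
                             bound_fraction=max(r.bound_fraction_green,
                                                r.bound_fraction_red),
                             ratio_percent=r.ratio_percent))
    return pd.DataFrame(rows)


def crosstalk_study(kappas: Sequence[float] = (0.0, 0.05, 0.1, 0.2),
                    n_seeds: int = 2, seed: int = 0,
                    duration: float = 8.0) -> pd.DataFrame:
    """Apparent FCCS ratio at f = 0 as green-to-red crosstalk grows.

    The same underlying photon stream is rerouted per photon with shared
    uniforms, so the rerouted photon set grows monotonically with kappa:
    spectral bleed-through alone inflates the apparent cross-correlation,
    reproducing a persistent nonzero control baseline.
    """
    vol = ObservationVolume(_FCCS_DET.r0, _FCCS_DET.w)
    rows = []
    for i in range(n_seeds):
        s = _run_seed(seed, i)
        cfg = _mixture_cfg(0.0, s, duration, crosstalk=0.0)
        stream = simulate_photon_stream(cfg)
        for kappa, st in zip(kappas,
                             reroute_crosstalk(stream, kappas, seed=s)):
            m = analyze_measurement(st, vol)
            r = fccs_ratio(m)
            rows.append(dict(kappa=kappa, seed=i,
                             ratio_percent=r.ratio_percent, valid=r.valid))
    return pd.DataFrame(rows)


@dataclass
class CohortStudy:
    """Simulated per-cell FCCS ratios for a labeled cohort."""

    ratios: np.ndarray
    f_dual: float
    crosstalk: float
    measurements: List[FCCSMeasurement]


def simulate_cohort(n_cells: int, f_dual: float, seed: int = 0,
                    crosstalk: float = 0.12, duration: float = 5.0,
                    conc_sd: float = 0.15) -> CohortStudy:
    """Simulate a cohort of cells and measure per-cell FCCS ratios.

    Each cell draws lognormal expression-level jitter (sd ``conc_sd`` in
    log space) per color around the nominal abundance; crosstalk defaults
    to a realistic eGFP bleed-through, which keeps the f = 0 baseline
    ratio well above zero as in real control measurements.
    """
    vol = ObservationVolume(_FCCS_DET.r0, _FCCS_DET.w)
    rng = np.random.Generator(np.random.SFC64(_run_seed(seed, 999)))
    ratios = []
    ms = []
    for c in range(n_cells):
        jg, jr = np.exp(rng.normal(0.0, conc_sd, size=2))
        total_g = max(int(round(_FCCS_TOTAL * jg)), 40)
        total_r = max(int(round(_FCCS_TOTAL * jr)), 40)
        n_dual = int(round(f_dual * min(total_g, total_r)))
        det = DetectionSpec(r0=_FCCS_DET.r0, w=_FCCS_DET.w,
                            crosstalk_g_to_r=crosstalk)
        cfg = two_color_config(
            n_green_only=total_g - n_dual, n_red_only=total_r - n_dual,
            n_dual=n_dual, D=25.0, detection=det, brightness=_BRIGHT,
            dt=40e-6, duration=duration,
            seed=_run_seed(seed, (int(round(f_dual * 1000)) * 131 + c)
                           % 10000))
        m = analyze_measurement(simulate_photon_stream(cfg), vol,
                                cell_id=f"cell{c:02d}")
        r = fccs_ratio(m)
        if r.valid:
            ratios.append(r.ratio_percent)
            ms.append(m)
    return CohortStudy(ratios=np.asarray(ratios), f_dual=f_dual,
                       crosstalk=crosstalk, measurements=ms)


def classification_level_study(pool: CohortStudy, n_replicates: int = 100,
                               group_size: int = 10, seed: int = 0,
                               alpha_level: float = 0.05) -> Dict[str, float]:
    """Empirical false-oligomeric rate under the null.

    Repeatedly partitions a same-generator pool of per-cell ratios into
    disjoint 'sample' and 'baseline' cohorts — each replicate a valid
    two-sample comparison under the null — and counts oligomeric calls.
    A calibrated one-sided test at level 0.05 should call oligomeric in
    at most ~10% of replicates.
    """
    rng = np.random.Generator(np.random.SFC64(_run_seed(seed, 4242)))
    ratios = pool.ratios
    if ratios.size < 2 * 3:
        raise ValueError("pool too small")
    gs = min(group_size, ratios.size // 2)
    calls = 0
    for _ in range(n_replicates):
        perm = rng.permutation(ratios.size)
        sample = ratios[perm[:gs]]
        base = ratios[perm[gs:2 * gs]]
        call = classify_state(sample, base, alpha_level=alpha_level)
        calls += call.label == "oligomeric"
    return {"false_call_rate": calls / n_replicates,
            "n_replicates": n_replicates, "pool_size": int(ratios.size)}


def contrast_study(oligomer_pool: CohortStudy, monomer_pool: CohortStudy):
    """Oligomeric vs monomeric cohort contrast: classification + Welch tier."""
    call = classify_state(oligomer_pool.ratios, monomer_pool.ratios)
    cmp = compare_groups(oligomer_pool.ratios, monomer_pool.ratios)
    return call, cmp


# ---------------------------------------------------------------------------
# triplet-parameter recovery
# ---------------------------------------------------------------------------

def triplet_recovery_study(T_R: float = 0.2, tau_R: float = 5e-6,
                           n_seeds: int = 3, seed: int = 0,
                           duration: float = 2.5) -> pd.DataFrame:
    """Recover triplet fraction and relaxation time from blinking streams.

    Triplet parameters are weakly identified (amplitude/timescale trade
    against each other at the first lags); tolerances downstream reflect
    that.
    """
    det = DetectionSpec(r0=0.25, w=2.0)
    box = 6.0 * det.z0
    vol = ObservationVolume(det.r0, det.w)
    sp = SpeciesSpec("green_only", n_particles=155, D=25.0,
                     brightness_green=250e3)
    rows = []
    for i in range(n_seeds):
        cfg = SimConfig(species=[sp], detection=det,
                        triplet=TripletSpec(T_R=T_R, tau_R=tau_R),
                        box_side=box, dt=1e-6, duration=duration,
                        seed=_run_seed(seed, i))
        curve = _single_species_curve(cfg)
        fit = fit_correlation(curve, "free3d", vol,
                              FitOptions(fit_triplet=True))
        rows.append(dict(seed=i, T_R_true=T_R, tau_R_true=tau_R,
                         T_R_fit=fit.params["T_R"],
                         tau_R_fit=fit.params["tau_R"],
                         converged=fit.converged))
    return pd.DataFrame(rows)
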