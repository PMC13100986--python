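"""Correlation models for free and anomalous 3D diffusion, and curve fitting.

The free-diffusion autocorrelation of N molecules in a 3D Gaussian
observation volume with structure parameter w = z0/r0, including a triplet
(dark-state) prefactor, is

    G(tau) = [1 + T_R exp(-tau/tau_R)/(1 - T_R)]
             * (1/N) * (1 + tau/tau_D)^-1 * (1 + tau/(w^2 tau_D))^-1/2

and the anomalous variant replaces tau/tau_D by (tau/tau_D)^alpha in both
diffusion factors (alpha = 1 recovers the free model exactly). N = <C> V_eff
with V_eff = pi^{3/2} r0^2 z0, so the amplitude reads concentration and the
decay time tau_D = r0^2 / 4D reads mobility.

Fitting is bounded weighted least squares (lmfit / trust-region reflective)
on an amplitude parameterization A = 1/N, which stays well-conditioned for
near-zero cross-correlation curves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import lmfit
import numpy as np

from .correlate import CorrelationCurve
from .simulate import AVOGADRO

__all__ = [
    "ObservationVolume", "FreeDiffusionParams", "AnomalousParams",
    "FitOptions", "FitResult", "eval_free", "eval_anomalous",
    "fit_correlation", "derive_D", "concentration_from_amplitude",
]


@dataclass(frozen=True)
class ObservationVolume:
    """Confocal observation volume: lateral radius r0 (um) and w = z0/r0."""

    r0: float
    w: float

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if self.w <= 1:
            raise ValueError("w must exceed 1")

    @property
    def z0(self) -> float:
        return self.w * self.r0

    @property
    def V_eff(self) -> float:
        """Effective volume pi^{3/2} r0^2 z0 in fL (1 um^3 == 1 fL)."""
        return math.pi ** 1.5 * self.r0 ** 2 * self.z0


@dataclass
class FreeDiffusionParams:
    """Parameters of the one-component 3D free-diffusion model."""

    N: float                 # mean molecules in V_eff (= <C> V_eff)
    tau_D: float             # diffusion time, s
    T_R: float = 0.0         # triplet fraction
    tau_R: float = 2e-6      # triplet relaxation time, s

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("N must be positive")
        if self.tau_D <= 0 or self.tau_R <= 0:
            raise ValueError("tau_D and tau_R must be positive")
        if not (0.0 <= self.T_R < 1.0):
            raise ValueError("T_R must lie in [0, 1)")
        if self.T_R > 0.0 and self.tau_R >= self.tau_D:
            warnings.warn("tau_R >= tau_D: triplet slower than diffusion",
                          stacklevel=2)


@dataclass
class AnomalousParams(FreeDiffusionParams):
    """Free-diffusion parameters plus the anomalous exponent alpha."""

    alpha: float = 1.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if not (0.0 < self.alpha <= 2.0):
            raise ValueError("alpha must lie in (0, 2]")


def _triplet_prefactor(tau, T_R, tau_R):
    if T_R == 0.0:
        return np.ones_like(np.asarray(tau, dtype=float))
    return 1.0 + T_R * np.exp(-np.asarray(tau, dtype=float) / tau_R) / (
        1.0 - T_R)


def _g_shape(tau, tau_D, w, alpha):
    x = (np.asarray(tau, dtype=float) / tau_D) ** alpha
    return 1.0 / ((1.0 + x) * np.sqrt(1.0 + x / w**2))


def eval_free(p: FreeDiffusionParams, tau, volume: ObservationVolume):
    """Evaluate the free-diffusion model G(tau); tau in s (scalar or array)."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0")
    g = _triplet_prefactor(tau, p.T_R, p.tau_R) / p.N \
        * _g_shape(tau, p.tau_D, volume.w, 1.0)
    return g if g.ndim else float(g)


def eval_anomalous(p: AnomalousParams, tau, volume: ObservationVolume):
    """Evaluate the anomalous-diffusion model; alpha = 1 equals eval_free."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0")
    if p.alpha <= 0:
        raise ValueError("alpha must be positive")
    g = _triplet_prefactor(tau, p.T_R, p.tau_R) / p.N \
        * _g_shape(tau, p.tau_D, volume.w, p.alpha)
    return g if g.ndim else float(g)


@dataclass
class FitOptions:
    """Options for fit_correlation.

    fit_triplet: float T_R/tau_R (True), or fix them at zero (False).
    float_w: float the structure parameter (calibration fits only).
    min_lag/max_lag restrict the fitted lag range (s).
    """

    min_lag: float = 1e-6
    max_lag: float = np.inf
    fit_triplet: bool = False
    float_w: bool = False
    w_bounds: tuple = (2.0, 10.0)
    fit_offset: bool = False     # additive baseline G_inf (absorbs
    #                              instrument/finite-system baselines)
    weights: str = "auto"        # auto | none
    max_restarts: int = 3


@dataclass
class FitResult:
    """Fitted correlation model with uncertainties and derived quantities."""

    model: str                        # {free3d, anomalous}
    params: dict                      # name -> value (N, tau_D, T_R, tau_R, [alpha, w])
    stderr: dict                      # name -> 1-SD uncertainty (may be nan)
    redchi: float
    lag_range: tuple
    volume: ObservationVolume
    converged: bool
    weighted: bool
    n_points: int = 0
    message: str = ""

    @property
    def amplitude(self) -> float:
        """Diffusion amplitude 1/N (triplet prefactor excluded)."""
        return 1.0 / self.params["N"] if np.isfinite(self.params["N"]) \
            and self.params["N"] > 0 else 0.0

    @property
    def g0(self) -> float:
        """Model value at tau -> 0: 1 / ((1 - T_R) N)."""
        return self.amplitude / (1.0 - self.params.get("T_R", 0.0))

    @property
    def D(self) -> float:
        return derive_D(self, self.volume)

    @property
    def concentration_nM(self) -> float:
        return concentration_from_amplitude(self, self.volume)


def _initial_guesses(lags, g, opts: FitOptions):
    # amplitude from the first post-triplet lag; tau_D from half-amplitude
    tau_r0 = 2e-6
    post = lags >= (5.0 * tau_r0 if opts.fit_triplet else lags[0])
    g_post = g[post] if post.any() else g
    a0 = max(float(g_post[0]), 1e-4)
    half = a0 / 2.0
    below = np.nonzero(g <= half)[0]
    tau_d0 = float(lags[below[0]]) if below.size else float(lags[-1] / 3.0)
    tau_d0 = min(max(tau_d0, lags[0]), lags[-1])
    return a0, tau_d0, tau_r0


def fit_correlation(curve: CorrelationCurve, model: str,
                    volume: ObservationVolume,
                    options: Optional[FitOptions] = None) -> FitResult:
    """Fit a correlation curve with the free or anomalous diffusion model.

    Requires >= 8 lags spanning at least two decades. Weights come from
    ``curve.sd`` when present (zeros floored to the smallest positive sd);
    otherwise the fit is unweighted. If the first solution sits on a
    parameter bound, up to ``max_restarts`` jittered restarts are tried and
    the best reduced chi-square kept. Non-convergence is flagged, never
    silent.
    """
    if model not in ("free3d", "anomalous"):
        raise ValueError("model must be 'free3d' or 'anomalous'")
    opts = options or FitOptions()
    cur = curve.restrict(opts.min_lag, opts.max_lag)
    lags, g = cur.lags, cur.G
    if lags.size < 8:
        raise ValueError("need at least 8 lags in the fitted range")
    if lags[-1] / lags[0] < 100.0:
        raise ValueError("fitted lags must span at least two decades")

    weighted = False
    weights = None
    if opts.weights == "auto" and cur.sd is not None:
        sd = cur.sd.copy()
        pos = sd > 0
        if pos.any():
            sd[~pos] = sd[pos].min()
            weights = 1.0 / sd
            weighted = True
        else:
            warnings.warn("all-zero sd: falling back to unweighted fit",
                          stacklevel=2)

    a0, tau_d0, tau_r0 = _initial_guesses(lags, g, opts)
    anomalous = model == "anomalous"

    def make_params(a, tau_d, t_r, tau_r, alpha, w):
        p = lmfit.Parameters()
        p.add("A", value=a, min=0.0, max=1e6)
        p.add("tau_D", value=tau_d, min=lags[0], max=10.0 * lags[-1])
        p.add("T_R", value=t_r if opts.fit_triplet else 0.0,
              min=0.0, max=0.8, vary=opts.fit_triplet)
        p.add("tau_R", value=tau_r, min=1e-7, max=1e-4,
              vary=opts.fit_triplet)
        p.add("alpha", value=alpha, min=0.2, max=2.0, vary=anomalous)
        p.add("w", value=w, min=opts.w_bounds[0], max=opts.w_bounds[1],
              vary=opts.float_w)
        p.add("offset", value=0.0, min=-0.05, max=0.05,
              vary=opts.fit_offset)
        return p

    def residual(p):
        v = p.valuesdict()
        pref = 1.0 + v["T_R"] * np.exp(-lags / v["tau_R"]) / (1.0 - v["T_R"])
        x = (lags / v["tau_D"]) ** v["alpha"]
        gm = pref * v["A"] / ((1.0 + x) * np.sqrt(1.0 + x / v["w"] ** 2)) \
            + v["offset"]
        r = gm - g
        return r * weights if weights is not None else r

    w_init = volume.w if not opts.float_w else float(np.clip(
        volume.w, *opts.w_bounds))
    starts = [(a0, tau_d0, 0.1, tau_r0, 0.9 if anomalous else 1.0, w_init)]

    def at_bound(res):
        for name, par in res.params.items():
            if not par.vary:
                continue
            span = par.max - par.min
            if span > 0 and (par.value - par.min < 1e-6 * span
                             or par.max - par.value < 1e-6 * span):
                return True
        return False

    best = None
    rng = np.random.Generator(np.random.SFC64(12345))
    attempt = 0
    while attempt <= opts.max_restarts:
        if attempt == 0:
            a, td, tr, trr, al, wv = starts[0]
        else:
            jit = rng.uniform(0.4, 2.5, size=2)
            a = a0 * jit[0]
            td = float(np.clip(tau_d0 * jit[1], lags[0], lags[-1]))
            tr, trr = 0.1, tau_r0
            al = float(rng.uniform(0.5, 1.5)) if anomalous else 1.0
            wv = w_init
        res = lmfit.minimize(residual, make_params(a, td, tr, trr, al, wv),
                             method="least_squares")
        if best is None or (res.success and res.redchi < best.redchi):
            best = res
        attempt += 1
        if best.success and not at_bound(best):
            break

    v = best.params.valuesdict()
    amp = v["A"]
    params = {
        "N": (1.0 / amp) if amp > 0 else np.inf,
        "tau_D": v["tau_D"],
        "T_R": v["T_R"],
        "tau_R": v["tau_R"],
    }
    stderr = {}
    for name, key in (("A", "N"), ("tau_D", "tau_D"), ("T_R", "T_R"),
                      ("tau_R", "tau_R")):
        e = best.params[name].stderr
        if name == "A" and e is not None and amp > 0:
            e = e / amp**2            # |d(1/A)| = dA / A^2
        stderr[key] = float(e) if e is not None else np.nan
    if anomalous:
        params["alpha"] = v["alpha"]
        e = best.params["alpha"].stderr
        stderr["alpha"] = float(e) if e is not None else np.nan
    if opts.float_w:
        params["w"] = v["w"]
        e = best.params["w"].stderr
        stderr["w"] = float(e) if e is not None else np.nan
    if opts.fit_offset:
        params["offset"] = v["offset"]
        e = best.params["offset"].stderr
        stderr["offset"] = float(e) if e is not None else np.nan

    return FitResult(
        model=model, params=params, stderr=stderr,
        redchi=float(best.redchi), lag_range=(float(lags[0]), float(lags[-1])),
        volume=volume, converged=bool(best.success), weighted=weighted,
        n_points=int(lags.size), message=str(best.message))


def derive_D(fit: FitResult, volume: Optional[ObservationVolume] = None
             ) -> float:
    """Diffusion coefficient D = r0^2 / (4 tau_D) in um^2/s.

    For anomalous fits this is the *apparent* transport coefficient at the
    diffusion time (the tabulated convention, um^2/s, with alpha reported
    alongside), not a dimensionally strict generalized coefficient.
    """
    vol = volume or fit.volume
    return vol.r0 ** 2 / (4.0 * fit.params["tau_D"])


def concentration_from_amplitude(fit: FitResult,
                                 volume: Optional[ObservationVolume] = None
                                 ) -> float:
    """Molar concentration in nM from N = <C> V_eff."""
    vol = volume or fit.volume
    n = fit.params["N"]
    if not np.isfinite(n):
        return 0.0
    return n / (vol.V_eff * 1e-15 * AVOGADRO) * 1e9
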