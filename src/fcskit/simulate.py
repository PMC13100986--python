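"""Stochastic photon-stream simulator for confocal FCS/FCCS.

Labeled molecules diffuse (Brownian or fractional-Brownian) through a cubic
box with periodic boundaries; a 3D Gaussian molecular detection function
(MDF) ``W(x,y,z) = exp(-2(x^2+y^2)/r0^2 - 2 z^2/z0^2)`` converts positions to
per-channel emission rates; triplet blinking is a two-state Markov chain on
the integration grid; detected counts are Poisson draws per bin with optional
green-to-red spectral crosstalk and uniform background.

The simulator is the in-package stand-in for live-cell confocal
acquisitions: it produces two-channel binned photon streams with the
statistical structure the downstream correlation analysis assumes
(amplitude 1/(C V_eff), diffusion decay at tau_D = r0^2/4D, triplet
shoulder, crosstalk-inflated cross-correlation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit
from scipy import fft as sfft

AVOGADRO = 6.02214076e23
#: molecules per um^3 at 1 nM
_MOLEC_PER_UM3_PER_NM = AVOGADRO * 1e-9 * 1e-15

# literature diffusion coefficients of the calibration dyes, um^2/s
DYE_D = {"R6G": 414.0, "R640": 470.0}
#: order-of-magnitude cytosolic mobility of free eGFP, um^2/s
CYTOSOLIC_GFP_D = 25.0

LABEL_CLASSES = ("green_only", "red_only", "dual")


@dataclass
class SpeciesSpec:
    """One molecular species: label class, abundance, mobility, brightness.

    Exactly one of ``n_particles`` / ``concentration_nM`` must be given.
    Mobility is either ordinary Brownian (``D`` in um^2/s, alpha = 1) or
    anomalous (``Gamma`` in um^2/s^alpha with ``alpha`` in (0, 2]); the
    ensemble MSD is 6 * Gamma * t**alpha in both cases (Gamma == D at
    alpha == 1). Brightness values are peak detected count rates (counts/s
    per molecule at the MDF maximum), before crosstalk.
    """

    label_class: str
    n_particles: Optional[int] = None
    concentration_nM: Optional[float] = None
    D: Optional[float] = None
    Gamma: Optional[float] = None
    alpha: float = 1.0
    brightness_green: float = 0.0
    brightness_red: float = 0.0

    def __post_init__(self) -> None:
        if self.label_class not in LABEL_CLASSES:
            raise ValueError(f"label_class must be one of {LABEL_CLASSES}")
        if (self.n_particles is None) == (self.concentration_nM is None):
            raise ValueError(
                "exactly one of n_particles / concentration_nM must be set")
        if self.n_particles is not None and self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")
        if (self.D is None) == (self.Gamma is None):
            raise ValueError("exactly one of D / Gamma must be set")
        if not (0.0 < self.alpha <= 2.0):
            raise ValueError("alpha must lie in (0, 2]")
        if self.D is not None and self.D <= 0:
            raise ValueError("D must be positive")
        if self.Gamma is not None and self.Gamma <= 0:
            raise ValueError("Gamma must be positive")
        if self.D is not None and self.alpha != 1.0:
            raise ValueError("use Gamma (not D) for alpha != 1")
        if self.brightness_green < 0 or self.brightness_red < 0:
            raise ValueError("brightness must be >= 0")
        if self.label_class == "green_only" and self.brightness_red != 0:
            raise ValueError("green_only species must have brightness_red = 0")
        if self.label_class == "red_only" and self.brightness_green != 0:
            raise ValueError("red_only species must have brightness_green = 0")

    @property
    def transport_coefficient(self) -> float:
        """Generalized coefficient Gamma (== D for Brownian motion)."""
        return self.D if self.D is not None else self.Gamma  # type: ignore

    def resolve_n_particles(self, box_side: float) -> int:
        if self.n_particles is not None:
            return self.n_particles
        n = self.concentration_nM * _MOLEC_PER_UM3_PER_NM * box_side**3
        return int(round(n))


@dataclass
class TripletSpec:
    """Photophysical dark-state (triplet) blinking parameters.

    T_R is the equilibrium dark-state fraction, tau_R the relaxation
    (correlation) time of the on/off telegraph. Telegraph rates follow as
    k_dark = T_R / tau_R (bright->dark) and k_bright = (1 - T_R) / tau_R
    (dark->bright), so the stationary dark occupancy is T_R and the
    autocorrelation time of the state process is tau_R.
    """

    T_R: float = 0.0
    tau_R: float = 2e-6

    def __post_init__(self) -> None:
        if not (0.0 <= self.T_R < 1.0):
            raise ValueError("T_R must lie in [0, 1)")
        if self.tau_R <= 0:
            raise ValueError("tau_R must be positive")

    @property
    def k_dark(self) -> float:
        return self.T_R / self.tau_R

    @property
    def k_bright(self) -> float:
        return (1.0 - self.T_R) / self.tau_R


@dataclass
class DetectionSpec:
    """Confocal detection geometry and channel imperfections.

    r0: lateral 1/e^2 radius (um); w: structure parameter z0/r0 (> 1).
    ``crosstalk_g_to_r`` is the probability that a detected green-fluorophore
    photon is routed into the red channel (eGFP bleed-through); backgrounds
    are uniform uncorrelated count rates per channel.
    """

    r0: float = 0.2
    w: float = 5.0
    crosstalk_g_to_r: float = 0.0
    background_green: float = 0.0
    background_red: float = 0.0

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if self.w <= 1:
            raise ValueError("structure parameter w must exceed 1")
        if not (0.0 <= self.crosstalk_g_to_r < 1.0):
            raise ValueError("crosstalk_g_to_r must lie in [0, 1)")
        if self.background_green < 0 or self.background_red < 0:
            raise ValueError("background rates must be >= 0")

    @property
    def z0(self) -> float:
        return self.w * self.r0


@dataclass
class SimConfig:
    """Full simulation recipe: geometry, time grid, species, photophysics."""

    species: Sequence[SpeciesSpec]
    detection: DetectionSpec = field(default_factory=DetectionSpec)
    triplet: TripletSpec = field(default_factory=TripletSpec)
    box_side: float = 3.0       # um
    dt: float = 1e-6            # s, integration/bin step
    duration: float = 60.0      # s, matching a 60 s acquisition
    seed: int = 0

    def __post_init__(self) -> None:
        if self.box_side <= 0 or self.dt <= 0 or self.duration <= 0:
            raise ValueError("box_side, dt, duration must be positive")
        if len(self.species) == 0:
            raise ValueError("at least one species required")
        if self.box_side < 6.0 * self.detection.z0 - 1e-12:
            warnings.warn(
                "box_side < 6*z0: periodic wrap-around may correlate the "
                "detection volume with its images", stacklevel=2)
        tau_d_min = min(self._tau_d(sp) for sp in self.species)
        if self.dt > tau_d_min / 10.0 + 1e-15:
            warnings.warn(
                f"dt = {self.dt:g} s exceeds tau_D/10 = {tau_d_min / 10:g} s "
                "for the fastest species; diffusion decay will be "
                "under-resolved", stacklevel=2)

    def _tau_d(self, sp: SpeciesSpec) -> float:
        r0 = self.detection.r0
        g = sp.transport_coefficient
        # anomalous: tau_D solves r0^2/4 = Gamma * tau_D^alpha
        return (r0**2 / (4.0 * g)) ** (1.0 / sp.alpha)

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


@dataclass
class PhotonStream:
    """Two-channel photon record: binned counts or per-channel timestamps.

    The simulator produces the binned form (counts shape ``(n_bins, 2)``,
    channel 0 = green, channel 1 = red). ``timestamps`` mode stores a sorted
    float array of arrival times per channel, as read from photon files.
    """

    counts: Optional[np.ndarray] = None
    bin_width: Optional[float] = None
    timestamps: Optional[dict] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts is None) == (self.timestamps is None):
            raise ValueError("exactly one of counts / timestamps must be set")
        if self.counts is not None:
            self.counts = np.asarray(self.counts)
            if self.counts.ndim != 2:
                raise ValueError("counts must be (n_bins, n_channels)")
            if self.bin_width is None or self.bin_width <= 0:
                raise ValueError("binned stream requires positive bin_width")
        else:
            for ch, ts in self.timestamps.items():
                ts = np.asarray(ts, dtype=float)
                bad = np.nonzero(np.diff(ts) < 0)[0]
                if bad.size:
                    raise ValueError(
                        f"channel {ch}: timestamps decrease at index "
                        f"{bad[0] + 1}")
                self.timestamps[ch] = ts

    @property
    def mode(self) -> str:
        return "binned" if self.counts is not None else "timestamps"

    @property
    def n_channels(self) -> int:
        if self.counts is not None:
            return self.counts.shape[1]
        return len(self.timestamps)

    @property
    def duration(self) -> float:
        if "duration" in self.metadata:
            return float(self.metadata["duration"])
        if self.counts is not None:
            return self.counts.shape[0] * self.bin_width
        return max((ts[-1] if len(ts) else 0.0)
                   for ts in self.timestamps.values())

    def total_counts(self, channel: Optional[int] = None):
        if self.counts is not None:
            return (int(self.counts.sum()) if channel is None
                    else int(self.counts[:, channel].sum()))
        if channel is None:
            return sum(len(ts) for ts in self.timestamps.values())
        return len(self.timestamps[channel])

    def to_timestamps(self, seed: int = 0) -> "PhotonStream":
        """Spread binned counts uniformly within each bin (seeded)."""
        if self.mode == "timestamps":
            return self
        rng = np.random.Generator(np.random.SFC64(seed))
        out = {}
        for ch in range(self.counts.shape[1]):
            c = self.counts[:, ch]
            idx = np.repeat(np.arange(c.size), c)
            ts = (idx + rng.random(idx.size)) * self.bin_width
            out[ch] = np.sort(ts)
        meta = dict(self.metadata)
        meta.setdefault("duration", self.counts.shape[0] * self.bin_width)
        return PhotonStream(timestamps=out, metadata=meta)


# ---------------------------------------------------------------------------
# numba kernels: position update + MDF accumulation
# ---------------------------------------------------------------------------

_Q_CUTOFF = 12.0  # skip exp() when 2*q > 24 (W < 4e-11)


@njit(cache=True, fastmath=True)
def _accum_mdf(pos, inc, half, r0i2, z0i2, out, t0):
    """Advance particles by precomputed increments; accumulate sum of W.

    pos: (3, n) float32 wrapped positions, updated in place.
    inc: (n_t, 3, n) float32 displacement per step.
    out: float64 accumulator, out[t0 + t] += sum_i W(pos_i(t)).
    """
    n_t = inc.shape[0]
    n = pos.shape[1]
    L = 2.0 * half
    for t in range(n_t):
        acc = 0.0
        for i in range(n):
            x = pos[0, i] + inc[t, 0, i]
            y = pos[1, i] + inc[t, 1, i]
            z = pos[2, i] + inc[t, 2, i]
            if x > half:
                x -= L
            elif x < -half:
                x += L
            if y > half:
                y -= L
            elif y < -half:
                y += L
            if z > half:
                z -= L
            elif z < -half:
                z += L
            pos[0, i] = x
            pos[1, i] = y
            pos[2, i] = z
            q = (x * x + y * y) * r0i2 + z * z * z0i2
            if q < _Q_CUTOFF:
                acc += math.exp(-2.0 * q)
        out[t0 + t] += acc


@njit(cache=True, fastmath=True)
def _accum_mdf_triplet(pos, inc, state, u, p_off, p_on, half, r0i2, z0i2,
                       out, t0):
    """As _accum_mdf, gating each molecule by a two-state telegraph.

    state: (n,) uint8, 1 = bright. u: (n_t, n) float32 uniforms.
    p_off = k_dark*dt (bright->dark), p_on = k_bright*dt (dark->bright).
    """
    n_t = inc.shape[0]
    n = pos.shape[1]
    L = 2.0 * half
    for t in range(n_t):
        acc = 0.0
        for i in range(n):
            x = pos[0, i] + inc[t, 0, i]
            y = pos[1, i] + inc[t, 1, i]
            z = pos[2, i] + inc[t, 2, i]
            if x > half:
                x -= L
            elif x < -half:
                x += L
            if y > half:
                y -= L
            elif y < -half:
                y += L
            if z > half:
                z -= L
            elif z < -half:
                z += L
            pos[0, i] = x
            pos[1, i] = y
            pos[2, i] = z
            if state[i] == 1:
                if u[t, i] < p_off:
                    state[i] = 0
                else:
                    q = (x * x + y * y) * r0i2 + z * z * z0i2
                    if q < _Q_CUTOFF:
                        acc += math.exp(-2.0 * q)
            else:
                if u[t, i] < p_on:
                    state[i] = 1
        out[t0 + t] += acc


# ---------------------------------------------------------------------------
# fractional Gaussian noise via circulant embedding (exact covariance)
# ---------------------------------------------------------------------------

def fgn_increments(n_steps: int, hurst: float, step_var: float,
                   rng: np.random.Generator, n_paths: int,
                   batch: int = 16) -> np.ndarray:
    """Exact fractional Gaussian noise by circulant embedding.

    Returns (n_paths, n_steps) float32 increments with per-step variance
    ``step_var`` and autocovariance gamma(k) = step_var/2 *
    (|k+1|^2H - 2|k|^2H + |k-1|^2H). Paths come in independent pairs from
    the real and imaginary parts of one FFT.
    """
    if not (0.0 < hurst <= 1.0):
        raise ValueError("hurst must lie in (0, 1]")
    n = int(n_steps)
    k = np.arange(n + 1, dtype=float)
    two_h = 2.0 * hurst
    g = 0.5 * step_var * ((k + 1.0) ** two_h - 2.0 * k ** two_h
                          + np.abs(k - 1.0) ** two_h)
    c = np.concatenate([g, g[-2:0:-1]])
    m = c.size  # 2n
    lam = np.fft.fft(c).real
    neg = lam.min()
    if neg < -1e-8 * lam.max():
        raise RuntimeError("circulant embedding not nonnegative definite")
    lam = np.clip(lam, 0.0, None)
    scale = np.sqrt(lam / m)
    out = np.empty((n_paths, n), dtype=np.float32)
    done = 0
    while done < n_paths:
        npair = min(batch, (n_paths - done + 1) // 2)
        z = rng.standard_normal((npair, m)) + 1j * rng.standard_normal(
            (npair, m))
        x = sfft.fft(z * scale, axis=1, workers=1)
        for j in range(npair):
            out[done] = x[j, :n].real.astype(np.float32)
            done += 1
            if done < n_paths:
                out[done] = x[j, :n].imag.astype(np.float32)
                done += 1
    return out


def _telegraph_params(trip: TripletSpec, dt: float):
    p_off = trip.k_dark * dt
    p_on = trip.k_bright * dt
    if max(p_off, p_on) > 0.5:
        warnings.warn("dt too coarse for triplet kinetics "
                      "(switch probability per step > 0.5)", stacklevel=3)
    return np.float32(p_off), np.float32(p_on)


def simulate_telegraph(trip: TripletSpec, dt: float, n_steps: int,
                       n_particles: int, seed: int = 0) -> np.ndarray:
    """Simulate the on/off triplet telegraph alone (for state-level checks).

    Returns (n_steps, n_particles) uint8 array, 1 = bright.
    """
    rng = np.random.Generator(np.random.SFC64(seed))
    p_off, p_on = _telegraph_params(trip, dt)
    state = (rng.random(n_particles) >= trip.T_R).astype(np.uint8)
    out = np.empty((n_steps, n_particles), dtype=np.uint8)
    u = rng.random((n_steps, n_particles), dtype=np.float32)
    _telegraph_kernel(state, u, p_off, p_on, out)
    return out


@njit(cache=True)
def _telegraph_kernel(state, u, p_off, p_on, out):
    n_t, n = u.shape
    for t in range(n_t):
        for i in range(n):
            if state[i] == 1:
                if u[t, i] < p_off:
                    state[i] = 0
            else:
                if u[t, i] < p_on:
                    state[i] = 1
            out[t, i] = state[i]


# ---------------------------------------------------------------------------
# trajectory + photon generation
# ---------------------------------------------------------------------------

_CHUNK_STEPS = 16384
_FBM_PARTICLE_BATCH = 24


def _brownian_sigma(sp: SpeciesSpec, dt: float) -> float:
    return math.sqrt(2.0 * sp.transport_coefficient * dt)


def simulate_trajectories(cfg: SimConfig, max_bytes: int = 2_000_000_000):
    """Simulate and return unwrapped per-species trajectories.

    Returns a list (one entry per species) of float64 arrays of shape
    ``(n_steps + 1, n_particles, 3)`` holding unwrapped positions in um
    (suitable for MSD analysis; apply ``wrap_positions`` for box
    coordinates). Intended for verification at small problem sizes; the
    photon-stream path streams positions without storing them.
    """
    rng = np.random.Generator(np.random.SFC64(cfg.seed))
    n_t = cfg.n_steps
    out = []
    for sp in cfg.species:
        n = sp.resolve_n_particles(cfg.box_side)
        need = (n_t + 1) * n * 3 * 8
        if need > max_bytes:
            raise MemoryError(
                f"trajectory storage {need / 1e9:.1f} GB exceeds limit; "
                "reduce n_steps or particles")
        start = (rng.random((1, n, 3)) - 0.5) * cfg.box_side
        if sp.alpha == 1.0:
            inc = rng.standard_normal((n_t, n, 3))
            inc *= _brownian_sigma(sp, cfg.dt)
        else:
            step_var = 2.0 * sp.Gamma * cfg.dt ** sp.alpha
            paths = fgn_increments(n_t, sp.alpha / 2.0, step_var, rng, n * 3)
            inc = np.moveaxis(
                paths.reshape(n, 3, n_t).astype(np.float64), 2, 0)
        pos = np.concatenate([start, start + np.cumsum(inc, axis=0)], axis=0)
        out.append(pos)
    return out


def wrap_positions(pos: np.ndarray, box_side: float) -> np.ndarray:
    """Map unwrapped coordinates into the centered periodic box."""
    half = box_side / 2.0
    return (pos + half) % box_side - half


def _species_weight_sum(cfg: SimConfig, sp: SpeciesSpec,
                        rng: np.random.Generator) -> np.ndarray:
    """Sum over the species' molecules of W(position)*on_state, per step."""
    det = cfg.detection
    n_t = cfg.n_steps
    n = sp.resolve_n_particles(cfg.box_side)
    out = np.zeros(n_t, dtype=np.float64)
    if n == 0:
        return out
    half = cfg.box_side / 2.0
    r0i2 = 1.0 / det.r0**2
    z0i2 = 1.0 / det.z0**2
    use_triplet = cfg.triplet.T_R > 0.0
    if use_triplet:
        p_off, p_on = _telegraph_params(cfg.triplet, cfg.dt)

    def init_pos(n_local):
        return ((rng.random((3, n_local), dtype=np.float32) - 0.5)
                * np.float32(cfg.box_side))

    def init_state(n_local):
        return (rng.random(n_local) >= cfg.triplet.T_R).astype(np.uint8)

    if sp.alpha == 1.0:
        sig = np.float32(_brownian_sigma(sp, cfg.dt))
        pos = init_pos(n)
        state = init_state(n) if use_triplet else None
        done = 0
        while done < n_t:
            chunk = min(_CHUNK_STEPS, n_t - done)
            inc = rng.standard_normal((chunk, 3, n), dtype=np.float32)
            np.multiply(inc, sig, out=inc)
            if use_triplet:
                u = rng.random((chunk, n), dtype=np.float32)
                _accum_mdf_triplet(pos, inc, state, u, p_off, p_on, half,
                                   r0i2, z0i2, out, done)
            else:
                _accum_mdf(pos, inc, half, r0i2, z0i2, out, done)
            done += chunk
    else:
        step_var = 2.0 * sp.Gamma * cfg.dt ** sp.alpha
        hurst = sp.alpha / 2.0
        done_p = 0
        while done_p < n:
            nb = min(_FBM_PARTICLE_BATCH, n - done_p)
            paths = fgn_increments(n_t, hurst, step_var, rng, nb * 3)
            inc = np.ascontiguousarray(
                np.transpose(paths.reshape(nb, 3, n_t), (2, 1, 0)))
            pos = init_pos(nb)
            if use_triplet:
                state = init_state(nb)
                u = rng.random((n_t, nb), dtype=np.float32)
                _accum_mdf_triplet(pos, inc, state, u, p_off, p_on, half,
                                   r0i2, z0i2, out, 0)
            else:
                _accum_mdf(pos, inc, half, r0i2, z0i2, out, 0)
            done_p += nb
    return out


def simulate_photon_stream(cfg: SimConfig) -> PhotonStream:
    """Simulate a two-channel binned photon stream (channel 0 green, 1 red).

    Per bin of width dt the expected counts in channel c are
    ``sum_species brightness_c * sum_molecules W * on * dt`` plus background;
    green-fluorophore photons are rerouted to red with probability
    ``crosstalk_g_to_r`` (applied as Poisson-rate transfer, exactly
    equivalent to per-photon Bernoulli rerouting); counts are Poisson.
    Bit-reproducible for a given config + seed.
    """
    det = cfg.detection
    rng = np.random.Generator(np.random.SFC64(cfg.seed))
    n_t = cfg.n_steps
    lam_g = np.zeros(n_t)
    lam_r = np.zeros(n_t)
    for sp in cfg.species:
        if sp.brightness_green == 0.0 and sp.brightness_red == 0.0:
            continue
        wsum = _species_weight_sum(cfg, sp, rng)
        if sp.brightness_green:
            lam_g += (sp.brightness_green * cfg.dt) * wsum
        if sp.brightness_red:
            lam_r += (sp.brightness_red * cfg.dt) * wsum
    kappa = det.crosstalk_g_to_r
    if kappa > 0.0:
        lam_r += kappa * lam_g
        lam_g *= (1.0 - kappa)
    lam_g += det.background_green * cfg.dt
    lam_r += det.background_red * cfg.dt
    peak = max(lam_g.max(initial=0.0), lam_r.max(initial=0.0))
    if peak > 1e6:
        raise RuntimeError(
            f"expected counts per bin reach {peak:.3g} > 1e6; reduce "
            "brightness or dt")
    counts = np.empty((n_t, 2), dtype=np.int32)
    counts[:, 0] = rng.poisson(lam_g)
    counts[:, 1] = rng.poisson(lam_r)
    return PhotonStream(counts=counts, bin_width=cfg.dt,
                        metadata={"config": cfg, "duration": n_t * cfg.dt})


def reroute_crosstalk(stream: PhotonStream, kappas: Sequence[float],
                      seed: int = 0) -> list:
    """Apply per-photon green-to-red rerouting post hoc, coupled across kappas.

    One uniform is drawn per green photon and compared against each kappa,
    so the set of rerouted photons grows monotonically with kappa — useful
    for strict-monotonicity studies of crosstalk effects. Returns one new
    binned stream per kappa.
    """
    if stream.mode != "binned":
        raise ValueError("reroute_crosstalk requires a binned stream")
    rng = np.random.Generator(np.random.SFC64(seed))
    g = stream.counts[:, 0].astype(np.int64)
    total = int(g.sum())
    u = rng.random(total)
    edges = np.concatenate([[0], np.cumsum(g)])
    out = []
    for kappa in kappas:
        if not (0.0 <= kappa < 1.0):
            raise ValueError("kappa must lie in [0, 1)")
        moved_flag = (u < kappa).astype(np.int64)
        moved = np.add.reduceat(
            np.concatenate([moved_flag, [0]]), edges[:-1])
        moved[g == 0] = 0
        counts = stream.counts.copy()
        counts[:, 0] = (g - moved).astype(counts.dtype)
        counts[:, 1] = counts[:, 1] + moved.astype(counts.dtype)
        meta = dict(stream.metadata)
        meta["rerouted_crosstalk"] = kappa
        out.append(PhotonStream(counts=counts, bin_width=stream.bin_width,
                                metadata=meta))
    return out


# ---------------------------------------------------------------------------
# convenience constructors
# ---------------------------------------------------------------------------

def dye_config(dye: str = "R6G", *, r0: float = 0.2, w: float = 5.0,
               n_particles: int = 310, box_side: Optional[float] = None,
               brightness: float = 150e3, dt: Optional[float] = None,
               duration: float = 60.0, seed: int = 0,
               channel: str = "green") -> SimConfig:
    """Calibration-dye measurement preset (R6G green / R640 red).

    All parameters are overridable conveniences; the literature diffusion
    coefficients are R6G 414 um^2/s and R640 470 um^2/s.
    """
    d_val = DYE_D[dye]
    det = DetectionSpec(r0=r0, w=w)
    if box_side is None:
        box_side = 6.0 * det.z0
    if dt is None:
        dt = (r0**2 / (4.0 * d_val)) / 10.0
    bright = dict(green_only=dict(brightness_green=brightness),
                  red_only=dict(brightness_red=brightness))
    label = "green_only" if channel == "green" else "red_only"
    sp = SpeciesSpec(label_class=label, n_particles=n_particles, D=d_val,
                     **bright[label])
    return SimConfig(species=[sp], detection=det, box_side=box_side, dt=dt,
                     duration=duration, seed=seed)


def two_color_config(*, n_green_only: int, n_red_only: int, n_dual: int,
                     D: float = CYTOSOLIC_GFP_D, Gamma: Optional[float] = None,
                     alpha: float = 1.0, detection: Optional[DetectionSpec] = None,
                     brightness: float = 150e3, box_side: Optional[float] = None,
                     dt: Optional[float] = None, duration: float = 60.0,
                     triplet: Optional[TripletSpec] = None,
                     seed: int = 0) -> SimConfig:
    """Two-color mixture of green-only, red-only and dual-labeled species.

    The standard FCCS scenario: the dual-labeled fraction models co-diffusing
    (oligomeric) complexes carrying both fluorophores.
    """
    det = detection or DetectionSpec(r0=0.25, w=2.0)
    if box_side is None:
        box_side = 6.0 * det.z0
    mobility = (dict(D=D) if alpha == 1.0 and Gamma is None
                else dict(Gamma=Gamma if Gamma is not None else D,
                          alpha=alpha))
    species = []
    if n_green_only:
        species.append(SpeciesSpec("green_only", n_particles=n_green_only,
                                   brightness_green=brightness, **mobility))
    if n_red_only:
        species.append(SpeciesSpec("red_only", n_particles=n_red_only,
                                   brightness_red=brightness, **mobility))
    if n_dual:
        species.append(SpeciesSpec("dual", n_particles=n_dual,
                                   brightness_green=brightness,
                                   brightness_red=brightness, **mobility))
    if not species:
        raise ValueError("all particle counts are zero")
    g = species[0].transport_coefficient
    a = species[0].alpha
    if dt is None:
        dt = (det.r0**2 / (4.0 * g)) ** (1.0 / a) / 12.0
    return SimConfig(species=species, detection=det,
                     triplet=triplet or TripletSpec(), box_side=box_side,
                     dt=dt, duration=duration, seed=seed)


def mean_rate_expected(cfg: SimConfig, channel: int = 0) -> float:
    """Closed-form mean detected count rate (no triplet, no crosstalk).

    Integral of the Gaussian MDF over all space is (pi/2)^{3/2} r0^2 z0, so
    each molecule contributes brightness * (pi/2)^{3/2} r0^2 z0 / box^3 on
    average, plus background.
    """
    det = cfg.detection
    v_mdf = (math.pi / 2.0) ** 1.5 * det.r0**2 * det.z0
    rate = (det.background_green, det.background_red)[channel]
    for sp in cfg.species:
        q = (sp.brightness_green, sp.brightness_red)[channel]
        n = sp.resolve_n_particles(cfg.box_side)
        rate += n * q * v_mdf / cfg.box_side**3
    return rate
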