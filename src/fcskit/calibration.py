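"""Observation-volume calibration from standard-dye measurements.

A free-diffusing dye of known diffusion coefficient (R6G at 414 um^2/s for
the green channel, R640 at 470 um^2/s for the red) is measured; the fitted
diffusion time then pins the lateral radius through r0 = sqrt(4 D_ref
tau_D), with the structure parameter w floated in the dye fit. The
resulting ObservationVolume is frozen and reused for all sample fits —
dye curves are high-SNR, cell curves are not, so w is never floated there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional

from .correlate import CorrelationCurve
from .models import FitOptions, FitResult, ObservationVolume, fit_correlation
from .simulate import DYE_D


@dataclass
class CalibrationResult:
    """An ObservationVolume plus the dye-fit diagnostics behind it."""

    volume: ObservationVolume
    fit: FitResult
    D_ref: float
    ill_conditioned: bool = False

    @property
    def r0(self) -> float:
        return self.volume.r0

    @property
    def w(self) -> float:
        return self.volume.w

    @property
    def V_eff(self) -> float:
        return self.volume.V_eff


@dataclass
class CrossCalibration:
    """Per-channel calibrations and the volume-mismatch ratio V_red/V_green."""

    green: CalibrationResult
    red: CalibrationResult

    @property
    def volume_mismatch(self) -> float:
        return self.red.V_eff / self.green.V_eff


def calibrate_volume(dye_curve: CorrelationCurve, D_ref: float,
                     options: Optional[FitOptions] = None
                     ) -> CalibrationResult:
    """Determine r0, w, V_eff from a standard-dye curve with known D_ref.

    Fits the free-diffusion model with w floated (bounds [2, 10] by
    default); r0 = sqrt(4 D_ref tau_D_fit), z0 = w r0. A fit with w pinned
    at a bound is flagged ill-conditioned; an unconverged fit raises.
    """
    if D_ref <= 0:
        raise ValueError("D_ref must be positive")
    opts = options or FitOptions()
    opts = FitOptions(**{**opts.__dict__, "float_w": True})
    # the seed volume only provides the w initial value
    seed_vol = ObservationVolume(r0=0.2, w=sum(opts.w_bounds) / 2.0)
    fit = fit_correlation(dye_curve, "free3d", seed_vol, opts)
    if not fit.converged:
        raise RuntimeError(f"dye fit did not converge: {fit.message}")
    w = fit.params["w"]
    lo, hi = opts.w_bounds
    ill = (w - lo < 1e-3 * (hi - lo)) or (hi - w < 1e-3 * (hi - lo))
    r0 = math.sqrt(4.0 * D_ref * fit.params["tau_D"])
    volume = ObservationVolume(r0=r0, w=w)
    return CalibrationResult(volume=volume, fit=fit, D_ref=D_ref,
                             ill_conditioned=ill)


def cross_calibrate(dye_green: CorrelationCurve, dye_red: CorrelationCurve,
                    D_refs: Optional[Dict[str, float]] = None,
                    options: Optional[FitOptions] = None) -> CrossCalibration:
    """Calibrate both detection channels with their standard dyes.

    Default references: R6G (green, 414 um^2/s) and R640 (red, 470 um^2/s).
    The volume-mismatch ratio V_red/V_green feeds the interpretation of
    cross-correlation amplitudes when the two channels see different
    volumes.
    """
    refs = D_refs or {"green": DYE_D["R6G"], "red": DYE_D["R640"]}
    green = calibrate_volume(dye_green, refs["green"], options)
    red = calibrate_volume(dye_red, refs["red"], options)
    return CrossCalibration(green=green, red=red)
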