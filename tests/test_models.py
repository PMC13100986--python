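"""Tests of model evaluation, nesting, fitting, and derived quantities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fcskit.correlate import CorrelationCurve
from fcskit.models import (AnomalousParams, FitOptions, FreeDiffusionParams,
                           ObservationVolume, concentration_from_amplitude,
                           derive_D, eval_anomalous, eval_free,
                           fit_correlation)

VOL5 = ObservationVolume(r0=0.2, w=5.0)


class TestEvaluation:
    def test_amplitude_identity(self):
        p = FreeDiffusionParams(N=4.0, tau_D=1e-4)
        assert eval_free(p, 0.0, VOL5) == pytest.approx(0.25)

    def test_half_amplitude_at_tau_d_for_flat_volume(self):
        # w -> infinity removes the axial factor: G(tau_D) = 0.5/N
        p = FreeDiffusionParams(N=2.0, tau_D=1e-4)
        vol = ObservationVolume(r0=0.2, w=1e8)
        assert eval_free(p, 1e-4, vol) == pytest.approx(0.25, rel=1e-9)

    def test_free_model_frozen_oracle(self):
        # independent arbitrary-precision substitution, frozen
        p = FreeDiffusionParams(N=10.0, tau_D=100e-6, T_R=0.2, tau_R=5e-6)
        assert eval_free(p, 10e-6, VOL5) == pytest.approx(
            0.09379748505144474, rel=1e-12)

    def test_anomalous_model_frozen_oracle(self):
        p = AnomalousParams(N=5.0, tau_D=1e-3, alpha=0.75)
        assert eval_anomalous(p, 1e-3, VOL5) == pytest.approx(
            0.09805806756909202, rel=1e-12)

    def test_amplitude_independent_of_alpha_at_zero_lag(self):
        for alpha in (0.4, 0.75, 1.0, 1.6):
            p = AnomalousParams(N=5.0, tau_D=1e-3, alpha=alpha)
            assert eval_anomalous(p, 0.0, VOL5) == pytest.approx(0.2)

    def test_monotone_decay(self):
        p = FreeDiffusionParams(N=3.0, tau_D=2e-4, T_R=0.2, tau_R=4e-6)
        tau = np.logspace(-7, 0, 200)
        g = eval_free(p, tau, VOL5)
        assert np.all(np.diff(g) < 0)
        assert np.all(g > 0)

    def test_triplet_prefactor_limits(self):
        p = FreeDiffusionParams(N=1.0, tau_D=1.0, T_R=0.3, tau_R=2e-6)
        # tau -> 0: G = 1/((1 - T_R) N)
        assert eval_free(p, 0.0, VOL5) == pytest.approx(1 / 0.7, rel=1e-6)
        # tau >> tau_R (but << tau_D): prefactor -> 1
        assert eval_free(p, 1e-4, VOL5) == pytest.approx(
            eval_free(FreeDiffusionParams(N=1.0, tau_D=1.0), 1e-4, VOL5),
            rel=1e-6)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(n=st.floats(0.1, 100), tau_d=st.floats(1e-5, 1e-2),
           t_r=st.floats(0, 0.7), w=st.floats(1.5, 10),
           log_tau=st.floats(-7, 0))
    def test_alpha_one_reduces_to_free_model(self, n, tau_d, t_r, w,
                                             log_tau):
        vol = ObservationVolume(r0=0.2, w=w)
        tau = 10.0 ** log_tau
        pf = FreeDiffusionParams(N=n, tau_D=tau_d, T_R=t_r, tau_R=2e-6)
        pa = AnomalousParams(N=n, tau_D=tau_d, T_R=t_r, tau_R=2e-6,
                             alpha=1.0)
        gf = eval_free(pf, tau, vol)
        ga = eval_anomalous(pa, tau, vol)
        assert abs(ga - gf) <= 1e-12 * gf

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            FreeDiffusionParams(N=1.0, tau_D=1e-4, T_R=1.0)
        with pytest.raises(ValueError):
            AnomalousParams(N=1.0, tau_D=1e-4, alpha=0.0)
        with pytest.raises(ValueError):
            eval_free(FreeDiffusionParams(N=1.0, tau_D=1e-4), -1.0, VOL5)


def _synthetic_curve(params, vol, model="free", n_lags=64, noise_sd=None):
    lags = np.logspace(-6, 0, n_lags)
    if model == "free":
        g = eval_free(params, lags, vol)
    else:
        g = eval_anomalous(params, lags, vol)
    sd = None if noise_sd is None else np.full_like(g, noise_sd)
    return CorrelationCurve(lags, g, sd=sd)


class TestFitting:
    def test_noiseless_free_fit_exact_recovery(self):
        truth = FreeDiffusionParams(N=8.0, tau_D=2e-4, T_R=0.15,
                                    tau_R=5e-6)
        curve = _synthetic_curve(truth, VOL5)
        fit = fit_correlation(curve, "free3d", VOL5,
                              FitOptions(fit_triplet=True))
        assert fit.converged
        assert fit.params["N"] == pytest.approx(8.0, rel=1e-6)
        assert fit.params["tau_D"] == pytest.approx(2e-4, rel=1e-6)
        assert fit.params["T_R"] == pytest.approx(0.15, abs=1e-6)
        assert fit.params["tau_R"] == pytest.approx(5e-6, rel=1e-4)

    def test_noiseless_anomalous_fit_exact_recovery(self):
        truth = AnomalousParams(N=3.0, tau_D=5e-4, alpha=0.75)
        curve = _synthetic_curve(truth, VOL5, model="anomalous")
        fit = fit_correlation(curve, "anomalous", VOL5)
        assert fit.converged
        assert fit.params["alpha"] == pytest.approx(0.75, rel=1e-6)
        assert fit.params["N"] == pytest.approx(3.0, rel=1e-6)

    def test_degenerate_curves_rejected(self):
        p = FreeDiffusionParams(N=2.0, tau_D=1e-4)
        with pytest.raises(ValueError, match="8 lags"):
            fit_correlation(_synthetic_curve(p, VOL5, n_lags=3),
                            "free3d", VOL5)
        lags = np.linspace(1e-4, 5e-4, 10)
        narrow = CorrelationCurve(lags, eval_free(p, lags, VOL5))
        with pytest.raises(ValueError, match="decades"):
            fit_correlation(narrow, "free3d", VOL5)

    def test_all_zero_sd_falls_back_unweighted(self):
        p = FreeDiffusionParams(N=2.0, tau_D=1e-4)
        curve = _synthetic_curve(p, VOL5, noise_sd=0.0)
        with pytest.warns(UserWarning, match="unweighted"):
            fit = fit_correlation(curve, "free3d", VOL5)
        assert not fit.weighted
        assert fit.converged

    def test_zero_amplitude_curve_yields_zero_amplitude(self):
        # flat noise floor around zero: amplitude ~ 0, N -> inf
        rng = np.random.default_rng(8)
        lags = np.logspace(-6, 0, 64)
        g = rng.normal(0.0, 1e-4, 64)
        curve = CorrelationCurve(lags, g, sd=np.full(64, 1e-4))
        fit = fit_correlation(curve, "free3d", VOL5)
        assert fit.amplitude < 1e-3


class TestDerived:
    def test_derive_d_arithmetic(self):
        fit = _fit_stub(tau_D=100e-6)
        assert derive_D(fit, ObservationVolume(0.2, 5.0)) == pytest.approx(
            100.0)
        fit2 = _fit_stub(tau_D=200e-6)
        assert derive_D(fit2, ObservationVolume(0.2, 5.0)) == pytest.approx(
            50.0)

    def test_concentration_avogadro_arithmetic(self):
        vol1 = ObservationVolume(r0=(1.0 / (np.pi**1.5 * 5.0))**(1 / 3),
                                 w=5.0)   # V_eff = 1 fL
        assert vol1.V_eff == pytest.approx(1.0, rel=1e-12)
        fit = _fit_stub(N=1.0)
        assert concentration_from_amplitude(fit, vol1) == pytest.approx(
            1.66053906717, rel=1e-9)
        # doubling V_eff at fixed N halves C
        vol2 = ObservationVolume(r0=vol1.r0 * 2**(1 / 3), w=5.0)
        assert concentration_from_amplitude(fit, vol2) == pytest.approx(
            1.66053906717 / 2, rel=1e-9)

    def test_zero_molecules_zero_concentration(self):
        fit = _fit_stub(N=np.inf)
        assert concentration_from_amplitude(fit, VOL5) == 0.0

    def test_volume_identity(self):
        vol = ObservationVolume(r0=0.2, w=5.0)
        assert vol.V_eff == pytest.approx(0.222733119873, rel=1e-10)
        assert vol.V_eff == pytest.approx(np.pi**1.5 * vol.w * vol.r0**3,
                                          rel=1e-14)


def _fit_stub(N=1.0, tau_D=1e-4):
    from fcskit.models import FitResult
    return FitResult(model="free3d",
                     params={"N": N, "tau_D": tau_D, "T_R": 0.0,
                             "tau_R": 2e-6},
                     stderr={}, redchi=1.0, lag_range=(1e-6, 1.0),
                     volume=VOL5, converged=True, weighted=False)
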