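"""Tests of the photon-stream simulator: diffusion statistics, photophysics,
detection model, and reproducibility."""

import numpy as np
import pytest

from fcskit.simulate import (DetectionSpec, PhotonStream, SimConfig,
                             SpeciesSpec, TripletSpec, fgn_increments,
                             mean_rate_expected, reroute_crosstalk,
                             simulate_photon_stream, simulate_telegraph,
                             simulate_trajectories, wrap_positions)


def _cfg(species, *, r0=0.25, w=2.0, dt=1e-6, duration=0.05, seed=1,
         triplet=None, **det_kw):
    det = DetectionSpec(r0=r0, w=w, **det_kw)
    return SimConfig(species=species, detection=det,
                     triplet=triplet or TripletSpec(),
                     box_side=6 * det.z0, dt=dt, duration=duration,
                     seed=seed)


class TestSpecValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(label_class="green_only", D=100.0),                 # no abundance
        dict(label_class="green_only", n_particles=5,
             concentration_nM=1.0, D=100.0),                     # both
        dict(label_class="green_only", n_particles=5),           # no mobility
        dict(label_class="green_only", n_particles=5, D=-1.0),
        dict(label_class="green_only", n_particles=5, Gamma=5.0,
             alpha=2.5),
        dict(label_class="green_only", n_particles=5, Gamma=-5.0,
             alpha=0.7),
        dict(label_class="green_only", n_particles=5, D=10.0,
             brightness_red=1e4),                                # wrong color
        dict(label_class="nonsense", n_particles=5, D=10.0),
    ])
    def test_invalid_species_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SpeciesSpec(**kwargs)

    def test_concentration_resolves_to_particle_count(self):
        # 1.661 nM in a 10x10x10 um box is ~1000 molecules
        sp = SpeciesSpec("green_only", concentration_nM=1.66053906717,
                         D=10.0)
        assert sp.resolve_n_particles(10.0) == 1000

    def test_triplet_rates_match_equilibrium(self):
        t = TripletSpec(T_R=0.2, tau_R=5e-6)
        assert t.k_dark / (t.k_dark + t.k_bright) == pytest.approx(0.2)
        assert 1.0 / (t.k_dark + t.k_bright) == pytest.approx(5e-6)

    def test_geometry_warnings(self):
        det = DetectionSpec(r0=0.25, w=2.0)
        sp = SpeciesSpec("green_only", n_particles=5, D=25.0)
        with pytest.warns(UserWarning, match="box_side"):
            SimConfig(species=[sp], detection=det, box_side=1.0,
                      dt=1e-6, duration=0.01)
        with pytest.warns(UserWarning, match="tau_D/10"):
            SimConfig(species=[sp], detection=det, box_side=3.0,
                      dt=1e-3, duration=0.1)


class TestTrajectories:
    def test_brownian_msd_matches_theory(self):
        # ensemble MSD at lag 10 us for D = 100: 6 D t = 6.0e-3 um^2
        sp = SpeciesSpec("green_only", n_particles=2000, D=100.0)
        cfg = _cfg([sp], dt=1e-6, duration=5e-5, seed=2)
        (pos,) = simulate_trajectories(cfg)
        disp = pos[10] - pos[0]
        msd = np.mean(np.sum(disp**2, axis=1))
        assert msd == pytest.approx(6.0e-3, rel=0.05)

    def test_fbm_msd_slope(self):
        # log-log MSD slope for alpha = 0.7 within +-0.05
        sp = SpeciesSpec("green_only", n_particles=600, Gamma=5.0,
                         alpha=0.7)
        cfg = _cfg([sp], r0=0.3, dt=3e-5, duration=3e-5 * 512, seed=3)
        (pos,) = simulate_trajectories(cfg)
        ks = np.array([1, 2, 4, 8, 16, 32, 64, 128])
        msd = [np.mean(np.sum((pos[k:] - pos[:-k])**2, axis=2))
               for k in ks]
        slope = np.polyfit(np.log(ks), np.log(msd), 1)[0]
        assert slope == pytest.approx(0.7, abs=0.05)

    def test_alpha_one_identical_to_brownian_pathway(self):
        a = SpeciesSpec("green_only", n_particles=50, D=100.0,
                        brightness_green=1e5)
        b = SpeciesSpec("green_only", n_particles=50, Gamma=100.0,
                        alpha=1.0, brightness_green=1e5)
        sa = simulate_photon_stream(_cfg([a], duration=0.02, seed=4))
        sb = simulate_photon_stream(_cfg([b], duration=0.02, seed=4))
        np.testing.assert_array_equal(sa.counts, sb.counts)

    def test_wrap_preserves_count_and_bounds(self):
        sp = SpeciesSpec("green_only", n_particles=100, D=400.0)
        cfg = _cfg([sp], dt=1e-5, duration=1e-3, seed=5)
        (pos,) = simulate_trajectories(cfg)
        wrapped = wrap_positions(pos, cfg.box_side)
        assert wrapped.shape == pos.shape          # nothing lost
        assert np.all(np.abs(wrapped) <= cfg.box_side / 2 + 1e-9)


class TestFgn:
    def test_autocovariance_matches_closed_form(self):
        rng = np.random.default_rng(6)
        n, hurst, var = 1024, 0.35, 2.0
        paths = fgn_increments(n, hurst, var, rng, 400).astype(float)
        k = np.arange(4)
        gamma = 0.5 * var * ((k + 1.0)**(2 * hurst) - 2 * k**(2 * hurst)
                             + np.abs(k - 1.0)**(2 * hurst))
        for kk in k:
            emp = np.mean(paths[:, :n - kk] * paths[:, kk:] if kk else
                          paths**2)
            assert emp == pytest.approx(gamma[kk], abs=4 * var / np.sqrt(
                400 * n))

    def test_hurst_half_is_white_noise(self):
        rng = np.random.default_rng(7)
        paths = fgn_increments(512, 0.5, 1.0, rng, 100).astype(float)
        lag1 = np.mean(paths[:, :-1] * paths[:, 1:])
        assert abs(lag1) < 4 / np.sqrt(100 * 512)


class TestPhotonStream:
    def test_zero_brightness_gives_empty_stream(self):
        sp = SpeciesSpec("green_only", n_particles=100, D=25.0)
        s = simulate_photon_stream(_cfg([sp], duration=0.01, seed=8))
        assert s.total_counts() == 0

    def test_mean_rate_matches_mdf_integral(self):
        sp = SpeciesSpec("green_only", n_particles=500, D=25.0,
                         brightness_green=2e5)
        cfg = _cfg([sp], dt=4e-5, duration=2.0, seed=9)
        s = simulate_photon_stream(cfg)
        rate = s.total_counts(0) / cfg.duration
        expected = mean_rate_expected(cfg, 0)
        # diffusing-particle rate fluctuates beyond Poisson; allow 5%
        assert rate == pytest.approx(expected, rel=0.05)

    def test_crosstalk_fraction(self):
        # kappa = 0.1, no red brightness/background: 10% of photons in red
        sp = SpeciesSpec("green_only", n_particles=300, D=25.0,
                         brightness_green=2e5)
        cfg = _cfg([sp], dt=4e-5, duration=1.0, seed=10,
                   crosstalk_g_to_r=0.1)
        s = simulate_photon_stream(cfg)
        frac = s.total_counts(1) / s.total_counts()
        assert frac == pytest.approx(0.10, abs=0.01)

    def test_seed_determinism(self):
        sp = SpeciesSpec("dual", n_particles=60, D=25.0,
                         brightness_green=1e5, brightness_red=8e4)
        trip = TripletSpec(T_R=0.15, tau_R=5e-6)
        s1 = simulate_photon_stream(_cfg([sp], duration=0.02, seed=11,
                                         triplet=trip))
        s2 = simulate_photon_stream(_cfg([sp], duration=0.02, seed=11,
                                         triplet=trip))
        s3 = simulate_photon_stream(_cfg([sp], duration=0.02, seed=12,
                                         triplet=trip))
        np.testing.assert_array_equal(s1.counts, s2.counts)
        assert not np.array_equal(s1.counts, s3.counts)

    def test_dual_label_channels_correlated(self, dual_stream):
        _, s = dual_stream
        g = s.counts[:, 0].astype(float)
        r = s.counts[:, 1].astype(float)
        pearson = np.corrcoef(g, r)[0, 1]
        assert pearson > 0.9

    def test_overflow_guard(self):
        sp = SpeciesSpec("green_only", n_particles=100, D=25.0,
                         brightness_green=1e14)
        with pytest.raises(RuntimeError, match="1e6"):
            simulate_photon_stream(_cfg([sp], duration=0.001, seed=13))

    def test_timestamps_mode_validation(self):
        with pytest.raises(ValueError, match="decrease at index 2"):
            PhotonStream(timestamps={0: np.array([0.0, 1.0, 0.5])})

    def test_to_timestamps_conserves_counts(self):
        sp = SpeciesSpec("green_only", n_particles=100, D=25.0,
                         brightness_green=1e5)
        s = simulate_photon_stream(_cfg([sp], duration=0.01, seed=14))
        ts = s.to_timestamps(seed=0)
        assert ts.total_counts(0) == s.total_counts(0)
        assert np.all(np.diff(ts.timestamps[0]) >= 0)


class TestTriplet:
    def test_dark_occupancy_and_correlation_time(self):
        trip = TripletSpec(T_R=0.25, tau_R=5e-6)
        dt = 5e-7
        states = simulate_telegraph(trip, dt, n_steps=25000,
                                    n_particles=64, seed=15)
        dark = 1.0 - states.mean()
        assert dark == pytest.approx(0.25, abs=0.005)      # within 2%
        # autocorrelation of the state decays with time constant tau_R
        x = states.astype(float) - states.mean()
        def ac(k):
            return np.mean(x[:-k] * x[k:])
        k1, k2 = 4, 12
        tau_est = (k2 - k1) * dt / np.log(ac(k1) / ac(k2))
        assert tau_est == pytest.approx(5e-6, rel=0.2)


class TestReroute:
    def test_coupled_rerouting_monotone_and_conserving(self, small_stream):
        _, s = small_stream
        kappas = [0.0, 0.05, 0.1, 0.2]
        outs = reroute_crosstalk(s, kappas, seed=3)
        total = s.total_counts()
        reds = [o.total_counts(1) for o in outs]
        assert outs[0].total_counts(1) == s.total_counts(1)
        assert all(o.total_counts() == total for o in outs)
        assert np.all(np.diff(reds) > 0)
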