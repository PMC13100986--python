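"""Tests of binning and the direct / multi-tau correlators."""

import numpy as np
import pytest

from fcskit.correlate import (CorrelationCurve, IntensityTrace, bin_photons,
                              correlate_direct, correlate_multitau,
                              estimate_errors)
from fcskit.simulate import PhotonStream


def _trace(arr, width=1e-3):
    return IntensityTrace(np.asarray(arr), width)


class TestBinning:
    def test_direct_counting(self):
        s = PhotonStream(timestamps={0: np.array([0.5e-3, 1.5e-3, 1.6e-3])},
                         metadata={"duration": 3e-3})
        t = bin_photons(s, 1e-3)
        np.testing.assert_array_equal(t.counts[:, 0], [1, 2, 0])

    def test_rebin_conserves_counts(self):
        rng = np.random.default_rng(0)
        t = _trace(rng.poisson(3.0, size=1001))
        r = t.rebin(4)
        assert r.counts.sum() == t.counts[:1000].sum()
        np.testing.assert_array_equal(
            r.counts[:, 0], t.counts[:1000, 0].reshape(-1, 4).sum(axis=1))

    def test_poisson_rate_recovered(self):
        lam = 5e4
        rng = np.random.default_rng(1)
        n = 20000
        s = PhotonStream(counts=rng.poisson(lam * 1e-5, (n, 1)).astype(int),
                         bin_width=1e-5, metadata={"duration": n * 1e-5})
        t = bin_photons(s, 1e-4)
        mean = t.counts.mean()
        se = np.sqrt(lam * 1e-4 / t.n_bins)
        assert abs(mean - lam * 1e-4) < 3 * se

    def test_empty_stream_warns(self):
        s = PhotonStream(timestamps={0: np.array([])},
                         metadata={"duration": 1e-2})
        with pytest.warns(UserWarning, match="empty"):
            t = bin_photons(s, 1e-3)
        assert t.counts.sum() == 0

    def test_noninteger_rebin_rejected(self):
        s = PhotonStream(counts=np.ones((100, 1), int), bin_width=1e-5)
        with pytest.raises(ValueError, match="integer multiple"):
            bin_photons(s, 2.5e-5)


class TestDirect:
    def test_constant_trace_has_zero_correlation(self):
        c = correlate_direct(_trace([7] * 200), _trace([7] * 200),
                             max_lag=20e-3)
        np.testing.assert_allclose(c.G, 0.0, atol=1e-14)

    def test_alternating_trace_anticorrelated_at_lag_one(self):
        a = _trace(([1, 0] * 100))
        c = correlate_direct(a, a, max_lag=1.5e-3)
        assert c.G[0] == pytest.approx(-1.0)

    def test_iid_poisson_within_null_band(self):
        rng = np.random.default_rng(2)
        n = 10000
        a = _trace(rng.poisson(5.0, n))
        c = correlate_direct(a, a, max_lag=50e-3)
        assert np.all(np.abs(c.G) < 4 / np.sqrt(n))

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="zero mean"):
            correlate_direct(_trace([0] * 100), _trace([0] * 100),
                             max_lag=5e-3)


class TestMultitau:
    def test_matches_direct_at_every_stage(self):
        rng = np.random.default_rng(3)
        a = _trace(rng.poisson(4.0, 10000), width=1e-5)
        mt = correlate_multitau(a, a, m_channels=16)
        meta = mt.metadata
        # stage 0: native resolution
        direct = correlate_direct(a, a, max_lag=16e-5)
        np.testing.assert_allclose(mt.G[:16], direct.G, rtol=1e-10,
                                   atol=1e-12)
        # coarser stages: direct correlator on rebinned traces
        idx = 16
        for stage in range(1, meta["n_stages"]):
            r = a.rebin(2 ** stage)
            d = correlate_direct(r, r, max_lag=16 * r.bin_width)
            for k in range(9, 17):
                assert mt.G[idx] == pytest.approx(d.G[k - 1], rel=1e-10,
                                                  abs=1e-12)
                idx += 1
        assert idx == mt.lags.size

    def test_lag_grid_strictly_increasing_and_spans_duration(self):
        rng = np.random.default_rng(4)
        a = _trace(rng.poisson(4.0, 40000), width=1e-5)
        mt = correlate_multitau(a, a)
        assert np.all(np.diff(mt.lags) > 0)
        assert mt.lags[-1] >= 0.1 * a.duration * 0.5

    def test_decays_to_zero_on_simulated_stream(self, small_stream):
        cfg, s = small_stream
        t = bin_photons(s, cfg.dt).channel(0)
        mt = correlate_multitau(t, t)
        assert mt.G[0] > 0.2                      # finite amplitude
        assert abs(np.mean(mt.G[-5:])) < 0.02     # decayed at long lags

    def test_cross_symmetry_within_errors(self, dual_stream):
        cfg, s = dual_stream
        tr = bin_photons(s, cfg.dt)
        g, r = tr.channel(0), tr.channel(1)
        ab = estimate_errors(g, r, n_segments=8, channel_pair=(0, 1))
        ba = estimate_errors(r, g, n_segments=8, channel_pair=(1, 0))
        diff = np.abs(ab.G - ba.G)
        bound = 3 * np.sqrt(ab.sd**2 + ba.sd**2) + 1e-12
        assert (diff < bound).mean() > 0.95

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            correlate_multitau(_trace([1] * 20), _trace([1] * 20))


class TestErrors:
    def test_identical_segments_zero_sd(self):
        block = np.random.default_rng(5).poisson(4.0, 500)
        a = _trace(np.tile(block, 8))
        c = estimate_errors(a, a, n_segments=8)
        np.testing.assert_allclose(c.sd, 0.0, atol=1e-12)

    def test_sd_scales_with_segment_count(self):
        # at fixed segment length, the standard error of the mean curve
        # falls as 1/sqrt(n_segments)
        rng = np.random.default_rng(6)
        seg_len = 2500
        s5 = estimate_errors(_trace(rng.poisson(4.0, seg_len * 5)),
                             _trace(rng.poisson(4.0, seg_len * 5)),
                             n_segments=5)
        s20 = estimate_errors(_trace(rng.poisson(4.0, seg_len * 20)),
                              _trace(rng.poisson(4.0, seg_len * 20)),
                              n_segments=20)
        n = min(s5.lags.size, s20.lags.size)
        ratio = np.median(s5.sd[:n] / s20.sd[:n])
        # expected sqrt(20/5) = 2, within factor 1.5
        assert 2 / 1.5 < ratio < 2 * 1.5

    def test_single_segment_has_no_sd(self):
        a = _trace(np.random.default_rng(7).poisson(4.0, 2000))
        c = estimate_errors(a, a, n_segments=1)
        assert c.sd is None

    def test_curve_validation(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            CorrelationCurve(np.array([1e-3, 1e-3]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="positive"):
            CorrelationCurve(np.array([0.0, 1e-3]), np.array([1.0, 1.0]))
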