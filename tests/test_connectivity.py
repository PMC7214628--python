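import numpy as np
import pytest
from hypothesis import given, strategies as st

import piecewisefc as pfc
from piecewisefc.connectivity import band_freq_grid
from piecewisefc.errors import ParameterError

from .conftest import small_epochs


def _from_imag(im):
    """Cross-spectrum trial array (1 link, 1 freq, 1 sample, n trials)."""
    im = np.asarray(im, dtype=float)
    return (1.0 + 1j * im)[None, None, None, :] * 0 + 1j * im


def pli_oracle(z):
    """Direct evaluation: |mean over trials of sgn(Im z)|."""
    return abs(np.mean([np.sign(v.imag) for v in z]))


def wpli_oracle(z):
    """Direct evaluation: |mean Im| / mean |Im| (0 when denominator is 0)."""
    num = abs(np.mean([v.imag for v in z]))
    den = np.mean([abs(v.imag) for v in z])
    return 0.0 if den == 0 else num / den


class TestHandValues:
    @pytest.mark.parametrize("signs,expected", [
        ((1, 1, 1, 1), 1.0),
        ((1, 1, -1, -1), 0.0),
        ((1, 1, 1, -1), 0.5),
    ])
    def test_pli(self, signs, expected):
        assert pfc.pli(1j * np.array(signs, float)) == pytest.approx(
            expected, abs=1e-12)

    @pytest.mark.parametrize("im,expected", [
        ((2, 1, 1), 1.0),
        ((2, 1, -1), 0.5),
        ((1, -1), 0.0),
    ])
    def test_wpli(self, im, expected):
        assert pfc.wpli(1j * np.array(im, float)) == pytest.approx(
            expected, abs=1e-12)

    def test_wpli_zero_imag_defined_as_zero(self):
        assert pfc.wpli(np.array([1.0, 2.0, 3.0]) + 0j) == 0.0

    def test_single_trial_warns(self):
        with pytest.warns(UserWarning, match="single trial"):
            pfc.pli(np.array([1j]))


class TestOracleEquivalence:
    @given(seed=st.integers(0, 10 ** 6), n=st.integers(2, 10))
    def test_matches_direct_evaluation(self, seed, n):
        g = np.random.default_rng(seed)
        z = g.standard_normal(n) + 1j * g.standard_normal(n)
        assert pfc.pli(z) == pytest.approx(pli_oracle(z), abs=1e-12)
        assert pfc.wpli(z) == pytest.approx(wpli_oracle(z), abs=1e-12)

    @given(seed=st.integers(0, 10 ** 6))
    def test_bounds_and_sign_condition(self, seed):
        g = np.random.default_rng(seed)
        z = g.standard_normal(8) + 1j * g.standard_normal(8)
        p, w = pfc.pli(z), pfc.wpli(z)
        assert 0.0 <= p <= 1.0 and 0.0 <= w <= 1.0
        same_sign = np.all(z.imag > 0) or np.all(z.imag < 0)
        assert (w == pytest.approx(1.0, abs=1e-12)) == bool(same_sign)


class TestMorletCWT:
    def _sine(self, freq, fs=256.0, T=512, phase=0.0):
        t = np.arange(T) / fs
        return np.sin(2 * np.pi * freq * t + phase)

    def test_frequency_selectivity(self):
        fs, T = 256.0, 512
        data = np.broadcast_to(self._sine(10.0, fs, T)[None, :, None],
                               (1, T, 4)).copy()
        x = pfc.EpochedEEG(data, fs, np.array([0, 0, 1, 1]), ["a"], t0=0.0)
        W = pfc.morlet_cwt(x, [5.0, 10.0, 20.0])
        mid = slice(T // 2 - 32, T // 2 + 32)
        amps = np.abs(W.values[0, :, mid, 0]).mean(axis=1)
        assert np.argmax(amps) == 1
        # unit gain at the matching centre frequency
        assert amps[1] == pytest.approx(1.0, rel=0.02)

    def test_zero_signal_gives_zero(self):
        x = small_epochs(0).copy_with(data=np.zeros((3, 64, 12)))
        W = pfc.morlet_cwt(x, [10.0, 20.0])
        assert np.max(np.abs(W.values)) < 1e-12

    def test_quarter_period_delay_phase(self):
        fs, T, f0 = 256.0, 1024, 10.0
        a = self._sine(f0, fs, T)
        b = self._sine(f0, fs, T, phase=-np.pi / 2)  # delayed quarter period
        data = np.stack([a, b])[:, :, None] * np.ones((1, 1, 4))
        x = pfc.EpochedEEG(data, fs, np.array([0, 0, 1, 1]), ["a", "b"],
                           t0=0.0)
        W = pfc.morlet_cwt(x, [f0])
        S = pfc.cross_spectrum(W)
        mid = slice(T // 4, 3 * T // 4)
        angles = np.angle(S.values[0, 0, mid, 0])
        assert np.max(np.abs(angles - np.pi / 2)) < 0.1

    def test_parameter_validation(self):
        x = small_epochs(0)
        with pytest.raises(ParameterError):
            pfc.morlet_cwt(x, [])
        with pytest.raises(ParameterError):
            pfc.morlet_cwt(x, [100.0])  # above Nyquist for fs=128
        with pytest.raises(ParameterError):
            pfc.morlet_cwt(x, [10.0], cycles=2)

    def test_edge_mask_shrinks_with_frequency(self):
        x = small_epochs(0, T=256)
        W = pfc.morlet_cwt(x, [5.0, 20.0])
        valid = W.edge_valid()
        assert valid[1].sum() > valid[0].sum()


class TestCrossSpectrum:
    def test_complex_arithmetic_and_link_count(self):
        W = pfc.WaveletCoefficients(
            values=np.array([[[[1.0 + 0j]]], [[[0.0 + 1j]]]]),
            freqs=np.array([10.0]), times=np.array([0.0]), fs=100.0,
            cycles=7.0)
        S = pfc.cross_spectrum(W)
        assert S.values.shape[0] == 1  # self-pairs excluded
        assert S.values[0, 0, 0, 0] == pytest.approx(-1j)

    def test_swapping_channels_conjugates(self, rng):
        vals = rng.standard_normal((3, 2, 4, 5)) \
            + 1j * rng.standard_normal((3, 2, 4, 5))
        W = pfc.WaveletCoefficients(vals, np.array([5.0, 10.0]),
                                    np.arange(4) / 100, 100.0, 7.0)
        Wswap = pfc.WaveletCoefficients(vals[[1, 0, 2]],
                                        np.array([5.0, 10.0]),
                                        np.arange(4) / 100, 100.0, 7.0)
        S = pfc.cross_spectrum(W)
        Sswap = pfc.cross_spectrum(Wswap)
        np.testing.assert_allclose(Sswap.values[0], np.conj(S.values[0]))

    def test_metric_symmetric_in_channel_order(self, rng):
        vals = rng.standard_normal((2, 1, 3, 8)) \
            + 1j * rng.standard_normal((2, 1, 3, 8))
        mk = lambda v: pfc.WaveletCoefficients(v, np.array([6.0]),
                                               np.arange(3) / 100, 100.0, 7.0)
        for fn in (pfc.pli, pfc.wpli):
            y = fn(pfc.cross_spectrum(mk(vals)).values)
            y_sw = fn(pfc.cross_spectrum(mk(vals[::-1])).values)
            np.testing.assert_allclose(y, y_sw, atol=1e-12)

    def test_unit_normalized_variant_collapses_wpli_onto_pli(self, rng):
        vals = rng.standard_normal((2, 1, 3, 10)) \
            + 1j * rng.standard_normal((2, 1, 3, 10))
        W = pfc.WaveletCoefficients(vals, np.array([6.0]),
                                    np.arange(3) / 100, 100.0, 7.0)
        Sn = pfc.cross_spectrum(W, normalize=True)
        S = pfc.cross_spectrum(W)
        np.testing.assert_allclose(
            pfc.wpli(Sn.values, weight="magnitude"), pfc.pli(S.values),
            atol=1e-12)


class TestBandAverage:
    def test_closed_interval_membership(self):
        freqs = np.array([5.0, 6.0, 7.0, 8.0])
        y = np.array([0.1, 0.2, 0.3, 0.4])[None, :, None]
        out = pfc.band_average(y, freqs, "theta")
        assert out[0, 0] == pytest.approx(0.25)

    def test_single_bin_identity(self):
        y = np.array([[[0.7]]])
        assert pfc.band_average(y, [6.0], "theta")[0, 0] == 0.7

    def test_empty_band_rejected(self):
        with pytest.raises(ParameterError, match="no frequency bin"):
            pfc.band_average(np.ones((1, 1, 1)), [25.0], "theta")


class TestBaselineNormalize:
    def _series(self, values):
        return pfc.ConnectivitySeries(
            values=np.asarray(values, float), times=np.linspace(-0.2, 0.8, 10),
            band=pfc.DEFAULT_BANDS["theta"], metric="wpli")

    def test_constant_maps_to_zero(self):
        cs = self._series(np.full((2, 10), 0.3))
        out = pfc.baseline_normalize_fc(cs)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_subtracts_baseline_and_clips(self):
        vals = np.full((1, 10), 0.2)
        vals[0, 5:] = 0.5
        vals[0, 4] = 0.05  # dips below baseline mean -> clipped to 0
        cs = self._series(vals)
        out = pfc.baseline_normalize_fc(cs)
        np.testing.assert_allclose(out.values[0, 5:], 0.3)
        assert out.values[0, 4] == 0.0

    def test_noop_mode(self):
        cs = self._series(np.full((1, 10), 0.4))
        assert pfc.baseline_normalize_fc(cs, mode="none") is cs


class TestSubjectConnectivity:
    def test_condition_split_matches_trial_counts(self):
        x = small_epochs(5, C=3, T=128, N=20, fs=128.0)
        out = pfc.subject_connectivity(x, "theta", rng=0)
        assert set(out) == {0, 1}
        for cs in out.values():
            assert cs.values.shape == (3, 128)
            assert np.all((cs.values >= 0) & (cs.values <= 1))

    def test_band_grid_closed_edges(self):
        np.testing.assert_array_equal(band_freq_grid("theta"),
                                      [5.0, 6.0, 7.0, 8.0])
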