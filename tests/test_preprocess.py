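"""Epoching, artifact rejection, PSD and band-pass filtering."""

import numpy as np
import pytest

from srcnet import (
    EpochSet,
    band_table,
    bandpass,
    get_band,
    psd_periodogram,
    reject_amplitude,
    reject_theta_alpha,
    segment_epochs,
    select_epochs,
)
from srcnet.preprocess import BandDefinition, band_power

FS = 1000.0


def sinusoid_epochs(freqs, fs=FS, seconds=2.0, amplitude=1.0):
    """One epoch per frequency, single node."""
    t = np.arange(int(fs * seconds)) / fs
    data = np.stack([amplitude * np.cos(2 * np.pi * f * t)[None, :] for f in freqs])
    return EpochSet(data=data, fs=fs)


class TestBandTable:
    def test_canonical_bands(self):
        table = band_table()
        assert len(table) == 11
        edges = {b.name: (b.low, b.high) for b in table}
        assert edges["delta"] == (1, 4)
        assert edges["theta"] == (4, 8)
        assert edges["alpha"] == (8, 12)
        assert edges["alpha1"] == (8, 10)
        assert edges["alpha2"] == (10, 12)
        assert edges["beta"] == (12, 30)
        assert edges["beta1"] == (12, 18)
        assert edges["beta2"] == (18, 22)
        assert edges["beta3"] == (22, 30)
        assert edges["beta4"] == (18, 30)
        assert edges["gamma"] == (30, 55)

    def test_unknown_band(self):
        with pytest.raises(KeyError):
            get_band("mu")

    def test_invalid_edges(self):
        with pytest.raises(ValueError):
            BandDefinition("bad", 10, 5)


class TestSegmentation:
    @pytest.mark.parametrize(
        "seconds,expected_epochs", [(60.0, 30), (3.5, 1), (2.0, 1), (4.1, 2)]
    )
    def test_epoch_count(self, seconds, expected_epochs):
        cont = np.zeros((3, int(FS * seconds)))
        es = segment_epochs(cont, FS, epoch_seconds=2.0)
        assert es.n_epochs == expected_epochs
        assert es.n_samples == 2000

    def test_too_short(self):
        with pytest.raises(ValueError):
            segment_epochs(np.zeros((2, 1900)), FS, epoch_seconds=2.0)

    def test_temporal_order(self):
        cont = np.arange(4000, dtype=float)[None, :]
        es = segment_epochs(cont, FS, 2.0)
        assert es.data[0, 0, 0] == 0 and es.data[1, 0, 0] == 2000


class TestAmplitudeRejection:
    def test_exceeding_epoch_removed(self, rng):
        data = rng.uniform(-50, 50, size=(5, 4, 200))
        data[2, 1, 17] = 150.0
        kept, mask = reject_amplitude(EpochSet(data=data, fs=FS), limit=100.0)
        assert kept.n_epochs == 4
        assert mask.tolist() == [True, True, False, True, True]

    def test_all_within_limit_kept(self, rng):
        data = rng.uniform(-99, 99, size=(6, 3, 100))
        kept, mask = reject_amplitude(EpochSet(data=data, fs=FS))
        assert kept.n_epochs == 6 and mask.all()

    def test_boundary_is_strict(self):
        data = np.zeros((1, 2, 100))
        data[0, 0, 5] = 100.0  # exactly at the limit: "exceeding" means >
        kept, mask = reject_amplitude(EpochSet(data=data, fs=FS), limit=100.0)
        assert kept.n_epochs == 1

    def test_idempotent(self, rng):
        data = rng.uniform(-50, 50, size=(5, 2, 100))
        data[0] += 300
        once, _ = reject_amplitude(EpochSet(data=data, fs=FS))
        twice, mask2 = reject_amplitude(once)
        assert mask2.all()
        np.testing.assert_array_equal(once.data, twice.data)


class TestPeriodogram:
    def test_peak_at_tone_frequency(self):
        es = sinusoid_epochs([10.0])
        freqs, psd = psd_periodogram(es.data[0], FS)
        assert freqs[np.argmax(psd[0])] == pytest.approx(10.0)

    def test_zero_signal(self):
        freqs, psd = psd_periodogram(np.zeros((2, 1000)), FS)
        assert np.all(psd == 0)

    def test_parseval_white_noise(self, rng):
        x = rng.normal(0, 1, size=(1, 4000))
        freqs, psd = psd_periodogram(x, FS)
        df = freqs[1] - freqs[0]
        total = psd.sum() * df
        assert total == pytest.approx(np.mean(x**2), rel=1e-6)

    def test_matches_direct_dft_oracle(self, rng):
        # independent oracle: periodogram from the explicit DFT definition
        x = rng.normal(size=512)
        n = len(x)
        dft = np.array([np.sum(x * np.exp(-2j * np.pi * k * np.arange(n) / n))
                        for k in range(n // 2 + 1)])
        oracle = np.abs(dft) ** 2 / (n * FS)
        oracle[1:-1] *= 2  # one-sided
        _, psd = psd_periodogram(x[None, :], FS)
        np.testing.assert_allclose(psd[0], oracle, atol=1e-10)


class TestThetaAlphaRejection:
    def test_alpha_dominant_kept(self):
        es = sinusoid_epochs([10.0])
        kept, mask = reject_theta_alpha(es)
        assert mask.all()

    def test_theta_dominant_removed(self):
        es = sinusoid_epochs([6.0])
        kept, mask = reject_theta_alpha(es)
        assert kept.n_epochs == 0  # theta/alpha ratio >> 1

    def test_equal_power_kept_strict(self):
        t = np.arange(2000) / FS
        sig = np.cos(2 * np.pi * 6 * t) + np.cos(2 * np.pi * 10 * t)
        es = EpochSet(data=sig[None, None, :], fs=FS)
        kept, mask = reject_theta_alpha(es, threshold=1.0)
        assert mask.all()  # ratio ~= 1, strict > keeps it

    def test_zero_alpha_power_removed_with_warning(self):
        es = sinusoid_epochs([6.0])
        es.data[0] -= es.data[0]  # zero signal: zero alpha power
        with pytest.warns(UserWarning):
            _, mask = reject_theta_alpha(es)
        assert not mask.any()


class TestSelectEpochs:
    def test_deterministic_under_seed(self, rng):
        es = EpochSet(data=rng.normal(size=(40, 2, 100)), fs=FS)
        a = select_epochs(es, k=30, seed=7)
        b = select_epochs(es, k=30, seed=7)
        np.testing.assert_array_equal(a.data, b.data)
        assert a.n_epochs == 30

    def test_exactly_k_keeps_all(self, rng):
        es = EpochSet(data=rng.normal(size=(30, 2, 50)), fs=FS)
        sel = select_epochs(es, k=30, seed=0)
        np.testing.assert_array_equal(sel.data, es.data)

    def test_too_few_strict_raises(self, rng):
        es = EpochSet(data=rng.normal(size=(29, 2, 50)), fs=FS)
        with pytest.raises(ValueError):
            select_epochs(es, k=30, seed=0)
        with pytest.warns(UserWarning):
            sel = select_epochs(es, k=30, seed=0, allow_fewer=True)
        assert sel.n_epochs == 29

    def test_preserves_labels_and_fs(self, rng):
        es = EpochSet(data=rng.normal(size=(10, 2, 50)), fs=FS, node_labels=["a", "b"])
        sel = select_epochs(es, k=5, seed=1)
        assert sel.node_labels == ["a", "b"] and sel.fs == FS


class TestBandpass:
    def gain(self, f, band_name, fs=FS):
        t = np.arange(int(fs * 2)) / fs
        es = EpochSet(data=np.cos(2 * np.pi * f * t)[None, None, :], fs=fs)
        out = bandpass(es, get_band(band_name))
        mid = out.data[0, 0, 400:-400]
        return np.sqrt(2 * np.mean(mid**2))  # sinusoid amplitude from RMS

    def test_in_band_unity_gain(self):
        assert 0.9 < self.gain(10.0, "alpha") < 1.1

    def test_out_of_band_attenuation(self):
        assert self.gain(10.0, "gamma") < 0.1

    def test_dc_through_delta(self):
        es = EpochSet(data=np.full((1, 1, 2000), 5.0), fs=FS)
        out = bandpass(es, get_band("delta"))
        assert np.max(np.abs(out.data)) < 0.05

    def test_linearity(self, rng):
        es = EpochSet(data=rng.normal(size=(2, 3, 1000)), fs=FS)
        out1 = bandpass(es, get_band("beta"))
        out3 = bandpass(es.copy_with(3.0 * es.data), get_band("beta"))
        np.testing.assert_allclose(3.0 * out1.data, out3.data, atol=1e-9)

    def test_band_above_nyquist(self):
        es = EpochSet(data=np.random.default_rng(0).normal(size=(1, 1, 200)), fs=100.0)
        with pytest.raises(ValueError):
            bandpass(es, get_band("gamma"))
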