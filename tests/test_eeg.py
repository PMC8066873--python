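"""EEG filtering, channel QC, band envelopes and ICA cleaning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nvcpipe.eeg import (
    BandDefinition,
    EEGRecording,
    band_power_envelope,
    band_power_envelopes,
    canonical_bands,
    filter_eeg,
    qc_channels,
    remove_artifacts_ica,
)
from nvcpipe.errors import DataError, NumericalError, ParameterError

FS = 250.0


def _rec(data, fs=FS, **kw):
    return EEGRecording(np.asarray(data, dtype=float), fs, **kw)


def _sine(freq, n=5000, fs=FS, amp=1.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / fs)


def _central(x, frac=0.2):
    k = int(len(x) * frac)
    return x[k:-k]


class TestFilterEEG:
    def test_dc_is_removed(self):
        rec = _rec(np.full((4, 5000), 7.5))
        out = filter_eeg(rec)
        assert np.abs(out.data).max() < 1e-6 * 7.5

    @pytest.mark.parametrize("method", ["fft", "filtfilt"])
    def test_10hz_passband_gain(self, method):
        rec = _rec(np.tile(_sine(10.0), (4, 1)))
        out = filter_eeg(rec, method=method)
        amp = np.abs(_central(out.data[0])).max()
        assert abs(amp - 1.0) < 0.05

    @pytest.mark.parametrize("method", ["fft", "filtfilt"])
    def test_50hz_notch_attenuation(self, method):
        rec = _rec(np.tile(_sine(50.0), (4, 1)))
        out = filter_eeg(rec, method=method)
        assert np.abs(_central(out.data[0])).max() < 0.1

    def test_fft_and_filtfilt_agree_in_interior(self, rng):
        rec = _rec(rng.standard_normal((4, 5000)))
        a = filter_eeg(rec, method="fft").data
        b = filter_eeg(rec, method="filtfilt").data
        inner = slice(500, 4500)
        rms = np.sqrt(np.mean((a[:, inner] - b[:, inner]) ** 2))
        assert rms < 0.05 * b[:, inner].std()

    def test_low_sampling_rate_rejected(self):
        rec = _rec(np.zeros((4, 1000)), fs=120.0)
        with pytest.raises(ParameterError):
            filter_eeg(rec)

    def test_in_band_filtering_near_idempotent(self, rng):
        """Filtering a signal already inside the pass-band changes its RMS by < 5%."""
        from nvcpipe._filters import butter_bandpass_sos, zero_phase_filter

        inband = zero_phase_filter(
            rng.standard_normal((4, 10000)), butter_bandpass_sos(5.0, 40.0, FS, 4), FS, "filtfilt"
        )
        rec = _rec(inband)
        out = filter_eeg(rec)
        inner = slice(1000, 9000)
        r1 = np.sqrt(np.mean(rec.data[:, inner] ** 2))
        r2 = np.sqrt(np.mean(out.data[:, inner] ** 2))
        assert abs(r2 - r1) / r1 < 0.05


class TestBandEnvelope:
    ALPHA = BandDefinition("alpha", 7.4, 13.0)
    THETA = BandDefinition("theta", 3.5, 8.2)

    @pytest.mark.parametrize("method", ["fft", "filtfilt"])
    def test_constant_amplitude_carrier(self, method):
        amp = 3.0
        rec = _rec(np.tile(_sine(10.0, amp=amp), (4, 1)))
        env = band_power_envelope(rec, self.ALPHA, method=method).envelope
        assert np.allclose(_central(env[0]), amp, rtol=0.05)

    def test_am_modulator_recovered(self):
        n = 50000
        t = np.arange(n) / FS
        modulator = 1.0 + 0.5 * np.sin(2 * np.pi * 0.1 * t)
        carrier = modulator * np.sin(2 * np.pi * 10.0 * t)
        rec = _rec(np.tile(carrier, (4, 1)))
        env = band_power_envelope(rec, self.ALPHA).envelope[0]
        r = np.corrcoef(_central(env), _central(modulator))[0, 1]
        assert r > 0.95

    def test_out_of_band_attenuation(self):
        rec = _rec(np.tile(_sine(20.0), (4, 1)))
        env = band_power_envelope(rec, self.THETA).envelope
        assert _central(env[0]).max() < 0.05

    def test_band_outside_nyquist_rejected(self):
        rec = _rec(np.zeros((4, 1000)), fs=50.0)
        with pytest.raises(ParameterError):
            band_power_envelope(rec, BandDefinition("beta", 13.0, 30.0))

    def test_inverted_band_rejected(self):
        with pytest.raises(ParameterError):
            BandDefinition("bad", 13.0, 7.4)

    def test_decimated_envelope_matches_full_rate(self, rng):
        rec = _rec(rng.standard_normal((4, 15000)))
        full = band_power_envelopes(rec, [self.ALPHA])["alpha"]
        dec = band_power_envelopes(rec, [self.ALPHA], decim=3)["alpha"]
        assert dec.fs == pytest.approx(FS / 3)
        # decimated samples are the full-rate envelope at every 3rd point
        sub = full.envelope[:, :: 3][:, : dec.envelope.shape[1]]
        inner = slice(200, -200)
        err = np.abs(dec.envelope[:, inner] - sub[:, inner]).max()
        assert err < 0.02 * full.envelope.std()

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(4, 8), st.integers(600, 1200))
    def test_envelope_nonnegative_and_shape_preserving(self, seed, n_ch, n_s):
        data = np.random.default_rng(seed).standard_normal((n_ch, n_s))
        rec = _rec(data)
        env = band_power_envelope(rec, self.ALPHA).envelope
        assert env.shape == data.shape
        assert (env >= 0).all()

    def test_band_power_budget_on_white_noise(self, rng):
        """Band envelope mean squares sum to less than total signal power."""
        rec = filter_eeg(_rec(rng.standard_normal((4, 20000))))
        envs = band_power_envelopes(rec, canonical_bands())
        total = np.mean(rec.data**2)
        band_sum = sum(np.mean(_central(e.envelope[0]) ** 2) for e in envs.values())
        assert band_sum < total


class TestChannelQC:
    def test_clean_data_untouched(self, rng):
        rec = _rec(rng.standard_normal((6, 1000)))
        out, rejected = qc_channels(rec)
        assert rejected == [] and out is rec

    def test_saturated_and_flat_channels_dropped(self, rng):
        data = rng.standard_normal((6, 1000))
        data[1] = 600.0  # flat AND saturated
        data[4, 500] = 1000.0  # single excursion
        out, rejected = qc_channels(_rec(data))
        assert set(rejected) == {"E2", "E5"}
        assert out.n_channels == 4

    def test_select_channels_by_label_and_seeded_draw(self, rng):
        rec = _rec(rng.standard_normal((8, 500)))
        sub = rec.select_channels(labels=["E3", "E5", "E7", "E8"])
        assert sub.channel_labels == ["E3", "E5", "E7", "E8"]
        a = rec.select_channels(n=4, seed=9)
        b = rec.select_channels(n=4, seed=9)
        assert a.channel_labels == b.channel_labels


class TestICA:
    @staticmethod
    def _mixed_rec(rng, n_ch=16, n_s=15000):
        latents = rng.standard_normal((3, n_s))
        from scipy.signal import sosfiltfilt

        from nvcpipe._filters import butter_bandpass_sos

        for i, (lo, hi) in enumerate([(3.5, 8.2), (7.4, 13.0), (13.0, 30.0)]):
            latents[i] = sosfiltfilt(butter_bandpass_sos(lo, hi, FS, 4), latents[i])
        mix = rng.uniform(0.5, 1.5, size=(n_ch, 3))
        data = mix @ latents + 0.3 * rng.standard_normal((n_ch, n_s))
        pos = np.column_stack([np.zeros(n_ch), np.linspace(-1, 1, n_ch)])
        return EEGRecording(data, FS, channel_positions=pos)

    def test_no_artifacts_means_no_flags(self, rng):
        rec = self._mixed_rec(rng)
        cleaned, report = remove_artifacts_ica(rec, seed=0)
        assert report.flagged == []
        for i in range(rec.n_channels):
            assert np.corrcoef(cleaned.data[i], rec.data[i])[0, 1] > 0.99

    def test_blink_like_artifact_removed(self, rng):
        rec = self._mixed_rec(rng)
        t = np.arange(rec.n_samples) / FS
        art = np.zeros(rec.n_samples)
        for t0 in np.arange(2.0, 58.0, 4.0):
            art += np.exp(-0.5 * ((t - t0) / 0.15) ** 2)
        art *= 100.0  # 100 uV ocular transients
        frontal_weight = np.exp(-((rec.channel_positions[:, 1] - 1.0) ** 2) / 0.3)
        dirty = EEGRecording(
            rec.data + np.outer(frontal_weight, art), FS, channel_positions=rec.channel_positions
        )
        before = max(abs(np.corrcoef(dirty.data[i], art)[0, 1]) for i in range(dirty.n_channels))
        cleaned, report = remove_artifacts_ica(dirty, seed=0)
        after = max(abs(np.corrcoef(cleaned.data[i], art)[0, 1]) for i in range(dirty.n_channels))
        assert before > 0.8
        assert len(report.flagged) >= 1
        assert after < 0.2

    def test_degenerate_input_rejected(self):
        with pytest.raises((NumericalError, DataError)):
            remove_artifacts_ica(_rec(np.random.default_rng(0).standard_normal((4, 10))))
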