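"""Time-frequency tests: Morlet amplitude, artifact bins, percent change."""

import numpy as np
import pytest

from gammaswitch.datatypes import ElectrodeSite, EpochSet, HGASeries, TFRResult
from gammaswitch.timefreq import (
    TFRConfig,
    mark_artifact_bins,
    morlet_amplitude,
    percent_change,
    roi_aggregate,
)

SF = 1000.0


def make_epochs(data):
    data = np.asarray(data, dtype=float)
    return EpochSet(
        data=data,
        sfreq=SF,
        ch_names=[f"CH{i}" for i in range(data.shape[1])],
        alignment=data.shape[2] // 2,
        kind="gameplay",
    )


def oracle_amplitude(sig, freq, sfreq, n_cycles=7.0):
    """Independent frequency-domain Morlet amplitude.

    Builds the wavelet from its analytic definition (Gaussian envelope
    of width n_cycles/(2*pi*f), complex carrier, unit discrete L2 norm)
    and convolves by pointwise multiplication of zero-padded FFTs.
    """
    sigma_t = n_cycles / (2 * np.pi * freq)
    half = int(np.ceil(4 * sigma_t * sfreq))
    t = np.arange(-half, half + 1) / sfreq
    w = np.exp(-(t**2) / (2 * sigma_t**2)) * np.exp(2j * np.pi * freq * t)
    w = w / np.sqrt(np.sum(np.abs(w) ** 2))
    n = sig.size + w.size - 1
    conv = np.fft.ifft(np.fft.fft(sig, n) * np.fft.fft(w, n))
    start = (w.size - 1) // 2
    return np.abs(conv[start : start + sig.size])


class TestMorlet:
    def test_zero_signal_zero_amplitude(self):
        tfr = morlet_amplitude(make_epochs(np.zeros((1, 1, 2400))))
        assert np.allclose(tfr.amplitude, 0.0)

    @pytest.mark.parametrize("amp", [1.0, 2.0, 5.0])
    def test_sinusoid_linearity_and_peak(self, amp):
        """Amplitude at the 90 Hz bin is proportional to the input
        amplitude and peaks at the 90 Hz bin."""
        t = np.arange(2400) / SF
        sig = amp * np.sin(2 * np.pi * 90 * t)
        tfr = morlet_amplitude(make_epochs(sig[None, None, :]))
        fi = int(np.flatnonzero(tfr.freqs == 90.0)[0])
        mid = slice(90, 150)
        readout = tfr.amplitude[0, 0, fi, mid].mean()
        base = morlet_amplitude(
            make_epochs(np.sin(2 * np.pi * 90 * t)[None, None, :])
        ).amplitude[0, 0, fi, mid].mean()
        assert readout == pytest.approx(amp * base, rel=1e-9)
        assert tfr.freqs[tfr.amplitude[0, 0, :, 120].argmax()] == 90.0

    def test_agreement_with_fft_oracle(self, rng):
        """Morlet amplitude matches a direct frequency-domain convolution
        oracle within 1% relative error on random signals."""
        for _ in range(20):
            sig = rng.standard_normal(2400)
            tfr = morlet_amplitude(make_epochs(sig[None, None, :]))
            for fi, f in enumerate(tfr.freqs):
                ours = tfr.amplitude[0, 0, fi]
                ref = oracle_amplitude(sig, f, SF)[::10]
                ok = ~tfr.artifact_mask[0, 0, fi]
                rel = np.abs(ours[ok] - ref[ok]) / ref[ok].max()
                assert rel.max() < 0.01

    def test_tone_burst_localized(self):
        """A 90 Hz burst at 300-500 ms elevates high-gamma amplitude in
        that window and nowhere far from it."""
        t = np.arange(2400) / SF
        sig = np.zeros(2400)
        on, off = 1500, 1700  # +300..+500 ms (cue at center sample 1200)
        sig[on:off] = np.sin(2 * np.pi * 90 * t[on:off])
        tfr = morlet_amplitude(make_epochs(sig[None, None, :]))
        fi = int(np.flatnonzero(tfr.freqs == 90.0)[0])
        times = tfr.times_ms
        inside = tfr.amplitude[0, 0, fi, (times > 320) & (times < 480)]
        outside = tfr.amplitude[0, 0, fi, (times > -800) & (times < 100)]
        assert inside.mean() > 10 * outside.mean()

    def test_epoch_too_short(self):
        with pytest.raises(ValueError, match="too short"):
            morlet_amplitude(make_epochs(np.zeros((1, 1, 100))))

    def test_white_noise_flat_across_frequencies(self, rng):
        """Unit-energy wavelets give approximately flat mean amplitude
        across frequency bins for white noise."""
        tfr = morlet_amplitude(make_epochs(rng.standard_normal((30, 1, 2400))))
        m = np.ma.MaskedArray(tfr.amplitude, tfr.artifact_mask).mean(axis=(0, 1, 3))
        assert (m.max() - m.min()) / m.mean() < 0.1


class TestArtifactMask:
    def test_constant_amplitude_nothing_masked(self):
        """All z-scores are zero for a constant-amplitude result, so the
        artifact rule masks no bins."""
        tfr = flat_tfr(2.0)
        marked = mark_artifact_bins(tfr)
        assert int(marked.artifact_mask.sum()) == 0

    def test_spike_bins_masked_at_latency(self, rng):
        """A broadband transient is masked at its latency, and the
        surviving high-gamma mean there comes from unmasked bins."""
        data = 0.1 * rng.standard_normal((8, 1, 2400))
        data[0, 0, 1190:1210] += 30.0 * rng.standard_normal(20)
        tfr = mark_artifact_bins(morlet_amplitude(make_epochs(data)))
        times = tfr.times_ms
        lo, hi = TFRConfig().artifact_band
        band = (tfr.freqs >= lo) & (tfr.freqs <= hi)
        at_spike = tfr.artifact_mask[0, 0][np.ix_(band, (times > -50) & (times < 50))]
        assert at_spike.any()
        far = tfr.artifact_mask[1, 0][np.ix_(band, (times > -50) & (times < 50))]
        assert far.mean() < 0.2

    def test_degenerate_threshold_surfaces_error(self, rng):
        """Threshold 0 with an artifact band covering the whole range
        masks everything, and the downstream baseline mean errors out."""
        cfg = TFRConfig(artifact_band=(30.0, 110.0), artifact_z_threshold=0.0)
        data = rng.standard_normal((3, 1, 2400))
        tfr = mark_artifact_bins(morlet_amplitude(make_epochs(data), cfg), cfg)
        with pytest.raises(ValueError, match="baseline"):
            percent_change(tfr, mode="vs_gameplay_mean", config=cfg)


def flat_tfr(value, n_epochs=2, n_ch=1, n_bins=10):
    freqs = TFRConfig().freqs
    amp = np.full((n_epochs, n_ch, freqs.size, n_bins), float(value))
    return TFRResult(
        amplitude=amp,
        artifact_mask=np.zeros_like(amp, dtype=bool),
        freqs=freqs,
        times_ms=np.arange(n_bins) * 10.0,
        ch_names=[f"CH{i}" for i in range(n_ch)],
    )


class TestPercentChange:
    def test_equal_to_reference_is_zero(self):
        out = percent_change(flat_tfr(2.0), flat_tfr(2.0), "vs_reference")
        np.testing.assert_allclose(out.data, 0.0)

    def test_ratio_one_point_five_is_fifty_percent(self):
        out = percent_change(flat_tfr(3.0), flat_tfr(2.0), "vs_reference")
        np.testing.assert_allclose(out.data, 50.0)

    def test_gameplay_mean_mode_centers_at_zero(self, rng):
        data = rng.standard_normal((6, 2, 2400))
        tfr = morlet_amplitude(make_epochs(data))
        out = percent_change(tfr, mode="vs_gameplay_mean")
        assert np.nanmean(out.data, axis=(0, 2)) == pytest.approx(
            np.zeros(2), abs=1e-8
        )

    def test_reference_required(self):
        with pytest.raises(ValueError, match="reference"):
            percent_change(flat_tfr(1.0), None, "vs_reference")

    def test_scale_equivariance(self, rng):
        """Scaling the input signal scales amplitudes but leaves the
        percent-change series unchanged."""
        data = rng.standard_normal((4, 1, 2400))
        ref = rng.standard_normal((4, 1, 2400))
        t1 = morlet_amplitude(make_epochs(data))
        t2 = morlet_amplitude(make_epochs(3.0 * data))
        np.testing.assert_allclose(t2.amplitude, 3.0 * t1.amplitude, rtol=1e-9)
        r1 = morlet_amplitude(make_epochs(ref))
        r2 = morlet_amplitude(make_epochs(3.0 * ref))
        p1 = percent_change(t1, r1, "vs_reference")
        p2 = percent_change(t2, r2, "vs_reference")
        np.testing.assert_allclose(p1.data, p2.data, rtol=1e-6, atol=1e-8)


def hga_series(values, labels):
    values = np.asarray(values, dtype=float)
    return HGASeries(
        data=values,
        times_ms=np.arange(values.shape[2]) * 10.0,
        labels=labels,
        mode="vs_reference",
    )


def site(label, roi):
    return ElectrodeSite(label, (0.0, 0.0, 0.0), roi, "right")


class TestRoiAggregate:
    def test_single_channel_roi_identity(self, rng):
        vals = rng.standard_normal((3, 1, 5))
        out = roi_aggregate(hga_series(vals, ["CH0"]), [site("CH0", "precuneus_right")])
        np.testing.assert_allclose(out.data[:, 0, :], vals[:, 0, :])
        assert out.unit_counts == {"precuneus_right": 1}

    def test_two_channel_mean(self):
        vals = np.stack([np.full((1, 5), 10.0), np.full((1, 5), 30.0)], axis=1)
        out = roi_aggregate(
            hga_series(vals, ["CH0", "CH1"]),
            [site("CH0", "roi_a"), site("CH1", "roi_a")],
        )
        np.testing.assert_allclose(out.data, 20.0)

    def test_many_rois_all_present(self, rng):
        """A montage populating 56 ROIs yields 56 output series."""
        labels = [f"CH{i}" for i in range(56)]
        montage = [site(l, f"roi_{i:02d}") for i, l in enumerate(labels)]
        out = roi_aggregate(hga_series(rng.standard_normal((2, 56, 4)), labels), montage)
        assert len(out.labels) == 56

    def test_excluded_channels_ignored(self, rng):
        vals = rng.standard_normal((2, 2, 4))
        montage = [
            site("CH0", "roi_a"),
            ElectrodeSite("CH1", (0, 0, 0), "roi_a", "right", exclusion_reason="artifact"),
        ]
        out = roi_aggregate(hga_series(vals, ["CH0", "CH1"]), montage)
        np.testing.assert_allclose(out.data[:, 0, :], vals[:, 0, :])
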