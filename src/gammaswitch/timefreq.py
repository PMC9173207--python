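"""Morlet wavelet amplitude, artifact-bin rejection, and percent change.

Signals are decomposed with 7-cycle complex Morlet wavelets at 5-Hz
centers over 30-110 Hz, sampled every 10 ms.  The modulus of the
convolution is the band amplitude (proportional to the square root of
band power).  Wavelets are discretely L2-normalized (unit energy) so
white noise yields a flat mean amplitude across frequency bins and
amplitudes are comparable across frequencies.

Artifact handling follows a two-stage mask: (i) edge bins whose wavelet
half-support leaves the epoch, and (ii) bins in the 30-85 Hz band whose
amplitude z-score (per channel and frequency, across all time bins and
epochs of a patient) exceeds |2| - a guard against interictal spikes.

High-gamma (70-110 Hz) amplitude is averaged over unmasked frequency
bins per time bin and expressed as percent change against either the
non-gameplay reference mean or the gameplay-period mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import fftconvolve

from .datatypes import ElectrodeSite, EpochSet, HGASeries, TFRResult


@dataclass
class TFRConfig:
    freq_min: float = 30.0
    freq_max: float = 110.0
    freq_step: float = 5.0
    n_cycles: float = 7.0
    time_step_ms: float = 10.0
    high_gamma_band: tuple[float, float] = (70.0, 110.0)
    artifact_band: tuple[float, float] = (30.0, 85.0)
    artifact_z_threshold: float = 2.0

    def __post_init__(self) -> None:
        for lo, hi in (self.high_gamma_band, self.artifact_band):
            if lo < self.freq_min or hi > self.freq_max:
                raise ValueError("analysis bands must lie within [freq_min, freq_max]")

    @property
    def freqs(self) -> np.ndarray:
        return np.arange(self.freq_min, self.freq_max + self.freq_step / 2, self.freq_step)


def morlet_wavelet(freq: float, sfreq: float, n_cycles: float = 7.0) -> np.ndarray:
    """Discrete complex Morlet wavelet, unit L2 norm, support +-4 sigma_t."""
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(4.0 * sigma_t * sfreq))
    t = np.arange(-half, half + 1) / sfreq
    w = np.exp(-(t**2) / (2 * sigma_t**2)) * np.exp(2j * np.pi * freq * t)
    w /= np.linalg.norm(w)
    return w


def morlet_amplitude(epochs: EpochSet, config: Optional[TFRConfig] = None) -> TFRResult:
    """Morlet amplitude of every epoch, channel, frequency and time bin.

    Time bins sit every ``time_step_ms`` starting at the first epoch
    sample; edge bins within half the wavelet support of either epoch
    edge are flagged in the artifact mask (never zero-padded into the
    average).
    """
    if config is None:
        config = TFRConfig()
    freqs = config.freqs
    sfreq = epochs.sfreq
    min_support = config.n_cycles / freqs.min() * sfreq
    if epochs.n_samples < min_support:
        raise ValueError(
            f"epoch too short for {config.n_cycles}-cycle wavelet at {freqs.min()} Hz"
        )
    step = int(round(config.time_step_ms / 1000.0 * sfreq))
    bin_idx = np.arange(0, epochs.n_samples, step)
    times_ms = epochs.times_ms[bin_idx]
    n_e, n_c, n_t = epochs.data.shape
    amp = np.empty((n_e, n_c, freqs.size, bin_idx.size))
    mask = np.zeros_like(amp, dtype=bool)
    for fi, f in enumerate(freqs):
        w = morlet_wavelet(f, sfreq, config.n_cycles)
        conv = fftconvolve(epochs.data, w[np.newaxis, np.newaxis, :], mode="same", axes=-1)
        amp[:, :, fi, :] = np.abs(conv[:, :, bin_idx])
        half = w.size // 2
        edge = (bin_idx < half) | (bin_idx >= n_t - half)
        mask[:, :, fi, edge] = True
    return TFRResult(
        amplitude=amp,
        artifact_mask=mask,
        freqs=freqs,
        times_ms=times_ms,
        ch_names=list(epochs.ch_names),
    )


def mark_artifact_bins(tfr: TFRResult, config: Optional[TFRConfig] = None) -> TFRResult:
    """Mask 30-85 Hz bins with |z| above threshold.

    The z-score population is all (epoch, time) bins of a given channel
    and frequency, excluding already-masked edge bins.  The mask
    applies only to the offending frequency rows, so the high-gamma
    average at that time bin is computed from surviving bins.
    """
    if config is None:
        config = TFRConfig()
    lo, hi = config.artifact_band
    in_band = (tfr.freqs >= lo) & (tfr.freqs <= hi)
    mask = tfr.artifact_mask.copy()
    a = np.ma.MaskedArray(tfr.amplitude, mask=mask)
    mu = a.mean(axis=(0, 3))  # channels x freqs
    sd = a.std(axis=(0, 3), ddof=0)
    sd_safe = np.where(sd.filled(0.0) > 0, sd.filled(1.0), 1.0)
    z = (tfr.amplitude - mu.filled(0.0)[None, :, :, None]) / sd_safe[None, :, :, None]
    hits = np.abs(z) > config.artifact_z_threshold
    hits[:, :, ~in_band, :] = False
    # Channels/freqs with zero variance can't be z-scored; nothing masked there.
    hits[:, sd.filled(0.0) == 0.0, :] = False
    mask |= hits
    return TFRResult(
        amplitude=tfr.amplitude,
        artifact_mask=mask,
        freqs=tfr.freqs,
        times_ms=tfr.times_ms,
        ch_names=list(tfr.ch_names),
    )


def _high_gamma_mean(tfr: TFRResult, band: tuple[float, float]) -> np.ma.MaskedArray:
    sel = (tfr.freqs >= band[0]) & (tfr.freqs <= band[1])
    a = np.ma.MaskedArray(tfr.amplitude[:, :, sel, :], mask=tfr.artifact_mask[:, :, sel, :])
    return a.mean(axis=2)  # epochs x channels x time bins


def percent_change(
    tfr_gameplay: TFRResult,
    tfr_reference: Optional[TFRResult] = None,
    mode: str = "vs_reference",
    config: Optional[TFRConfig] = None,
) -> HGASeries:
    """Per-trial high-gamma percent-change series per channel.

    ``vs_reference``: 100 * (HGA - ref_mean) / ref_mean, where ref_mean
    is the scalar unmasked mean over all reference epochs, high-gamma
    bins and times of that channel.  ``vs_gameplay_mean``: the same with
    the channel's own gameplay-period mean as baseline (the resulting
    series averages to zero over the gameplay window by construction).
    """
    if config is None:
        config = TFRConfig()
    hga = _high_gamma_mean(tfr_gameplay, config.high_gamma_band)
    if mode == "vs_reference":
        if tfr_reference is None:
            raise ValueError("vs_reference normalization needs a reference TFRResult")
        ref = _high_gamma_mean(tfr_reference, config.high_gamma_band)
        baseline = ref.mean(axis=(0, 2))  # per channel scalar
    elif mode == "vs_gameplay_mean":
        baseline = hga.mean(axis=(0, 2))
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    baseline = baseline.filled(np.nan)
    if np.any(~np.isfinite(baseline)) or np.any(baseline <= 0):
        raise ValueError(
            "non-positive or undefined baseline amplitude; check artifact masking"
        )
    pct = 100.0 * (hga - baseline[None, :, None]) / baseline[None, :, None]
    return HGASeries(
        data=pct.filled(np.nan),
        times_ms=tfr_gameplay.times_ms,
        labels=list(tfr_gameplay.ch_names),
        mode=mode,
    )


def roi_aggregate(
    series: HGASeries, montage: Sequence[ElectrodeSite]
) -> HGASeries:
    """Unweighted mean across included channels within each ROI.

    ROIs without any included channel in ``series`` are absent from the
    output; per-ROI channel counts are reported on the result.
    """
    by_label = {s.label: s for s in montage}
    roi_members: dict[str, list[int]] = {}
    for i, name in enumerate(series.labels):
        site = by_label.get(name)
        if site is None or not site.included:
            continue
        roi_members.setdefault(site.roi, []).append(i)
    rois = sorted(roi_members)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", "Mean of empty slice")
        out = np.stack(
            [np.nanmean(series.data[:, roi_members[r], :], axis=1) for r in rois],
            axis=1,
        )
    return HGASeries(
        data=out,
        times_ms=series.times_ms,
        labels=rois,
        mode=series.mode,
        unit_counts={r: len(roi_members[r]) for r in rois},
    )
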