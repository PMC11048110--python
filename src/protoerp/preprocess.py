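"""Bandpass filtering, resampling, window slicing and standardization.

Epochs are bandpass filtered with a zero-phase (forward-backward)
Butterworth filter, 2-30 Hz and order 4 by default.  Zero-phase filtering
doubles the effective order but leaves ERP peak latencies undistorted,
which matters for prototype matching; the filter runs per epoch with
reflect padding to soften edge effects.

Standardization is strictly fit-on-train: channel means and SDs are
estimated on a training collection only and applied unchanged elsewhere,
so a held-out subject never contributes statistics (zero-calibration
hygiene at the preprocessing stage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, resample_poly

from .data_io import EpochSet, SubjectCollection, ValidationError

__all__ = ["PreprocConfig", "bandpass", "resample", "slice_window",
           "ChannelStats", "fit_standardizer", "standardize", "apply_preproc"]


@dataclass
class PreprocConfig:
    band_low: float = 2.0
    band_high: float = 30.0
    order: int = 4
    resample_to: float | None = 125.0
    window: tuple[float, float] | None = None   # (start_s, end_s); None = full epoch
    standardize: bool = True

    def validate(self, sfreq: float) -> None:
        if not (0.0 < self.band_low < self.band_high):
            raise ValidationError(
                f"need 0 < band_low < band_high, got ({self.band_low}, {self.band_high})")
        if self.band_high >= sfreq / 2.0:
            raise ValidationError(
                f"band_high {self.band_high} Hz must be below the Nyquist "
                f"frequency {sfreq / 2.0} Hz")
        if self.order < 2 or self.order % 2:
            raise ValidationError(f"order must be even and >= 2, got {self.order}")


def bandpass(epochs: EpochSet, config: PreprocConfig) -> EpochSet:
    """Zero-phase Butterworth bandpass, applied per trial and channel."""
    config.validate(epochs.sfreq)
    b, a = butter(config.order, [config.band_low, config.band_high],
                  btype="bandpass", fs=epochs.sfreq)
    padlen = min(3 * (max(len(a), len(b)) - 1) * 4, epochs.n_samples - 1)
    filtered = filtfilt(b, a, epochs.data, axis=-1, padtype="even",
                        padlen=padlen)
    return epochs.replace_data(filtered)


def resample(epochs: EpochSet, to_hz: float) -> EpochSet:
    """Polyphase resampling along time to ``to_hz``."""
    if to_hz <= 0:
        raise ValidationError(f"resample rate must be positive, got {to_hz}")
    if to_hz == epochs.sfreq:
        return epochs
    from fractions import Fraction

    frac = Fraction(to_hz / epochs.sfreq).limit_denominator(1000)
    out = resample_poly(epochs.data, frac.numerator, frac.denominator, axis=-1)
    return epochs.replace_data(out, sfreq=to_hz)


def slice_window(epochs: EpochSet, window: tuple[float, float]) -> EpochSet:
    """Keep samples in the half-open interval [start_s, end_s).

    Sample index convention: ``floor(t * sfreq)``, 0-based.
    """
    start_s, end_s = window
    lo = int(np.floor(start_s * epochs.sfreq))
    hi = int(np.floor(end_s * epochs.sfreq))
    if not (0 <= lo < hi <= epochs.n_samples):
        raise ValidationError(
            f"window [{start_s}, {end_s}) maps to samples [{lo}, {hi}) which is "
            f"empty or outside the epoch of {epochs.n_samples} samples")
    return epochs.replace_data(epochs.data[:, :, lo:hi])


@dataclass
class ChannelStats:
    mean: np.ndarray   # (n_channels,)
    sd: np.ndarray     # (n_channels,)


def fit_standardizer(train: SubjectCollection) -> ChannelStats:
    """Per-channel mean/SD pooled over all training subjects, trials, samples."""
    stacked = np.concatenate([es.data for es in train.subjects.values()], axis=0)
    mean = stacked.mean(axis=(0, 2))
    sd = stacked.std(axis=(0, 2))
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = train.subjects[train.subject_ids[0]].channel_names
        bad = names[zero[0]] if names else f"index {zero[0]}"
        raise ValidationError(f"zero-variance channel: {bad}")
    return ChannelStats(mean=mean, sd=sd)


def standardize(train: SubjectCollection,
                apply_to: SubjectCollection) -> SubjectCollection:
    """Z-score ``apply_to`` per channel using statistics from ``train`` only."""
    if train.n_channels != apply_to.n_channels:
        raise ValidationError(
            f"channel count mismatch: train {train.n_channels} vs "
            f"apply_to {apply_to.n_channels}")
    stats = fit_standardizer(train)
    m = stats.mean[None, :, None]
    s = stats.sd[None, :, None]
    return apply_to.map_data(lambda es: es.replace_data((es.data - m) / s))


def apply_preproc(coll: SubjectCollection, config: PreprocConfig,
                  stats: ChannelStats | None = None) -> SubjectCollection:
    """Filter -> resample -> slice for every subject.

    Standardization needs a fit/apply split and is done separately via
    :func:`standardize` (or by passing precomputed ``stats``).
    """
    def one(es: EpochSet) -> EpochSet:
        out = bandpass(es, config)
        if config.resample_to is not None:
            out = resample(out, config.resample_to)
        if config.window is not None:
            out = slice_window(out, config.window)
        return out

    out = coll.map_data(one)
    if stats is not None:
        m = stats.mean[None, :, None]
        s = stats.sd[None, :, None]
        out = out.map_data(lambda es: es.replace_data((es.data - m) / s))
    return out
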