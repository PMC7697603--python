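"""Continuous-EEG cleaning and epoching.

The fixed preprocessing chain is band-pass -> z-score -> notch -> segment:

1. **Band-pass** 10–30 Hz (5th-order Butterworth, applied forward–backward so
   it is zero-phase) isolates the sensorimotor mu (8–13 Hz) and beta
   (13–30 Hz) rhythms whose amplitude is modulated by motor imagery.
2. **Z-score normalization** per channel, ``z = (w - mean) / sd`` with the
   population standard deviation over the full continuous recording, removes
   absolute amplitude and inter-channel dispersion.
3. **Notch** at 60 Hz (second-order IIR, quality 30, zero-phase) rejects
   power-line interference; it can be disabled for pre-notched data.
4. **Segmentation** cuts one cue-locked epoch per marker using a half-open
   sample window.

Filtering is zero-phase throughout so epochs are never time-shifted relative
to their cues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .exceptions import (
    DegenerateDataError,
    OutOfRangeError,
    ParameterError,
)
from .io import PipelineConfig, RawRecording

__all__ = [
    "EpochSet",
    "NormalizationParams",
    "bandpass_filter",
    "zscore_normalize",
    "notch_filter",
    "segment_epochs",
    "preprocess",
]


@dataclass
class EpochSet:
    """Cue-locked trials.

    data has shape (n_trials, n_channels, n_samples); labels holds one class
    string per trial; window is (start, end) in seconds relative to the cue.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    window: tuple[float, float]
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=str)
        if self.data.ndim != 3:
            raise ParameterError("epoch data must be 3-D (trials x channels x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ParameterError("one label per trial required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def pick(self, labels) -> "EpochSet":
        """Sub-select channels by label, preserving the requested order."""
        idx = []
        for lab in labels:
            if lab not in self.channel_labels:
                from .exceptions import ChannelNotFoundError

                raise ChannelNotFoundError(f"channel {lab!r} not in epochs")
            idx.append(self.channel_labels.index(lab))
        return EpochSet(
            data=self.data[:, idx, :],
            labels=self.labels.copy(),
            fs=self.fs,
            window=self.window,
            channel_labels=list(labels),
        )


@dataclass(frozen=True)
class NormalizationParams:
    """Per-channel mean and population standard deviation used for z-scoring."""

    mean: np.ndarray
    std: np.ndarray


def _check_band(fs: float, *freqs: float) -> None:
    nyq = fs / 2.0
    for f in freqs:
        if f is None:
            continue
        if not 0 < f < nyq:
            raise ParameterError(f"frequency {f} Hz outside (0, Nyquist={nyq} Hz)")


def bandpass_filter(
    recording: RawRecording,
    low_hz: float = 10.0,
    high_hz: float = 30.0,
    order: int = 5,
) -> RawRecording:
    """Zero-phase Butterworth band-pass.

    The filter is designed as second-order sections and applied with
    ``sosfiltfilt`` (forward–backward), which squares the magnitude response
    and cancels the phase, so cue timing is preserved exactly.
    """
    if order < 1:
        raise ParameterError("filter order must be >= 1")
    if not low_hz < high_hz:
        raise ParameterError("low cutoff must be below high cutoff")
    _check_band(recording.fs, low_hz, high_hz)
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=recording.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, recording.data, axis=1)
    if not np.all(np.isfinite(filtered)):
        raise DegenerateDataError("band-pass filter produced non-finite output")
    return recording.copy_with(filtered)


def zscore_normalize(
    recording: RawRecording,
) -> tuple[RawRecording, NormalizationParams]:
    """Per-channel z-scoring over the full continuous recording.

    Uses the population (divide-by-N) standard deviation. A constant channel
    makes the transform undefined and raises, naming the offending electrode.
    """
    mean = recording.data.mean(axis=1)
    std = recording.data.std(axis=1)  # population (ddof=0)
    bad = np.flatnonzero(std <= 0)
    if bad.size:
        names = [recording.channel_labels[i] for i in bad]
        raise DegenerateDataError(f"constant channel(s), cannot z-score: {names}")
    z = (recording.data - mean[:, None]) / std[:, None]
    return recording.copy_with(z), NormalizationParams(mean=mean, std=std)


def notch_filter(
    recording: RawRecording,
    freq_hz: float | None = 60.0,
    quality: float = 30.0,
) -> RawRecording:
    """Zero-phase second-order IIR notch; ``freq_hz=None`` disables it."""
    if freq_hz is None:
        return recording.copy_with(recording.data.copy())
    _check_band(recording.fs, freq_hz)
    b, a = signal.iirnotch(freq_hz, quality, fs=recording.fs)
    filtered = signal.filtfilt(b, a, recording.data, axis=1)
    return recording.copy_with(filtered)


def segment_epochs(
    recording: RawRecording,
    window: tuple[float, float],
) -> EpochSet:
    """Cut one cue-locked epoch per marker.

    The sample window is half-open: ``[round((cue_s+start)*fs),
    round((cue_s+end)*fs))`` with 0-based indices, so every trial has exactly
    ``round((end-start)*fs)`` samples. Markers whose window exceeds the
    recording bounds are reported together in one error.
    """
    start_s, end_s = window
    if not start_s < end_s:
        raise ParameterError("epoch start must be < end")
    fs = recording.fs
    n = recording.n_samples
    n_len = int(round((end_s - start_s) * fs))
    trials, labels, offenders = [], [], []
    for k, m in enumerate(recording.markers):
        cue_s = m.sample / fs
        a = int(round((cue_s + start_s) * fs))
        b = a + n_len
        if a < 0 or b > n:
            offenders.append((k, m.sample))
            continue
        trials.append(recording.data[:, a:b])
        labels.append(m.label)
    if offenders:
        raise OutOfRangeError(
            f"epoch window {window} out of bounds for markers "
            f"(index, sample): {offenders}"
        )
    data = np.stack(trials) if trials else np.empty((0, recording.n_channels, n_len))
    return EpochSet(
        data=data,
        labels=np.asarray(labels, dtype=str),
        fs=fs,
        window=(start_s, end_s),
        channel_labels=list(recording.channel_labels),
    )


def preprocess(recording: RawRecording, config: PipelineConfig) -> EpochSet:
    """Run the full fixed-order chain: band-pass, z-score, notch, segment.

    The notch stage is skipped (with a warning) when the configured line
    frequency is not representable at the recording's sampling rate — data
    sampled below 2x the line frequency cannot carry that interference.
    """
    rec = bandpass_filter(recording, *config.band, order=config.filter_order)
    rec, _ = zscore_normalize(rec)
    notch_hz = config.notch_hz
    if notch_hz is not None and notch_hz >= recording.fs / 2:
        logging.getLogger(__name__).warning(
            "notch at %g Hz >= Nyquist (%g Hz); stage skipped",
            notch_hz, recording.fs / 2)
        notch_hz = None
    rec = notch_filter(rec, notch_hz)
    return segment_epochs(rec, config.epoch_window)
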