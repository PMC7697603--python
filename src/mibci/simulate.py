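"""Synthetic two-class motor-imagery EEG with known ground truth.

Motor imagery attenuates the sensorimotor mu (8–13 Hz) and beta (13–30 Hz)
rhythms contralateral to the imagined limb (event-related
desynchronization). The generator emulates exactly that contrast: every
channel carries 1/f background noise plus band-limited mu and beta
oscillations; on a configurable subset of *informative* channels the
oscillation amplitude is scaled by (1 - effect/2) or (1 + effect/2)
depending on the trial class, lateralized so the first half of the
informative channels is attenuated for class A and the second half for
class B. An optional 60 Hz tone models power-line pickup.

The oscillations are band-passed white noise, not sinusoids, so
wavelet-packet sub-bands receive broadband structure as they would from
real EEG. With ``effect = 1`` the class amplitude ratio on an informative
channel is (1.5 / 0.5) = 3, i.e. a 9x band-power ratio — a deliberately
strong, unambiguous contrast; ``effect = 0`` is an exact null. Everything
is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .exceptions import ParameterError
from .io import CHANNEL_SETS, Marker, RawRecording

__all__ = ["SyntheticConfig", "generate_recording", "make_fixture_suite"]

_DEFAULT_CLASSES = ("left", "right")


@dataclass
class SyntheticConfig:
    """Generation parameters for two-class MI-like EEG.

    Defaults: 100 trials per class over 18 sensorimotor channels at 100 Hz,
    4 s trials with 1 s inter-trial gaps, informative channels C3 and C4
    (indices 1 and 4 of the 18-channel montage), a full-strength class
    contrast (effect 1.0), 1/f background of 10 uV RMS, mu/beta rhythm
    amplitudes of 15/8 uV RMS (the sensorimotor idling rhythm dominates its
    band at central electrodes), and no line noise.
    """

    n_trials_per_class: int = 100
    n_channels: int = 18
    fs: float = 100.0
    trial_s: float = 4.0
    gap_s: float = 1.0
    informative_channels: tuple[int, ...] | None = None
    effect: float = 1.0
    noise_exponent: float = 1.0
    noise_amplitude: float = 10.0
    mu_amplitude: float = 15.0
    beta_amplitude: float = 8.0
    line_noise_hz: float | None = None
    line_amplitude: float = 2.0
    classes: tuple[str, str] = _DEFAULT_CLASSES
    channel_labels: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect < 0:
            raise ParameterError("effect must be >= 0")
        if self.fs <= 60.0:
            raise ParameterError("fs must exceed 60 Hz (2 x 30 Hz band edge)")
        if self.n_trials_per_class < 1 or self.n_channels < 1:
            raise ParameterError("need at least one trial and one channel")
        if self.informative_channels is not None and any(
                not 0 <= c < self.n_channels
                for c in self.informative_channels):
            raise ParameterError("informative_channels outside channel range")
        if len(set(self.classes)) != 2:
            raise ParameterError("exactly two distinct class names required")

    def resolved_informative(self) -> tuple[int, ...]:
        """Explicit informative indices, or the montage's C3/C4-like pair."""
        if self.informative_channels is not None:
            return tuple(self.informative_channels)
        labels = self.resolved_labels()
        lateral = [i for i, lab in enumerate(labels) if lab in ("C3", "C4")]
        if len(lateral) == 2:
            return tuple(lateral)
        return (0, self.n_channels - 1) if self.n_channels > 1 else (0,)

    def resolved_labels(self) -> list[str]:
        """Explicit labels, or a registry montage matching the channel count."""
        if self.channel_labels is not None:
            if len(self.channel_labels) != self.n_channels:
                raise ParameterError("channel_labels length mismatch")
            return list(self.channel_labels)
        for name in ("channel-set-2-bci", "channel-set-1-auto",
                     "channel-set-1-bci"):
            if len(CHANNEL_SETS[name]) == self.n_channels:
                return list(CHANNEL_SETS[name])
        return [f"EEG{i:02d}" for i in range(self.n_channels)]


def _pink_noise(rng: np.random.Generator, n: int, exponent: float,
                fs: float) -> np.ndarray:
    """1/f^exponent noise via spectral shaping, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    freqs[0] = freqs[1]  # keep DC finite
    spec *= freqs ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _band_noise(rng: np.random.Generator, n: int, band: tuple[float, float],
                fs: float) -> np.ndarray:
    """Band-limited white noise (4th-order Butterworth), unit RMS."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n + 200))[100:-100]
    return x / x.std()


def generate_recording(config: SyntheticConfig) -> RawRecording:
    """Generate a continuous recording with cue markers.

    Trials are concatenated with inter-trial gaps (a leading gap included);
    markers sit at trial onsets and the class sequence is a seeded balanced
    shuffle. Informative channels are split into two lateralized halves:
    for class A (first class name) the first half is attenuated and the
    second amplified, and vice versa for class B.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n_trial = int(round(config.trial_s * fs))
    n_gap = int(round(config.gap_s * fs))
    n_trials = 2 * config.n_trials_per_class
    n_total = n_gap + n_trials * (n_trial + n_gap)

    labels_seq = np.array(
        [config.classes[0]] * config.n_trials_per_class
        + [config.classes[1]] * config.n_trials_per_class
    )
    rng.shuffle(labels_seq)

    info = list(config.resolved_informative())
    half = max(1, len(info) // 2) if info else 0
    first_half, second_half = set(info[:half]), set(info[half:])

    gain = {
        (config.classes[0], "first"): 1.0 - config.effect / 2.0,
        (config.classes[0], "second"): 1.0 + config.effect / 2.0,
        (config.classes[1], "first"): 1.0 + config.effect / 2.0,
        (config.classes[1], "second"): 1.0 - config.effect / 2.0,
    }

    data = np.empty((config.n_channels, n_total))
    t_all = np.arange(n_total) / fs
    for c in range(config.n_channels):
        x = config.noise_amplitude * _pink_noise(
            rng, n_total, config.noise_exponent, fs)
        if config.line_noise_hz is not None:
            phase = rng.uniform(0, 2 * np.pi)
            x += config.line_amplitude * np.sqrt(2) * np.sin(
                2 * np.pi * config.line_noise_hz * t_all + phase)
        for k in range(n_trials):
            a = n_gap + k * (n_trial + n_gap)
            mu = config.mu_amplitude * _band_noise(rng, n_trial, (8, 13), fs)
            beta = config.beta_amplitude * _band_noise(rng, n_trial, (13, 30), fs)
            g = 1.0
            if c in first_half:
                g = gain[(labels_seq[k], "first")]
            elif c in second_half:
                g = gain[(labels_seq[k], "second")]
            x[a:a + n_trial] += g * (mu + beta)
        data[c] = x

    markers = [
        Marker(sample=n_gap + k * (n_trial + n_gap), label=str(labels_seq[k]))
        for k in range(n_trials)
    ]
    return RawRecording(data=data, fs=fs,
                        channel_labels=config.resolved_labels(),
                        markers=markers)


def make_fixture_suite(seed: int = 0) -> dict[str, tuple[RawRecording, dict]]:
    """The named fixtures exercised by the end-to-end tests.

    Returns a mapping fixture-name -> (recording, expected-properties dict).
    """
    suite: dict[str, tuple[RawRecording, dict]] = {}

    strong18 = SyntheticConfig(seed=seed)
    suite["strong-effect-18-channel"] = (
        generate_recording(strong18),
        {"n_channels": 18, "labels": list(CHANNEL_SETS["channel-set-2-bci"]),
         "effect": 1.0, "informative": list(strong18.resolved_informative()),
         "n_trials": 200},
    )

    strong13 = SyntheticConfig(n_channels=13, informative_channels=(0, 9),
                               seed=seed + 1)
    suite["strong-effect-13-channel"] = (
        generate_recording(strong13),
        {"n_channels": 13, "labels": list(CHANNEL_SETS["channel-set-1-auto"]),
         "effect": 1.0, "informative": [0, 9], "n_trials": 200},
    )

    null = SyntheticConfig(effect=0.0, seed=seed + 2)
    suite["null-effect"] = (
        generate_recording(null),
        {"n_channels": 18, "effect": 0.0, "n_trials": 200},
    )

    line = SyntheticConfig(n_channels=3, informative_channels=(0, 2),
                           line_noise_hz=60.0, fs=250.0, seed=seed + 3)
    suite["line-noise-contaminated"] = (
        generate_recording(line),
        {"n_channels": 3, "line_noise_hz": 60.0, "fs": 250.0,
         "n_trials": 200},
    )
    return suite


def _with(config: SyntheticConfig, **kwargs) -> SyntheticConfig:
    """Convenience: a copy of config with fields replaced."""
    return replace(config, **kwargs)
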