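"""Recording containers, channel-set registry, and on-disk formats.

Two interchange formats are supported natively:

* **EDF / EDF+** — the standard 16-bit exchange format for clinical and BCI
  EEG. Reading goes through :func:`mne.io.read_raw_edf`; writing uses a
  minimal EDF+ writer (:func:`write_edf`) sufficient for uniform-rate
  recordings with cue annotations.
* **Matrix bundle** — a delimited numeric matrix (one channel per row) plus a
  JSON sidecar holding the sampling rate, channel labels and cue markers.
  The bundle round-trips losslessly and is convenient for fixtures and for
  data exported from vendor tools.

The module also ships the named electrode-set registry used throughout the
pipeline (sensorimotor 10–20 montage subsets of 3, 18, 3 and 13 channels).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ChannelNotFoundError,
    FormatError,
    ParameterError,
    RegistryError,
    SchemaError,
    UnsupportedTaskError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Marker",
    "RawRecording",
    "ChannelSet",
    "PipelineConfig",
    "CHANNEL_SETS",
    "resolve_channel_set",
    "read_edf",
    "write_edf",
    "read_matrix_bundle",
    "write_matrix_bundle",
    "read_feature_table",
    "write_feature_table",
]


@dataclass(frozen=True)
class Marker:
    """A task cue: sample index of the cue plus its class label."""

    sample: int
    label: str


@dataclass
class RawRecording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts (or normalized units after z-scoring).
    fs : float
        Sampling rate in Hz, > 0.
    channel_labels : list of str
        Unique 10–20 system electrode names, one per data row.
    markers : list of Marker
        Task cues. At most two distinct class labels may appear.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    markers: list[Marker] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ParameterError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ParameterError(f"sampling rate must be > 0, got {self.fs}")
        if len(self.channel_labels) != self.data.shape[0]:
            raise SchemaError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise SchemaError("channel labels must be unique")
        n = self.data.shape[1]
        for m in self.markers:
            if not 0 <= m.sample < n:
                raise ParameterError(
                    f"marker at sample {m.sample} outside [0, {n})"
                )
        labels = {m.label for m in self.markers}
        if len(labels) > 2:
            raise UnsupportedTaskError(
                f"binary tasks only; found {len(labels)} classes: {sorted(labels)}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray) -> "RawRecording":
        """New recording sharing metadata but carrying different samples."""
        return RawRecording(
            data=data,
            fs=self.fs,
            channel_labels=list(self.channel_labels),
            markers=list(self.markers),
        )


@dataclass(frozen=True)
class ChannelSet:
    """A named, ordered subset of electrode labels."""

    name: str
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ParameterError(f"duplicate labels in channel set {self.name!r}")

    def __len__(self) -> int:
        return len(self.labels)


#: Shipped sensorimotor electrode sets. The 18-channel set covers the
#: sensorimotor cortex (C/CP/P rows); the 13-channel set is the deduplicated
#: union of the C3, Cz and C4 four-neighborhoods (C1 and C2 each border two
#: of the three seeds, so the union has 13 electrodes, not 15).
CHANNEL_SETS: dict[str, tuple[str, ...]] = {
    "channel-set-1-bci": ("C3", "Cz", "C4"),
    "channel-set-2-bci": (
        "C5", "C3", "C1", "C2", "C4", "C6",
        "CP5", "CP3", "CP1", "CP2", "CP4", "CP6",
        "P5", "P3", "P1", "P2", "P4", "P6",
    ),
    "channel-set-1-auto": (
        "C3", "FC3", "C5", "CP3", "C1",
        "Cz", "FCz", "CPz", "C2",
        "C4", "FC4", "CP4", "C6",
    ),
    "channel-set-2-auto": ("C3", "Cz", "C4"),
}


def resolve_channel_set(
    name_or_labels: str | Sequence[str],
    recording: RawRecording | None = None,
) -> ChannelSet:
    """Resolve a registered set name or an explicit label list.

    When a recording is given, every label is checked against it and a
    :class:`ChannelNotFoundError` names the first missing electrode.
    """
    if isinstance(name_or_labels, str):
        if name_or_labels not in CHANNEL_SETS:
            raise RegistryError(
                f"unknown channel set {name_or_labels!r}; "
                f"registered: {sorted(CHANNEL_SETS)}"
            )
        cs = ChannelSet(name_or_labels, CHANNEL_SETS[name_or_labels])
    else:
        cs = ChannelSet("custom", tuple(name_or_labels))
    if recording is not None:
        have = set(recording.channel_labels)
        for lab in cs.labels:
            if lab not in have:
                raise ChannelNotFoundError(
                    f"channel {lab!r} not present in recording "
                    f"(has {recording.channel_labels})"
                )
    return cs


@dataclass
class PipelineConfig:
    """All tunable settings of the preprocessing/feature/selection pipeline.

    Defaults reproduce the standard configuration: 10–30 Hz band-pass
    (5th-order Butterworth, zero phase), per-channel z-scoring, 60 Hz notch,
    0.5–3.5 s cue-locked epochs, 4-level db4 wavelet-packet features,
    quadratic Renyi entropy, linear SVM, 10-fold CV.
    """

    band: tuple[float, float] = (10.0, 30.0)
    filter_order: int = 5
    notch_hz: float | None = 60.0
    epoch_window: tuple[float, float] = (0.5, 3.5)
    wavelet: str = "db4"
    wpd_level: int = 4
    wpd_mode: str = "periodization"
    layout_variant: str = "cyclic-gamma"  # or "adjacent-gamma-plus-activity"
    renyi_q: float = 2.0
    classifier: str = "svm-linear"  # svm-linear | lda | knn
    knn_k: int = 5
    svm_c: float = 1.0
    cv_folds: int = 10
    fs_inner_folds: int = 10
    fs_patience: int = 5
    seed: int = 0
    channel_set: str | Sequence[str] = "channel-set-2-bci"

    def __post_init__(self) -> None:
        low, high = self.band
        if not low < high:
            raise ParameterError(f"band low must be < high, got {self.band}")
        if not self.epoch_window[0] < self.epoch_window[1]:
            raise ParameterError(f"epoch start must be < end, got {self.epoch_window}")
        if self.wpd_level < 1:
            raise ParameterError("wpd_level must be >= 1")
        if self.cv_folds < 2:
            raise ParameterError("cv_folds must be >= 2")
        if self.renyi_q <= 0 or self.renyi_q == 1:
            raise ParameterError("renyi_q must be > 0 and != 1")
        if self.knn_k % 2 == 0:
            raise ParameterError("knn_k must be odd")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if not isinstance(d["channel_set"], str):
            d["channel_set"] = list(d["channel_set"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        for key in ("band", "epoch_window"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def read_edf(
    path: str | Path,
    task_names: Sequence[str] | None = None,
) -> RawRecording:
    """Read an EDF/EDF+ file into a :class:`RawRecording`.

    Annotations become cue markers. When ``task_names`` is given only
    annotations with those descriptions are kept (at most two names);
    otherwise every annotation is mapped and the two-class invariant is
    enforced on the result.
    """
    import mne

    path = Path(path)
    if task_names is not None and len(set(task_names)) > 2:
        raise UnsupportedTaskError("at most two task names may be configured")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalize parser failures
        raise FormatError(f"could not parse {path} as EDF: {exc}") from exc

    fs_all = set(raw.info["sfreq"] for _ in [0])
    if len(fs_all) != 1:
        raise FormatError("channels with differing sampling rates are unsupported")
    fs = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # mne returns volts; store microvolts
    # EDF labels carry a signal-type prefix ("EEG C3"); keep the bare name
    labels = [ch[4:] if ch.startswith("EEG ") else ch for ch in raw.ch_names]

    markers: list[Marker] = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        if task_names is not None and desc not in task_names:
            continue
        markers.append(Marker(sample=int(round(onset * fs)), label=str(desc)))
    if not markers:
        logger.warning("EDF file %s contains no task annotations", path)
    return RawRecording(data=data, fs=fs, channel_labels=labels, markers=markers)


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: RawRecording, path: str | Path) -> None:
    """Write a recording as 16-bit EDF+ with cue annotations.

    The writer targets round-tripping of pipeline fixtures: all channels share
    one sampling rate, data records are 1 s long, and markers are stored as
    EDF+ timestamped annotations. Amplitudes are quantized to the 16-bit
    digital range spanned by each channel's physical min/max, so a read-back
    agrees with the source to within (range / 2**16) per channel. If the
    recording length is not a whole number of records the last record is
    zero-padded (a read-back then reports the padded length).
    """
    path = Path(path)
    fs = recording.fs
    spr = int(round(fs))  # samples per 1 s record
    if abs(fs - spr) > 1e-9:
        raise ParameterError("EDF writer requires an integer sampling rate")
    n_sig = recording.n_channels
    n_samples = recording.n_samples
    n_rec = math.ceil(n_samples / spr)
    if n_rec * spr != n_samples:
        logger.warning("zero-padding final EDF record (%d -> %d samples)",
                       n_samples, n_rec * spr)

    data = np.zeros((n_sig, n_rec * spr))
    data[:, :n_samples] = recording.data

    # Physical/digital scaling per channel.
    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max - phys_min <= 0
    phys_min[flat] -= 1.0
    phys_max[flat] += 1.0
    dig_min, dig_max = -32768, 32767
    gain = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint(
        (data - phys_min[:, None]) * gain[:, None] + dig_min
    ).astype("<i2")

    # Annotation payload per record: a timekeeping TAL plus any cue TALs.
    tals: list[bytes] = []
    for r in range(n_rec):
        tal = f"+{r}\x14\x14\x00".encode("ascii")
        for m in recording.markers:
            if r * spr <= m.sample < (r + 1) * spr:
                onset = m.sample / fs
                tal += f"+{onset:.4f}\x14{m.label}\x14\x00".encode("ascii")
        tals.append(tal)
    ann_bytes = max(len(t) for t in tals)
    ann_spr = (ann_bytes + 1) // 2 + 8  # 2 bytes per "sample", headroom

    n_total = n_sig + 1  # + annotations signal
    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),          # local patient id (anonymous)
        _edf_field("Startdate X X X X", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(str(256 * (n_total + 1)), 8),
        _edf_field("EDF+C", 44),
        _edf_field(str(n_rec), 8),
        _edf_field("1", 8),                  # record duration, seconds
        _edf_field(str(n_total), 4),
    ])
    labels = [f"EEG {lab}" for lab in recording.channel_labels] + ["EDF Annotations"]
    transducer = [""] * n_total
    dim = ["uV"] * n_sig + [""]
    pmin = [f"{v:.6g}"[:8] for v in phys_min] + ["-1"]
    pmax = [f"{v:.6g}"[:8] for v in phys_max] + ["1"]
    dmin = [str(dig_min)] * n_sig + [str(dig_min)]
    dmax = [str(dig_max)] * n_sig + [str(dig_max)]
    prefilter = [""] * n_total
    nsamp = [str(spr)] * n_sig + [str(ann_spr)]
    for values, width in [
        (labels, 16), (transducer, 80), (dim, 8), (pmin, 8), (pmax, 8),
        (dmin, 8), (dmax, 8), (prefilter, 80), (nsamp, 8),
    ]:
        header += b"".join(_edf_field(v, width) for v in values)
    header += b" " * (32 * n_total)  # reserved

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())
            tal = tals[r].ljust(ann_spr * 2, b"\x00")
            fh.write(tal)


# ---------------------------------------------------------------------------
# Matrix bundle
# ---------------------------------------------------------------------------

def write_matrix_bundle(
    recording: RawRecording,
    matrix_path: str | Path,
    sidecar_path: str | Path,
) -> None:
    """Write the delimited-matrix + JSON-sidecar dialect (lossless)."""
    np.savetxt(matrix_path, recording.data, fmt="%.17g", delimiter="\t")
    sidecar = {
        "fs": recording.fs,
        "labels": list(recording.channel_labels),
        "markers": [{"sample": m.sample, "label": m.label} for m in recording.markers],
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=1))


def read_matrix_bundle(
    matrix_path: str | Path,
    sidecar_path: str | Path,
) -> RawRecording:
    """Read the delimited-matrix + sidecar dialect.

    The matrix is one channel per row, comma- or whitespace-delimited. The
    sidecar is JSON with keys ``fs``, ``labels`` and ``markers``.
    """
    matrix_path, sidecar_path = Path(matrix_path), Path(sidecar_path)
    first = matrix_path.open().readline()
    delim = "," if "," in first else None
    try:
        data = np.loadtxt(matrix_path, delimiter=delim, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"could not parse {matrix_path} as a numeric matrix: {exc}")
    try:
        sidecar = json.loads(sidecar_path.read_text())
        fs = float(sidecar["fs"])
        labels = [str(x) for x in sidecar["labels"]]
        markers = [
            Marker(sample=int(m["sample"]), label=str(m["label"]))
            for m in sidecar.get("markers", [])
        ]
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise SchemaError(f"bad sidecar {sidecar_path}: {exc}") from exc
    if len(labels) != data.shape[0]:
        raise SchemaError(
            f"sidecar lists {len(labels)} labels but matrix has {data.shape[0]} rows"
        )
    classes = {m.label for m in markers}
    if len(classes) > 2:
        raise UnsupportedTaskError(
            f"binary tasks only; sidecar has {len(classes)} classes"
        )
    return RawRecording(data=data, fs=fs, channel_labels=labels, markers=markers)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def write_feature_table(
    features: pd.DataFrame,
    labels: Sequence[str] | None,
    path: str | Path,
) -> None:
    """Write a trials x features table as TSV.

    Column names follow the canonical ``CH:<label>|<domain>|<subband>|<stat>``
    scheme; the class label, if given, is stored in a leading ``label`` column.
    """
    out = features.copy()
    if labels is not None:
        out.insert(0, "label", list(labels))
    out.to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Read a feature table written by :func:`write_feature_table`."""
    df = pd.read_csv(path, sep="\t")
    labels = None
    if "label" in df.columns:
        labels = df.pop("label").to_numpy(dtype=str)
    return df, labels
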