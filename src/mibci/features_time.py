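"""Time-domain feature set: six statistics per trial per channel.

The statistics, computed on the band-passed, normalized epoch:

* **RMS** — root mean square, sqrt(mean(y^2)).
* **Renyi entropy** of order q on the normalized energy distribution
  p_j = y_j^2 / sum(y^2): H_q = log(sum p^q) / (1 - q), natural log. Raw
  samples can be negative, so the entropy is taken over the energy
  distribution rather than the samples themselves; values lie in [0, log M].
* **Hjorth mobility** — sqrt(var(y') / var(y)) with y' the first difference
  and population variances.
* **Hjorth complexity** — mobility(y') / mobility(y).
* **Waveform length** — sum |y_j - y_{j-1}|.
* **Mean absolute value** — mean |y|.

Hjorth *activity* (the signal variance) can be appended via
``include_activity`` for the seven-feature layout variant; it is off by
default. The derivative is the plain first difference, not scaled by fs:
the scale factor cancels in complexity and is a constant shared by all
trials in mobility.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import DegenerateDataError, EmptyInputError, ParameterError
from .preprocessing import EpochSet

__all__ = [
    "rms",
    "renyi_entropy",
    "hjorth_activity",
    "hjorth_mobility",
    "hjorth_complexity",
    "waveform_length",
    "mean_abs_value",
    "TimeFeatureExtractor",
    "extract_time_features",
    "TIME_STATS",
]

#: canonical statistic order in the default six-feature layout
TIME_STATS = ("rms", "renyi", "mobility", "complexity", "wl", "mav")


def _as_vector(y) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if y.size == 0:
        raise EmptyInputError("empty sample vector")
    return y


def rms(y) -> float:
    """Root mean square of the samples."""
    y = _as_vector(y)
    return float(np.sqrt(np.mean(y * y)))


def renyi_entropy(y, q: float = 2.0) -> float:
    """Renyi entropy of order q of the signal's energy distribution.

    Requires q > 0, q != 1 and at least one non-zero sample.
    """
    if q <= 0 or q == 1:
        raise ParameterError("Renyi order q must be > 0 and != 1")
    y = _as_vector(y)
    e = y * y
    total = e.sum()
    if total <= 0:
        raise DegenerateDataError("all-zero signal has no energy distribution")
    p = e / total
    # 0^q is 0 for q > 0; mask zeros to keep fractional q well defined
    p = p[p > 0]
    return float(np.log(np.sum(p**q)) / (1.0 - q))


def hjorth_activity(y) -> float:
    """Hjorth activity: population variance of the samples."""
    y = _as_vector(y)
    return float(np.var(y))


def hjorth_mobility(y) -> float:
    """Hjorth mobility sqrt(var(dy)/var(y)), population variances."""
    y = _as_vector(y)
    if y.size < 2:
        raise EmptyInputError("mobility needs at least 2 samples")
    vy = np.var(y)
    vd = np.var(np.diff(y))
    if vy <= 0 or vd <= 0:
        raise DegenerateDataError("zero-variance signal or derivative")
    return float(np.sqrt(vd / vy))


def hjorth_complexity(y) -> float:
    """Hjorth complexity: mobility of the first difference over mobility of y."""
    y = _as_vector(y)
    if y.size < 3:
        raise EmptyInputError("complexity needs at least 3 samples")
    return hjorth_mobility(np.diff(y)) / hjorth_mobility(y)


def waveform_length(y) -> float:
    """Total variation of the sample path, sum of |successive differences|."""
    y = _as_vector(y)
    if y.size < 2:
        raise EmptyInputError("waveform length needs at least 2 samples")
    return float(np.sum(np.abs(np.diff(y))))


def mean_abs_value(y) -> float:
    """Mean absolute value of the samples."""
    y = _as_vector(y)
    return float(np.mean(np.abs(y)))


class TimeFeatureExtractor(TransformerMixin, BaseEstimator):
    """Vectorized time-domain feature block, one column group per channel.

    Transforms a (n_trials, n_channels, n_samples) epoch array into a
    (n_trials, n_channels * 6) matrix (6 -> 7 with ``include_activity``),
    channel-major with statistic order rms, renyi, [activity,] mobility,
    complexity, wl, mav. Stateless apart from recording the input layout at
    fit time.

    Parameters
    ----------
    renyi_q : float, default 2.0
        Order of the Renyi entropy (quadratic is the conventional EEG choice).
    include_activity : bool, default False
        Append Hjorth activity (variance) as a seventh statistic.
    channel_labels : sequence of str, optional
        Electrode names used in ``get_feature_names_out``; generic ``chNN``
        names are used when omitted.
    """

    def __init__(self, renyi_q: float = 2.0, include_activity: bool = False,
                 channel_labels=None):
        self.renyi_q = renyi_q
        self.include_activity = include_activity
        self.channel_labels = channel_labels

    @property
    def _stats(self) -> tuple[str, ...]:
        if self.include_activity:
            return ("rms", "renyi", "activity", "mobility", "complexity", "wl", "mav")
        return TIME_STATS

    def fit(self, X, y=None):
        X = self._check_input(X)
        self.n_channels_ = X.shape[1]
        self.n_features_out_ = self.n_channels_ * len(self._stats)
        return self

    def _check_input(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ParameterError("expected 3-D array (trials x channels x samples)")
        if X.shape[-1] < 3:
            raise EmptyInputError("need at least 3 samples per trial")
        return X

    def _labels(self, n_channels: int) -> list[str]:
        if self.channel_labels is not None:
            if len(self.channel_labels) != n_channels:
                raise ParameterError("channel_labels length mismatch")
            return list(self.channel_labels)
        return [f"ch{i:02d}" for i in range(n_channels)]

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        names = [
            f"CH:{lab}|time|NA|{stat}"
            for lab in self._labels(self.n_channels_)
            for stat in self._stats
        ]
        return np.asarray(names, dtype=object)

    def transform(self, X) -> np.ndarray:
        X = self._check_input(X)
        if self.renyi_q <= 0 or self.renyi_q == 1:
            raise ParameterError("renyi_q must be > 0 and != 1")
        n_tr, n_ch, _ = X.shape

        vy = X.var(axis=-1)
        d1 = np.diff(X, axis=-1)
        d2 = np.diff(d1, axis=-1)
        vd1 = d1.var(axis=-1)
        vd2 = d2.var(axis=-1)
        if np.any(vy <= 0) or np.any(vd1 <= 0) or np.any(vd2 <= 0):
            t, c = np.argwhere((vy <= 0) | (vd1 <= 0) | (vd2 <= 0))[0]
            raise DegenerateDataError(
                f"degenerate signal at trial {t}, channel {c} (zero variance)"
            )

        energy = X * X
        tot = energy.sum(axis=-1, keepdims=True)
        if np.any(tot <= 0):
            t, c = np.argwhere(tot[..., 0] <= 0)[0]
            raise DegenerateDataError(f"all-zero trial {t}, channel {c}")
        p = energy / tot
        with np.errstate(divide="ignore", invalid="ignore"):
            pq = np.where(p > 0, p, 1.0) ** self.renyi_q
            pq = np.where(p > 0, pq, 0.0)
        renyi = np.log(pq.sum(axis=-1)) / (1.0 - self.renyi_q)

        mob = np.sqrt(vd1 / vy)
        mob_d = np.sqrt(vd2 / vd1)
        cols = {
            "rms": np.sqrt(energy.mean(axis=-1)),
            "renyi": renyi,
            "activity": vy,
            "mobility": mob,
            "complexity": mob_d / mob,
            "wl": np.abs(d1).sum(axis=-1),
            "mav": np.abs(X).mean(axis=-1),
        }
        stats = self._stats
        out = np.empty((n_tr, n_ch * len(stats)))
        for c in range(n_ch):
            for s, stat in enumerate(stats):
                out[:, c * len(stats) + s] = cols[stat][:, c]
        return out


def extract_time_features(
    epochs: EpochSet,
    channel_set=None,
    renyi_q: float = 2.0,
    include_activity: bool = False,
) -> pd.DataFrame:
    """Time-feature block as a DataFrame with canonical column names.

    ``channel_set`` may be a registered set name, an explicit label list, or
    None to use every channel in the epochs.
    """
    if channel_set is not None:
        from .io import resolve_channel_set

        cs = resolve_channel_set(channel_set)
        epochs = epochs.pick(cs.labels)
    ext = TimeFeatureExtractor(
        renyi_q=renyi_q,
        include_activity=include_activity,
        channel_labels=epochs.channel_labels,
    ).fit(epochs.data)
    return pd.DataFrame(ext.transform(epochs.data),
                        columns=ext.get_feature_names_out())
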