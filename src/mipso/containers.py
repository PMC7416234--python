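"""Labelled data containers shared across the pipeline.

Two containers travel through every stage: :class:`TrialTensor`, the raw
``trials x channels x samples`` recording with per-trial class labels in
{-1, +1}, and :class:`FeatureMatrix`, the ``trials x features`` table of
spectral power values whose columns remember which (channel, frequency)
pair they came from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TrialTensor", "FeatureMatrix"]


@dataclass
class TrialTensor:
    """Multichannel trials with class labels.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Raw signal amplitudes.
    labels : ndarray, shape (n_trials,)
        Class labels, every entry -1 or +1.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str, optional
        Human-readable channel identifiers; defaults to ``ch0..ch{C-1}``.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError(
                f"trial data must be 3-D (trials, channels, samples); got shape {self.data.shape}"
            )
        if self.labels.ndim != 1 or len(self.labels) != self.data.shape[0]:
            raise ValueError("labels must be a vector with one entry per trial")
        if not np.all(np.isin(self.labels, (-1, 1))):
            raise ValueError("labels may only take the values -1 and +1")
        self.labels = self.labels.astype(np.int64)
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise ValueError("fs must be a positive sampling rate in Hz")
        if self.channel_names is None:
            self.channel_names = [f"ch{c}" for c in range(self.n_channels)]
        elif len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must match the channel axis")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def duration(self) -> float:
        """Trial length in seconds."""
        return self.n_samples / self.fs

    def subset(self, trial_idx: np.ndarray) -> "TrialTensor":
        """Return a new tensor containing the given trials."""
        idx = np.asarray(trial_idx)
        return TrialTensor(
            self.data[idx], self.labels[idx], self.fs, list(self.channel_names)
        )


@dataclass
class FeatureMatrix:
    """Per-trial spectral-power features with (channel, frequency) provenance.

    ``columns[j]`` is the ``(channel, frequency_hz)`` pair that produced
    column ``j``.  Column order is channel-major, frequency ascending, so a
    64-channel, 35-frequency extraction yields exactly 2240 columns.
    """

    values: np.ndarray
    columns: list[tuple[int, float]]
    labels: np.ndarray
    _channel_index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D (trials, features)")
        if len(self.columns) != self.values.shape[1]:
            raise ValueError("columns must describe every feature column")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels must have one entry per trial")
        self.columns = [(int(c), float(f)) for c, f in self.columns]
        self._channel_index = {}
        for j, (c, _) in enumerate(self.columns):
            self._channel_index.setdefault(c, []).append(j)

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def channels(self) -> list[int]:
        """Sorted distinct channel ids present among the columns."""
        return sorted(self._channel_index)

    def channel_columns(self, channel: int) -> np.ndarray:
        """Column indices belonging to one channel."""
        return np.asarray(self._channel_index.get(int(channel), []), dtype=np.intp)

    def column_names(self) -> list[str]:
        return [
            f"ch{c}_f{int(f) if float(f).is_integer() else f}" for c, f in self.columns
        ]

    def restrict(self, column_mask: np.ndarray) -> "FeatureMatrix":
        """Return the sub-matrix whose columns are flagged in ``column_mask``."""
        m = np.asarray(column_mask, dtype=bool)
        if m.shape != (self.n_features,):
            raise ValueError("column mask length must equal n_features")
        keep = np.flatnonzero(m)
        return FeatureMatrix(
            self.values[:, keep], [self.columns[j] for j in keep], self.labels
        )

    def subset_trials(self, trial_idx: np.ndarray) -> "FeatureMatrix":
        idx = np.asarray(trial_idx)
        return FeatureMatrix(self.values[idx], list(self.columns), self.labels[idx])

    def to_frame(self) -> pd.DataFrame:
        """Feature table as a DataFrame with a final ``label`` column."""
        df = pd.DataFrame(self.values, columns=self.column_names())
        df["label"] = self.labels
        return df
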