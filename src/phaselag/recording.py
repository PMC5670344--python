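"""Core in-memory containers for continuous recordings and epoched data.

Amplitudes are always in microvolts (µV); sampling rates in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ContinuousRecording", "EpochSet"]


@dataclass
class ContinuousRecording:
    """A multichannel continuous time series.

    Parameters
    ----------
    data
        Array of shape (n_channels, n_samples), amplitudes in µV.
    fs_hz
        Sampling rate in Hz.
    labels
        Channel names, one per row of ``data``; must be unique.
    eog_labels
        Subset of ``labels`` marking electro-oculogram channels. Every
        other channel is treated as EEG.
    """

    data: np.ndarray
    fs_hz: float
    labels: tuple[str, ...]
    eog_labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = tuple(self.labels)
        self.eog_labels = tuple(self.eog_labels)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.labels):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.labels)} labels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not set(self.eog_labels) <= set(self.labels):
            missing = set(self.eog_labels) - set(self.labels)
            raise ValueError(f"eog_labels not in labels: {sorted(missing)}")
        if not self.fs_hz > 0:
            raise ValueError("fs_hz must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def eeg_labels(self) -> tuple[str, ...]:
        return tuple(l for l in self.labels if l not in self.eog_labels)

    @property
    def eeg_indices(self) -> np.ndarray:
        eog = set(self.eog_labels)
        return np.array([i for i, l in enumerate(self.labels) if l not in eog])

    @property
    def eog_indices(self) -> np.ndarray:
        eog = set(self.eog_labels)
        return np.array(
            [i for i, l in enumerate(self.labels) if l in eog], dtype=int
        )

    def channel(self, label: str) -> np.ndarray:
        """Return the sample vector for one channel."""
        return self.data[self.labels.index(label)]

    def with_data(self, data: np.ndarray, fs_hz: float | None = None) -> "ContinuousRecording":
        """Copy of this recording with new samples (and optionally a new rate)."""
        return replace(self, data=data, fs_hz=self.fs_hz if fs_hz is None else fs_hz)


@dataclass
class EpochSet:
    """Fixed-length non-overlapping segments ("pseudotrials") of a recording.

    ``epochs`` has shape (n_trials, n_channels, n_samples_per_trial); the
    boolean ``rejected`` mask flags artifact trials that downstream
    estimators must skip.
    """

    epochs: np.ndarray
    fs_hz: float
    epoch_length_s: float
    labels: tuple[str, ...]
    eog_labels: tuple[str, ...] = field(default_factory=tuple)
    rejected: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = tuple(self.labels)
        self.eog_labels = tuple(self.eog_labels)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (trials x channels x samples)")
        n_trials, n_ch, n_samp = self.epochs.shape
        if n_ch != len(self.labels):
            raise ValueError("channel count does not match labels")
        expect = int(round(self.fs_hz * self.epoch_length_s))
        if n_samp != expect:
            raise ValueError(
                f"epoch has {n_samp} samples; expected {expect} "
                f"({self.epoch_length_s} s at {self.fs_hz} Hz)"
            )
        if self.rejected is None:
            self.rejected = np.zeros(n_trials, dtype=bool)
        self.rejected = np.asarray(self.rejected, dtype=bool)
        if self.rejected.shape != (n_trials,):
            raise ValueError("rejected mask length must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]

    @property
    def n_retained(self) -> int:
        return int((~self.rejected).sum())

    @property
    def retained(self) -> np.ndarray:
        """Epochs that survived artifact screening."""
        return self.epochs[~self.rejected]

    @property
    def rejection_rate(self) -> float:
        return float(self.rejected.mean()) if self.n_trials else 0.0

    @property
    def eeg_labels(self) -> tuple[str, ...]:
        return tuple(l for l in self.labels if l not in self.eog_labels)

    @property
    def eeg_indices(self) -> np.ndarray:
        eog = set(self.eog_labels)
        return np.array([i for i, l in enumerate(self.labels) if l not in eog])

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label {label!r}") from None
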