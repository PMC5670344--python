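"""Cross-spectral phase-synchronization estimators.

For a channel pair, the per-epoch cross-spectrum is

    S_j(f) = X1_j(f) * conj(X2_j(f))

with X the discrete Fourier transform of one 1-s epoch (rectangular
window, so 1 Hz bins).  Only the imaginary part of S enters the
estimators below, which makes them insensitive to instantaneous
(zero-phase-lag) coupling such as volume conduction:

    WPLI  = |<Im S>| / <|Im S|>
    PLI   = |<sign Im S>|
    debiased WPLI-square
          = sum_{j != k} Im S_j Im S_k / sum_{j != k} |Im S_j Im S_k|

The debiased square is computed in its O(N) algebraic form
((ΣI)^2 − ΣI^2) / ((Σ|I|)^2 − ΣI^2) and converges to WPLI^2 as the
number of epochs grows; in finite samples it can be negative and is
deliberately not clipped (the surrogate-normalization step presumes a
signed statistic).  All three estimators return 0 when every Im S_j is
zero (the 0/0 case: pure zero-lag coupling, which the measures are
designed to ignore).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording import EpochSet

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "CrossSpectrumSet",
    "ConnectivitySpectrum",
    "epoch_cross_spectra",
    "wpli",
    "pli",
    "debiased_wpli_square",
    "band_average",
    "pairwise_connectivity",
    "connectivity_spectra",
]

MEASURES = ("debiased_wpli_square", "wpli", "pli")


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with inclusive integer bounds (Hz)."""

    name: str
    lo_hz: int
    hi_hz: int

    def __post_init__(self) -> None:
        if not (1 <= self.lo_hz <= self.hi_hz):
            raise ValueError(f"invalid band bounds ({self.lo_hz}, {self.hi_hz})")


#: Canonical analysis bands: theta, alpha, beta and the low-gamma band in
#: which the group synchrony difference concentrates.
DEFAULT_BANDS = (
    BandDefinition("theta", 4, 7),
    BandDefinition("alpha", 8, 13),
    BandDefinition("beta", 15, 23),
    BandDefinition("low_gamma", 25, 40),
)


@dataclass
class CrossSpectrumSet:
    """Per-epoch complex cross-spectra for one channel pair."""

    pair: tuple[str, str]
    freqs_hz: np.ndarray  # integer frequencies, 1..fs/2
    values: np.ndarray  # (n_epochs, n_freqs) complex

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]


@dataclass
class ConnectivitySpectrum:
    """A real-valued synchronization spectrum for one channel pair."""

    pair: tuple[str, str]
    freqs_hz: np.ndarray
    measure: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")


def _integer_bins(n_samples: int, fs_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """Indices and values of integer-Hz rFFT bins in 1..fs/2."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs_hz)
    mask = (freqs >= 1.0) & (freqs <= fs_hz / 2.0)
    mask &= np.isclose(freqs, np.round(freqs), atol=1e-9)
    return np.nonzero(mask)[0], np.round(freqs[mask]).astype(int)


def epoch_cross_spectra(epochs: EpochSet, pair: tuple[str, str]) -> CrossSpectrumSet:
    """Per-epoch cross-spectra S_j(f) = X1_j(f) conj(X2_j(f)) at integer f.

    Uses the retained (non-rejected) epochs only; the FFT is taken with a
    rectangular window so that 1-s epochs give exactly 1 Hz resolution.
    """
    i1 = epochs.channel_index(pair[0])
    i2 = epochs.channel_index(pair[1])
    data = epochs.retained
    if data.shape[0] < 2:
        raise ValueError("need at least 2 retained epochs for cross-spectra")
    idx, freqs = _integer_bins(epochs.n_samples, epochs.fs_hz)
    x1 = np.fft.rfft(data[:, i1, :], axis=-1)[:, idx]
    x2 = np.fft.rfft(data[:, i2, :], axis=-1)[:, idx]
    return CrossSpectrumSet(pair=(pair[0], pair[1]), freqs_hz=freqs, values=x1 * np.conj(x2))


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(den, dtype=float)
    good = den > 0
    out[good] = num[good] / den[good]
    return out


def wpli(cs: CrossSpectrumSet) -> ConnectivitySpectrum:
    """Weighted phase lag index |<Im S>| / <|Im S|> per frequency."""
    im = cs.values.imag
    vals = _safe_ratio(np.abs(im.mean(axis=0)), np.abs(im).mean(axis=0))
    return ConnectivitySpectrum(cs.pair, cs.freqs_hz, "wpli", vals)


def pli(cs: CrossSpectrumSet) -> ConnectivitySpectrum:
    """Phase lag index |<sign Im S>| per frequency (sign(0) = 0)."""
    im = cs.values.imag
    vals = np.abs(np.sign(im).mean(axis=0))
    return ConnectivitySpectrum(cs.pair, cs.freqs_hz, "pli", vals)


def debiased_wpli_square(cs: CrossSpectrumSet) -> ConnectivitySpectrum:
    """Debiased estimator of the squared WPLI.

    O(N) evaluation of the double sum over ordered epoch pairs j != k;
    requires at least two epochs.
    """
    if cs.n_epochs < 2:
        raise ValueError("debiased WPLI-square needs N >= 2 epochs")
    im = cs.values.imag
    sum_im = im.sum(axis=0)
    sum_sq = (im**2).sum(axis=0)
    sum_abs = np.abs(im).sum(axis=0)
    num = sum_im**2 - sum_sq
    den = sum_abs**2 - sum_sq
    vals = np.zeros_like(den)
    good = den > 0
    vals[good] = num[good] / den[good]
    return ConnectivitySpectrum(cs.pair, cs.freqs_hz, "debiased_wpli_square", vals)


_MEASURE_FN = {"wpli": wpli, "pli": pli, "debiased_wpli_square": debiased_wpli_square}


def band_average(spec: ConnectivitySpectrum, band: BandDefinition) -> float:
    """Arithmetic mean of the spectrum over the band's integer bins (inclusive)."""
    mask = (spec.freqs_hz >= band.lo_hz) & (spec.freqs_hz <= band.hi_hz)
    if not mask.any():
        raise ValueError(f"band {band.name} ({band.lo_hz}-{band.hi_hz} Hz) is empty")
    return float(spec.values[mask].mean())


def eeg_pairs(epochs: EpochSet) -> list[tuple[str, str]]:
    """All unordered EEG channel pairs, in label order."""
    return list(itertools.combinations(epochs.eeg_labels, 2))


def pairwise_connectivity(
    epochs: EpochSet,
    measure: str = "debiased_wpli_square",
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Band-averaged connectivity for all unordered EEG channel pairs.

    Returns
    -------
    table
        Tidy frame with columns channel_a, channel_b, band, measure, value
        (one row per pair per band).
    global_means
        Across-pairs mean per band — the "global" synchrony summary.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    fn = _MEASURE_FN[measure]
    rows = []
    for a, b in eeg_pairs(epochs):
        spec = fn(epoch_cross_spectra(epochs, (a, b)))
        for band in bands:
            rows.append((a, b, band.name, measure, band_average(spec, band)))
    table = pd.DataFrame(rows, columns=["channel_a", "channel_b", "band", "measure", "value"])
    global_means = table.groupby("band", sort=False)["value"].mean().to_dict()
    return table, global_means


def connectivity_spectra(
    epochs: EpochSet, measure: str = "debiased_wpli_square"
) -> pd.DataFrame:
    """Per-frequency connectivity for every EEG pair (for spectra plots)."""
    fn = _MEASURE_FN[measure]
    rows = []
    for a, b in eeg_pairs(epochs):
        spec = fn(epoch_cross_spectra(epochs, (a, b)))
        for f, v in zip(spec.freqs_hz, spec.values):
            rows.append((a, b, int(f), measure, float(v)))
    return pd.DataFrame(rows, columns=["channel_a", "channel_b", "freq_hz", "measure", "value"])


def global_band_statistic(
    epochs: EpochSet,
    band: BandDefinition,
    measure: str = "debiased_wpli_square",
) -> float:
    """Across-pairs mean band synchrony — the statistic the surrogate null targets.

    Equivalent to averaging `pairwise_connectivity`'s single-band table,
    but computed without the tidy-table plumbing because surrogate nulls
    evaluate it thousands of times per subject.
    """
    fn = _MEASURE_FN[measure]
    data = epochs.retained
    if data.shape[0] < 2:
        raise ValueError("need at least 2 retained epochs")
    idx, freqs = _integer_bins(epochs.n_samples, epochs.fs_hz)
    bmask = (freqs >= band.lo_hz) & (freqs <= band.hi_hz)
    if not bmask.any():
        raise ValueError(f"band {band.name} is empty at this resolution")
    eeg_idx = epochs.eeg_indices
    labels = epochs.eeg_labels
    X = np.fft.rfft(data[:, eeg_idx, :], axis=-1)[:, :, idx][:, :, bmask]
    total = 0.0
    n_pairs = 0
    for a in range(len(eeg_idx)):
        for b in range(a + 1, len(eeg_idx)):
            cs = CrossSpectrumSet(
                (labels[a], labels[b]), freqs[bmask], X[:, a, :] * np.conj(X[:, b, :])
            )
            total += float(fn(cs).values.mean())
            n_pairs += 1
    return total / n_pairs
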