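"""Empirical null distributions from channel-shuffled surrogate data.

Each channel's retained samples (concatenated across retained epochs) are
independently permuted and re-segmented, which destroys all temporal
structure while preserving each channel's marginal amplitude distribution
exactly.  Computing a synchrony statistic on many such surrogates gives a
per-subject empirical null against which the observed statistic is tested
(add-one permutation p-value) or z-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .recording import EpochSet

__all__ = [
    "NullDistribution",
    "shuffle_surrogate",
    "null_distribution",
    "empirical_p",
    "normalize",
]


@dataclass
class NullDistribution:
    """B surrogate values of one synchrony statistic for one subject."""

    values: np.ndarray
    statistic: str = "statistic"
    subject_id: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("null distribution must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("null distribution contains non-finite values")

    @property
    def B(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        """Sample standard deviation (denominator B - 1)."""
        return float(self.values.std(ddof=1)) if self.B > 1 else 0.0

    def summary(self, observed: float | None = None) -> dict:
        out = {
            "subject_id": self.subject_id,
            "statistic": self.statistic,
            "B": self.B,
            "mean": self.mean,
            "sd": self.sd,
            "seed": self.seed,
        }
        if observed is not None:
            out["observed"] = float(observed)
            out["p"] = empirical_p(observed, self)
            out["z"] = normalize(observed, self)
        return out


def shuffle_surrogate(epochs: EpochSet, rng: np.random.Generator) -> EpochSet:
    """One surrogate data set: per-channel random permutation of all samples.

    Operates on the retained epochs only; the output contains the same
    number of retained epochs (none rejected) with each channel's samples
    drawn — without replacement — from that channel's concatenated input,
    independently across channels.
    """
    data = epochs.retained  # (n_ret, n_ch, n_samp)
    n_ret, n_ch, n_samp = data.shape
    if n_ret < 1:
        raise ValueError("no retained epochs to shuffle")
    flat = data.transpose(1, 0, 2).reshape(n_ch, n_ret * n_samp)
    out = np.empty_like(flat)
    for c in range(n_ch):
        out[c] = flat[c, rng.permutation(n_ret * n_samp)]
    shuffled = out.reshape(n_ch, n_ret, n_samp).transpose(1, 0, 2)
    return EpochSet(
        epochs=shuffled,
        fs_hz=epochs.fs_hz,
        epoch_length_s=epochs.epoch_length_s,
        labels=epochs.labels,
        eog_labels=epochs.eog_labels,
    )


def null_distribution(
    epochs: EpochSet,
    statistic_fn: Callable[[EpochSet], float],
    B: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    statistic: str = "statistic",
    subject_id: str = "",
) -> NullDistribution:
    """B surrogate statistics with a reproducible per-replicate stream.

    Replicate b uses the b-th child of ``SeedSequence(seed)``, so results
    are independent of evaluation order and reproducible given the seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(B)
    vals = np.empty(B)
    for b in range(B):
        rng = np.random.default_rng(children[b])
        vals[b] = statistic_fn(shuffle_surrogate(epochs, rng))
    stored_seed = seed if isinstance(seed, int) else None
    return NullDistribution(
        values=vals, statistic=statistic, subject_id=subject_id, seed=stored_seed
    )


def empirical_p(
    observed: float, null: NullDistribution, alternative: str = "greater"
) -> float:
    """Add-one permutation p-value of ``observed`` against the null.

    One-sided "greater" by default (synchrony larger than chance);
    "less" and "two-sided" are available.
    """
    B = null.B
    p_greater = (1 + int(np.sum(null.values >= observed))) / (1 + B)
    if alternative == "greater":
        return p_greater
    p_less = (1 + int(np.sum(null.values <= observed))) / (1 + B)
    if alternative == "less":
        return p_less
    if alternative == "two-sided":
        return min(1.0, 2.0 * min(p_greater, p_less))
    raise ValueError(f"unknown alternative {alternative!r}")


def normalize(observed: float, null: NullDistribution) -> float:
    """z-score of the observed statistic: (observed − null mean) / null SD."""
    sd = null.sd
    if not sd > 0:
        raise ValueError(
            f"null distribution of {null.statistic!r} has zero standard deviation"
        )
    return (observed - null.mean) / sd
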