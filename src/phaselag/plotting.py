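"""Simple figures: across-pairs connectivity spectra and the
structure–function scatter."""

from __future__ import annotations

import pandas as pd


def plot_group_spectra(spectra: pd.DataFrame, cohort: pd.DataFrame, ax=None):
    """Across-pairs mean spectrum per group, ±1 SEM shading.

    ``spectra`` is the tidy per-frequency table written by the
    connectivity stage (subject_id, channel_a, channel_b, freq_hz, value).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    merged = spectra.merge(cohort[["subject_id", "group"]], on="subject_id")
    per_subj = merged.groupby(["group", "subject_id", "freq_hz"])["value"].mean().reset_index()
    for group, sub in per_subj.groupby("group"):
        g = sub.groupby("freq_hz")["value"]
        mean, sem = g.mean(), g.sem()
        ax.plot(mean.index, mean.values, label=group)
        ax.fill_between(mean.index, mean - sem, mean + sem, alpha=0.3)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("synchronization")
    ax.legend()
    return ax


def plot_structure_function(normalized_sync: pd.DataFrame, fa: pd.Series, ax=None):
    """Scatter of null-normalized synchrony against ROI FA."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(fa, normalized_sync["z"])
    ax.set_xlabel("fractional anisotropy")
    ax.set_ylabel("normalized synchrony (z)")
    return ax
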