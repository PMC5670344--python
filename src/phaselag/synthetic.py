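"""Synthetic resting-EEG cohorts with known phase-coupling structure.

The generative model is built so that the WPLI estimator family is its
natural detector and so that population values are available in closed
form / by quadrature for recovery tests:

* Each consecutive 1-s block of the recording draws a common carrier
  phase φ_b ~ Uniform(0, 2π).  Channel c's oscillatory component in
  block b is  A · cos(2π f0 t + φ_b + δ_c + η_{b,c})  with per-channel
  phase offsets δ_c and von Mises(0, κ) jitter η_{b,c}.  Large κ means
  tight phase coupling at the configured lags; κ = 0 means independent
  phases.
* Volume conduction is modeled as a shared broadband component added
  identically (zero-lag) to every EEG channel — invisible to phase-lag
  measures by construction.
* Ocular artifact is one low-frequency (< 4 Hz) smoothed process e(t)
  leaked into each EEG channel with fixed propagation factors and
  emitted (scaled) as the two EOG channels, so regression correction is
  exactly solvable.
* Independent Gaussian sensor noise per channel.
* Per-subject fractional anisotropy for a designated ROI is linearly
  coupled to the subject's coupling strength κ_i; all other ROIs carry
  baseline plus noise.

All randomness flows from a single seed through `numpy.random.SeedSequence`
spawning, so cohort generation is bit-reproducible given (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, signal, special

from .recording import ContinuousRecording, EpochSet
from .reference_data import DEFAULT_ROI_VOCABULARY, fa_reference

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_recording",
    "simulate_epochs",
    "simulate_cohort",
    "expected_wpli",
    "expected_pair_wpli",
]

DEFAULT_CHANNELS = ("Fz", "Cz", "Pz", "Oz", "C3", "C4")
DEFAULT_EOG = ("VEOGup", "VEOGdown")

_PI = math.pi


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Defaults mirror the acquisition this package targets: ~2.5 min
    eyes-closed recordings at 2,048 Hz on a reduced six-electrode montage
    plus two vertical EOG channels, with the group coupling difference
    carried at 32 Hz (inside the 25–40 Hz low-gamma band) and group
    κ-means of 4 (control) vs 0 (case).
    """

    n_per_group: dict = field(default_factory=lambda: {"case": 15, "control": 22})
    channel_labels: tuple = DEFAULT_CHANNELS
    eog_labels: tuple = DEFAULT_EOG
    fs_hz: float = 2048.0
    duration_s: float = 150.0
    f0_hz: float = 32.0
    #: per-EEG-channel phase offsets δ_c (rad); pairwise differences set the
    #: population phase lags the estimators should detect
    lag_rad: tuple = (0.0, 0.1 * _PI, 0.2 * _PI, 0.3 * _PI, 0.4 * _PI, 0.5 * _PI)
    kappa_mean_by_group: dict = field(default_factory=lambda: {"case": 0.0, "control": 4.0})
    kappa_sd: float = 0.5
    amplitude_uv: float = 10.0
    zero_lag_gain: float = 2.0
    noise_sd: float = 5.0
    #: per-EEG-channel leakage factors of the ocular source (frontal largest)
    eog_propagation: tuple = (0.12, 0.08, 0.05, 0.03, 0.06, 0.06)
    eog_amplitude_uv: float = 20.0
    #: fraction of 1-s blocks receiving an injected high-amplitude artifact
    artifact_rate: float = 0.0
    artifact_amplitude_uv: float = 250.0
    #: linear FA model for the designated ROI: fa = baseline + slope·(κ_i − κ̄) + ε
    fa_roi: tuple = ("inferior cerebellar peduncle", "right")
    fa_baseline: float = 0.285
    fa_slope: float = 0.005
    fa_noise_sd: float = 0.004
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "fs_hz",
            "duration_s",
            "f0_hz",
            "amplitude_uv",
            "zero_lag_gain",
            "noise_sd",
            "eog_amplitude_uv",
            "fa_baseline",
            "fa_slope",
            "fa_noise_sd",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"configuration parameter {name} must be finite")
        if not self.fs_hz > 2 * self.f0_hz:
            raise ValueError(f"fs_hz ({self.fs_hz}) must exceed 2·f0_hz ({2 * self.f0_hz})")
        if abs(self.duration_s * self.fs_hz - round(self.duration_s * self.fs_hz)) > 1e-9:
            raise ValueError("duration_s x fs_hz must be an integer sample count")
        if abs(self.fs_hz - round(self.fs_hz)) > 1e-9:
            raise ValueError("fs_hz must be integral (1-s blocks are sample-aligned)")
        if abs(self.duration_s - round(self.duration_s)) > 1e-9:
            raise ValueError("duration_s must be integral (whole 1-s blocks)")
        if any(k < 0 for k in self.kappa_mean_by_group.values()) or self.kappa_sd < 0:
            raise ValueError("kappa values must be >= 0")
        if self.fa_noise_sd < 0:
            raise ValueError("fa_noise_sd must be >= 0")
        if len(self.lag_rad) != len(self.channel_labels):
            raise ValueError("lag_rad must have one offset per EEG channel")
        if len(self.eog_propagation) != len(self.channel_labels):
            raise ValueError("eog_propagation must have one factor per EEG channel")
        if not 0 <= self.artifact_rate <= 1:
            raise ValueError("artifact_rate must be in [0, 1]")

    @property
    def all_labels(self) -> tuple:
        return tuple(self.channel_labels) + tuple(self.eog_labels)


@dataclass
class SyntheticCohort:
    """Generated recordings plus metadata, FA table and ground truth."""

    recordings: dict  # subject_id -> ContinuousRecording
    metadata: pd.DataFrame  # subject_id, group
    fa_table: pd.DataFrame  # subject_id, roi, side, fa
    truth: dict  # per-subject kappa, artifact blocks, config echo

    @property
    def subject_ids(self) -> list:
        return list(self.metadata["subject_id"])


def _von_mises_jitter(rng: np.random.Generator, kappa: float, size) -> np.ndarray:
    """Phase jitter draws; κ = 0 is uniform, effectively-infinite κ is 0."""
    if not np.isfinite(kappa) or kappa > 1e8:
        return np.zeros(size)
    if kappa == 0:
        return rng.uniform(-_PI, _PI, size)
    return rng.vonmises(0.0, kappa, size)


def _smooth_lowfreq(rng: np.random.Generator, n: int, fs_hz: float, cutoff_hz: float = 3.0) -> np.ndarray:
    """Unit-SD low-frequency (< ~4 Hz) process for the ocular source."""
    raw = rng.standard_normal(n)
    sos = signal.butter(4, cutoff_hz, btype="lowpass", fs=fs_hz, output="sos")
    e = signal.sosfiltfilt(sos, raw)
    sd = e.std()
    return e / sd if sd > 0 else e


def simulate_recording(
    config: SimulationConfig,
    kappa: float,
    rng: np.random.Generator,
    return_details: bool = False,
):
    """One subject's multichannel recording under coupling strength κ.

    Returns the recording, or ``(recording, details)`` where details
    holds the injected-artifact block indices (ground truth for
    rejection-rate tests).
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    fs = int(round(config.fs_hz))
    n_blocks = int(round(config.duration_s))
    n = fs * n_blocks
    t = np.arange(n) / fs
    n_eeg = len(config.channel_labels)

    phi = rng.uniform(0.0, 2 * _PI, n_blocks)  # common carrier phase per block
    eta = _von_mises_jitter(rng, kappa, (n_blocks, n_eeg))
    block_of = np.repeat(np.arange(n_blocks), fs)

    eeg = np.empty((n_eeg, n))
    carrier = 2 * _PI * config.f0_hz * t
    for c in range(n_eeg):
        phase = phi[block_of] + config.lag_rad[c] + eta[block_of, c]
        eeg[c] = config.amplitude_uv * np.cos(carrier + phase)

    if config.zero_lag_gain != 0:
        shared = rng.standard_normal(n)  # broadband, identical across channels
        eeg += config.zero_lag_gain * shared

    e = _smooth_lowfreq(rng, n, fs) * config.eog_amplitude_uv
    for c in range(n_eeg):
        eeg[c] += config.eog_propagation[c] * e

    if config.noise_sd > 0:
        eeg += rng.normal(0.0, config.noise_sd, (n_eeg, n))

    artifact_blocks: list[int] = []
    if config.artifact_rate > 0:
        n_art = int(round(config.artifact_rate * n_blocks))
        artifact_blocks = sorted(rng.choice(n_blocks, size=n_art, replace=False).tolist())
        tau = np.arange(fs) / fs
        burst = (
            config.artifact_amplitude_uv
            * np.hanning(fs)
            * np.sin(2 * _PI * 5.0 * tau + _PI / 4)
        )
        for i, b in enumerate(artifact_blocks):
            eeg[i % n_eeg, b * fs : (b + 1) * fs] += burst

    # EOG electrodes record the ocular source directly (opposite polarity
    # below the eye); noiseless so the leakage is exactly regressable.
    eog = np.vstack([e, -0.5 * e])

    rec = ContinuousRecording(
        data=np.vstack([eeg, eog]),
        fs_hz=float(fs),
        labels=config.all_labels,
        eog_labels=config.eog_labels,
    )
    if return_details:
        return rec, {"kappa": kappa, "artifact_blocks": artifact_blocks}
    return rec


def simulate_epochs(
    n_epochs: int,
    kappa: float,
    rng: np.random.Generator,
    fs_hz: float = 256.0,
    f0_hz: float = 32.0,
    lag_rad: tuple = (0.0, 0.5 * _PI),
    labels: tuple | None = None,
    amplitude_uv: float = 10.0,
    zero_lag_gain: float = 0.0,
    noise_sd: float = 5.0,
) -> EpochSet:
    """Epoched data straight from the phase model, at the analysis rate.

    Equivalent to generating with `simulate_recording` and epoching —
    blocks and epochs are both 1-s and sample-aligned, and the carrier
    sits on an integer frequency bin — but skips the continuous-time
    plumbing.  Used for estimator-level Monte-Carlo studies where the
    preprocessing chain is not under test.
    """
    fs = int(round(fs_hz))
    n_ch = len(lag_rad)
    if labels is None:
        labels = tuple(f"ch{i}" for i in range(n_ch))
    t = np.arange(fs) / fs
    carrier = 2 * _PI * f0_hz * t  # (fs,)
    phi = rng.uniform(0.0, 2 * _PI, n_epochs)
    eta = _von_mises_jitter(rng, kappa, (n_epochs, n_ch))
    phase = phi[:, None] + np.asarray(lag_rad)[None, :] + eta  # (n_epochs, n_ch)
    data = amplitude_uv * np.cos(carrier[None, None, :] + phase[:, :, None])
    if zero_lag_gain != 0:
        shared = rng.standard_normal((n_epochs, 1, fs))
        data = data + zero_lag_gain * shared
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, data.shape)
    return EpochSet(
        epochs=data, fs_hz=float(fs), epoch_length_s=1.0, labels=labels
    )


def _bessel_ratio(kappa: float, n: int = 1) -> float:
    """I_n(kappa) / I_0(kappa), overflow-safe."""
    if not np.isfinite(kappa):
        return 1.0
    return float(special.ive(n, kappa) / special.ive(0, kappa))


def _vm_pdf(x: np.ndarray, kappa: float) -> np.ndarray:
    # exp(kappa cos x) / (2 pi I0(kappa)) in exponentially-scaled form
    return np.exp(kappa * (np.cos(x) - 1.0)) / (2 * _PI * special.ive(0, kappa))


def expected_wpli(kappa: float, delta: float) -> float:
    """Population WPLI for phase difference Δθ = delta + von Mises(0, κ).

    Returns |E sin Δθ| / E |sin Δθ|, with the numerator in closed form
    (|sin δ| · I1(κ)/I0(κ)) and the denominator by adaptive quadrature to
    absolute tolerance better than 1e-8.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    sin_d = math.sin(delta)
    if not np.isfinite(kappa) or kappa > 1e12:
        return 0.0 if sin_d == 0 else 1.0
    num = abs(sin_d) * _bessel_ratio(kappa)
    if num == 0.0:
        return 0.0
    # integrand kinks where sin(delta + x) = 0, i.e. x = -delta mod pi
    k0 = (-delta) % (2 * _PI) - _PI
    pts = sorted({k0, (k0 + _PI) if k0 + _PI <= _PI else k0 - _PI})
    den, _ = integrate.quad(
        lambda x: abs(math.sin(delta + x)) * _vm_pdf(np.array(x), kappa),
        -_PI,
        _PI,
        points=pts,
        limit=200,
        epsabs=1e-10,
        epsrel=1e-10,
    )
    return num / den


def expected_pair_wpli(kappa: float, delta: float, n_grid: int = 1 << 15) -> float:
    """Population WPLI when BOTH channels carry von Mises(0, κ) jitter.

    The pairwise phase difference is Δθ = delta + η1 − η2; the density of
    η1 − η2 has Fourier coefficients (I_n(κ)/I_0(κ))², summed here to
    machine precision and integrated on a dense periodic grid.  This is
    the recovery oracle matching `simulate_recording` / `simulate_epochs`.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    sin_d = math.sin(delta)
    if not np.isfinite(kappa) or kappa > 1e12:
        return 0.0 if sin_d == 0 else 1.0
    c1 = _bessel_ratio(kappa)
    num = abs(sin_d) * c1 * c1
    if num == 0.0:
        return 0.0
    x = -_PI + 2 * _PI * np.arange(n_grid) / n_grid
    dens = np.full(n_grid, 1.0 / (2 * _PI))
    n = 1
    while True:
        cn = _bessel_ratio(kappa, n)
        if cn * cn < 1e-17 or n > 4 * int(kappa + 10):
            break
        dens += (cn * cn / _PI) * np.cos(n * x)
        n += 1
    den = float(np.mean(np.abs(np.sin(delta + x)) * dens) * 2 * _PI)
    return num / den


def _subject_ids(n_per_group: dict) -> list[tuple[str, str]]:
    out = []
    for group in sorted(n_per_group):
        for i in range(n_per_group[group]):
            out.append((f"sub-{group}{i + 1:02d}", group))
    return out


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """A full two-group cohort: recordings, metadata, FA table, truth.

    Per subject, κ_i ~ Normal(group mean, kappa_sd) truncated (clipped)
    at 0; the designated ROI's FA follows
    fa_baseline + fa_slope · (κ_i − mean κ) + Normal(0, fa_noise_sd),
    every other ROI its published baseline plus the same noise.
    """
    if len(config.n_per_group) != 2:
        raise ValueError("exactly two groups must be configured")
    if any(n < 2 for n in config.n_per_group.values()):
        raise ValueError("need at least 2 subjects per group")

    ids = _subject_ids(config.n_per_group)
    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(len(ids) + 1)
    fa_rng = np.random.default_rng(streams[-1])

    kappas = {}
    recordings = {}
    details = {}
    for (sid, group), ss in zip(ids, streams):
        rng = np.random.default_rng(ss)
        k = max(0.0, rng.normal(config.kappa_mean_by_group[group], config.kappa_sd))
        kappas[sid] = k
        rec, det = simulate_recording(config, k, rng, return_details=True)
        recordings[sid] = rec
        details[sid] = det

    metadata = pd.DataFrame(ids, columns=["subject_id", "group"])

    baselines = {
        (r.roi, r.side): r.control_mean for r in fa_reference().itertuples()
    }
    kbar = float(np.mean(list(kappas.values())))
    fa_rows = []
    for sid, _group in ids:
        for roi, side in DEFAULT_ROI_VOCABULARY:
            base = config.fa_baseline if (roi, side) == config.fa_roi else baselines[(roi, side)]
            fa = base + fa_rng.normal(0.0, config.fa_noise_sd)
            if (roi, side) == config.fa_roi:
                fa += config.fa_slope * (kappas[sid] - kbar)
            fa_rows.append((sid, roi, side, float(np.clip(fa, 0.0, 1.0))))
    fa_table = pd.DataFrame(fa_rows, columns=["subject_id", "roi", "side", "fa"])

    truth = {
        "kappa": kappas,
        "kappa_mean": kbar,
        "artifact_blocks": {sid: d["artifact_blocks"] for sid, d in details.items()},
        "seed": config.seed,
    }
    return SyntheticCohort(
        recordings=recordings, metadata=metadata, fa_table=fa_table, truth=truth
    )
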