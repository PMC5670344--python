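"""File formats: recordings (TSV with JSON sidecar, 16-bit EDF), cohort
metadata / FA tables (CSV), and cohort export.

EDF reading goes through ``mne``; writing uses a minimal standard EDF
writer (no pre-installed package exports EDF), which stores each channel
as 16-bit integers against a symmetric physical range — round trips are
exact to one quantization step.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import ContinuousRecording
from .reference_data import DEFAULT_ROI_VOCABULARY

__all__ = [
    "read_recording",
    "write_recording",
    "write_recording_tsv",
    "write_recording_edf",
    "read_tables",
    "write_cohort",
]

logger = logging.getLogger("phaselag")

_DEFAULT_EOG_MARKERS = ("EOG",)


def _guess_eog(labels) -> tuple:
    return tuple(l for l in labels if any(m in l.upper() for m in _DEFAULT_EOG_MARKERS))


# ---------------------------------------------------------------- TSV

def write_recording_tsv(rec: ContinuousRecording, path) -> Path:
    """Tab-separated samples (one row per sample) plus a JSON sidecar.

    The sidecar (same stem, ``.json``) stores fs_hz, eog_labels and units
    so the file round-trips without external configuration.
    """
    path = Path(path)
    header = "\t".join(rec.labels)
    np.savetxt(path, rec.data.T, fmt="%.17g", delimiter="\t", header=header, comments="")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {"fs_hz": rec.fs_hz, "eog_labels": list(rec.eog_labels), "units": "uV"},
            indent=1,
        )
    )
    return path


def _read_recording_tsv(path: Path, fs_hz, eog_labels) -> ContinuousRecording:
    with open(path) as fh:
        labels = tuple(fh.readline().rstrip("\n").split("\t"))
    if len(set(labels)) != len(labels):
        raise ValueError(f"{path}: duplicate channel labels in header")
    data = np.loadtxt(path, skiprows=1, delimiter="\t", ndmin=2).T
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fs_hz = fs_hz if fs_hz is not None else meta.get("fs_hz")
        eog_labels = eog_labels if eog_labels is not None else tuple(meta.get("eog_labels", ()))
    if fs_hz is None:
        raise ValueError(f"{path}: sampling rate unknown (no sidecar and fs_hz not given)")
    if eog_labels is None:
        eog_labels = _guess_eog(labels)
    return ContinuousRecording(data=data, fs_hz=float(fs_hz), labels=labels, eog_labels=eog_labels)


# ---------------------------------------------------------------- EDF

def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def write_recording_edf(rec: ContinuousRecording, path) -> Path:
    """Write a standard 16-bit EDF file with 1-second data records.

    The physical range per signal is symmetric (±ceil of the absolute
    maximum), the digital range ±32767, so the quantization step is
    ``2·pmax / 65534``.  Requires an integral sampling rate; a trailing
    partial second is zero-padded.
    """
    path = Path(path)
    fs = int(round(rec.fs_hz))
    if abs(rec.fs_hz - fs) > 1e-9:
        raise ValueError("EDF export requires an integral sampling rate")
    n_sig = rec.n_channels
    n_records = math.ceil(rec.n_samples / fs)
    padded = np.zeros((n_sig, n_records * fs))
    padded[:, : rec.n_samples] = rec.data

    pmax = np.maximum(np.ceil(np.abs(padded).max(axis=1)), 1.0)
    dmin, dmax = -32767, 32767
    scale = pmax / dmax  # µV per digital unit
    digital = np.round(padded / scale[:, None]).astype("<i2")

    header = bytearray()
    header += _ascii("0", 8)
    header += _ascii("X X X X", 80)  # local patient id (anonymous)
    header += _ascii("Startdate X X X X", 80)
    header += _ascii("01.01.00", 8)
    header += _ascii("00.00.00", 8)
    header += _ascii(256 * (1 + n_sig), 8)
    header += _ascii("", 44)
    header += _ascii(n_records, 8)
    header += _ascii("1", 8)  # record duration in s
    header += _ascii(n_sig, 4)

    def field(values, width):
        return b"".join(_ascii(v, width) for v in values)

    header += field(rec.labels, 16)
    header += field([""] * n_sig, 80)  # transducer
    header += field(["uV"] * n_sig, 8)
    header += field([f"{-p:g}" for p in pmax], 8)
    header += field([f"{p:g}" for p in pmax], 8)
    header += field([str(dmin)] * n_sig, 8)
    header += field([str(dmax)] * n_sig, 8)
    header += field([""] * n_sig, 80)  # prefiltering
    header += field([str(fs)] * n_sig, 8)
    header += field([""] * n_sig, 32)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.astype("<i2").tobytes())
    return path


def _read_recording_edf(path: Path, eog_labels) -> ContinuousRecording:
    import mne  # deferred: slow import, only needed for EDF

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = tuple(raw.ch_names)
    if len(set(labels)) != len(labels):
        raise ValueError(f"{path}: duplicate channel labels")
    data = raw.get_data() * 1e6  # mne returns volts
    if eog_labels is None:
        eog_labels = _guess_eog(labels)
    return ContinuousRecording(
        data=data, fs_hz=float(raw.info["sfreq"]), labels=labels, eog_labels=eog_labels
    )


def read_recording(path, format: str | None = None, fs_hz=None, eog_labels=None) -> ContinuousRecording:
    """Read a recording from TSV (+sidecar) or EDF; format inferred from suffix."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "tsv")
    if fmt == "edf":
        return _read_recording_edf(path, eog_labels)
    if fmt == "tsv":
        return _read_recording_tsv(path, fs_hz, eog_labels)
    raise ValueError(f"unknown recording format {fmt!r}")


def write_recording(rec: ContinuousRecording, path, format: str | None = None) -> Path:
    path = Path(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "tsv")
    if fmt == "edf":
        return write_recording_edf(rec, path)
    if fmt == "tsv":
        return write_recording_tsv(rec, path)
    raise ValueError(f"unknown recording format {fmt!r}")


# ---------------------------------------------------------------- tables

VALID_GROUPS = {"case", "control"}


def read_tables(
    cohort_csv,
    fa_csv,
    strict_roi: bool = True,
    roi_vocabulary=DEFAULT_ROI_VOCABULARY,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate the cohort metadata and per-ROI FA tables.

    Checks: required columns, unique subject ids, known group labels,
    FA in [0, 1], unique (subject, roi, side) keys, and — when
    ``strict_roi`` — ROI names restricted to the configured vocabulary.
    """
    cohort = pd.read_csv(cohort_csv)
    if not {"subject_id", "group"} <= set(cohort.columns):
        raise ValueError(f"{cohort_csv}: needs subject_id and group columns")
    dup = cohort["subject_id"].duplicated()
    if dup.any():
        raise ValueError(f"{cohort_csv}: duplicate subject_id at rows {list(cohort.index[dup])}")
    bad = ~cohort["group"].isin(VALID_GROUPS)
    if bad.any():
        raise ValueError(
            f"{cohort_csv}: unknown group labels at rows {list(cohort.index[bad])} "
            f"(expected one of {sorted(VALID_GROUPS)})"
        )

    fa = pd.read_csv(fa_csv)
    if not {"subject_id", "roi", "side", "fa"} <= set(fa.columns):
        raise ValueError(f"{fa_csv}: needs subject_id, roi, side, fa columns")
    out_of_range = ~fa["fa"].between(0.0, 1.0)
    if out_of_range.any():
        raise ValueError(
            f"{fa_csv}: FA outside [0, 1] at rows {list(fa.index[out_of_range])}"
        )
    dup = fa.duplicated(subset=["subject_id", "roi", "side"])
    if dup.any():
        raise ValueError(f"{fa_csv}: duplicate (subject, roi, side) at rows {list(fa.index[dup])}")
    if roi_vocabulary is not None:
        vocab = set(roi_vocabulary)
        unknown = ~fa.apply(lambda r: (r["roi"], r["side"]) in vocab, axis=1)
        if unknown.any():
            msg = f"{fa_csv}: unknown ROI at rows {list(fa.index[unknown])}"
            if strict_roi:
                raise ValueError(msg)
            logger.warning(msg)
    return cohort, fa


def write_cohort(cohort, outdir, format: str = "tsv") -> dict:
    """Write a synthetic cohort: one recording file per subject plus
    metadata CSV, FA CSV and a truth JSON (per-subject κ) for tests."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suffix = ".edf" if format == "edf" else ".tsv"
    rec_paths = {}
    for sid, rec in cohort.recordings.items():
        rec_paths[sid] = str(write_recording(rec, outdir / f"{sid}{suffix}", format=format))
    cohort.metadata.to_csv(outdir / "cohort.csv", index=False)
    cohort.fa_table.to_csv(outdir / "fa.csv", index=False)
    truth = dict(cohort.truth)
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return {
        "recordings": rec_paths,
        "cohort_csv": str(outdir / "cohort.csv"),
        "fa_csv": str(outdir / "fa.csv"),
        "truth_json": str(outdir / "truth.json"),
    }
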