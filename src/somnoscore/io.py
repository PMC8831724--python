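"""Readers and writers for recordings and hypnograms.

Two recording formats are supported:

* **EDF** (16-bit): written by :mod:`somnoscore.edf`, read back through
  ``mne.io.read_raw_edf``.  The EEG channel carries µV units and the
  digitizer rail as its physical range; accelerometer axes (or a
  precomputed magnitude) carry G units.  Schedule metadata that EDF cannot
  represent (start offset, light/dark durations) is round-tripped through
  the header's free-text recording-identification field.
* **Delimited text**: comma-separated, header row, '.' decimal, one sample
  per row, with metadata in leading ``#``-comment lines.  Columns are
  ``time,eeg,ax,ay,az`` (axes) or ``time,eeg,motion`` (magnitude).

Hypnograms are CSV with columns ``epoch_index,stage,substage``.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Hypnogram, Recording, ValidationError
from .edf import EdfSignal, read_edf_header, write_edf

__all__ = [
    "read_recording",
    "write_recording",
    "read_hypnogram",
    "write_hypnogram",
    "FormatError",
]

_MOTION_PHYS_G = 8.0  # accelerometer physical range written to EDF (±G)

_META_KEYS = ("start_offset_s", "light_phase_s", "analyzed_dark_s")


class FormatError(ValueError):
    """Raised when an input file is missing required channels or structure."""


def _infer_format(path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix in (".csv", ".txt", ".tsv"):
        return "delimited"
    raise FormatError(f"cannot infer format from suffix {suffix!r}; pass format=")


def read_recording(path, format: str | None = None) -> Recording:
    """Read a recording from EDF or delimited text.

    The file must provide one EEG channel and either three accelerometer
    axes or a precomputed motion magnitude; the magnitude is canonicalized
    at ingest as the Euclidean norm of the axes.
    """
    fmt = format or _infer_format(path)
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "delimited":
        return _read_delimited(path)
    raise FormatError(f"unknown format {fmt!r}")


def write_recording(rec: Recording, path, format: str | None = None) -> None:
    fmt = format or _infer_format(path)
    if fmt == "edf":
        _write_edf(rec, path)
    elif fmt == "delimited":
        _write_delimited(rec, path)
    else:
        raise FormatError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------- EDF

def _meta_string(rec: Recording) -> str:
    return " ".join(f"{k}={getattr(rec, k):g}" for k in _META_KEYS)


def _parse_meta(recording_id: str) -> dict:
    out = {}
    for token in recording_id.split():
        if "=" in token:
            key, _, value = token.partition("=")
            if key in _META_KEYS:
                try:
                    out[key] = float(value)
                except ValueError:
                    pass
    return out


def _write_edf(rec: Recording, path) -> None:
    if rec.motion_rate_hz != rec.sample_rate_hz and rec.motion_rate_hz is not None:
        mrate = rec.motion_rate_hz
    else:
        mrate = rec.sample_rate_hz
    signals = [
        EdfSignal("EEG", rec.eeg, rec.sample_rate_hz, -rec.adc_rail, rec.adc_rail, "uV"),
    ]
    if rec.motion_axes is not None:
        for label, ax in zip(("MotionX", "MotionY", "MotionZ"), rec.motion_axes):
            signals.append(EdfSignal(label, ax, mrate, -_MOTION_PHYS_G, _MOTION_PHYS_G, "G"))
    else:
        signals.append(EdfSignal("Motion", rec.motion, mrate, -_MOTION_PHYS_G, _MOTION_PHYS_G, "G"))
    write_edf(path, signals, recording_id=_meta_string(rec))


def _read_edf(path) -> Recording:
    import mne

    header = read_edf_header(path)
    sig_meta = {s["label"]: s for s in header["signals"]}
    labels = list(sig_meta)
    axis_labels = [l for l in ("MotionX", "MotionY", "MotionZ") if l in labels]
    has_magnitude = "Motion" in labels
    if "EEG" not in labels:
        raise FormatError(f"{path}: no EEG channel (channels: {labels})")
    if not has_magnitude and len(axis_labels) != 3:
        raise FormatError(
            f"{path}: no accelerometer channels (need Motion or MotionX/Y/Z; got {labels})"
        )

    raw = mne.io.read_raw_edf(os.fspath(path), preload=True, verbose="error")
    data = {}
    for name in raw.ch_names:
        idx = raw.ch_names.index(name)
        x = raw.get_data(picks=[idx])[0]
        unit = sig_meta.get(name, {}).get("unit", "")
        # mne converts recognized voltage dimensions to SI; bring µV back.
        if unit.lower() in ("uv", "µv"):
            x = x * 1e6
        data[name] = x
    meta = _parse_meta(header["recording_id"])
    eeg = data["EEG"]
    if axis_labels:
        axes = np.vstack([data[l] for l in ("MotionX", "MotionY", "MotionZ")])
        motion = Recording.motion_magnitude(axes)
    else:
        axes = None
        motion = data["Motion"]
    return Recording(
        eeg=eeg,
        motion=motion,
        sample_rate_hz=float(raw.info["sfreq"]),
        motion_rate_hz=float(raw.info["sfreq"]),
        adc_rail=float(sig_meta["EEG"]["physical_max"]),
        motion_axes=axes,
        **meta,
    )


# ---------------------------------------------------------------- delimited

def _write_delimited(rec: Recording, path) -> None:
    n = rec.n_samples
    t = np.arange(n) / rec.sample_rate_hz
    cols = {"time": t, "eeg": rec.eeg}
    if rec.motion_axes is not None and rec.motion_axes.shape[1] == n:
        cols["ax"], cols["ay"], cols["az"] = rec.motion_axes
    else:
        if rec.motion.size != n:
            raise FormatError(
                "delimited format stores one sample per row; motion must share the EEG rate"
            )
        cols["motion"] = rec.motion
    with open(path, "w") as fh:
        fh.write(f"# sample_rate_hz={rec.sample_rate_hz:g}\n")
        fh.write(f"# adc_rail={rec.adc_rail:g}\n")
        for key in _META_KEYS:
            fh.write(f"# {key}={getattr(rec, key):g}\n")
        pd.DataFrame(cols).to_csv(fh, index=False)


def _read_delimited(path) -> Recording:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            token = line[1:].strip()
            if "=" in token:
                key, _, value = token.partition("=")
                meta[key.strip()] = float(value)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if "eeg" not in df.columns:
        raise FormatError(f"{path}: missing 'eeg' column (columns: {list(df.columns)})")
    if "sample_rate_hz" in meta:
        rate = meta.pop("sample_rate_hz")
    elif "time" in df.columns and len(df) > 1:
        dt = np.diff(df["time"].to_numpy())
        if np.ptp(dt) > 1e-6:
            raise ValidationError(f"{path}: time column is not uniformly sampled")
        rate = 1.0 / float(np.median(dt))
    else:
        raise FormatError(f"{path}: no sample rate (no metadata line and no time column)")
    if {"ax", "ay", "az"} <= set(df.columns):
        axes = df[["ax", "ay", "az"]].to_numpy().T
        motion = Recording.motion_magnitude(axes)
    elif "motion" in df.columns:
        axes = None
        motion = df["motion"].to_numpy()
    else:
        raise FormatError(f"{path}: no motion columns (need ax,ay,az or motion)")
    kwargs = {k: v for k, v in meta.items() if k in _META_KEYS or k == "adc_rail"}
    return Recording(
        eeg=df["eeg"].to_numpy(),
        motion=motion,
        sample_rate_hz=rate,
        motion_axes=axes,
        **kwargs,
    )


# ---------------------------------------------------------------- hypnograms

def write_hypnogram(h: Hypnogram, path) -> None:
    pd.DataFrame(
        {
            "epoch_index": np.arange(len(h)),
            "stage": h.stages,
            "substage": h.substages,
        }
    ).to_csv(path, index=False)


def read_hypnogram(path) -> Hypnogram:
    # keep_default_na: the substage token "NA" is a label, not a missing value
    df = pd.read_csv(path, dtype={"stage": str, "substage": str}, keep_default_na=False)
    required = {"epoch_index", "stage", "substage"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: hypnogram needs columns {sorted(required)}")
    if len(df) == 0:
        return Hypnogram(stages=np.array([], dtype="<U6"), substages=np.array([], dtype="<U6"))
    df = df.sort_values("epoch_index")
    # Hypnogram validation rejects unknown stage tokens.
    return Hypnogram(stages=df["stage"].to_numpy(), substages=df["substage"].to_numpy())
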