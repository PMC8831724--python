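"""Minimal 16-bit EDF writer.

Recordings are read back with :mod:`mne`; no EDF *writer* is bundled with the
scientific stack this package targets, so a small standards-conformant writer
is provided here.  It emits plain EDF (not EDF+): ASCII header, one data
record per second, little-endian 16-bit samples scaled linearly between the
declared physical and digital ranges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EdfSignal", "write_edf", "read_edf_header", "read_edf_signal_headers"]

_DIG_MIN, _DIG_MAX = -32768, 32767


@dataclass
class EdfSignal:
    """One channel to be written: physical samples plus scaling metadata."""

    label: str
    data: np.ndarray
    rate_hz: float
    physical_min: float
    physical_max: float
    unit: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.physical_min >= self.physical_max:
            raise ValueError("physical_min must be < physical_max")
        spr = self.rate_hz * 1.0
        if abs(spr - round(spr)) > 1e-9:
            raise ValueError("sampling rate must be an integer number of samples per 1-s record")


def _field(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {value!r} > {width} chars")
    return b.ljust(width)


def write_edf(path, signals: list[EdfSignal], start_date: str = "01.01.00",
              start_time: str = "00.00.00", recording_id: str = "X") -> None:
    """Write channels to ``path`` as 16-bit EDF with 1-s data records.

    All channels must span the same whole number of seconds.  Values outside
    a channel's physical range are clipped to the rail (by EDF's linear
    scaling they cannot be represented anyway).
    """
    if not signals:
        raise ValueError("no signals to write")
    n_records = None
    for s in signals:
        nr = s.data.size / s.rate_hz
        if abs(nr - round(nr)) > 1e-9:
            raise ValueError(f"channel {s.label}: length is not a whole number of seconds")
        nr = int(round(nr))
        if n_records is None:
            n_records = nr
        elif nr != n_records:
            raise ValueError("channels span different durations")
    ns = len(signals)

    header = b"".join(
        [
            _field("0", 8),
            _field("X", 80),
            _field(recording_id, 80),
            _field(start_date, 8),
            _field(start_time, 8),
            _field(str(256 * (ns + 1)), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field("1", 8),
            _field(str(ns), 4),
        ]
    )
    per_signal = [
        [_field(s.label, 16) for s in signals],
        [_field("", 80) for s in signals],                       # transducer
        [_field(s.unit, 8) for s in signals],
        [_field(f"{s.physical_min:g}", 8) for s in signals],
        [_field(f"{s.physical_max:g}", 8) for s in signals],
        [_field(str(_DIG_MIN), 8) for s in signals],
        [_field(str(_DIG_MAX), 8) for s in signals],
        [_field("", 80) for s in signals],                       # prefiltering
        [_field(str(int(round(s.rate_hz))), 8) for s in signals],
        [_field("", 32) for s in signals],
    ]
    header += b"".join(b"".join(block) for block in per_signal)

    digitized = []
    for s in signals:
        span = s.physical_max - s.physical_min
        dig = np.round(
            (np.clip(s.data, s.physical_min, s.physical_max) - s.physical_min)
            / span * (_DIG_MAX - _DIG_MIN) + _DIG_MIN
        ).astype("<i2")
        digitized.append(dig)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for s, dig in zip(signals, digitized):
                spr = int(round(s.rate_hz))
                fh.write(dig[r * spr : (r + 1) * spr].tobytes())


def read_edf_signal_headers(path) -> list[dict]:
    """Read per-channel metadata (label, unit, physical range, rate) from an EDF header.

    Sample data are read through :func:`mne.io.read_raw_edf`; this helper only
    recovers scaling metadata (e.g. the digitizer rail) that mne does not
    surface in its public Raw interface.
    """
    return read_edf_header(path)["signals"]


def read_edf_header(path) -> dict:
    """Parse the full ASCII EDF header: recording id plus per-channel metadata."""
    with open(path, "rb") as fh:
        fixed = fh.read(256)
        ns = int(fixed[252:256].decode("ascii").strip())
        raw = fh.read(256 * ns)
    recording_id = fixed[88:168].decode("ascii").strip()
    widths = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
    offset = 0
    blocks = []
    for w in widths:
        blocks.append([raw[offset + i * w : offset + (i + 1) * w].decode("ascii").strip()
                       for i in range(ns)])
        offset += ns * w
    out = []
    for i in range(ns):
        out.append(
            {
                "label": blocks[0][i],
                "unit": blocks[2][i],
                "physical_min": float(blocks[3][i]),
                "physical_max": float(blocks[4][i]),
                "samples_per_record": int(blocks[8][i]),
            }
        )
    return {"recording_id": recording_id, "signals": out}
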