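"""Minimal EDF (European Data Format) codec.

Implements the subset of EDF needed to persist multichannel EEG: one header,
identical integer sampling rate on every signal, 1-second data records of
little-endian 16-bit integers.  Physical units are microvolts.  The last
record is zero-padded when the signal length is not a whole number of
records, so a read-back recording may be up to ``fs - 1`` samples longer
than what was written.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .exceptions import FormatError, SchemaError
from .io import Recording

_HDR = 256  # bytes, fixed part
_DIG_MAX = 32767


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b.ljust(width)


def write_edf(rec: Recording, path) -> None:
    """Write a recording as EDF with 1-second records.

    Requires an integer sampling rate (record layout is samples-per-second).
    Each channel is scaled to a symmetric physical range covering its data,
    quantized to 16 bits.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per record per signal
    n_ch = rec.n_channels
    n_rec = math.ceil(rec.n_samples / spr)
    n_pad = n_rec * spr - rec.n_samples

    data = rec.data
    if n_pad:
        data = np.concatenate([data, np.zeros((n_ch, n_pad))], axis=1)

    # Per-channel symmetric physical range; degenerate all-zero channels get
    # a unit range so the gain is finite.
    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    gain = phys_max / _DIG_MAX
    digital = np.round(data / gain[:, None]).astype("<i2")

    header = bytearray()
    header += _field("0", 8)
    header += _field(rec.subject_id or "X", 80)
    header += _field("Startdate 01-JAN-2000", 80)
    header += _field("01.01.00", 8)
    header += _field("00.00.00", 8)
    header += _field(str(_HDR + 256 * n_ch), 8)
    header += _field("", 44)
    header += _field(str(n_rec), 8)
    header += _field("1", 8)  # record duration, seconds
    header += _field(str(n_ch), 4)

    labels = [f"EEG {lab}"[:16] for lab in rec.channel_labels]
    for lab in labels:
        header += _field(lab, 16)
    for _ in range(n_ch):
        header += _field("", 80)  # transducer
    for _ in range(n_ch):
        header += _field("uV", 8)
    for p in phys_max:
        header += _field(f"{-p:.6g}"[:8], 8)
    for p in phys_max:
        header += _field(f"{p:.6g}"[:8], 8)
    for _ in range(n_ch):
        header += _field(str(-_DIG_MAX), 8)
    for _ in range(n_ch):
        header += _field(str(_DIG_MAX), 8)
    for _ in range(n_ch):
        header += _field("", 80)  # prefiltering
    for _ in range(n_ch):
        header += _field(str(spr), 8)
    for _ in range(n_ch):
        header += _field("", 32)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        # record-major, signal-contiguous within a record
        for r in range(n_rec):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())


def read_edf(path) -> Recording:
    """Read an EDF file written by :func:`write_edf` (or compatible)."""
    raw = Path(path).read_bytes()
    if len(raw) < _HDR:
        raise FormatError("file too short to be EDF")

    def sfield(off: int, width: int) -> str:
        return raw[off:off + width].decode("ascii", errors="replace").strip()

    version = sfield(0, 8)
    if version != "0":
        raise FormatError(f"unsupported EDF version {version!r}")
    subject_id = sfield(8, 80)
    n_rec = int(sfield(236, 8))
    rec_dur = float(sfield(244, 8))
    n_ch = int(sfield(252, 4))
    if rec_dur <= 0 or n_ch < 1:
        raise FormatError("invalid EDF header")

    off = _HDR

    def per_signal(width: int):
        nonlocal off
        vals = [sfield(off + i * width, width) for i in range(n_ch)]
        off += n_ch * width
        return vals

    labels = per_signal(16)
    per_signal(80)  # transducer
    per_signal(8)   # physical dimension
    phys_min = [float(v) for v in per_signal(8)]
    phys_max = [float(v) for v in per_signal(8)]
    dig_min = [int(v) for v in per_signal(8)]
    dig_max = [int(v) for v in per_signal(8)]
    per_signal(80)  # prefiltering
    spr = [int(v) for v in per_signal(8)]
    per_signal(32)

    if len(set(spr)) != 1:
        raise FormatError("mixed per-signal sampling rates are not supported")
    spr0 = spr[0]
    fs = spr0 / rec_dur

    body = np.frombuffer(raw[off:], dtype="<i2")
    expected = n_rec * n_ch * spr0
    if body.size < expected:
        raise FormatError("EDF body shorter than header declares")
    body = body[:expected].reshape(n_rec, n_ch, spr0)
    digital = body.transpose(1, 0, 2).reshape(n_ch, n_rec * spr0).astype(float)

    data = np.empty_like(digital)
    for c in range(n_ch):
        if dig_max[c] == dig_min[c]:
            raise FormatError("degenerate digital range")
        g = (phys_max[c] - phys_min[c]) / (dig_max[c] - dig_min[c])
        data[c] = (digital[c] - dig_min[c]) * g + phys_min[c]

    clean = [lab[4:] if lab.startswith("EEG ") else lab for lab in labels]
    if len(set(clean)) != len(clean):
        raise SchemaError("duplicate channel labels in EDF")
    return Recording(data=data, fs=fs, channel_labels=clean, subject_id=subject_id)
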