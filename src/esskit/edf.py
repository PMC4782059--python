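"""Minimal European Data Format (EDF) reader/writer.

EDF stores multichannel time series as a 256-byte fixed header, one
256-byte descriptor block per signal, and a sequence of data records of
16-bit little-endian integers with per-channel linear scaling between
digital and physical units.  This module implements the classic (non-EDF+)
profile used for the container payloads: a common integer sampling rate
for all channels and one-second data records.

Values are exchanged as microvolts (physical dimension ``uV``) in float
arrays of shape (channels, samples).  Writing quantizes to 16 bits using
a per-channel scale derived from the observed minimum/maximum; the scale
is recorded in the header, so a read-back reproduces the signal up to
quantization (relative error ~= range / 65536).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import SignalError

__all__ = ["EdfData", "EdfHeader", "read_edf", "read_edf_header", "write_edf"]

_DIG_MIN = -32768
_DIG_MAX = 32767


@dataclass
class EdfHeader:
    n_channels: int
    n_records: int
    record_duration: float
    samples_per_record: list[int]
    channel_labels: list[str]
    physical_dims: list[str]

    @property
    def duration_seconds(self) -> float:
        return self.n_records * self.record_duration

    @property
    def sampling_rate(self) -> float:
        if not self.samples_per_record or self.record_duration <= 0:
            return 0.0
        return self.samples_per_record[0] / self.record_duration


@dataclass
class EdfData:
    data: np.ndarray  # (channels, samples), physical units (uV)
    sampling_rate: float
    channel_labels: list[str]
    header: EdfHeader


def _field(value: str, width: int) -> bytes:
    raw = value.encode("ascii", "replace")[:width]
    return raw.ljust(width)


def write_edf(
    path: str | Path,
    data: np.ndarray,
    sampling_rate: float,
    channel_labels: list[str],
    physical_dim: str = "uV",
    patient_id: str = "X X X X",
    recording_id: str = "Startdate 01-JAN-2000 X X X",
) -> None:
    """Write *data* (channels x samples, physical units) as 16-bit EDF.

    The sampling rate must be a positive integer and the sample count a
    multiple of it (whole one-second records).  Header date/time fields
    are fixed constants so output bytes depend only on the data.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2:
        raise SignalError("data must be a (channels, samples) matrix")
    n_ch, n_samp = data.shape
    if n_ch != len(channel_labels):
        raise SignalError("channel_labels length must equal channel count")
    rate = int(round(sampling_rate))
    if rate <= 0 or abs(rate - sampling_rate) > 1e-9:
        raise SignalError(
            f"EDF writer requires a positive integer sampling rate, got {sampling_rate}"
        )
    if n_samp % rate != 0:
        raise SignalError(
            f"sample count {n_samp} is not a whole number of 1 s records at {rate} Hz"
        )
    n_records = n_samp // rate

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmin = np.where(flat, pmin - 1.0, pmin)
    pmax = np.where(flat, pmax + 1.0, pmax)
    # EDF headers hold 8 ascii chars per physical bound; round outward so
    # every sample stays inside the recorded physical range.
    pmin = np.floor(pmin * 1e3) / 1e3
    pmax = np.ceil(pmax * 1e3) / 1e3

    scale = (pmax - pmin) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((data - pmin[:, None]) / scale[:, None]) + _DIG_MIN
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    header_bytes = 256 * (1 + n_ch)
    parts = [
        _field("0", 8),
        _field(patient_id, 80),
        _field(recording_id, 80),
        _field("01.01.00", 8),
        _field("00.00.00", 8),
        _field(str(header_bytes), 8),
        _field("", 44),
        _field(str(n_records), 8),
        _field("1", 8),
        _field(str(n_ch), 4),
    ]

    def num_field(v: float, width: int) -> bytes:
        s = f"{v:.3f}".rstrip("0").rstrip(".")
        if len(s) > width:
            s = s[:width]
        return _field(s, width)

    parts += [_field(lab, 16) for lab in channel_labels]
    parts += [_field("", 80)] * n_ch  # transducer
    parts += [_field(physical_dim, 8)] * n_ch
    parts += [num_field(v, 8) for v in pmin]
    parts += [num_field(v, 8) for v in pmax]
    parts += [_field(str(_DIG_MIN), 8)] * n_ch
    parts += [_field(str(_DIG_MAX), 8)] * n_ch
    parts += [_field("", 80)] * n_ch  # prefiltering
    parts += [_field(str(rate), 8)] * n_ch
    parts += [_field("", 32)] * n_ch

    with open(path, "wb") as fh:
        fh.write(b"".join(parts))
        # records: per record, all samples of ch0, then ch1, ...
        rec_view = digital.reshape(n_ch, n_records, rate)
        fh.write(np.ascontiguousarray(rec_view.transpose(1, 0, 2)).tobytes())


def _read_header(fh) -> tuple[EdfHeader, np.ndarray, np.ndarray]:
    fixed = fh.read(256)
    if len(fixed) < 256:
        raise SignalError("truncated EDF header")

    def asc(b: bytes) -> str:
        return b.decode("ascii", "replace").strip()

    try:
        n_records = int(asc(fixed[236:244]))
        record_duration = float(asc(fixed[244:252]))
        n_ch = int(asc(fixed[252:256]))
    except ValueError as exc:
        raise SignalError(f"malformed EDF header: {exc}") from exc
    if n_ch <= 0:
        raise SignalError("EDF header declares no signals")
    sig = fh.read(256 * n_ch)
    if len(sig) < 256 * n_ch:
        raise SignalError("truncated EDF signal headers")

    def block(offset: int, width: int) -> list[str]:
        out = []
        for i in range(n_ch):
            start = offset * n_ch + i * width
            out.append(asc(sig[start : start + width]))
        return out

    labels = block(0, 16)
    phys_dims = block(16 * 1 + 80, 8)  # after transducer block
    # byte offsets of the per-signal arrays within `sig`
    o_pmin = (16 + 80 + 8) * n_ch
    o_pmax = o_pmin + 8 * n_ch
    o_dmin = o_pmax + 8 * n_ch
    o_dmax = o_dmin + 8 * n_ch
    o_spr = o_dmax + 8 * n_ch + 80 * n_ch

    def floats(off: int, width: int = 8) -> np.ndarray:
        return np.array(
            [float(asc(sig[off + i * width : off + (i + 1) * width]) or "0")
             for i in range(n_ch)]
        )

    pmin = floats(o_pmin)
    pmax = floats(o_pmax)
    dmin = floats(o_dmin)
    dmax = floats(o_dmax)
    spr = [int(asc(sig[o_spr + i * 8 : o_spr + (i + 1) * 8]) or "0") for i in range(n_ch)]
    if n_records < 0:
        # -1 marks "unknown"; infer from file size
        pos = fh.tell()
        fh.seek(0, 2)
        payload = fh.tell() - pos
        fh.seek(pos)
        rec_bytes = 2 * sum(spr)
        n_records = payload // rec_bytes if rec_bytes else 0
    header = EdfHeader(
        n_channels=n_ch,
        n_records=n_records,
        record_duration=record_duration,
        samples_per_record=spr,
        channel_labels=labels,
        physical_dims=phys_dims,
    )
    gains = np.where(dmax - dmin == 0, 1.0, (pmax - pmin) / np.where(dmax - dmin == 0, 1.0, dmax - dmin))
    offsets = pmin - gains * dmin
    return header, gains, offsets


def read_edf_header(path: str | Path) -> EdfHeader:
    """Header only (duration, channel count, labels) — no payload read."""
    with open(path, "rb") as fh:
        header, _, _ = _read_header(fh)
    return header


def read_edf(path: str | Path) -> EdfData:
    """Read an EDF file written by :func:`write_edf` (uniform rate)."""
    with open(path, "rb") as fh:
        header, gains, offsets = _read_header(fh)
        spr = header.samples_per_record
        if len(set(spr)) != 1:
            raise SignalError("mixed per-channel sampling rates are not supported")
        n_ch, nr, s = header.n_channels, header.n_records, spr[0]
        payload = fh.read(2 * n_ch * s * nr)
        if len(payload) < 2 * n_ch * s * nr:
            raise SignalError("EDF payload shorter than header declares")
    digital = np.frombuffer(payload, dtype="<i2").reshape(nr, n_ch, s)
    data = digital.transpose(1, 0, 2).reshape(n_ch, nr * s).astype(np.float64)
    data = data * gains[:, None] + offsets[:, None]
    rate = header.sampling_rate
    if not math.isfinite(rate) or rate <= 0:
        raise SignalError("EDF header has a non-positive sampling rate")
    return EdfData(
        data=data,
        sampling_rate=rate,
        channel_labels=header.channel_labels,
        header=header,
    )
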