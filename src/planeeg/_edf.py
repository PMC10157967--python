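"""Minimal European Data Format (EDF) reader/writer.

Implements the fixed-layout EDF container (256-byte global header, 256
bytes per signal, 16-bit little-endian samples) sufficient for continuous
multichannel voltage recordings with one shared sampling rate.  Amplitudes
are in microvolts.  The writer uses 1-second data records, so recordings
must span a whole number of seconds; this keeps write -> read round-trips
exact in sample count without padding.
"""

from __future__ import annotations

import numpy as np

__all__ = ["read_edf", "write_edf"]

_HDR = 256


def _field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, data: np.ndarray, fs: float, channel_labels=None) -> None:
    """Write a (n_channels, n_samples) microvolt array as EDF.

    ``fs`` must be a positive integer number of samples per second and the
    recording must span a whole number of seconds (1 s data records).
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_ch, n_samp = data.shape
    if fs <= 0 or abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires a positive integer sampling rate")
    spr = int(round(fs))
    if n_samp % spr != 0:
        raise ValueError(
            "EDF writer requires a whole number of seconds "
            f"({n_samp} samples at {spr} Hz); use delimited text instead"
        )
    n_rec = n_samp // spr
    if channel_labels is None:
        channel_labels = [f"ch{i}" for i in range(n_ch)]
    if len(channel_labels) != n_ch:
        raise ValueError("channel_labels length does not match channel count")

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767

    with open(path, "wb") as fh:
        fh.write(_field("0", 8))
        fh.write(_field("X X X X", 80))
        fh.write(_field("Startdate 01-JAN-1985 X X X", 80))
        fh.write(_field("01.01.85", 8))
        fh.write(_field("00.00.00", 8))
        fh.write(_field(str(_HDR * (n_ch + 1)), 8))
        fh.write(_field("", 44))
        fh.write(_field(str(n_rec), 8))
        fh.write(_field("1", 8))
        fh.write(_field(str(n_ch), 4))
        for lab in channel_labels:
            fh.write(_field(lab, 16))
        for _ in range(n_ch):
            fh.write(_field("", 80))        # transducer
        for _ in range(n_ch):
            fh.write(_field("uV", 8))
        for v in pmin:
            fh.write(_field(f"{v:.6g}"[:8], 8))
        for v in pmax:
            fh.write(_field(f"{v:.6g}"[:8], 8))
        for _ in range(n_ch):
            fh.write(_field(str(dmin), 8))
        for _ in range(n_ch):
            fh.write(_field(str(dmax), 8))
        for _ in range(n_ch):
            fh.write(_field("", 80))        # prefiltering
        for _ in range(n_ch):
            fh.write(_field(str(spr), 8))
        for _ in range(n_ch):
            fh.write(_field("", 32))

        # re-read the 8-char physical bounds so scaling matches the header text
        hp_min = np.array([float(f"{v:.6g}"[:8]) for v in pmin])
        hp_max = np.array([float(f"{v:.6g}"[:8]) for v in pmax])
        scale = (dmax - dmin) / (hp_max - hp_min)
        dig = np.rint((data - hp_min[:, None]) * scale[:, None] + dmin)
        dig = np.clip(dig, dmin, dmax).astype("<i2")
        records = dig.reshape(n_ch, n_rec, spr).transpose(1, 0, 2)
        fh.write(records.tobytes())


def read_edf(path):
    """Read an EDF file; return ``(data, fs, channel_labels)`` in microvolts.

    All signals must share one sampling rate; annotation channels are not
    supported.
    """
    with open(path, "rb") as fh:
        hdr = fh.read(_HDR)
        if len(hdr) < _HDR:
            raise ValueError("truncated EDF header")
        n_rec = int(hdr[236:244].decode("ascii").strip())
        rec_dur = float(hdr[244:252].decode("ascii").strip())
        n_ch = int(hdr[252:256].decode("ascii").strip())
        sig = fh.read(_HDR * n_ch)

        def col(off, width):
            base = off * n_ch
            return [
                sig[base + i * width: base + (i + 1) * width].decode("ascii").strip()
                for i in range(n_ch)
            ]

        labels = col(0, 16)
        pmin = np.array([float(v) for v in col(16 + 80 + 8, 8)])
        pmax = np.array([float(v) for v in col(16 + 80 + 8 + 8, 8)])
        dmin = np.array([float(v) for v in col(16 + 80 + 8 + 16, 8)])
        dmax = np.array([float(v) for v in col(16 + 80 + 8 + 24, 8)])
        spr = np.array([int(v) for v in col(216, 8)])
        if len(set(spr)) != 1:
            raise ValueError("inconsistent per-channel sampling rates in EDF")
        fs = spr[0] / rec_dur
        raw = np.frombuffer(fh.read(n_rec * spr.sum() * 2), dtype="<i2")
    if raw.size != n_rec * spr.sum():
        raise ValueError("EDF data section shorter than header declares")
    records = raw.reshape(n_rec, n_ch, spr[0])
    dig = records.transpose(1, 0, 2).reshape(n_ch, -1).astype(float)
    scale = (pmax - pmin) / (dmax - dmin)
    data = (dig - dmin[:, None]) * scale[:, None] + pmin[:, None]
    return data, float(fs), labels
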