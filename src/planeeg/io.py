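"""Recording container and file I/O (EDF and delimited text)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _edf

__all__ = ["Recording", "read_recording", "write_recording"]

_TEXT_SUFFIXES = {".txt", ".tsv", ".csv", ".dat"}


@dataclass
class Recording:
    """A continuous multichannel voltage recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Potentials in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
    group : str or None
        Experimental condition label (e.g. ``"darkness"``, ``"light"``,
        ``"control"``).
    source : str
        Originating file path, or ``"synthetic"``.
    meta : dict
        Free-form provenance metadata (generation seed, parameters, ...).
    """

    data: np.ndarray
    fs: float
    channel_labels: list = None
    group: str = None
    source: str = "synthetic"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("data must be a (n_channels, n_samples) matrix")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.channel_labels is None:
            self.channel_labels = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length does not match data")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds (n_samples / fs)."""
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray) -> "Recording":
        return Recording(
            data=data, fs=self.fs, channel_labels=list(self.channel_labels),
            group=self.group, source=self.source, meta=dict(self.meta),
        )


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("edf", "text"):
            raise ValueError(f"unknown recording format: {format!r}")
        return format
    if path.suffix.lower() == ".edf":
        return "edf"
    if path.suffix.lower() in _TEXT_SUFFIXES:
        return "text"
    raise ValueError(f"cannot infer recording format from suffix {path.suffix!r}")


def read_recording(path, format: str | None = None, group: str | None = None,
                   fs: float | None = None) -> Recording:
    """Read a continuous recording from EDF or delimited text.

    For delimited text the first column is interpreted as time in seconds
    when it is uniformly increasing (fs is then derived from it); otherwise
    every column is a channel and ``fs`` must be given.  Delimiters (tab,
    comma, whitespace) are auto-detected.  Values are microvolts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "edf":
        data, fs_file, labels = _edf.read_edf(path)
        return Recording(data=data, fs=fs_file, channel_labels=labels,
                         group=group, source=str(path))

    with open(path) as fh:
        first = next((ln for ln in fh if ln.strip()
                      and not ln.lstrip().startswith("#")), "")
    sep = "\t" if "\t" in first else ("," if "," in first else r"\s+")
    df = pd.read_csv(path, sep=sep, engine="python", header=None,
                     comment="#", skip_blank_lines=True)
    if df.iloc[0].apply(lambda v: isinstance(v, str)).any():
        df = df.iloc[1:].astype(float).reset_index(drop=True)
    arr = df.to_numpy(dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("delimited recording needs at least two rows")
    first = arr[:, 0]
    dt = np.diff(first)
    time_like = (
        arr.shape[1] >= 2
        and np.all(dt > 0)
        and np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9)
    )
    if time_like:
        fs_derived = 1.0 / dt.mean()
        if fs is not None and abs(fs_derived - fs) / fs > 1e-3:
            raise ValueError(
                f"fs argument ({fs} Hz) disagrees with the time column "
                f"({fs_derived:.6g} Hz)"
            )
        data = arr[:, 1:].T
        return Recording(data=data, fs=float(fs_derived), group=group,
                         source=str(path))
    if fs is None:
        raise ValueError(
            "missing fs: delimited recording has no time column, so the "
            "sampling rate must be supplied"
        )
    return Recording(data=arr.T, fs=float(fs), group=group, source=str(path))


def write_recording(recording: Recording, path, format: str | None = None) -> None:
    """Write a Recording as EDF or as tab-delimited text (time + channels)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "edf":
        _edf.write_edf(path, recording.data, recording.fs,
                       recording.channel_labels)
        return
    t = np.arange(recording.n_samples) / recording.fs
    cols = {"time": t}
    for lab, row in zip(recording.channel_labels, recording.data):
        cols[lab] = row
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, header=False,
                              float_format="%.9g")
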