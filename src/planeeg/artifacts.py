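"""Automatic artifact rejection for epoched recordings.

Per (channel, epoch) cell, four quality metrics are computed: the peak
absolute amplitude, the within-epoch sample variance, the mean absolute
standardized amplitude ("z-value", standardized against channel statistics
pooled over all epochs), and the within-epoch kurtosis.  A cell is flagged
when its peak lies more than ``peak_k`` standard deviations from the mean
peak (both tails) or when its variance, z-value, or kurtosis lies more
than ``dist_k`` standard deviations *above* that metric's mean (upper tail
only); means and SDs are taken across all cells in one pass, with strict
inequalities at the thresholds.  A flagged cell removes its epoch; a
channel is removed when its metrics, averaged over epochs, exceed the same
thresholds.  A dataset is retained when at least ``min_channels`` channels
and at least ``min_epochs`` epochs survive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import EpochSet

__all__ = [
    "RejectionCriteria", "RejectionReport",
    "compute_epoch_metrics", "autoreject",
]

METRICS = ("peak", "variance", "zvalue", "kurtosis")


@dataclass
class RejectionCriteria:
    """Thresholds for the automatic rejection.

    ``peak_k`` (default 5) is the two-tailed SD multiplier on the peak
    amplitude; ``dist_k`` (default 2.5) the upper-tail multiplier on
    variance, z-value, and kurtosis.  ``min_epochs=6`` encodes the "more
    than 5 surviving segments" retention rule.  ``kurtosis`` selects the
    Pearson (standardized fourth moment; Gaussian -> 3) or excess
    (Gaussian -> 0) convention; the choice shifts the metric by a constant
    and therefore never changes which epochs are removed.
    """

    peak_k: float = 5.0
    dist_k: float = 2.5
    min_epochs: int = 6
    min_channels: int = 1
    kurtosis: str = "pearson"

    def __post_init__(self):
        if self.peak_k <= 0 or self.dist_k <= 0:
            raise ValueError("SD multipliers must be positive")
        if self.min_epochs < 1 or self.min_channels < 1:
            raise ValueError("min_epochs and min_channels must be >= 1")
        if self.kurtosis not in ("pearson", "excess"):
            raise ValueError("kurtosis convention must be 'pearson' or 'excess'")


def compute_epoch_metrics(epochs: EpochSet,
                          kurtosis: str = "pearson") -> pd.DataFrame:
    """Per-(channel, epoch) quality metrics as a tidy DataFrame.

    Columns: channel, epoch, peak (µV), variance (µV²), zvalue, kurtosis.
    Zero-variance epochs report kurtosis 0 and zero-variance channels
    report zvalue 0, each with a warning rather than an error.
    """
    x = epochs.data                                   # (E, C, S)
    n_ep, n_ch, n_s = x.shape
    if n_ep < 1 or n_ch < 1:
        raise ValueError("need at least one epoch and one channel")

    peak = np.abs(x).max(axis=2)                      # (E, C)
    var = x.var(axis=2, ddof=1) if n_s > 1 else np.zeros((n_ep, n_ch))

    # channel statistics pooled over all epochs of that channel
    pooled = np.transpose(x, (1, 0, 2)).reshape(n_ch, -1)
    ch_mean = pooled.mean(axis=1)
    ch_sd = pooled.std(axis=1, ddof=1) if pooled.shape[1] > 1 else np.zeros(n_ch)
    dead = ch_sd <= 0
    if dead.any():
        warnings.warn("zero-variance channel(s): z-value reported as 0")
    safe_sd = np.where(dead, 1.0, ch_sd)
    z = np.abs(x - ch_mean[None, :, None]).mean(axis=2) / safe_sd[None, :]
    z[:, dead] = 0.0

    centered = x - x.mean(axis=2, keepdims=True)
    m2 = (centered ** 2).mean(axis=2)
    m4 = (centered ** 4).mean(axis=2)
    flat = m2 <= 0
    if flat.any():
        warnings.warn("zero-variance epoch(s): kurtosis reported as 0")
    kurt = np.where(flat, 0.0, m4 / np.where(flat, 1.0, m2) ** 2)
    if kurtosis == "excess":
        kurt = np.where(flat, 0.0, kurt - 3.0)

    ep_idx, ch_idx = np.meshgrid(np.arange(n_ep), np.arange(n_ch),
                                 indexing="ij")
    return pd.DataFrame({
        "channel": ch_idx.ravel(),
        "epoch": ep_idx.ravel(),
        "peak": peak.ravel(),
        "variance": var.ravel(),
        "zvalue": z.ravel(),
        "kurtosis": kurt.ravel(),
    })


@dataclass
class RejectionReport:
    """Outcome of :func:`autoreject` for one dataset."""

    metrics: pd.DataFrame
    removed_epochs: np.ndarray
    removed_channels: np.ndarray
    n_epochs: int
    n_channels: int
    retained: bool
    thresholds: dict = field(default_factory=dict)

    @property
    def surviving_epochs(self) -> np.ndarray:
        return np.setdiff1d(np.arange(self.n_epochs), self.removed_epochs)

    @property
    def surviving_channels(self) -> np.ndarray:
        return np.setdiff1d(np.arange(self.n_channels), self.removed_channels)

    def to_frame(self) -> pd.DataFrame:
        """Metric table with per-cell removal flags (report CSV layout)."""
        df = self.metrics.copy()
        df["epoch_removed"] = df["epoch"].isin(self.removed_epochs)
        df["channel_removed"] = df["channel"].isin(self.removed_channels)
        return df


def _cell_flags(values: np.ndarray, mean: float, sd: float, k: float,
                two_tailed: bool) -> np.ndarray:
    if two_tailed:
        return np.abs(values - mean) > k * sd
    return values - mean > k * sd


def autoreject(epochs: EpochSet,
               criteria: RejectionCriteria | None = None) -> RejectionReport:
    """Single-pass automatic rejection of epochs and channels.

    Thresholds are computed once from the full metric table (no iterative
    re-thresholding).  Strict inequalities mean that a table with zero
    spread removes nothing.
    """
    criteria = criteria or RejectionCriteria()
    df = compute_epoch_metrics(epochs, kurtosis=criteria.kurtosis)
    n_ep, n_ch = epochs.n_epochs, epochs.n_channels

    thresholds = {}
    ep_bad = np.zeros(n_ep, dtype=bool)
    ch_bad = np.zeros(n_ch, dtype=bool)
    for metric in METRICS:
        vals = df[metric].to_numpy()
        mean = vals.mean()
        sd = vals.std(ddof=1) if vals.size > 1 else 0.0
        k = criteria.peak_k if metric == "peak" else criteria.dist_k
        two = metric == "peak"
        thresholds[metric] = {"mean": mean, "sd": sd, "k": k,
                              "two_tailed": two}
        cell_bad = _cell_flags(vals, mean, sd, k, two)
        # any flagged cell removes its epoch
        cells = df.loc[cell_bad]
        ep_bad[cells["epoch"].unique()] = True
        # channel criterion: same thresholds on the epoch-averaged metric
        ch_vals = df.groupby("channel")[metric].mean().to_numpy()
        ch_bad |= _cell_flags(ch_vals, mean, sd, k, two)

    removed_epochs = np.flatnonzero(ep_bad)
    removed_channels = np.flatnonzero(ch_bad)
    retained = (n_ch - removed_channels.size >= criteria.min_channels
                and n_ep - removed_epochs.size >= criteria.min_epochs)
    return RejectionReport(
        metrics=df, removed_epochs=removed_epochs,
        removed_channels=removed_channels, n_epochs=n_ep, n_channels=n_ch,
        retained=retained, thresholds=thresholds,
    )
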