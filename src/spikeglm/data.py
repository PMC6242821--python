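"""Spike-count containers and plain-text / HDF5 I/O.

The native on-disk exchange format for spikes is a delimited event list with
columns ``time_s`` (float seconds) and ``channel`` (integer), as produced by
standard MEA spike-detection pipelines.  Binned count matrices and fitted
models are persisted in HDF5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd


@dataclass
class SpikeCountMatrix:
    """Binned spike counts, neurons × time bins.

    Attributes
    ----------
    counts : ndarray of int, shape (n_neurons, n_bins)
    dt : float
        Seconds per bin.
    neuron_ids : ndarray
        Channel / neuron labels, one per row.
    """

    counts: np.ndarray
    dt: float
    neuron_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (neurons x bins)")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.counts.shape[0])
        else:
            self.neuron_ids = np.asarray(self.neuron_ids)
            if len(self.neuron_ids) != self.counts.shape[0]:
                raise ValueError("neuron_ids length must match number of rows")

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def duration(self) -> float:
        """Total recorded time in seconds."""
        return self.n_bins * self.dt

    def mean_rates(self) -> np.ndarray:
        """Per-neuron mean firing rate in Hz."""
        if self.n_bins == 0:
            return np.zeros(self.n_neurons)
        return self.counts.mean(axis=1) / self.dt

    def drop_silent(self, min_rate_hz: float = 0.1) -> "SpikeCountMatrix":
        """Drop channels with mean rate below ``min_rate_hz`` (default 0.1 Hz),
        the standard electrode-exclusion rule for these recordings."""
        keep = self.mean_rates() >= min_rate_hz
        return SpikeCountMatrix(self.counts[keep], self.dt, self.neuron_ids[keep])

    def population_rate(self) -> np.ndarray:
        """Summed counts per bin across neurons."""
        return self.counts.sum(axis=0)


def bin_events(times_s: np.ndarray, channels: np.ndarray, dt: float,
               n_neurons: int | None = None,
               n_bins: int | None = None) -> SpikeCountMatrix:
    """Bin an event list (time, channel) into a SpikeCountMatrix.

    Events are assigned to bin ``floor(t / dt)``; channels are used directly
    as row indices 0..n_neurons-1.  Binning is order-free.
    """
    times_s = np.asarray(times_s, float)
    channels = np.asarray(channels, int)
    if times_s.size and times_s.min() < 0:
        raise ValueError("event times must be non-negative")
    if channels.size and channels.min() < 0:
        raise ValueError("channels must be non-negative")
    if n_neurons is None:
        n_neurons = int(channels.max()) + 1 if channels.size else 0
    if n_bins is None:
        t_max = float(times_s.max()) if times_s.size else 0.0
        n_bins = int(np.floor(t_max / dt + 1e-9)) + 1 if times_s.size else 0
    counts = np.zeros((n_neurons, n_bins), dtype=np.int64)
    if times_s.size:
        bins = np.minimum((times_s / dt).astype(int), n_bins - 1)
        np.add.at(counts, (channels, bins), 1)
    return SpikeCountMatrix(counts, dt)


def read_events(path, dt: float, n_neurons: int | None = None,
                n_bins: int | None = None) -> SpikeCountMatrix:
    """Read a delimited event list (columns time_s, channel) and bin it.

    Malformed rows are reported with their line numbers.
    """
    df = pd.read_csv(path)
    required = {"time_s", "channel"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, "
                         f"found {list(df.columns)}")
    times = pd.to_numeric(df["time_s"], errors="coerce")
    chans = pd.to_numeric(df["channel"], errors="coerce")
    bad = times.isna() | chans.isna() | (chans != chans.round())
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"{path}: malformed rows at lines {lines[:20]}")
    return bin_events(times.to_numpy(), chans.to_numpy().astype(int), dt,
                      n_neurons=n_neurons, n_bins=n_bins)


def write_events(path, matrix: SpikeCountMatrix) -> None:
    """Write counts as an event list, one row per spike at the bin center.

    A count of k in bin u of neuron i yields k identical rows with
    time (u + 0.5)·dt and channel = neuron_ids[i]; this round-trips exactly
    under ``read_events`` with the same dt.
    """
    rows_i, rows_u = np.nonzero(matrix.counts)
    mult = matrix.counts[rows_i, rows_u]
    times = np.repeat((rows_u + 0.5) * matrix.dt, mult)
    chans = np.repeat(matrix.neuron_ids[rows_i], mult)
    order = np.argsort(times, kind="stable")
    pd.DataFrame({"time_s": times[order], "channel": chans[order]}).to_csv(
        path, index=False)


def save_counts(path, matrix: SpikeCountMatrix) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=matrix.counts)
        f.create_dataset("neuron_ids", data=np.asarray(matrix.neuron_ids))
        f.attrs["dt"] = matrix.dt


def load_counts(path) -> SpikeCountMatrix:
    with h5py.File(path, "r") as f:
        return SpikeCountMatrix(f["counts"][()], float(f.attrs["dt"]),
                                f["neuron_ids"][()])
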