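"""Core containers: binary event rasters and continuous multichannel recordings.

An :class:`EventRaster` is the point-processed representation of a recording:
a sparse set of (channel, time-bin) events on a fixed channels x bins grid.
A :class:`ContinuousRecording` is the analog representation: a channels x
samples real matrix with a sampling rate, normalized per channel to zero mean
and unit standard deviation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["EventRaster", "ContinuousRecording"]


@dataclass
class EventRaster:
    """Sparse binary channels x time-bins event raster.

    Events are stored as parallel integer arrays ``channels`` / ``times``,
    sorted by (time, channel) with no duplicate (channel, bin) pairs.

    Parameters
    ----------
    channels, times
        Event coordinates, 0-based.
    n_channels, n_bins
        Grid dimensions.
    bin_ms
        Width of one time bin in milliseconds (1.0 at a 1 kHz sampling rate
        with no rebinning).
    """

    channels: np.ndarray
    times: np.ndarray
    n_channels: int
    n_bins: int
    bin_ms: float = 1.0

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=np.int64)
        if self.channels.shape != self.times.shape or self.channels.ndim != 1:
            raise ValueError("channels and times must be equal-length 1-D arrays")
        if self.n_channels < 1 or self.n_bins < 1:
            raise ValueError("n_channels and n_bins must be positive")
        if self.channels.size:
            if self.channels.min() < 0 or self.channels.max() >= self.n_channels:
                raise ValueError("channel index out of range")
            if self.times.min() < 0 or self.times.max() >= self.n_bins:
                raise ValueError("bin index out of range")
        self._canonicalize()

    def _canonicalize(self) -> None:
        """Sort by (time, channel) and drop duplicate events."""
        key = self.times * self.n_channels + self.channels
        key = np.unique(key)
        self.times = key // self.n_channels
        self.channels = key % self.n_channels

    # -- basic queries ---------------------------------------------------

    @property
    def n_events(self) -> int:
        return int(self.channels.size)

    def counts_per_bin(self) -> np.ndarray:
        """Number of events in each time bin (length ``n_bins``)."""
        return np.bincount(self.times, minlength=self.n_bins)

    def counts_per_channel(self) -> np.ndarray:
        return np.bincount(self.channels, minlength=self.n_channels)

    def to_dense(self) -> np.ndarray:
        """Dense boolean channels x bins matrix (use only for small rasters)."""
        out = np.zeros((self.n_channels, self.n_bins), dtype=bool)
        out[self.channels, self.times] = True
        return out

    @classmethod
    def from_dense(cls, dense: np.ndarray, bin_ms: float = 1.0) -> "EventRaster":
        dense = np.asarray(dense)
        ch, t = np.nonzero(dense)
        return cls(ch, t, dense.shape[0], dense.shape[1], bin_ms)

    # -- transformations -------------------------------------------------

    def subset_channels(self, keep: np.ndarray) -> "EventRaster":
        """Restrict to a channel subset, relabelling channels 0..len(keep)-1."""
        keep = np.asarray(keep, dtype=np.int64)
        lut = -np.ones(self.n_channels, dtype=np.int64)
        lut[keep] = np.arange(keep.size)
        mask = lut[self.channels] >= 0
        return EventRaster(
            lut[self.channels[mask]], self.times[mask], keep.size, self.n_bins, self.bin_ms
        )

    def rebin(self, factor: int) -> "EventRaster":
        """Coarsen time by ``factor``: a coarse bin is active for a channel iff
        any constituent fine bin holds an event (logical OR; the raster stays
        binary, so event counts are not conserved)."""
        if factor < 1:
            raise ValueError("rebin factor must be >= 1")
        if factor == 1:
            return EventRaster(
                self.channels.copy(), self.times.copy(), self.n_channels, self.n_bins, self.bin_ms
            )
        n_coarse = -(-self.n_bins // factor)
        return EventRaster(
            self.channels, self.times // factor, self.n_channels, n_coarse, self.bin_ms * factor
        )

    # -- I/O ---------------------------------------------------------------

    def write_tsv(self, path: str | Path) -> None:
        """Write the sparse event list: ``# key value`` header lines followed
        by 0-based ``channel<TAB>bin`` rows."""
        with open(path, "w") as fh:
            fh.write(f"# n_channels\t{self.n_channels}\n")
            fh.write(f"# n_bins\t{self.n_bins}\n")
            fh.write(f"# bin_ms\t{self.bin_ms}\n")
            for c, t in zip(self.channels, self.times):
                fh.write(f"{c}\t{t}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "EventRaster":
        meta: dict[str, float] = {}
        ch, tt = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    key, val = line[1:].split()
                    meta[key] = float(val)
                else:
                    a, b = line.split("\t")
                    ch.append(int(a))
                    tt.append(int(b))
        return cls(
            np.array(ch, dtype=np.int64),
            np.array(tt, dtype=np.int64),
            int(meta["n_channels"]),
            int(meta["n_bins"]),
            meta.get("bin_ms", 1.0),
        )


@dataclass
class ContinuousRecording:
    """Channels x samples real-valued recording with a sampling rate in Hz."""

    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def normalized(self) -> "ContinuousRecording":
        """Per-channel z-scoring: remove the mean, divide by the SD."""
        if self.n_samples == 0:
            raise ValueError("empty recording")
        sd = self.data.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("cannot normalize a zero-variance channel")
        out = (self.data - self.data.mean(axis=1, keepdims=True)) / sd
        return ContinuousRecording(out, self.sampling_rate, self.channel_labels)

    def is_normalized(self, tol: float = 1e-6) -> bool:
        mu = self.data.mean(axis=1)
        sd = self.data.std(axis=1)
        return bool(np.all(np.abs(mu) < tol) and np.all(np.abs(sd - 1) < tol))

    def write_tsv(self, path: str | Path) -> None:
        np.savetxt(path, self.data, delimiter="\t", header=f"sampling_rate\t{self.sampling_rate}")

    @classmethod
    def read_tsv(cls, path: str | Path, sampling_rate: float | None = None) -> "ContinuousRecording":
        with open(path) as fh:
            first = fh.readline()
            rate = sampling_rate
            if first.startswith("#"):
                parts = first[1:].split()
                if len(parts) == 2 and parts[0] == "sampling_rate":
                    rate = float(parts[1])
                data = np.loadtxt(fh, delimiter="\t", ndmin=2)
            else:
                data = np.loadtxt(
                    io.StringIO(first + fh.read()), delimiter="\t", ndmin=2
                )
        if rate is None:
            raise ValueError("sampling_rate not in file header and not given")
        return cls(data, rate)
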