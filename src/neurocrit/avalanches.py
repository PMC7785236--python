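"""Avalanche extraction from binary event rasters.

An avalanche is a maximal run of consecutive time bins that each contain at
least one event on any channel, bounded by empty bins (or the record
boundary). Its duration T is the run length in bins, its size S the total
number of events in the run (events, not distinct channels, so S can exceed
the channel count for long avalanches), and its profile the per-bin event
counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster import EventRaster

__all__ = ["Avalanche", "AvalancheCatalog", "extract_avalanches", "mean_profiles_by_duration"]


@dataclass
class Avalanche:
    start_bin: int
    duration_T: int
    size_S: int
    profile: np.ndarray
    boundary_truncated: bool = False

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=np.int64)
        if self.profile.size != self.duration_T:
            raise ValueError("profile length must equal duration_T")
        if self.profile.min(initial=1) < 1:
            raise ValueError("every profile bin must hold >= 1 event")
        if int(self.profile.sum()) != self.size_S:
            raise ValueError("size_S must equal sum(profile)")


@dataclass
class AvalancheCatalog:
    """Ordered, non-overlapping avalanches extracted from one raster."""

    avalanches: list[Avalanche]
    n_channels: int
    n_bins: int
    bin_ms: float = 1.0

    def __len__(self) -> int:
        return len(self.avalanches)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([a.size_S for a in self.avalanches], dtype=np.int64)

    @property
    def durations(self) -> np.ndarray:
        return np.array([a.duration_T for a in self.avalanches], dtype=np.int64)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("start_bin\tT\tS\tprofile\n")
            for a in self.avalanches:
                prof = ",".join(str(int(v)) for v in a.profile)
                fh.write(f"{a.start_bin}\t{a.duration_T}\t{a.size_S}\t{prof}\n")


def extract_avalanches(
    raster: EventRaster, *, drop_boundary_truncated: bool = False
) -> AvalancheCatalog:
    """Extract all avalanches from a raster, in start-bin order.

    Avalanches clipped by the record boundary are kept and flagged
    ``boundary_truncated``; set ``drop_boundary_truncated`` to exclude them.
    """
    out: list[Avalanche] = []
    if raster.n_events:
        times = raster.times  # sorted
        counts = np.bincount(times)
        busy = np.flatnonzero(counts)
        # split the sorted non-empty bins into consecutive runs
        breaks = np.flatnonzero(np.diff(busy) > 1) + 1
        for run in np.split(busy, breaks):
            start, end = int(run[0]), int(run[-1])
            profile = counts[start : end + 1]
            trunc = start == 0 or end == raster.n_bins - 1
            if trunc and drop_boundary_truncated:
                continue
            out.append(
                Avalanche(start, end - start + 1, int(profile.sum()), profile, trunc)
            )
    return AvalancheCatalog(out, raster.n_channels, raster.n_bins, raster.bin_ms)


def mean_profiles_by_duration(
    catalog: AvalancheCatalog, min_count: int = 1
) -> dict[int, np.ndarray]:
    """Element-wise mean profile for each duration with >= min_count avalanches.

    Returns an empty map when no duration qualifies; downstream collapse
    stages must handle that.
    """
    if len(catalog) == 0:
        raise ValueError("empty catalog")
    by_T: dict[int, list[np.ndarray]] = {}
    for a in catalog.avalanches:
        by_T.setdefault(a.duration_T, []).append(a.profile)
    return {
        T: np.mean(profs, axis=0)
        for T, profs in sorted(by_T.items())
        if len(profs) >= min_count
    }
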