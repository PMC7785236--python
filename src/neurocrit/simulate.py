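"""Synthetic data with the statistical structure the avalanche analysis assumes.

The generators here stand in for resting-state ECoG-like recordings: a
critical (or sub/super-critical) branching process produces a sparse binary
event raster organized into avalanches; ``synthesize_ecog`` embeds those
events as high-amplitude pulses in Gaussian background noise so the
point-process stage has something to detect; ``sample_truncated_powerlaw``
draws from the discrete doubly-truncated power law used throughout the
inference tests; ``jitter_null`` is the surrogate used to destroy
cross-channel temporal coordination while preserving per-channel rates.

At a branching ratio of 1 the branching process sits at its critical point
and mean-field theory gives avalanche size exponent tau = 3/2, duration
exponent alpha = 2 and <S>(T) ~ T^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .powerlaw import truncated_pmf
from .raster import ContinuousRecording, EventRaster

__all__ = [
    "BranchingParams",
    "TruncatedPowerLawParams",
    "sample_truncated_powerlaw",
    "simulate_branching_raster",
    "synthesize_ecog",
    "jitter_null",
]


@dataclass
class BranchingParams:
    """Parameters of the discrete-time branching-process raster generator.

    branching_ratio
        Expected descendants per active unit per step: 1 is critical,
        < 1 subcritical, > 1 supercritical.
    drive_rate
        Expected spontaneous seeds per bin (Poisson); keep low so cascades
        are separated by quiet bins.
    max_active
        Cap on the momentary number of active channels.
    """

    n_channels: int = 128
    n_bins: int = 600_000
    branching_ratio: float = 1.0
    drive_rate: float = 0.01
    max_active: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.branching_ratio < 0 or self.drive_rate < 0:
            raise ValueError("branching_ratio and drive_rate must be >= 0")
        if self.max_active is None:
            self.max_active = self.n_channels
        if self.max_active < 1:
            raise ValueError("max_active must be >= 1")


@dataclass
class TruncatedPowerLawParams:
    """Parameters for the discrete doubly-truncated power-law sampler."""

    exponent: float
    x_min: int
    x_max: int
    n: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.x_min > self.x_max:
            raise ValueError("x_min must be <= x_max")
        if self.x_min < 1:
            raise ValueError("x_min must be >= 1")
        if self.exponent <= 0:
            raise ValueError("exponent must be positive")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def sample_truncated_powerlaw(params: TruncatedPowerLawParams) -> np.ndarray:
    """Draw ``params.n`` i.i.d. integers from p(x) ∝ x^-exponent on
    [x_min, x_max], by inverse-CDF on the enumerated normalized pmf."""
    rng = np.random.default_rng(params.seed)
    support, pmf = truncated_pmf(params.exponent, params.x_min, params.x_max)
    cum = np.cumsum(pmf)
    idx = np.searchsorted(cum, rng.random(params.n), side="left")
    return support[np.minimum(idx, support.size - 1)].astype(np.int64)


def simulate_branching_raster(params: BranchingParams) -> EventRaster:
    """Simulate a branching process on ``n_channels`` units.

    At each bin, Poisson(drive_rate) spontaneous seeds start activity on
    random quiet channels; every unit active at bin t produces
    Binomial(n_channels, branching_ratio/n_channels) descendants, and the
    pooled descendants are placed on distinct uniformly random channels at
    t+1 (capped at ``max_active``). Placing descendants on distinct channels
    keeps the realized offspring mean at the nominal branching ratio until
    the cap bites; letting them collide and merge instead would make the
    process drift subcritical well below the array size. The raster entry is
    1 iff the channel is active in the bin.
    """
    rng = np.random.default_rng(params.seed)
    n_ch, n_bins = params.n_channels, params.n_bins
    p_desc = min(params.branching_ratio / n_ch, 1.0)

    seeds_per_bin = rng.poisson(params.drive_rate, n_bins)
    seed_bins = np.flatnonzero(seeds_per_bin)
    ev_ch: list[np.ndarray] = []
    ev_t: list[np.ndarray] = []

    active = np.empty(0, dtype=np.int64)
    i = 0  # index into seed_bins
    t = int(seed_bins[0]) if seed_bins.size else n_bins
    while t < n_bins:
        cur = active
        if i < seed_bins.size and seed_bins[i] == t:
            n_seed = int(seeds_per_bin[t])
            i += 1
            mask = np.zeros(n_ch, dtype=bool)
            mask[cur] = True
            quiet = np.flatnonzero(~mask)
            if quiet.size:
                chosen = rng.choice(quiet, size=min(n_seed, quiet.size), replace=False)
                cur = np.concatenate([cur, chosen])
        if cur.size > params.max_active:
            cur = rng.choice(cur, size=params.max_active, replace=False)
        if cur.size == 0:
            active = cur
            t = int(seed_bins[i]) if i < seed_bins.size else n_bins
            continue
        ev_ch.append(cur)
        ev_t.append(np.full(cur.size, t, dtype=np.int64))
        if p_desc > 0 and t + 1 < n_bins:
            n_desc = rng.binomial(cur.size * n_ch, p_desc)
            n_next = min(int(n_desc), params.max_active)
            if n_next:
                active = rng.choice(n_ch, size=n_next, replace=False)
            else:
                active = np.empty(0, dtype=np.int64)
        else:
            active = np.empty(0, dtype=np.int64)
        t += 1
        if active.size == 0 and (i >= seed_bins.size or seed_bins[i] > t):
            t = int(seed_bins[i]) if i < seed_bins.size else n_bins

    if ev_ch:
        channels = np.concatenate(ev_ch)
        times = np.concatenate(ev_t)
    else:
        channels = np.empty(0, dtype=np.int64)
        times = np.empty(0, dtype=np.int64)
    return EventRaster(channels, times, n_ch, n_bins, bin_ms=1.0)


#: Deterministic pulse shape added at each event, scaled to unit peak.
PULSE = np.array([0.5, 1.0, 0.5])


def synthesize_ecog(
    raster: EventRaster,
    sampling_rate: float = 1000.0,
    event_amplitude: float = 6.0,
    seed: int = 0,
) -> ContinuousRecording:
    """Embed raster events in Gaussian background noise.

    Each channel is unit-variance white Gaussian noise; at each raster event
    a brief deterministic pulse with peak ``event_amplitude`` (in background
    SD units) is added at the event bin. One raster bin maps to one sample,
    so the output is n_channels x n_bins at ``sampling_rate``.
    """
    if event_amplitude <= 0:
        raise ValueError("event_amplitude must be positive")
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((raster.n_channels, raster.n_bins))
    half = PULSE.size // 2
    for k, w in enumerate(PULSE):
        off = k - half
        tt = raster.times + off
        ok = (tt >= 0) & (tt < raster.n_bins)
        data[raster.channels[ok], tt[ok]] += w * event_amplitude
    return ContinuousRecording(data, sampling_rate)


def jitter_null(raster: EventRaster, window_ms: float, seed: int = 0) -> EventRaster:
    """Jitter surrogate: displace each event independently by an integer
    offset uniform on [-window, +window] bins (wrap-around at the record
    boundary), preserving per-channel event counts exactly.

    Collisions (two events of one channel landing in the same bin) are
    resolved by re-drawing the offending offsets, so the event count is
    conserved rather than merged away.
    """
    if window_ms < 0:
        raise ValueError("window_ms must be >= 0")
    if window_ms > raster.n_bins * raster.bin_ms:
        raise ValueError("jitter window exceeds the recording length")
    w = int(round(window_ms / raster.bin_ms))
    if w == 0:
        return EventRaster(
            raster.channels.copy(), raster.times.copy(),
            raster.n_channels, raster.n_bins, raster.bin_ms,
        )
    rng = np.random.default_rng(seed)
    new_times = (raster.times + rng.integers(-w, w + 1, raster.n_events)) % raster.n_bins
    # resolve per-channel collisions by re-jittering from the original times
    for _ in range(1000):
        key = raster.channels * raster.n_bins + new_times
        order = np.argsort(key, kind="stable")
        dup_sorted = np.zeros(key.size, dtype=bool)
        dup_sorted[1:] = key[order][1:] == key[order][:-1]
        dup = np.zeros(key.size, dtype=bool)
        dup[order] = dup_sorted
        if not dup.any():
            break
        n_dup = int(dup.sum())
        new_times[dup] = (
            raster.times[dup] + rng.integers(-w, w + 1, n_dup)
        ) % raster.n_bins
    else:  # pragma: no cover - only reachable on near-full rasters
        raise RuntimeError("could not resolve jitter collisions")
    return EventRaster(
        raster.channels, new_times, raster.n_channels, raster.n_bins, raster.bin_ms
    )
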