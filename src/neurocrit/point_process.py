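"""Threshold-and-correlation point process.

Reduces a normalized continuous recording to a binary event raster:

1. For each channel, every maximal excursion where ``|X(t)| >= sigma``
   (sigma in SD units, default 4) contributes exactly one event, at the
   sample of the excursion's global |X| maximum.
2. For every excursion window ``[t_min, t_max]``, the Pearson correlation
   between the seed channel's signal on that window and every other
   channel's signal on the same window is computed; channels with
   ``rho >= 0.75`` gain a co-event at their own in-window |X| maximum, even
   if they never crossed the threshold.

The threshold can also be chosen from the data as the amplitude at which
the pooled amplitude histogram diverges from its best-fit Gaussian.

The raster keeps one bin per sample (no rebinning): 1 ms bins at 1 kHz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .raster import ContinuousRecording, EventRaster

__all__ = [
    "PointProcessParams",
    "fit_gaussian_threshold",
    "binarize",
    "propagate_correlated_events",
    "point_process",
]

logger = logging.getLogger(__name__)

DEFAULT_SIGMA = 4.0
DEFAULT_RHO = 0.75


@dataclass
class PointProcessParams:
    """Point-process configuration: amplitude threshold ``sigma`` (SD units),
    correlation threshold ``rho``, and whether to fit sigma from the data."""

    sigma: float = DEFAULT_SIGMA
    rho: float = DEFAULT_RHO
    auto_threshold: bool = False
    candidate_range: tuple[float, float] = (2.0, 6.0)
    absolute_rho: bool = False

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")


def _excursions(x: np.ndarray, sigma: float) -> list[tuple[int, int]]:
    """Maximal runs of |x| >= sigma as (t_min, t_max) inclusive index pairs."""
    above = np.abs(x) >= sigma
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [above.size - 1]])
    return list(zip(starts.tolist(), ends.tolist()))


def fit_gaussian_threshold(
    recording: ContinuousRecording,
    candidate_range: tuple[float, float] = (2.0, 6.0),
    *,
    step: float = 0.25,
    ratio: float = 2.0,
    default: float = DEFAULT_SIGMA,
) -> float:
    """Amplitude (SD units) at which the empirical distribution leaves the
    best-fit Gaussian.

    Pools |X| over all channels, bins it on a ``step``-SD grid over
    ``candidate_range``, and returns the left edge of the first bin at which
    the empirical bin probability exceeds the folded-Gaussian bin probability
    (from the pooled fit of mean and SD) by more than ``ratio`` for two
    consecutive bins. Returns ``default`` when no divergence is found.
    """
    if recording.n_samples == 0:
        raise ValueError("empty recording")
    lo, hi = candidate_range
    if not lo < hi:
        raise ValueError("candidate_range must be increasing")
    x = recording.data.ravel()
    mu, sd = float(x.mean()), float(x.std())
    if sd == 0:
        raise ValueError("zero-variance recording")
    a = np.abs(x - mu) / sd
    edges = np.arange(lo, hi + step / 2, step)
    emp, _ = np.histogram(a, bins=edges)
    emp_p = emp / a.size
    gauss_p = 2 * (norm.cdf(edges[1:]) - norm.cdf(edges[:-1]))
    diverged = emp_p > ratio * gauss_p
    for i in range(diverged.size - 1):
        if diverged[i] and diverged[i + 1]:
            return float(edges[i])
    return float(default)


def binarize(recording: ContinuousRecording, sigma: float = DEFAULT_SIGMA) -> EventRaster:
    """One event per supra-threshold excursion, at the sample of the
    excursion's global |X| maximum (earliest sample on ties)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    ch_idx: list[int] = []
    t_idx: list[int] = []
    for c in range(recording.n_channels):
        x = recording.data[c]
        for t0, t1 in _excursions(x, sigma):
            peak = t0 + int(np.argmax(np.abs(x[t0 : t1 + 1])))
            ch_idx.append(c)
            t_idx.append(peak)
    return EventRaster(
        np.array(ch_idx, dtype=np.int64),
        np.array(t_idx, dtype=np.int64),
        recording.n_channels,
        recording.n_samples,
        bin_ms=1000.0 / recording.sampling_rate,
    )


def propagate_correlated_events(
    recording: ContinuousRecording,
    raster: EventRaster,
    rho: float = DEFAULT_RHO,
    sigma: float = DEFAULT_SIGMA,
    *,
    absolute_rho: bool = False,
) -> EventRaster:
    """Add correlation-propagated co-events to a seed raster.

    For every excursion window of every channel holding a seed event, each
    other channel whose in-window Pearson correlation with the seed channel
    reaches ``rho`` gains one event at its own in-window |X| maximum.
    Windows shorter than 3 samples are skipped (correlation degenerate);
    their count is logged. Duplicate (channel, bin) events merge, so the
    result is a superset of the seed raster.
    """
    data = recording.data
    n_ch = recording.n_channels
    new_ch = [raster.channels]
    new_t = [raster.times]
    skipped = 0
    for c in range(n_ch):
        x = data[c]
        for t0, t1 in _excursions(x, sigma):
            if t1 - t0 + 1 < 3:
                skipped += 1
                continue
            seg = x[t0 : t1 + 1]
            seg0 = seg - seg.mean()
            denom_seed = np.sqrt((seg0**2).sum())
            if denom_seed == 0:
                skipped += 1
                continue
            others = data[:, t0 : t1 + 1]
            others0 = others - others.mean(axis=1, keepdims=True)
            denom = np.sqrt((others0**2).sum(axis=1))
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (others0 @ seg0) / (denom * denom_seed)
            if absolute_rho:
                r = np.abs(r)
            hit = np.flatnonzero(np.nan_to_num(r) >= rho)
            hit = hit[hit != c]
            if hit.size:
                peaks = t0 + np.argmax(np.abs(others[hit]), axis=1)
                new_ch.append(hit.astype(np.int64))
                new_t.append(peaks.astype(np.int64))
    if skipped:
        logger.info("propagate_correlated_events: skipped %d short/degenerate windows", skipped)
    return EventRaster(
        np.concatenate(new_ch),
        np.concatenate(new_t),
        raster.n_channels,
        raster.n_bins,
        raster.bin_ms,
    )


def point_process(
    recording: ContinuousRecording, params: PointProcessParams | None = None
) -> EventRaster:
    """Full pipeline: normalize, (optionally) fit the threshold, binarize,
    and propagate correlated co-events."""
    params = params or PointProcessParams()
    rec = recording if recording.is_normalized() else recording.normalized()
    sigma = (
        fit_gaussian_threshold(rec, params.candidate_range)
        if params.auto_threshold
        else params.sigma
    )
    seeds = binarize(rec, sigma)
    return propagate_correlated_events(
        rec, seeds, params.rho, sigma, absolute_rho=params.absolute_rho
    )
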