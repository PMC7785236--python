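"""Criticality test battery: exponent relations, shape collapse, finite-size
scaling.

Near a critical point the avalanche exponents obey the crackling-noise
relation ``(alpha - 1)/(tau - 1) = 1/(sigma nu z)``, the mean size at a given
duration scales as ``<S>(T) ~ T^(1/sigma nu z)``, and mean avalanche profiles
of different durations collapse onto a single scaling function when time is
normalized to [0, 1] and amplitude divided by ``T^gamma`` with
``gamma = 1/(sigma nu z) - 1``. This module estimates 1/(sigma nu z) all
three ways, and tests finite-size scaling: avalanche size/duration
distributions from channel-subsampled rasters should collapse onto each
other once time is rebinned by the inverse sampled fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import wasserstein_distance

from .avalanches import AvalancheCatalog, extract_avalanches
from .powerlaw import PowerLawFit
from .raster import EventRaster

__all__ = [
    "ScalingExponents",
    "FssResult",
    "snz_from_regression",
    "exponent_relation",
    "percentage_difference",
    "shape_collapse",
    "distribution_distance",
    "finite_size_scaling",
    "average_fold_change",
]


class InsufficientScalingDataError(ValueError):
    pass


@dataclass
class ScalingExponents:
    """The three 1/(sigma nu z) estimates for one recording, plus their
    pairwise percentage differences (keys 'relation_regression',
    'relation_collapse', 'regression_collapse')."""

    tau: float
    alpha: float
    snz_relation: float
    snz_regression: float
    snz_collapse: float
    gamma: float = field(init=False)
    pct_diffs: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.gamma = self.snz_collapse - 1.0
        self.pct_diffs = {}
        for name, (a, b) in {
            "relation_regression": (self.snz_relation, self.snz_regression),
            "relation_collapse": (self.snz_relation, self.snz_collapse),
            "regression_collapse": (self.snz_regression, self.snz_collapse),
        }.items():
            try:
                self.pct_diffs[name] = percentage_difference(a, b)
            except ValueError:
                self.pct_diffs[name] = float("nan")


@dataclass
class FssResult:
    """Finite-size-scaling summary for one statistic (sizes or durations).

    ``fold_change = (distance_rebinned - distance_raw)/distance_raw``;
    values <= 0 indicate that rebinning collapsed the subsampled
    distributions onto each other.
    """

    statistic: str
    metric: str
    fractions: tuple[float, ...]
    n_draws: int
    distance_raw: float
    distance_rebinned: float
    fold_change: float


def snz_from_regression(catalog: AvalancheCatalog, dur_fit: PowerLawFit) -> float:
    """OLS slope of log<S> vs log T over durations inside the fitted range."""
    S, T = catalog.sizes, catalog.durations
    u = np.unique(T)
    u = u[(u >= dur_fit.x_min) & (u <= dur_fit.x_max)]
    if u.size < 3:
        raise InsufficientScalingDataError(
            f"need >= 3 distinct durations in [{dur_fit.x_min}, {dur_fit.x_max}], got {u.size}"
        )
    mean_s = np.array([S[T == t].mean() for t in u])
    slope, _ = np.polyfit(np.log(u.astype(float)), np.log(mean_s), 1)
    return float(slope)


def exponent_relation(tau: float, alpha: float) -> float:
    """The crackling-noise prediction (alpha - 1)/(tau - 1) for 1/(sigma nu z)."""
    if tau <= 1:
        raise ValueError("tau must exceed 1")
    return (alpha - 1.0) / (tau - 1.0)


def percentage_difference(a: float, b: float) -> float:
    """|a - b| / mean(a, b) * 100, defined for positive inputs."""
    if a <= 0 or b <= 0:
        raise ValueError("percentage difference requires positive inputs")
    return abs(a - b) / ((a + b) / 2.0) * 100.0


def shape_collapse(
    mean_profiles: dict[int, np.ndarray],
    gamma_grid: tuple[float, float, float] = (-0.5, 2.5, 0.01),
    *,
    n_points: int = 100,
) -> tuple[float, float]:
    """Optimal profile-rescaling exponent gamma and its collapse error.

    Each mean profile of duration T is interpolated onto a common normalized
    time grid u in [0, 1] and divided by ``T**gamma``; the collapse error at
    a given gamma is the variance across the rescaled curves averaged over
    the grid, normalized by the squared mean curve. Returns the gamma
    minimizing the error (grid search over ``gamma_grid`` = (low, high,
    step)) and the minimal error. ``1/(sigma nu z) = gamma + 1``.
    """
    profiles = {T: np.asarray(p, dtype=float) for T, p in mean_profiles.items() if T >= 2}
    if len(profiles) < 3:
        raise InsufficientScalingDataError("need mean profiles for >= 3 durations")
    u = np.linspace(0.0, 1.0, n_points)
    curves = np.stack(
        [np.interp(u, np.linspace(0.0, 1.0, p.size), p) for p in profiles.values()]
    )
    durations = np.array(list(profiles.keys()), dtype=float)[:, None]
    lo, hi, step = gamma_grid
    gammas = np.arange(lo, hi + step / 2, step)
    best_g, best_err = lo, np.inf
    for g in gammas:
        scaled = curves / durations**g
        mean_curve = scaled.mean(axis=0)
        denom = float((mean_curve**2).mean())
        if denom == 0:
            continue
        err = float(scaled.var(axis=0).mean()) / denom
        if err < best_err:
            best_g, best_err = float(g), err
    return best_g, best_err


def distribution_distance(samples_a, samples_b, metric: str = "ks") -> float:
    """Distance between two empirical distributions.

    ``ks``: sup-distance between the empirical CDFs. ``wasserstein``:
    1-Wasserstein distance between the distributions of log-transformed
    values (logs so that heavy tails do not dominate the transport cost).
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if metric == "ks":
        grid = np.unique(np.concatenate([a, b]))
        cdf_a = np.searchsorted(np.sort(a), grid, side="right") / a.size
        cdf_b = np.searchsorted(np.sort(b), grid, side="right") / b.size
        return float(np.max(np.abs(cdf_a - cdf_b)))
    if metric == "wasserstein":
        return float(wasserstein_distance(np.log(a), np.log(b)))
    raise ValueError(f"unknown metric {metric!r}; use 'ks' or 'wasserstein'")


def _pairwise_mean(dists: list[np.ndarray], metric: str) -> float:
    n = len(dists)
    if n < 2:  # a single distribution has no pairs to differ
        return 0.0
    vals = [
        distribution_distance(dists[i], dists[j], metric)
        for i in range(n)
        for j in range(i + 1, n)
    ]
    return float(np.mean(vals))


def finite_size_scaling(
    raster: EventRaster,
    fractions: tuple[float, ...] = (1.0, 0.5, 0.25, 0.125),
    n_draws: int = 10,
    metric: str = "ks",
    seed: int = 0,
) -> tuple[FssResult, FssResult]:
    """Finite-size-scaling test on one raster; returns (sizes, durations).

    Stage 1 (no rebinning): for each fraction f, draw ``n_draws`` random
    channel subsets of size floor(f * n_channels) (without replacement),
    extract avalanches, and pool them into one size and one duration
    distribution per fraction; the raw distance is the mean pairwise
    distance across the fraction-level distributions. Stage 2: the same
    subsets, but the subset raster is first rebinned by round(1/f) (logical
    OR within coarse bins); distances recomputed identically. The fold
    change ``(rebinned - raw)/raw`` is <= 0 when renormalization collapses
    the subsampled distributions.
    """
    fractions = tuple(fractions)
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    subsets: dict[float, list[np.ndarray]] = {}
    for f in fractions:
        k = int(np.floor(f * raster.n_channels))
        if k < 2:
            raise ValueError(f"fraction {f} leaves fewer than 2 channels")
        reps = 1 if f >= 1.0 else n_draws
        subsets[f] = [
            np.sort(rng.choice(raster.n_channels, size=k, replace=False))
            for _ in range(reps)
        ]

    def pooled(rebin: bool) -> tuple[list[np.ndarray], list[np.ndarray]]:
        size_d, dur_d = [], []
        for f in fractions:
            factor = max(1, int(round(1.0 / f))) if rebin else 1
            ss, dd = [], []
            for keep in subsets[f]:
                sub = raster.subset_channels(keep)
                if factor > 1:
                    sub = sub.rebin(factor)
                cat = extract_avalanches(sub)
                ss.append(cat.sizes)
                dd.append(cat.durations)
            s = np.concatenate(ss)
            d = np.concatenate(dd)
            if s.size == 0:
                raise ValueError(f"no avalanches at fraction {f}")
            size_d.append(s)
            dur_d.append(d)
        return size_d, dur_d

    raw_s, raw_d = pooled(rebin=False)
    reb_s, reb_d = pooled(rebin=True)
    out = []
    for stat, raw, reb in (("size", raw_s, reb_s), ("duration", raw_d, reb_d)):
        d_raw = _pairwise_mean(raw, metric)
        d_reb = _pairwise_mean(reb, metric)
        fold = (d_reb - d_raw) / d_raw if d_raw > 0 else float("nan")
        out.append(
            FssResult(stat, metric, fractions, n_draws, d_raw, d_reb, fold)
        )
    return out[0], out[1]


def average_fold_change(per_scan_pairs: list[tuple[float, float]]) -> float:
    """Mean over scans of (rebinned - raw)/raw; every raw value must be > 0."""
    if not per_scan_pairs:
        raise ValueError("no (raw, rebinned) pairs given")
    folds = []
    for raw, rebinned in per_scan_pairs:
        if raw <= 0:
            raise ValueError("raw distance must be > 0")
        folds.append((rebinned - raw) / raw)
    return float(np.mean(folds))
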