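"""Per-recording criticality battery and condition-level summaries.

``run_battery`` chains the full analysis on one recording or raster:
point process (for continuous input) -> avalanche extraction -> truncated
power-law fits of sizes and durations -> scaling battery (<S>(T) regression,
exponent relation, shape collapse, finite-size scaling) -> TSE complexity.
``summarize_conditions`` averages battery rows within conditions and
computes the condition-level fold changes (rebinned-vs-raw distribution
distances, and drug-vs-awake complexity for subject-matched scan pairs).

A packaged reference table (``load_reference_table``) carries published
session-level battery values from macaque ECoG resting-state/anaesthesia
recordings (awake, ketamine, propofol conditions); it drives the worked
examples and the summary-arithmetic checks.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import pearsonr

from . import complexity as cx
from . import scaling as sc
from .avalanches import AvalancheCatalog, extract_avalanches, mean_profiles_by_duration
from .point_process import PointProcessParams, point_process
from .powerlaw import PowerLawFit, scan_range
from .raster import ContinuousRecording, EventRaster

__all__ = [
    "BatteryConfig",
    "BatteryRow",
    "CriticalityReport",
    "ConditionSummary",
    "BatteryError",
    "channel_rates",
    "rate_correlation",
    "run_battery",
    "summarize_conditions",
    "load_reference_table",
    "rows_from_dataframe",
]

logger = logging.getLogger(__name__)


class BatteryError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""


@dataclass
class BatteryConfig:
    """All tunables of the per-recording battery, with one master seed."""

    sigma: float = 4.0
    rho: float = 0.75
    auto_threshold: bool = False
    candidate_range: tuple[float, float] = (2.0, 6.0)
    min_points_per_bound: int = 5
    n_surrogates: int = 500
    min_profile_count: int = 10
    gamma_grid: tuple[float, float, float] = (-0.5, 2.5, 0.01)
    fss_fractions: tuple[float, ...] = (1.0, 0.5, 0.25, 0.125)
    fss_draws: int = 10
    fss_metric: str = "ks"
    k_grid: tuple[int, ...] = cx.DEFAULT_K_GRID
    n_subsets_per_k: int = 20
    n_nulls: int = 20
    jitter_window_ms: float = 30_000.0
    drop_boundary_truncated: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BatteryConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("candidate_range", "gamma_grid", "fss_fractions", "k_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for key in ("candidate_range", "gamma_grid", "fss_fractions", "k_grid"):
            d[key] = list(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class BatteryRow:
    """One battery-table row (the schema of the reference table)."""

    subject: str
    condition: str
    tau: float
    xmin_s: float
    xmax_s: float
    alpha: float
    xmin_d: float
    xmax_d: float
    exp_rel: float
    snz_regression: float
    snz_collapse: float
    complexity: float
    rebin_ks_d: float
    norebin_ks_d: float
    rebin_ks_s: float
    norebin_ks_s: float
    rates: np.ndarray | None = None


@dataclass
class CriticalityReport:
    """Full per-recording battery output; failed stages are recorded in
    ``errors`` keyed by stage name with their fields left None."""

    recording_id: str
    condition: str
    config: BatteryConfig
    n_channels: int = 0
    n_bins: int = 0
    n_events: int = 0
    n_avalanches: int = 0
    rates: np.ndarray | None = None
    mean_rate: float = float("nan")
    size_fit: PowerLawFit | None = None
    dur_fit: PowerLawFit | None = None
    scaling: sc.ScalingExponents | None = None
    fss_size: sc.FssResult | None = None
    fss_duration: sc.FssResult | None = None
    complexity: cx.ComplexityResult | None = None
    errors: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, np.ndarray):
                return [float(v) for v in obj]
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj

        return clean(dataclasses.asdict(self))

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_row(self) -> BatteryRow:
        s, d = self.size_fit, self.dur_fit
        sca = self.scaling
        return BatteryRow(
            subject=self.recording_id,
            condition=self.condition,
            tau=s.exponent if s else float("nan"),
            xmin_s=s.x_min if s else float("nan"),
            xmax_s=s.x_max if s else float("nan"),
            alpha=d.exponent if d else float("nan"),
            xmin_d=d.x_min if d else float("nan"),
            xmax_d=d.x_max if d else float("nan"),
            exp_rel=sca.snz_relation if sca else float("nan"),
            snz_regression=sca.snz_regression if sca else float("nan"),
            snz_collapse=sca.snz_collapse if sca else float("nan"),
            complexity=self.complexity.c_n if self.complexity else float("nan"),
            rebin_ks_d=self.fss_duration.distance_rebinned if self.fss_duration else float("nan"),
            norebin_ks_d=self.fss_duration.distance_raw if self.fss_duration else float("nan"),
            rebin_ks_s=self.fss_size.distance_rebinned if self.fss_size else float("nan"),
            norebin_ks_s=self.fss_size.distance_raw if self.fss_size else float("nan"),
            rates=self.rates,
        )


@dataclass
class ConditionSummary:
    """Per-condition means of the battery columns plus fold changes."""

    condition: str
    n_scans: int
    mean_tau: float
    mean_alpha: float
    mean_xmin_s: float
    mean_xmax_s: float
    mean_xmin_d: float
    mean_xmax_d: float
    mean_snz_relation: float
    mean_snz_regression: float
    mean_snz_collapse: float
    mean_complexity: float
    fold_size: float
    fold_duration: float
    mean_rate_correlation: float = float("nan")
    complexity_fold_vs: dict[str, float] = field(default_factory=dict)


def channel_rates(raster: EventRaster) -> tuple[np.ndarray, float]:
    """Per-channel event rates in events/ms, and the grand mean rate."""
    if raster.n_bins <= 0:
        raise ValueError("raster has no bins")
    length_ms = raster.n_bins * raster.bin_ms
    rates = raster.counts_per_channel() / length_ms
    return rates, float(rates.mean())


def rate_correlation(rates_a, rates_b) -> float:
    """Pearson correlation of two per-channel rate vectors; NaN for
    zero-variance input (undefined)."""
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("rate vectors must have equal length >= 3")
    if a.std() == 0 or b.std() == 0:
        logger.warning("rate_correlation: zero-variance rate vector, returning NaN")
        return float("nan")
    return float(pearsonr(a, b).statistic)


def run_battery(
    data: ContinuousRecording | EventRaster,
    config: BatteryConfig | None = None,
    *,
    recording_id: str = "recording",
    condition: str = "",
) -> CriticalityReport:
    """Execute the full criticality battery on one recording or raster.

    Deterministic for a fixed config (all stage seeds derive from
    ``config.seed``). An empty point-processed raster aborts with a
    stage-tagged :class:`BatteryError`; later-stage failures are recorded in
    ``report.errors`` and leave their fields None.
    """
    config = config or BatteryConfig()
    report = CriticalityReport(recording_id, condition, config)
    ss = np.random.SeedSequence(config.seed)
    seed_scan_s, seed_scan_d, seed_fss, seed_cx = [
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(4)
    ]

    if isinstance(data, ContinuousRecording):
        try:
            raster = point_process(
                data,
                PointProcessParams(
                    sigma=config.sigma,
                    rho=config.rho,
                    auto_threshold=config.auto_threshold,
                    candidate_range=config.candidate_range,
                ),
            )
        except Exception as exc:
            raise BatteryError(f"point_process: {exc}") from exc
    else:
        raster = data
    if raster.n_events == 0:
        raise BatteryError("point_process: no events detected")

    report.n_channels = raster.n_channels
    report.n_bins = raster.n_bins
    report.n_events = raster.n_events
    report.rates, report.mean_rate = channel_rates(raster)

    catalog = extract_avalanches(
        raster, drop_boundary_truncated=config.drop_boundary_truncated
    )
    report.n_avalanches = len(catalog)
    if len(catalog) == 0:
        raise BatteryError("avalanches: no avalanches in raster")

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            report.errors[name] = str(exc)
            logger.warning("battery stage %s failed: %s", name, exc)
            return None

    size_fit = stage(
        "powerlaw_sizes",
        lambda: scan_range(
            catalog.sizes, config.min_points_per_bound, config.n_surrogates, seed_scan_s
        ),
    )
    dur_fit = stage(
        "powerlaw_durations",
        lambda: scan_range(
            catalog.durations, config.min_points_per_bound, config.n_surrogates, seed_scan_d
        ),
    )
    report.size_fit, report.dur_fit = size_fit, dur_fit

    if size_fit and dur_fit:
        def do_scaling():
            snz_reg = sc.snz_from_regression(catalog, dur_fit)
            profiles = mean_profiles_by_duration(catalog, config.min_profile_count)
            gamma, _ = sc.shape_collapse(profiles, config.gamma_grid)
            return sc.ScalingExponents(
                tau=size_fit.exponent,
                alpha=dur_fit.exponent,
                snz_relation=sc.exponent_relation(size_fit.exponent, dur_fit.exponent),
                snz_regression=snz_reg,
                snz_collapse=gamma + 1.0,
            )

        report.scaling = stage("scaling", do_scaling)

    def do_fss():
        return sc.finite_size_scaling(
            raster, config.fss_fractions, config.fss_draws, config.fss_metric, seed_fss
        )

    fss = stage("fss", do_fss)
    if fss:
        report.fss_size, report.fss_duration = fss

    report.complexity = stage(
        "complexity",
        lambda: cx.tse_complexity(
            raster,
            config.k_grid,
            config.n_subsets_per_k,
            config.n_nulls,
            config.jitter_window_ms,
            seed_cx,
        ),
    )
    return report


def _mean(vals) -> float:
    vals = [v for v in vals if np.isfinite(v)]
    return float(np.mean(vals)) if vals else float("nan")


def summarize_conditions(
    rows: list[BatteryRow], *, awake_condition: str = "awake"
) -> list[ConditionSummary]:
    """Condition-level summary of battery rows.

    Means are taken over each condition's scans; non-positive shape-collapse
    estimates (a failed collapse) are excluded from the collapse mean.
    Distribution-distance fold changes average ``(rebin - norebin)/norebin``
    over the condition's scans. Complexity fold changes are computed per
    drug condition over subject-matched awake/drug scan pairs (unmatched
    scans are skipped with a warning). When per-channel rates are present,
    the mean pairwise within-condition rate correlation is reported.
    """
    if not rows:
        raise ValueError("no battery rows")
    by_cond: dict[str, list[BatteryRow]] = {}
    for r in rows:
        by_cond.setdefault(r.condition, []).append(r)
    awake_by_subject = {
        r.subject: r for r in by_cond.get(awake_condition, [])
    }

    out = []
    for cond, members in by_cond.items():
        collapse_vals = [r.snz_collapse for r in members if r.snz_collapse > 0]
        fold_size = sc.average_fold_change(
            [(r.norebin_ks_s, r.rebin_ks_s) for r in members]
        )
        fold_dur = sc.average_fold_change(
            [(r.norebin_ks_d, r.rebin_ks_d) for r in members]
        )
        cx_folds: dict[str, float] = {}
        if cond != awake_condition:
            pair_folds = []
            for r in members:
                mate = awake_by_subject.get(r.subject)
                if mate is None:
                    logger.warning(
                        "no awake scan for subject %s; skipping complexity fold", r.subject
                    )
                    continue
                pair_folds.append(cx.complexity_fold_change(mate.complexity, r.complexity))
            if pair_folds:
                cx_folds[awake_condition] = float(np.mean(pair_folds))
        corr = float("nan")
        rate_rows = [r for r in members if r.rates is not None]
        if len(rate_rows) >= 2:
            vals = [
                rate_correlation(rate_rows[i].rates, rate_rows[j].rates)
                for i in range(len(rate_rows))
                for j in range(i + 1, len(rate_rows))
            ]
            corr = _mean(vals)
        out.append(
            ConditionSummary(
                condition=cond,
                n_scans=len(members),
                mean_tau=_mean(r.tau for r in members),
                mean_alpha=_mean(r.alpha for r in members),
                mean_xmin_s=_mean(r.xmin_s for r in members),
                mean_xmax_s=_mean(r.xmax_s for r in members),
                mean_xmin_d=_mean(r.xmin_d for r in members),
                mean_xmax_d=_mean(r.xmax_d for r in members),
                mean_snz_relation=_mean(r.exp_rel for r in members),
                mean_snz_regression=_mean(r.snz_regression for r in members),
                mean_snz_collapse=_mean(collapse_vals),
                mean_complexity=_mean(r.complexity for r in members),
                fold_size=fold_size,
                fold_duration=fold_dur,
                mean_rate_correlation=corr,
                complexity_fold_vs=cx_folds,
            )
        )
    return out


def load_reference_table() -> pd.DataFrame:
    """Published session-level battery values (macaque ECoG, awake vs
    ketamine vs propofol) shipped with the package."""
    with resources.files("neurocrit.data").joinpath("reference_battery.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def rows_from_dataframe(df: pd.DataFrame) -> list[BatteryRow]:
    cols = [f.name for f in dataclasses.fields(BatteryRow) if f.name != "rates"]
    return [BatteryRow(**{c: row[c] for c in cols}) for _, row in df.iterrows()]
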