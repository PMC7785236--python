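"""Diagnostic plots: CCDFs, size-vs-duration scaling, shape collapse,
finite-size scaling, and TSE integration curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .avalanches import AvalancheCatalog
from .complexity import ComplexityResult
from .powerlaw import PowerLawFit, ccdf

__all__ = [
    "plot_ccdf",
    "plot_size_vs_duration",
    "plot_shape_collapse",
    "plot_integration_curve",
]


def plot_ccdf(samples, fit: PowerLawFit | None = None, ax=None, **kwargs):
    """Log-log empirical CCDF, with the fitted range shaded if given."""
    ax = ax or plt.gca()
    curve = ccdf(samples)
    ax.loglog(curve.values, np.maximum(curve.ccdf, 1e-12), drawstyle="steps-post", **kwargs)
    if fit is not None:
        ax.axvspan(fit.x_min, fit.x_max, alpha=0.15, color="grey")
        ax.set_title(f"exponent {fit.exponent:.2f} on [{fit.x_min}, {fit.x_max}]")
    ax.set_xlabel("x")
    ax.set_ylabel("P(X > x)")
    return ax


def plot_size_vs_duration(catalog: AvalancheCatalog, ax=None, **kwargs):
    """Mean avalanche size for each duration, log-log."""
    ax = ax or plt.gca()
    S, T = catalog.sizes, catalog.durations
    u = np.unique(T)
    ax.loglog(u, [S[T == t].mean() for t in u], "o", ms=3, **kwargs)
    ax.set_xlabel("duration T (bins)")
    ax.set_ylabel("mean size <S>(T)")
    return ax


def plot_shape_collapse(mean_profiles: dict[int, np.ndarray], gamma: float, ax=None):
    """Mean profiles rescaled to normalized time and amplitude T^gamma."""
    ax = ax or plt.gca()
    for T, prof in sorted(mean_profiles.items()):
        prof = np.asarray(prof, dtype=float)
        u = np.linspace(0, 1, prof.size)
        ax.plot(u, prof / T**gamma, label=f"T={T}")
    ax.set_xlabel("t / T")
    ax.set_ylabel(f"profile / T^{gamma:.2f}")
    return ax


def plot_integration_curve(result: ComplexityResult, ax=None):
    """Null-corrected integration vs subset size against the linear reference."""
    ax = ax or plt.gca()
    k = np.array(result.k_grid)
    ax.plot(k, result.integration_curve, "o-", label="<I(k)> (corrected)")
    ax.plot(k, result.linear_reference, "--", label="linear reference")
    ax.set_xlabel("subset size k")
    ax.set_ylabel("integration (bits)")
    ax.legend()
    ax.set_title(f"C_N = {result.c_n:.4g} bits")
    return ax
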