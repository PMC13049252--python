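"""Plot helpers for fit curves and method-comparison figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .analysis import ComparisonStats, T1FitResults


def plot_fit_curve(
    fit: T1FitResults,
    signal: np.ndarray,
    ti_ms: np.ndarray,
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """Measured ROI signal and the fitted inversion-recovery curve."""
    if ax is None:
        _fig, ax = plt.subplots()
    ti = np.asarray(ti_ms, dtype=float)
    ax.plot(ti, signal, "o", ms=4, label="measured")
    fine = np.linspace(ti.min(), ti.max(), 400)
    ax.plot(fine, fit.predict(fine), "-", label=f"fit: T1 = {fit.t1_ms:.0f} ms")
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.set_xlabel("TI (ms)")
    ax.set_ylabel("signal (a.u.)")
    ax.legend(frameon=False)
    return ax


def plot_bland_altman(
    t1_a: np.ndarray,
    t1_b: np.ndarray,
    stats: ComparisonStats | None = None,
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """Bland-Altman percent-difference plot of paired T1 measurements."""
    from .analysis import compare_methods

    if stats is None:
        stats = compare_methods(t1_a, t1_b)
    if ax is None:
        _fig, ax = plt.subplots()
    a = np.asarray(t1_a, dtype=float)
    b = np.asarray(t1_b, dtype=float)
    mean = (a + b) / 2.0
    pct = 100.0 * (b - a) / mean
    ax.plot(mean, pct, "o")
    ax.axhline(stats.bias_percent, color="k", lw=1, label="bias")
    for y in stats.loa_percent:
        ax.axhline(y, color="k", lw=1, ls="--")
    ax.set_xlabel("mean T1 (ms)")
    ax.set_ylabel("difference (%)")
    ax.legend(frameon=False)
    return ax
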