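"""Diagnostic plots: decay time courses and ratio-clock regressions."""

from __future__ import annotations

import math
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .core import ConcentrationSeries
from .kinetics import decay_curve
from .ratio import RatioClockResults, RatioSeries


def plot_decay(
    series: Sequence[ConcentrationSeries],
    fits=None,
    ax: Optional[plt.Axes] = None,
):
    """Log-scale concentration time courses, one line per series, with
    optional fitted first-order curves overlaid per target."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for s in series:
        det = s.detections()
        if not det:
            continue
        t = [m.time_h for m in det]
        c = [m.copies_per_ml for m in det]
        ax.plot(t, c, "o-", alpha=0.4, lw=0.8, ms=3, label=None)
    if fits:
        tmax = max((m.time_h for s in series for m in s.measurements), default=72.0)
        tt = np.linspace(0, tmax, 200)
        for target, fit in fits.items():
            med_c0 = np.median(
                [
                    s.measurements[0].copies_per_ml
                    for s in series
                    if s.target == target and not s.measurements[0].censored
                ]
            )
            ax.plot(
                tt,
                decay_curve(med_c0, fit.k_hat, tt),
                "-",
                lw=2,
                label=f"{target.label}: k={fit.k_hat:.4f}/h",
            )
        ax.legend(fontsize=8)
    ax.set_yscale("log")
    ax.set_xlabel("time since removal (h)")
    ax.set_ylabel("copies / mL")
    return ax


def plot_ratio_clock(
    ratio_series: Sequence[RatioSeries],
    results: Optional[RatioClockResults] = None,
    ax: Optional[plt.Axes] = None,
):
    """Scatter of log10 ratios over time with the fitted clock line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for s in ratio_series:
        if s.points:
            t, r = zip(*s.points)
            ax.plot(t, r, "o", alpha=0.5, ms=4)
    if results is not None:
        reg = results.regression
        tmax = max((t for s in ratio_series for t, _ in s.points), default=1.0)
        tt = np.linspace(0, tmax, 2)
        ax.plot(tt, reg.intercept + reg.slope * tt, "k-", lw=2)
        ax.set_title(results.summary(), fontsize=9)
    kind = ratio_series[0].kind if ratio_series else "?"
    ax.set_xlabel("time since removal (h)")
    ax.set_ylabel(f"log10 Ratio {kind}")
    return ax
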