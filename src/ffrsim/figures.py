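"""Convenience plots of the sweep and cohort outputs.

The CSVs written by the pipeline are the authoritative artifacts; these
figures replicate the standard layouts — a four-panel sweep figure (FFR,
FFR_C and P_D versus alpha, plus FFR versus P_D) and scatter plots with
iso-FFR reference lines — for quick visual inspection.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .simulation_sweeps import DotCloud, SweepCurve

__all__ = ["plot_sweep_panels", "plot_dot_cloud", "plot_cohort_scatter"]

_STYLES = ["-", "--", "-.", ":"]


def plot_sweep_panels(curves: list[SweepCurve]):
    """Four panels: FFR(alpha), FFR_C(alpha), P_D(alpha), FFR(P_D)."""
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    for i, curve in enumerate(curves):
        style = _STYLES[i % len(_STYLES)]
        label = f"r={curve.setting.r:g}, v={curve.setting.v:g}"
        t = curve.table
        axes[0, 0].plot(t["alpha"], t["FFR"], style, label=label)
        axes[0, 1].plot(t["alpha"], t["FFR_C"], style)
        axes[1, 0].plot(t["alpha"], t["PD"], style)
        axes[1, 1].plot(t["PD"], t["FFR"], style)
    axes[0, 0].axhline(0.80, color="gray", lw=0.6)
    axes[0, 0].axhline(0.75, color="gray", lw=0.6)
    axes[0, 0].set_xlabel(r"$\alpha$")
    axes[0, 0].set_ylabel("FFR")
    axes[0, 0].legend(fontsize=8)
    axes[0, 1].set_xlabel(r"$\alpha$")
    axes[0, 1].set_ylabel(r"FFR$_C$ (mmHg)")
    axes[1, 0].set_xlabel(r"$\alpha$")
    axes[1, 0].set_ylabel(r"$P_D$ (mmHg)")
    axes[1, 1].set_xlabel(r"$P_D$ (mmHg)")
    axes[1, 1].set_ylabel("FFR")
    fig.tight_layout()
    return fig


def plot_dot_cloud(cloud: DotCloud):
    """P_D vs P_A dots for each stenosis degree with iso-FFR lines."""
    fig, ax = plt.subplots(figsize=(6, 6))
    pts = cloud.points
    ax.scatter(pts["PA"], pts["PD"], s=10, c=pts["alpha"], cmap="viridis")
    pa_line = np.linspace(0, pts["PA"].max() * 1.05, 2)
    for level in cloud.iso_ffr_lines:
        ax.plot(pa_line, level * pa_line, lw=0.7, color="gray")
        ax.annotate(f"FFR={level:g}", (pa_line[-1], level * pa_line[-1]), fontsize=7)
    ax.set_xlabel(r"$P_A$ (mmHg)")
    ax.set_ylabel(r"$P_D$ (mmHg)")
    fig.tight_layout()
    return fig


def plot_cohort_scatter(frame, fit=None):
    """Cohort P_D vs P_A by stenosis location, with optional fitted line."""
    fig, ax = plt.subplots(figsize=(6, 6))
    markers = {"p": "o", "m": "s", "d": "^"}
    for loc, sub in frame.groupby("location"):
        ax.scatter(sub["PA"], sub["PD_hyper"], marker=markers.get(loc, "x"), label=loc)
    pa_line = np.linspace(frame["PA"].min(), frame["PA"].max(), 2)
    ax.plot(pa_line, pa_line, color="black", lw=0.8, label="FFR = 1")
    if fit is not None:
        slope = fit.coefficients["slope"]
        intercept = fit.coefficients["intercept"]
        ax.plot(pa_line, slope * pa_line + intercept, color="tab:red",
                label=f"fit: slope={slope:.3f}, R={fit.correlation:.3f}")
    ax.set_xlabel(r"$P_A$ (mmHg)")
    ax.set_ylabel(r"$P_D$ (mmHg)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
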