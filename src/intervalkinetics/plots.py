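"""Diagnostic figures (vector output) for the interval-imaging fit."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .fitcrtd import CRTD, GlobalFitResult, KeffSeries
from .kinetics import AcquisitionProtocol, survival

__all__ = ["plot_keff_series", "plot_crtds"]


def plot_keff_series(
    series: KeffSeries, path: str | Path, title: str | None = None
) -> Path:
    """k_eff * tau_tl versus tau_tl with the straight-line fit.

    A linear trend indicates a single kinetic population (slope = k_off,
    intercept = k_b * tau_int); curvature indicates a mixture.
    """
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.plot(series.tau_tl, series.product, "o", color="tab:blue", label="data")
    grid = np.linspace(series.tau_tl.min(), series.tau_tl.max(), 100)
    ax.plot(grid, series.slope * grid + series.intercept, "-", color="tab:gray",
            label=f"line: slope {series.slope:.3g}/s, icpt {series.intercept:.3g}")
    ax.set_xlabel(r"$\tau_{tl}$ (s)")
    ax.set_ylabel(r"$k_{eff}\,\tau_{tl}$")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_crtds(
    crtds: list[CRTD],
    path: str | Path,
    fit: GlobalFitResult | None = None,
    protocol: AcquisitionProtocol | None = None,
) -> Path:
    """Semi-log CRTDs per tau_tl, optionally with the global-fit curves."""
    fig, ax = plt.subplots(figsize=(5, 3.8))
    cmap = plt.get_cmap("viridis")
    for i, crtd in enumerate(sorted(crtds, key=lambda c: c.tau_tl)):
        color = cmap(i / max(len(crtds) - 1, 1))
        t = crtd.m_grid * crtd.tau_tl
        mask = crtd.counts > 0
        ax.semilogy(t[mask], crtd.counts[mask], ".", ms=3, color=color,
                    label=rf"$\tau_{{tl}}$={crtd.tau_tl:g}s")
        if fit is not None and protocol is not None:
            model = fit.model
            s = survival(model, crtd.tau_tl, protocol.tau_int, t)
            s1 = survival(model, crtd.tau_tl, protocol.tau_int, crtd.tau_tl)
            ax.semilogy(t, crtd.counts[0] * s / s1, "-", lw=0.8, color=color)
    ax.set_xlabel("dwell time (s)")
    ax.set_ylabel("events $\\geq$ t")
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path
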