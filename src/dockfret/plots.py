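"""Publication-style figures for pipeline outputs (all return the Axes)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .idealize import TransitionMap
from .melting import MeltingCurve, MeltingResult
from .thermo import FretHistogram, MValueFit, TitrationPoint, TwoGaussianFit, _two_gauss

__all__ = ["plot_fret_histogram", "plot_delta_g_titration", "plot_transition_map",
           "plot_melting_curve"]


def plot_fret_histogram(hist: FretHistogram, fit: TwoGaussianFit | None = None, ax=None):
    ax = ax or plt.subplots()[1]
    ax.bar(hist.centers, hist.counts, width=np.diff(hist.edges), color="0.7",
           edgecolor="none", label=f"N = {hist.n_molecules} molecules")
    if fit is not None:
        x = np.linspace(hist.edges[0], hist.edges[-1], 400)
        y = _two_gauss(x, fit.amp_undock, fit.mu_undock, fit.sigma_undock,
                       fit.amp_dock, fit.mu_dock, fit.sigma_dock)
        ax.plot(x, y, "k-", lw=1.5)
        ax.axvline(fit.mu_undock, color="tab:blue", ls="--",
                   label=f"undocked {fit.mu_undock:.2f}")
        ax.axvline(fit.mu_dock, color="tab:red", ls="--",
                   label=f"docked {fit.mu_dock:.2f}")
    ax.set_xlabel("FRET efficiency")
    ax.set_ylabel("frames")
    ax.legend(fontsize=8)
    return ax


def plot_delta_g_titration(points: list[TitrationPoint], fit: MValueFit | None = None,
                           osmolyte: str = "osmolyte", ax=None):
    ax = ax or plt.subplots()[1]
    c = np.array([p.concentration for p in points])
    g = np.array([p.delta_g for p in points])
    sd = np.array([p.bootstrap_sd for p in points])
    ax.errorbar(c, g, yerr=np.where(np.isfinite(sd), sd, 0.0), fmt="o", capsize=3)
    if fit is not None:
        xs = np.linspace(c.min(), c.max(), 50)
        ax.plot(xs, fit.intercept + fit.m_value * xs, "k--",
                label=f"m = {fit.m_value:.2f} ± {fit.slope_se:.2f} kcal/mol/M")
        ax.legend(fontsize=8)
    ax.set_xlabel(f"[{osmolyte}] (M)")
    ax.set_ylabel(r"$\Delta G^\circ_{dock}$ (kcal/mol)")
    return ax


def plot_transition_map(tmap: TransitionMap, ax=None):
    ax = ax or plt.subplots()[1]
    im = ax.imshow(tmap.grid, origin="lower", extent=(0, 1, 0, 1), aspect="equal",
                   cmap="viridis")
    ax.plot([0, 1], [0, 1], "w:", lw=0.8)
    ax.set_xlabel("initial FRET")
    ax.set_ylabel("final FRET")
    ax.set_title(tmap.kind)
    plt.colorbar(im, ax=ax, shrink=0.8)
    return ax


def plot_melting_curve(curve: MeltingCurve, result: MeltingResult | None = None, ax=None):
    ax = ax or plt.subplots()[1]
    ax.plot(curve.temperature, curve.absorbance, ".", ms=3, color="0.4")
    if result is not None:
        for tm in result.tm_list:
            ax.axvline(tm, color="tab:red", ls="--", label=f"Tm = {tm:.1f} °C")
        if result.tm_list:
            ax.legend(fontsize=8)
    ax.set_xlabel("temperature (°C)")
    ax.set_ylabel("A260")
    if curve.label:
        ax.set_title(curve.label)
    return ax
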