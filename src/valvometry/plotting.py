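"""Functional plots: wavelet power / coherence heatmaps and CCF stem plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .envstats import CcfResult
from .rhythms import CoherenceResult, WaveletResult


def plot_power(result: WaveletResult, path=None, ax=None):
    """Time x period heatmap of wavelet power with the cone of influence."""
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    t = np.arange(len(result.times))
    mesh = ax.pcolormesh(t, result.periods_h, np.log2(result.power + 1e-12),
                         shading="auto", cmap="viridis")
    ax.plot(t, result.coi_h, "w--", lw=1)
    if result.signif_mask is not None and result.signif_mask.any():
        ax.contour(t, result.periods_h, result.signif_mask.astype(float),
                   levels=[0.5], colors="k", linewidths=0.7)
    ax.set_yscale("log", base=2)
    ax.set_ylim(result.periods_h[0], result.periods_h[-1])
    ax.set_ylabel("period (h)")
    ax.set_xlabel("sample")
    plt.colorbar(mesh, ax=ax, label="log2 power / variance")
    if path is not None:
        ax.figure.savefig(path, dpi=110, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_coherence(result: CoherenceResult, path=None, ax=None,
                   arrow_stride=(8, 40)):
    """Coherence heatmap with phase arrows (right = in phase, left = anti-phase)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    t = np.arange(len(result.times))
    mesh = ax.pcolormesh(t, result.periods_h, result.coherence, shading="auto",
                         vmin=0, vmax=1, cmap="magma")
    sj, st = arrow_stride
    tt, pp = np.meshgrid(t[::st], result.periods_h[::sj])
    ph = result.phase[::sj, ::st]
    ax.quiver(tt, pp, np.cos(ph), np.sin(ph), scale=40, width=2e-3, color="c")
    ax.plot(t, result.coi_h, "w--", lw=1)
    ax.set_yscale("log", base=2)
    ax.set_ylim(result.periods_h[0], result.periods_h[-1])
    ax.set_ylabel("period (h)")
    ax.set_xlabel("sample")
    plt.colorbar(mesh, ax=ax, label="squared coherence")
    if path is not None:
        ax.figure.savefig(path, dpi=110, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_ccf(result: CcfResult, path=None, ax=None):
    """Stem plot of the cross-correlation with +/-1.96/sqrt(N) bounds."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    ax.stem(result.lags, result.r, basefmt=" ")
    ax.axhline(result.conf_bound, ls="--", c="b", lw=0.8)
    ax.axhline(-result.conf_bound, ls="--", c="b", lw=0.8)
    ax.axhline(0, c="k", lw=0.8)
    ax.set_xlabel("lag (days; positive = closure lags covariate)")
    ax.set_ylabel("r")
    if path is not None:
        ax.figure.savefig(path, dpi=110, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
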