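"""Matplotlib helpers for switch curves, expression maps and hysteresis plots."""

from __future__ import annotations

import numpy as np

from .analysis import ExpressionMap, HillFit
from .network import BistabilityResult


def plot_switch_curve(ax, alpha, response, fit: HillFit | None = None, *,
                      label: str | None = None):
    """Log-log switch response with an optional Hill-fit overlay."""
    ax.loglog(alpha, response, "o", label=label)
    if fit is not None:
        grid = np.geomspace(min(alpha), max(alpha), 200)
        ax.loglog(grid, fit(grid), "-",
                  label=f"Hill H={fit.H:+.2f}, K={fit.K:.2f}")
    ax.set_xlabel(r"relative promoter strength $\alpha$")
    ax.set_ylabel("steady-state level (nM)")
    if label or fit:
        ax.legend()
    return ax


def plot_expression_map(ax, emap: ExpressionMap, *, cmap: str = "viridis"):
    """Heatmap of the per-alpha fate distribution over normalised-length bins."""
    data = emap.fractions.to_numpy()
    im = ax.imshow(data, aspect="auto", origin="lower", cmap=cmap,
                   extent=(0, data.shape[1], 0, data.shape[0]))
    ax.set_xticks(np.arange(data.shape[1]) + 0.5,
                  list(emap.fractions.columns), rotation=90, fontsize=7)
    step = max(1, data.shape[0] // 12)
    ax.set_yticks(np.arange(0, data.shape[0], step) + 0.5,
                  list(emap.fractions.index)[::step], fontsize=7)
    ax.set_xlabel(r"$\alpha$")
    ax.set_ylabel("normalised transcript length bin")
    return im


def plot_hysteresis(ax, result: BistabilityResult, species: str = "Y"):
    """Up/down branches of a dose sweep with detected thresholds."""
    ax.semilogy(result.k_WZ_grid, result.branch_values("up", species),
                "o-", label="up sweep")
    ax.semilogy(result.k_WZ_grid, result.branch_values("down", species),
                "s--", label="down sweep")
    for thr, name in ((result.threshold_on, "ON threshold"),
                      (result.threshold_off, "OFF threshold")):
        if thr is not None:
            ax.axvline(thr, color="grey", ls=":", lw=1)
            ax.text(thr, ax.get_ylim()[1], name, rotation=90, va="top",
                    fontsize=7)
    ax.set_xlabel(r"$k_{WZ}$ (nM/s)")
    ax.set_ylabel(f"[{species}] (nM)")
    ax.legend()
    return ax
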