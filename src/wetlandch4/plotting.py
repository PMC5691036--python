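"""Convenience plots: depth x time activity maps and oxic-fraction curves."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_r_heatmap", "plot_oxic_fraction"]


def plot_r_heatmap(results, ecosite: str = "", ax=None):
    """Depth x time map of the inverted net CH4 production rate.

    One column per month interval; red = production, blue = oxidation.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    grid = results[0].grid
    edges_t = [results[0].t_start] + [r.t_end for r in results]
    rmat = np.column_stack([r.mean_r.values for r in results])
    vmax = max(np.abs(rmat).max(), 1e-12)
    mesh = ax.pcolormesh(
        edges_t, grid.layer_edges, rmat, cmap="RdBu_r", vmin=-vmax, vmax=vmax
    )
    ax.invert_yaxis()
    ax.set_xlabel("day of study")
    ax.set_ylabel("depth (cm)")
    title = "net CH$_4$ production (nmol cm$^{-3}$ d$^{-1}$)"
    if ecosite:
        title = f"{ecosite}: {title}"
    ax.set_title(title)
    plt.colorbar(mesh, ax=ax)
    return ax


def plot_oxic_fraction(p_series, budget=None, ax=None):
    """Seasonal curves of the oxic-zone production share per ecosite."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for name, p, sd, color in (
        ("open water", p_series.p_op, p_series.p_op_sd, "tab:blue"),
        ("mud", p_series.p_mu, p_series.p_mu_sd, "tab:brown"),
    ):
        ax.plot(p_series.day, 100 * p, color=color, label=name)
        ax.fill_between(
            p_series.day, 100 * (p - sd), 100 * (p + sd), color=color, alpha=0.25
        )
    ax.axhline(0, color="red", linestyle="--", linewidth=1)
    if budget is not None:
        ax.axhline(
            100 * budget.f_oxic, color="k", linestyle=":",
            label=f"site-level f_oxic = {100 * budget.f_oxic:.0f}%",
        )
    ax.set_xlabel("day of study")
    ax.set_ylabel("CH$_4$ produced in oxic zone (%)")
    ax.legend(loc="best", fontsize=8)
    return ax
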