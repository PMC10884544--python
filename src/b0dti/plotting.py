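"""Figure exports for the simulation grid and the pooled analysis."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .anisotropy import SplineResult
from .pipelines import MEASURES

__all__ = ["plot_simulation_grid", "plot_pooled_measure"]


def plot_simulation_grid(grid: pd.DataFrame):
    """Heatmaps of the anisotropy coefficient B over the (TE, f) grid.

    One panel per condition x measure; cells where the isotropic
    representation was selected are hatched grey, mirroring the convention
    of showing unsupported anisotropy estimates in grey.
    """
    conditions = list(dict.fromkeys(grid["condition"]))
    fig, axes = plt.subplots(
        len(conditions), len(MEASURES),
        figsize=(3.2 * len(MEASURES), 2.6 * len(conditions)),
        squeeze=False,
    )
    te_vals = np.sort(grid["te"].unique())
    f_vals = np.sort(grid["f"].unique())
    vmax = float(np.nanmax(np.abs(grid["b_hat"])))
    for i, cond in enumerate(conditions):
        for j, m in enumerate(MEASURES):
            ax = axes[i][j]
            sub = grid[(grid.condition == cond) & (grid.measure == m)]
            B = sub.pivot_table(index="f", columns="te", values="b_hat").reindex(
                index=f_vals, columns=te_vals
            )
            iso = sub.pivot_table(
                index="f", columns="te", values="selected",
                aggfunc=lambda s: (s == "isotropic").any(),
            ).reindex(index=f_vals, columns=te_vals)
            mesh = ax.pcolormesh(
                te_vals, f_vals, B.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                shading="nearest",
            )
            masked = np.where(iso.to_numpy(dtype=bool), 1.0, np.nan)
            ax.pcolormesh(
                te_vals, f_vals, masked, cmap="Greys", vmin=0, vmax=2,
                shading="nearest", alpha=0.7,
            )
            ax.set_title(f"{cond}: {m.upper()}", fontsize=9)
            if i == len(conditions) - 1:
                ax.set_xlabel("TE (ms)")
            if j == 0:
                ax.set_ylabel("axonal fraction f")
    fig.colorbar(mesh, ax=axes, label="B (measure units)", shrink=0.8)
    return fig


def plot_pooled_measure(theta, values, spline: SplineResult, measure: str = "measure"):
    """Voxel scatter of a measure versus fibre angle with its spline curve."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(theta, values, ".", ms=2, alpha=0.25, color="tab:blue", rasterized=True)
    ax.plot(spline.grid, spline.curve, "-", color="tab:red", lw=2,
            label=f"spline (magnitude {spline.magnitude:+.3g})")
    ax.axvline(54.7356, color="crimson", ls="--", lw=1, label="magic angle")
    ax.set_xlabel(r"fibre angle $\theta$ to $B_0$ (deg)")
    ax.set_ylabel(measure)
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
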