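"""Optional figures: per-property boxplots and the hydrophobicity/EPS scatter.

Plot decoration only — nothing here feeds back into inference.  Requires
matplotlib (the ``plot`` extra).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["property_boxplots", "hydro_protein_scatter", "local_linear_smooth"]


def local_linear_smooth(x: np.ndarray, y: np.ndarray, frac: float = 0.6,
                        grid: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Tricube-weighted local-linear smoother (a lowess-style trend line)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 50)
    k = max(2, int(np.ceil(frac * x.size)))
    out = np.empty(grid.size)
    for i, g in enumerate(grid):
        d = np.abs(x - g)
        h = np.sort(d)[k - 1]
        w = np.clip(1 - (d / max(h, 1e-12)) ** 3, 0, None) ** 3
        sw = w.sum()
        xm = (w * x).sum() / sw
        ym = (w * y).sum() / sw
        sxx = (w * (x - xm) ** 2).sum()
        slope = 0.0 if sxx <= 0 else (w * (x - xm) * (y - ym)).sum() / sxx
        out[i] = ym + slope * (g - xm)
    return grid, out


def property_boxplots(table: pd.DataFrame, properties=None, path=None):
    """Side-by-side sediment/water boxplots for each property."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if properties is None:
        properties = [c for c in table.columns if c != "habitat"]
    fig, axes = plt.subplots(2, (len(properties) + 1) // 2, figsize=(3 * len(properties) / 2, 6))
    for ax, prop in zip(np.ravel(axes), properties):
        data = [table.loc[table["habitat"] == h, prop].dropna() for h in ("sediment", "water")]
        ax.boxplot(data, tick_labels=["sediment", "water"], whis=1.5)
        ax.set_title(prop, fontsize=9)
    for ax in np.ravel(axes)[len(properties):]:
        ax.axis("off")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def hydro_protein_scatter(table: pd.DataFrame, path=None, smooth_frac: float = 0.6):
    """Hydrophobicity vs EPS protein per habitat, with a smoothed trend."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(8, 4), sharex=True, sharey=True)
    for ax, hab in zip(axes, ("sediment", "water")):
        sub = table[table["habitat"] == hab][["hydrophobicity", "eps_protein"]].dropna()
        x, y = sub["hydrophobicity"].to_numpy(), sub["eps_protein"].to_numpy()
        ax.scatter(x, y, s=12, alpha=0.7)
        if x.size >= 5:
            gx, gy = local_linear_smooth(x, y, frac=smooth_frac)
            ax.plot(gx, gy, color="C3")
        ax.set_title(f"{hab} (n={x.size})")
        ax.set_xlabel("hydrophobicity")
    axes[0].set_ylabel("EPS protein (ug / 1e8 cells)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
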