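"""Static per-gene fit plots (observations, piecewise fit, breakpoint markers)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .gene_model import GeneFit
from .segreg import TimeVector, predict_segmented

__all__ = ["plot_gene"]


def plot_gene(fit: GeneFit, y, times: TimeVector, path) -> Path:
    """Scatter the observations, draw the fitted piecewise-linear curve and a
    dashed vertical marker at each estimated breakpoint; saves to ``path``."""
    path = Path(path)
    y = np.asarray(y, dtype=float)
    t = times.values
    grid = TimeVector(
        np.unique(
            np.concatenate(
                [np.linspace(times.t_min, times.t_max, 200), fit.breakpoints]
            )
        )
    )
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(t, y, s=18, color="#444444", zorder=3, label="observed")
    ax.plot(
        grid.values,
        predict_segmented(fit.model, grid),
        color="#d95f02",
        lw=2,
        label=f"fit (k={fit.k_selected}, {fit.trend_string})",
    )
    for b in fit.breakpoints:
        ax.axvline(float(b), color="#7570b3", ls="--", lw=1)
    ax.set_xlabel("time")
    ax.set_ylabel("expression")
    ax.set_title(f"{fit.gene_id}  adj R² = {fit.adj_r2:.3f}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
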