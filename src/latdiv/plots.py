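"""Optional SVG trend figures (diversity against latitude with SE ribbons)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from latdiv.mixedmodel import polynomial_design
from latdiv.selection import LadderResult


def plot_trend(y, band_latitudes, ladder: LadderResult, path,
               metric_label: str = "diversity") -> Path:
    """Scatter of band-level estimates with the selected polynomial curve.

    The ribbon is the pointwise standard error of the fixed-effect
    prediction, from the coefficient covariance of the selected fit.
    """
    y = np.asarray(y, dtype=float)
    lats = np.asarray(band_latitudes, dtype=float)
    fit = ladder.fits[ladder.selected_order]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.scatter(lats, y, s=12, alpha=0.5, color="#33658a", linewidths=0)
    grid = np.linspace(lats.min(), lats.max(), 200)
    if ladder.selected_order == 0 or ladder.scale is None:
        curve = np.full_like(grid, fit.beta[0])
        se = np.full_like(grid, fit.se_beta[0])
    else:
        zg = ladder.scale.transform(grid)
        Xg = polynomial_design(zg, ladder.selected_order)
        curve = Xg @ fit.beta
        if fit.cov_beta is not None:
            se = np.sqrt(np.einsum("ij,jk,ik->i", Xg, fit.cov_beta, Xg))
        else:
            se = np.zeros_like(curve)
    ax.plot(grid, curve, color="#f26419")
    ax.fill_between(grid, curve - se, curve + se, color="#f26419", alpha=0.25,
                    linewidth=0)
    ax.set_xlabel("latitudinal band (degrees)")
    ax.set_ylabel(metric_label)
    ax.set_title(f"selected order {ladder.selected_order}")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, format="svg")
    plt.close(fig)
    return path
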