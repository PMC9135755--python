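"""Diagnostic plots: allometric scatter with fitted lines, residual plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless by default; callers may switch backends
import matplotlib.pyplot as plt
import numpy as np


def plot_allometry(table, x, y, fit=None, ax=None, **scatter_kw):
    """Scatter of two (log) trait columns with an optional fitted line."""
    if ax is None:
        _, ax = plt.subplots()
    xs = table.column(x).to_numpy(dtype=float)
    ys = table.column(y).to_numpy(dtype=float)
    ax.scatter(xs, ys, s=18, alpha=0.7, **scatter_kw)
    if fit is not None:
        grid = np.linspace(np.nanmin(xs), np.nanmax(xs), 50)
        slope = fit.params.get(x, np.nan)
        const = fit.params.get("const", 0.0)
        ax.plot(grid, const + slope * grid, color="k", lw=1.5)
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    return ax


def plot_group_sma(table, x, y, results, ax=None):
    """Per-species scatter with the SMA line of each group."""
    if ax is None:
        _, ax = plt.subplots()
    for label, fit in results.fits.items():
        sub = table.data[table.species == label]
        xs = sub[x].to_numpy(dtype=float)
        pts = ax.scatter(xs, sub[y], s=18, label=label)
        grid = np.linspace(xs.min(), xs.max(), 20)
        ax.plot(grid, fit.elevation + fit.slope * grid,
                color=pts.get_facecolor()[0], lw=1.2)
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    ax.legend(fontsize=7)
    return ax


def plot_residual_association(fit, ax=None):
    """Second-stage residual regression: residuals of A against B."""
    if ax is None:
        _, ax = plt.subplots()
    xcol = fit.predictors[-1]
    model = getattr(fit, "model", None)
    # reconstruct second-stage points from residuals + fitted values
    yhat = None
    if model is not None and hasattr(model, "fittedvalues"):
        yhat = model.fittedvalues
    if yhat is not None:
        xs = (yhat + fit.resid - fit.params.get("const", 0.0)) \
            / fit.params[xcol]
        ax.scatter(xs, yhat + fit.resid, s=18, alpha=0.7)
        grid = np.linspace(xs.min(), xs.max(), 20)
        ax.plot(grid, fit.params.get("const", 0.0) + fit.params[xcol] * grid,
                color="k", lw=1.5)
    ax.set_xlabel(xcol)
    ax.set_ylabel(fit.response)
    return ax
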