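"""Thin matplotlib layer: survival and hazard panels with KM overlay."""

from __future__ import annotations

import numpy as np

from .survdata import KMCurve


def _step_xy(km: KMCurve):
    x = np.concatenate([[0.0], km.times])
    y = np.concatenate([[1.0], km.survival])
    return x, y


def plot_survival(models: dict, tmax: float, km: KMCurve | None = None,
                  ax=None, points=None, n_grid: int = 400):
    """Plot survival curves for a name → model mapping; returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    grid = np.linspace(0.0, tmax, n_grid)
    for name, model in models.items():
        ax.plot(grid, np.asarray(model.survival(grid)), label=name)
    if km is not None:
        x, y = _step_xy(km)
        ax.step(x, y, where="post", color="k", alpha=0.7, label="Kaplan-Meier")
        ax.step(np.concatenate([[0.0], km.times]),
                np.concatenate([[1.0], km.ci_lower]),
                where="post", color="k", alpha=0.25, lw=0.8)
        ax.step(np.concatenate([[0.0], km.times]),
                np.concatenate([[1.0], km.ci_upper]),
                where="post", color="k", alpha=0.25, lw=0.8)
    if points:
        ax.scatter([p.time for p in points], [p.survival for p in points],
                   zorder=5, marker="o", facecolors="none", edgecolors="red",
                   label="interpolated points")
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0.0, 1.02)
    ax.legend()
    return ax


def plot_hazard(models: dict, tmax: float, ax=None, n_grid: int = 400):
    """Plot hazard curves for a name → model mapping; returns the axes."""
    import matplotlib.pyplot as plt

    from .extrapolation import hazard_curve

    if ax is None:
        _, ax = plt.subplots()
    grid = np.linspace(tmax / n_grid, tmax, n_grid)
    for name, model in models.items():
        th = hazard_curve(model, grid)
        ax.plot(th[:, 0], th[:, 1], label=name)
    ax.set_xlabel("time")
    ax.set_ylabel("hazard rate")
    ax.legend()
    return ax


def plot_psa(result, ax=None):
    """Plot a PSA band (point estimate with 2.5/97.5 percentile envelope)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(result.grid, result.point_estimate, label="point estimate")
    ax.fill_between(result.grid, result.lower, result.upper, alpha=0.3,
                    label="2.5-97.5 percentile")
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0.0, 1.02)
    ax.legend()
    return ax
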