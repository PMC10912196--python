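"""Small matplotlib helpers for the standard figures.

Kept deliberately thin: growth curve with its rate curve, the per-flight
correlation series, and the confusion-matrix heatmap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import BIN_LABELS, ConfusionMatrix
from .growth import SigmoidFit

__all__ = ["plot_growth_curve", "plot_correlation_series", "plot_confusion_matrix"]


def plot_growth_curve(fit: SigmoidFit, ax=None, n_points: int = 200):
    """Fitted curve and its growth-rate curve on a twin axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = np.linspace(fit.window[0], fit.window[1], n_points)
    ax.plot(t, fit.value(t), label=f"{fit.family} fit")
    ax.set_xlabel("days after planting")
    ax.set_ylabel("trait value")
    ax2 = ax.twinx()
    ax2.plot(t, fit.rate(t), linestyle="--", color="tab:orange", label="growth rate")
    ax2.set_ylabel("growth rate (units/day)")
    ax.legend(loc="upper left")
    return ax


def plot_correlation_series(correlations: pd.DataFrame, year: str, ax=None):
    """Per-flight Pearson r vs yield, one line per trait."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for trait, g in correlations[correlations["year"] == year].groupby("trait"):
        ax.plot(g["dap"], g["r"], marker="o", label=trait)
    ax.axhline(0, color="gray", lw=0.5)
    ax.set_xlabel("days after planting")
    ax.set_ylabel("Pearson r with yield")
    ax.set_title(str(year))
    ax.legend()
    return ax


def plot_confusion_matrix(cm: ConfusionMatrix, ax=None, title: str | None = None):
    """Heatmap of the 4x4 measured-vs-estimated yield-bin counts."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    data = cm.counts.to_numpy()
    ax.imshow(data, cmap="Blues")
    ax.set_xticks(range(4), BIN_LABELS)
    ax.set_yticks(range(4), BIN_LABELS)
    ax.set_xlabel("estimated bin")
    ax.set_ylabel("measured bin")
    for i in range(4):
        for j in range(4):
            ax.text(j, i, str(data[i, j]), ha="center", va="center")
    if title:
        ax.set_title(title)
    return ax
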