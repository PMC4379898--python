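"""Optional figure helpers (requires matplotlib, ``pip install gametransfer[plot]``).

Two views cover most uses: a shaded table ("heat-map table") of any
training x test grid statistic, and the choice-probability profile along
the transformation loop with class segments shaded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _mpl():
    try:
        import matplotlib.pyplot as plt
    except ImportError as err:  # pragma: no cover
        raise ImportError(
            "plotting requires matplotlib; install the 'plot' extra"
        ) from err
    return plt


def plot_grid_heatmap(table: pd.DataFrame, title: str = "", fmt: str = "{:.2f}",
                      ax=None):
    """Shaded table of a (training x test) statistic, darker = larger."""
    plt = _mpl()
    if ax is None:
        _, ax = plt.subplots(figsize=(1.1 * len(table.columns) + 2, 0.5 * len(table) + 2))
    data = table.to_numpy(dtype=float)
    ax.imshow(data, cmap="Blues", aspect="auto")
    ax.set_xticks(range(len(table.columns)), table.columns)
    ax.set_yticks(range(len(table.index)), table.index)
    ax.set_xlabel("test set")
    ax.set_ylabel("training set")
    mid = np.nanmin(data) + 0.6 * (np.nanmax(data) - np.nanmin(data))
    for i in range(data.shape[0]):
        for j in range(data.shape[1]):
            if np.isnan(data[i, j]):
                continue
            ax.text(j, i, fmt.format(data[i, j]), ha="center", va="center",
                    color="white" if data[i, j] > mid else "black", fontsize=8)
    if title:
        ax.set_title(title)
    return ax


def plot_transform_profile(profile: pd.DataFrame, ax=None):
    """Population-mean P(action 0 | row) along the game loop, one line per
    training condition, with class segments shaded."""
    plt = _mpl()
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    one = profile[profile["training_class"] == profile["training_class"].iloc[0]]
    labels = one.sort_values("position")["game_class"].tolist()
    start = 0
    for k in range(1, len(labels) + 1):
        if k == len(labels) or labels[k] != labels[start]:
            ax.axvspan(start - 0.5, k - 0.5, alpha=0.08,
                       color=f"C{hash(labels[start]) % 10}")
            ax.text((start + k) / 2, 1.02, labels[start], ha="center", fontsize=8)
            start = k
    for cond, sub in profile.groupby("training_class"):
        sub = sub.sort_values("position")
        ax.plot(sub["position"], sub["p_action0_row"], label=cond, lw=1.2)
    ax.set_xlabel("position along the transformation loop")
    ax.set_ylabel("P(action 0 | row player)")
    ax.set_ylim(-0.02, 1.08)
    ax.legend(ncol=4, fontsize=8)
    return ax
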