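"""Figure exports: ternary lineage-score plots and metaprofile curves."""

from __future__ import annotations

import numpy as np
import pandas as pd

_SQRT3_2 = np.sqrt(3) / 2


def _ternary_xy(ternary: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Project simplex coordinates (EPI, PE, TE order) onto the plane."""
    a, b, c = (ternary.iloc[:, k].to_numpy() for k in range(3))
    return 0.5 * (2 * b + c) / (a + b + c), _SQRT3_2 * c / (a + b + c)


def ternary_plot(ternary: pd.DataFrame, labels: pd.Series, path) -> None:
    """Scatter cells on the lineage-score simplex, colored by label."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.5))
    x, y = _ternary_xy(ternary)
    for label in pd.unique(labels):
        mask = (labels == label).to_numpy()
        ax.scatter(x[mask], y[mask], s=8, label=str(label), alpha=0.7)
    corners = np.array([[0, 0], [1, 0], [0.5, _SQRT3_2], [0, 0]])
    ax.plot(corners[:, 0], corners[:, 1], color="black", lw=0.8)
    for (cx, cy), name in zip(corners[:3], ternary.columns):
        ax.annotate(name, (cx, cy), ha="center", va="bottom")
    ax.set_axis_off()
    ax.legend(frameon=False, fontsize=8)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def metaprofile_plot(
    per_group: pd.DataFrame, flank_bins: int, body_bins: int, path
) -> None:
    """Group-mean methylation curves over a scaled feature and its flanks."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    for group, row in per_group.iterrows():
        ax.plot(row.index, row.to_numpy(), label=str(group))
    for edge in (flank_bins, flank_bins + body_bins):
        ax.axvline(edge, color="grey", lw=0.6, ls="--")
    ax.set_xlabel("position (flank | scaled body | flank)")
    ax.set_ylabel("methylation level")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False, fontsize=8)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
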