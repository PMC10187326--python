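"""Plots for validation reports."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers may switch backends first
import matplotlib.pyplot as plt

from .metrics import BlandAltman


def plot_bland_altman(ba: BlandAltman, ax=None, title: str | None = None):
    """Bland-Altman scatter with the mean difference and 95% limits of agreement."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ba.means, ba.diffs, s=18, alpha=0.7, edgecolor="none")
    ax.axhline(ba.mean_diff, color="k", lw=1)
    for y in (ba.lower, ba.upper):
        ax.axhline(y, color="k", lw=1, ls=":")
    ax.set_xlabel("Mean of ground truth and predicted steps")
    ax.set_ylabel("Predicted - ground truth steps")
    if title:
        ax.set_title(title)
    return ax
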