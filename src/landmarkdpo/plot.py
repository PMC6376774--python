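"""Stacked probability plot for dynamic predictions over landmark time."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_stacked_probabilities"]


def plot_stacked_probabilities(predictions, ax=None, colors=None):
    """Stacked-area plot of per-category probabilities against landmark time.

    ``predictions`` is a tidy frame with columns ``s``, ``category`` and
    ``prob`` (as written by the CLI ``fit`` command); categories are stacked
    in their order of first appearance.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    cats = list(dict.fromkeys(predictions["category"]))
    s_vals = np.sort(predictions["s"].unique())
    stacks = np.vstack(
        [
            predictions[predictions["category"] == c].set_index("s").loc[s_vals, "prob"].to_numpy()
            for c in cats
        ]
    )
    ax.stackplot(s_vals, stacks, labels=cats, colors=colors)
    ax.set_xlabel("landmark time s")
    ax.set_ylabel("predicted probability")
    ax.set_ylim(0, 1)
    ax.legend(loc="upper right", fontsize="small")
    return ax
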