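"""Minimal matplotlib views of fitted results.

Conventions follow the field's figures: stimulated limbs in magenta,
controls in dark orange, arrows linking the left and right limb of each
individual in PC score space, and a jitter plot for percent asymmetry.
"""

from __future__ import annotations

import numpy as np

STIM_COLOR = "magenta"
CTRL_COLOR = "darkorange"


def plot_scores(channel, labels, specimen_labels=None, components=(0, 1), ax=None):
    """Scatter of two PC scores coloured by group, with antimere arrows."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    s = channel.pca.scores
    i, j = components
    lab = np.asarray(labels, dtype=bool)
    ax.scatter(s[~lab, i], s[~lab, j], c=CTRL_COLOR, label="control")
    ax.scatter(s[lab, i], s[lab, j], c=STIM_COLOR, label="stimulated")
    if specimen_labels is not None:
        pairs = {}
        for idx, name in enumerate(specimen_labels):
            ind, _, side = name.rpartition("_")
            pairs.setdefault(ind, {})[side] = idx
        for sides in pairs.values():
            if {"left", "right"} <= sides.keys():
                a, b = sides["left"], sides["right"]
                ax.annotate("", xy=(s[b, i], s[b, j]), xytext=(s[a, i], s[a, j]),
                            arrowprops={"arrowstyle": "->", "lw": 0.8,
                                        "color": "0.5"})
    vp = channel.pca.variance_percent
    ax.set_xlabel(f"PC{i + 1} ({vp[i]:.1f}%)")
    ax.set_ylabel(f"PC{j + 1} ({vp[j]:.1f}%)")
    ax.legend(frameon=False)
    return ax


def plot_percent_asymmetry(asymmetry_table, structure=None, ax=None, rng_seed=0):
    """Jitter plot of left/right percent asymmetry by group."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    df = asymmetry_table
    if structure is not None:
        df = df[df["structure"] == structure]
    rng = np.random.default_rng(rng_seed)
    for x0, (flag, color, name) in enumerate(
            [(True, STIM_COLOR, "stimulated"), (False, CTRL_COLOR, "control")]):
        sub = df[df["stimulated_individual"] == flag]
        x = x0 + rng.uniform(-0.12, 0.12, size=len(sub))
        ax.scatter(x, sub["percent_asymmetry"], c=color, label=name)
    ax.set_xticks([0, 1], ["stimulated", "control"])
    ax.set_ylabel("percent asymmetry (left vs right)")
    ax.axhline(0.0, color="0.8", lw=0.8)
    return ax
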