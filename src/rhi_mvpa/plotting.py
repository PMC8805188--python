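"""Basic figures: group AUC time courses and forward-model topographies."""

from __future__ import annotations

import numpy as np

from .group_stats import ClusterResult


def plot_group_auc(curves, cluster_result: ClusterResult | None = None, ax=None):
    """Group-mean AUC with SEM band and significant-cluster underlines."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    mat = np.stack([c.auc for c in curves])
    t = curves[0].bin_centers
    mean, sem = mat.mean(0), mat.std(0, ddof=1) / np.sqrt(mat.shape[0])
    ax.fill_between(t, mean - sem, mean + sem, alpha=0.3)
    ax.plot(t, mean, lw=2)
    ax.axhline(0.5, color="k", ls=":", lw=1)
    if cluster_result:
        y0 = ax.get_ylim()[0]
        for c in cluster_result.significant:
            ax.plot([c.start_s, c.end_s], [y0, y0], lw=4, color="C3")
    ax.set_xlabel("time relative to stimulus onset (s)")
    ax.set_ylabel("AUC")
    return ax


def plot_topography(values, ax=None):
    """Channel-value stem plot (no montage is attached to synthetic data)."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    ax.stem(np.asarray(values))
    ax.set_xlabel("channel")
    ax.set_ylabel("forward-model correlation")
    ax.set_ylim(-1, 1)
    return ax
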