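"""Plot helpers for cohort transcription profiles and onset-sorted heatmaps."""

from __future__ import annotations

import numpy as np

from .transcription import TraceSet, cohort_profile, heatmap_matrix


def plot_cohort_profile(ts: TraceSet, ax=None):
    """Mean ± s.e.m. normalized transcription of active nuclei over time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    prof = cohort_profile(ts)
    ax.plot(prof["t_min"], prof["mean"], color="C2")
    ax.fill_between(
        prof["t_min"],
        prof["mean"] - prof["sem"],
        prof["mean"] + prof["sem"],
        alpha=0.3,
        color="C2",
    )
    ax.set_xlabel("time into nc14 (min)")
    ax.set_ylabel("normalized fluorescence (AU)")
    return ax


def plot_heatmap(ts: TraceSet, ax=None):
    """Per-nucleus normalized traces, rows sorted by transcription onset."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mat = heatmap_matrix(ts)
    extent = [ts.t_min[0], ts.t_min[-1], mat.shape[0], 0]
    ax.imshow(np.nan_to_num(mat.to_numpy()), aspect="auto", extent=extent, cmap="viridis")
    ax.set_xlabel("time into nc14 (min)")
    ax.set_ylabel("nucleus (sorted by onset)")
    return ax
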