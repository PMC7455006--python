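"""Minimal plotting helpers for trajectory DataFrames."""

from __future__ import annotations

import pandas as pd


def plot_trajectory(stats: pd.DataFrame, axes=None):
    """Plot population counts and class means of a and l over time.

    Returns the two matplotlib axes (populations; parameter means).
    """
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(2, 1, sharex=True, figsize=(8, 6))
    ax0, ax1 = axes
    ax0.plot(stats["step"], stats["n_replicases"], label="replicases")
    ax0.plot(stats["step"], stats["n_parasites"], label="parasites")
    ax0.plot(stats["step"], stats["n_complexes"], label="complexes")
    ax0.set_ylabel("count")
    ax0.legend()
    ax1.plot(
        stats["step"], stats["mean_a_replicases"], label="mean a (replicases)"
    )
    ax1.plot(
        stats["step"], stats["mean_l_replicases"], label="mean l (replicases)"
    )
    ax1.plot(
        stats["step"], stats["mean_l_parasites"], label="mean l (parasites)"
    )
    ax1.set_xlabel("step")
    ax1.set_ylabel("population mean")
    ax1.set_ylim(0, 1)
    ax1.legend()
    return ax0, ax1
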