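"""Plots: action rasters of simulated/observed games and window trajectories."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers can switch backends first
import matplotlib.pyplot as plt
import numpy as np

from .game import GameRecord
from .windows import DiffSeries

__all__ = ["plot_record", "plot_window_trajectories"]


def plot_record(record: GameRecord, ax=None):
    """Raster of both players' actions over trials (dark = rush, light = avoid)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(2.0, 6.0))
    ax.imshow(
        record.actions,
        aspect="auto",
        cmap="Greys",
        vmin=0,
        vmax=1,
        interpolation="none",
    )
    ax.set_xticks([0, 1], ["P1", "P2"])
    ax.set_ylabel("trial")
    ax.set_title(record.pair_id)
    return ax


def plot_window_trajectories(diffs: DiffSeries, ax=None):
    """Per-window absolute parameter differences with -logL on a twin axis."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7.0, 4.0))
    x = np.arange(1, diffs.n_windows + 1)
    for name in diffs.diffs.columns:
        ax.plot(x, diffs.diffs[name], label=name)
    ax.set_xlabel("window start (trial)")
    ax.set_ylabel("|parameter difference|")
    ax.legend(loc="upper left", fontsize="small")
    twin = ax.twinx()
    twin.plot(x, diffs.fit_quality, "k--", label="-logL")
    twin.set_ylabel("-logL (dashed)")
    return ax
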