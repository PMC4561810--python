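"""Sliding-window refitting and the rule-convergence analysis.

Players can change their decision rule during a session.  Refitting the model
in overlapping 20-trial windows (stride 1, so a 100-trial game yields 81
windows) traces each player's parameters over time.  If the two players of a
dyad gradually converge on a shared rule, the absolute between-player
difference of each parameter shrinks over windows -- detected by a two-sample
t-test comparing the first half of the window series against the second --
and the model fits better as distinct patterns emerge, giving a positive
Pearson correlation between the parameter-difference trajectory and the
per-window fit-quality trajectory (``-logL``, which is an affine function of
the window BIC at fixed window size, so the correlation is identical either
way).

The window-level t-tests and correlations ignore the autocorrelation induced
by overlapping windows; their p-values are descriptive, not inferential.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .game import DEFAULT_PAYOFFS, GameRecord, PayoffMatrix
from .fitting import FitResult, OptimizerConfig, fit_pair
from .models import PARAM_CLASSES

__all__ = [
    "WindowSeries",
    "DiffSeries",
    "sliding_fit",
    "diff_series",
    "pool_diff_series",
    "halves_ttest",
    "diff_fit_correlation",
]


@dataclass(frozen=True)
class WindowSeries:
    """Per-window fits of one dyad: window t covers trials ``start .. start+w-1``."""

    model: str
    pair_id: str
    window_size: int
    starts: np.ndarray  # 1-based first trial of each window
    fits: Tuple[FitResult, ...]

    @property
    def n_windows(self) -> int:
        return len(self.fits)

    def param_frame(self) -> pd.DataFrame:
        """Long-format table: (window_start, player, parameter, value)."""
        rows = []
        names = PARAM_CLASSES[self.model].names
        for start, fit in zip(self.starts, self.fits):
            for player in (0, 1):
                for name in names:
                    rows.append(
                        {
                            "pair_id": self.pair_id,
                            "window_start": int(start),
                            "player": player + 1,
                            "parameter": name,
                            "value": getattr(fit.params[player], name),
                        }
                    )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class DiffSeries:
    """Per-window between-player parameter differences and fit quality.

    ``diffs[name]`` is the absolute difference of parameter ``name`` between
    the two players in each window; ``fit_quality`` is the per-window ``-logL``.
    """

    model: str
    window_size: int
    diffs: pd.DataFrame
    fit_quality: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.diffs)


def sliding_fit(
    model: str,
    record: GameRecord,
    window_size: int = 20,
    matrix: PayoffMatrix = DEFAULT_PAYOFFS,
    config: OptimizerConfig = OptimizerConfig(n_starts=5),
    warm_start: bool = True,
) -> WindowSeries:
    """Refit both players in every stride-1 window of ``window_size`` trials.

    Each window is treated as a fresh game (states restart from zero at the
    window's first trial) and its BIC uses ``n = window_size``.  With
    ``warm_start`` the previous window's solution is added to the random
    starts, which speeds the search and smooths the trajectories.
    """
    n = record.n_trials
    if n < window_size:
        raise ValueError(f"record has {n} trials, shorter than window {window_size}")
    if window_size < 2:
        raise ValueError("window_size must be >= 2")
    starts = np.arange(1, n - window_size + 2)
    fits: List[FitResult] = []
    prev: Optional[Tuple[Sequence, Sequence]] = None
    for s in starts:
        sub = GameRecord(
            record.pair_id,
            record.actions[s - 1 : s - 1 + window_size],
            record.payoffs[s - 1 : s - 1 + window_size],
        )
        fit = fit_pair(model, sub, matrix, config, extra_starts=prev)
        fits.append(fit)
        if warm_start:
            prev = ([fit.params[0].to_array()], [fit.params[1].to_array()])
    return WindowSeries(model, record.pair_id, window_size, starts, tuple(fits))


def diff_series(series: WindowSeries) -> DiffSeries:
    """Absolute between-player parameter differences and ``-logL`` per window."""
    names = PARAM_CLASSES[series.model].names
    rows = {
        name: [
            abs(getattr(f.params[0], name) - getattr(f.params[1], name))
            for f in series.fits
        ]
        for name in names
    }
    quality = np.array([-f.loglik for f in series.fits])
    return DiffSeries(series.model, series.window_size, pd.DataFrame(rows), quality)


def pool_diff_series(series_list: Sequence[DiffSeries], mode: str = "mean") -> DiffSeries:
    """Aggregate difference series across dyads of one pattern.

    ``mode="mean"`` averages the difference and fit-quality trajectories
    window-by-window; ``mode="concat"`` stacks the per-dyad series end to end
    (per-dyad testing is then done by calling the tests on each member).
    """
    if not series_list:
        raise ValueError("no series to pool")
    if mode == "mean":
        if len({s.n_windows for s in series_list}) != 1:
            raise ValueError("mean pooling requires equal window counts")
        diffs = sum(s.diffs for s in series_list) / len(series_list)
        quality = np.mean([s.fit_quality for s in series_list], axis=0)
    elif mode == "concat":
        diffs = pd.concat([s.diffs for s in series_list], ignore_index=True)
        quality = np.concatenate([s.fit_quality for s in series_list])
    else:
        raise ValueError(f"unknown pooling mode {mode!r}")
    first = series_list[0]
    return DiffSeries(first.model, first.window_size, diffs, quality)


def _halves(n: int) -> Tuple[slice, slice]:
    # first h vs last h windows; with an odd count the middle window is
    # dropped so both halves have the same size (81 windows -> 40 vs 40)
    h = n // 2
    return slice(0, h), slice(n - h, n)


def halves_ttest(series: DiffSeries) -> pd.DataFrame:
    """Two-sample t-test of each parameter difference, first vs second half.

    Negative ``t`` means the between-player differences shrank (the players'
    rules converged).  Halves with zero pooled variance make the test
    undefined; such rows are flagged ``defined = False``.
    """
    n = series.n_windows
    if n < 4:
        raise ValueError("need at least 4 windows for a half-split test")
    first, second = _halves(n)
    rows = []
    for name in series.diffs.columns:
        a = series.diffs[name].to_numpy()[second]
        b = series.diffs[name].to_numpy()[first]
        if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
            if np.mean(a) == np.mean(b):
                rows.append({"parameter": name, "t": 0.0, "p": 1.0, "defined": True})
            else:
                rows.append({"parameter": name, "t": np.nan, "p": np.nan, "defined": False})
            continue
        t, p = stats.ttest_ind(a, b)
        rows.append({"parameter": name, "t": float(t), "p": float(p), "defined": True})
    return pd.DataFrame(rows).set_index("parameter")


def diff_fit_correlation(series: DiffSeries) -> pd.DataFrame:
    """Pearson correlation of each parameter difference with per-window ``-logL``.

    Positive ``r`` means the model fits better (lower ``-logL``) in windows
    where the players' parameters are closer.  Zero-variance inputs make the
    correlation undefined and are flagged ``defined = False``.
    """
    if series.n_windows < 3:
        raise ValueError("need at least 3 windows for a correlation")
    q = series.fit_quality
    rows = []
    for name in series.diffs.columns:
        d = series.diffs[name].to_numpy()
        if np.ptp(d) == 0.0 or np.ptp(q) == 0.0:
            rows.append({"parameter": name, "r": np.nan, "p": np.nan, "defined": False})
            continue
        r, p = stats.pearsonr(d, q)
        rows.append({"parameter": name, "r": float(r), "p": float(p), "defined": True})
    return pd.DataFrame(rows).set_index("parameter")
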