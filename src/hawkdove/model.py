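"""Model/Results interface over the chicken-game utility models.

Usage follows the fit-and-inspect idiom of statistical modelling packages::

    import hawkdove as hd

    rec = hd.SelfConceptModel.simulate(p1, p2, n_trials=100, seed=1)
    res = hd.SelfConceptModel(rec).fit(seed=0)
    print(res.summary())
    win = hd.SelfConceptModel(rec).fit_windows(window_size=20)
    win.halves_ttest()

A model instance binds one dyad's :class:`~hawkdove.game.GameRecord` to one
of the three utility models; ``fit`` returns a results object carrying the
per-player estimates, log-likelihood, BIC and diagnostics, and
``fit_windows`` runs the sliding-window non-stationary analysis.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .game import (
    DEFAULT_PAYOFFS,
    GameRecord,
    PatternCounts,
    PayoffMatrix,
    REFERENCE_THRESHOLDS,
    Thresholds,
    classify,
    count_patterns,
)
from .fitting import FitResult, OptimizerConfig, baseline_bic, fit_pair
from .models import (
    DEFAULT_UPDATE_RULE,
    ModelParams,
    PARAM_CLASSES,
    params_from_array,
    sequence_loglik,
)
from .simulate import SimConfig, simulate_pair
from .windows import (
    DiffSeries,
    WindowSeries,
    diff_fit_correlation,
    diff_series,
    halves_ttest,
    sliding_fit,
)

__all__ = [
    "ChickenGameModel",
    "FehrSchmidtModel",
    "CoxReciprocityModel",
    "SelfConceptModel",
    "ChickenGameResults",
    "SlidingWindowResults",
    "model_class",
]


class ChickenGameModel:
    """Base class binding one dyad's record to a trial-level utility model."""

    model_name: str = ""

    def __init__(
        self,
        record: GameRecord,
        matrix: PayoffMatrix = DEFAULT_PAYOFFS,
        update_rule: str = DEFAULT_UPDATE_RULE,
    ):
        if not self.model_name:
            raise TypeError("instantiate a concrete model subclass")
        self.record = record
        self.matrix = matrix
        self.update_rule = update_rule

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        pair_id: Optional[str] = None,
        matrix: PayoffMatrix = DEFAULT_PAYOFFS,
    ) -> "ChickenGameModel":
        """Build from a game-record table; ``pair_id`` selects one dyad if
        the table contains several."""
        from .io import frame_to_records

        records = frame_to_records(df, matrix=matrix)
        if pair_id is not None:
            records = [r for r in records if r.pair_id == str(pair_id)]
        if len(records) != 1:
            raise ValueError(
                f"expected exactly one dyad, found {len(records)}; pass pair_id"
            )
        return cls(records[0], matrix=matrix)

    @classmethod
    def from_csv(
        cls,
        path,
        pair_id: Optional[str] = None,
        matrix: PayoffMatrix = DEFAULT_PAYOFFS,
    ) -> "ChickenGameModel":
        import pandas as pd

        return cls.from_dataframe(pd.read_csv(path), pair_id=pair_id, matrix=matrix)

    # -- core --------------------------------------------------------------
    def loglike(self, params_1, params_2) -> float:
        """Joint log-likelihood of the observed record at given parameters."""
        p1 = self._coerce(params_1)
        p2 = self._coerce(params_2)
        return sequence_loglik(
            self.model_name, p1, p2, self.record, self.matrix,
            update_rule=self.update_rule,
        )

    def fit(
        self, n_starts: int = 20, seed: int = 0, config: Optional[OptimizerConfig] = None
    ) -> "ChickenGameResults":
        """Multi-start bounded maximum-likelihood fit of both players."""
        cfg = config or OptimizerConfig(
            n_starts=n_starts, seed=seed, update_rule=self.update_rule
        )
        return ChickenGameResults(self, fit_pair(self.model_name, self.record, self.matrix, cfg))

    def fit_windows(
        self,
        window_size: int = 20,
        n_starts: int = 5,
        seed: int = 0,
        config: Optional[OptimizerConfig] = None,
        warm_start: bool = True,
    ) -> "SlidingWindowResults":
        """Sliding-window refit (stride 1) for the non-stationary analysis."""
        cfg = config or OptimizerConfig(
            n_starts=n_starts, seed=seed, update_rule=self.update_rule
        )
        series = sliding_fit(
            self.model_name, self.record, window_size, self.matrix, cfg, warm_start
        )
        return SlidingWindowResults(self, series)

    # -- behavioral patterns ----------------------------------------------
    def pattern_counts(self) -> PatternCounts:
        return count_patterns(self.record)

    def classify(self, thresholds: Thresholds = REFERENCE_THRESHOLDS) -> str:
        return classify(self.pattern_counts(), thresholds)

    # -- simulation --------------------------------------------------------
    @classmethod
    def simulate(
        cls,
        params_1,
        params_2,
        n_trials: int = 100,
        matrix: PayoffMatrix = DEFAULT_PAYOFFS,
        seed: Optional[int] = None,
        pair_id: str = "sim",
        update_rule: str = DEFAULT_UPDATE_RULE,
    ) -> GameRecord:
        """Simulate one dyad of agents of this model type."""
        p1 = cls._coerce_cls(params_1)
        p2 = cls._coerce_cls(params_2)
        config = SimConfig(
            model=cls.model_name,
            params_1=p1,
            params_2=p2,
            matrix=matrix,
            n_trials=n_trials,
            seed=seed,
            update_rule=update_rule,
        )
        return simulate_pair(config, pair_id=pair_id)

    # -- helpers -----------------------------------------------------------
    @classmethod
    def _coerce_cls(cls, params) -> ModelParams:
        if isinstance(params, PARAM_CLASSES[cls.model_name]) and params.model == cls.model_name:
            return params
        return params_from_array(cls.model_name, np.asarray(params, dtype=float))

    def _coerce(self, params) -> ModelParams:
        return self._coerce_cls(params)


class FehrSchmidtModel(ChickenGameModel):
    """Inequity-aversion model: utility penalizes payoff gaps (weights alpha, beta)."""

    model_name = "fs"


class CoxReciprocityModel(ChickenGameModel):
    """Reciprocity model: an emotional state weights the other's payoff in a CES utility."""

    model_name = "cox"


class SelfConceptModel(ChickenGameModel):
    """Self-concept model: reciprocity from comparing own and other's accumulated kindness."""

    model_name = "sc"


_MODEL_CLASSES = {
    "fs": FehrSchmidtModel,
    "cox": CoxReciprocityModel,
    "sc": SelfConceptModel,
}


def model_class(name: str):
    """The model class registered under the short name ``fs``, ``cox`` or ``sc``."""
    try:
        return _MODEL_CLASSES[name]
    except KeyError:
        raise ValueError(f"unknown model {name!r}; expected one of {sorted(_MODEL_CLASSES)}")


class ChickenGameResults:
    """Fitted-dyad results: per-player estimates, log-likelihood, BIC, diagnostics."""

    def __init__(self, model: ChickenGameModel, fit_result: FitResult):
        self.model = model
        self.fit_result = fit_result

    @property
    def params_1(self) -> ModelParams:
        return self.fit_result.params[0]

    @property
    def params_2(self) -> ModelParams:
        return self.fit_result.params[1]

    @property
    def llf(self) -> float:
        return self.fit_result.loglik

    @property
    def bic(self) -> float:
        return self.fit_result.bic

    @property
    def k(self) -> int:
        return self.fit_result.k

    @property
    def baseline_bic(self) -> float:
        return baseline_bic(self.fit_result.n_trials)

    @property
    def converged(self) -> bool:
        return self.fit_result.converged

    def params_frame(self) -> pd.DataFrame:
        names = PARAM_CLASSES[self.fit_result.model].names
        return pd.DataFrame(
            {
                "player_1": [getattr(self.params_1, n) for n in names],
                "player_2": [getattr(self.params_2, n) for n in names],
            },
            index=list(names),
        )

    def summary(self) -> str:
        fr = self.fit_result
        lines = [
            "Iterated chicken game maximum-likelihood fit",
            "=" * 52,
            f"model:        {fr.model}",
            f"pair:         {fr.pair_id}",
            f"n trials:     {fr.n_trials}",
            f"logL:         {fr.loglik:.4f}",
            f"k:            {fr.k}",
            f"BIC:          {fr.bic:.4f}",
            f"baseline BIC: {self.baseline_bic:.4f}",
            f"converged:    {fr.converged}",
            "-" * 52,
            self.params_frame().round(4).to_string(),
        ]
        flags = [pf.at_bounds for pf in fr.player_fits]
        if any(flags):
            who = ", ".join(str(i + 1) for i, f in enumerate(flags) if f)
            lines.append(f"note: player(s) {who} estimated at a parameter bound")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<ChickenGameResults model={self.fit_result.model} "
            f"pair={self.fit_result.pair_id} bic={self.bic:.2f}>"
        )


class SlidingWindowResults:
    """Non-stationary analysis results over overlapping trial windows."""

    def __init__(self, model: ChickenGameModel, series: WindowSeries):
        self.model = model
        self.series = series
        self._diffs: Optional[DiffSeries] = None

    @property
    def n_windows(self) -> int:
        return self.series.n_windows

    @property
    def diffs(self) -> DiffSeries:
        if self._diffs is None:
            self._diffs = diff_series(self.series)
        return self._diffs

    def param_frame(self) -> pd.DataFrame:
        return self.series.param_frame()

    def halves_ttest(self) -> pd.DataFrame:
        """First-half vs second-half t-test of the parameter differences."""
        return halves_ttest(self.diffs)

    def correlations(self) -> pd.DataFrame:
        """Pearson correlation of parameter differences with per-window -logL."""
        return diff_fit_correlation(self.diffs)

    def plot(self, ax=None):
        """Parameter-difference trajectories with the -logL curve overlaid."""
        from .plot import plot_window_trajectories

        return plot_window_trajectories(self.diffs, ax=ax)
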