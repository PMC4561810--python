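"""Maximum-likelihood estimation, BIC scoring, and cross-dyad model comparison.

Because each player's sequence likelihood depends only on that player's own
parameters given the observed joint history, the two players of a dyad are
optimized separately and their log-likelihoods summed.  Optimization is
bounded L-BFGS with multiple random starts (drawn uniformly over the
parameter bounds), which is far more robust on this likelihood surface than a
single-start search; the best start wins, ties broken first-found.

Model fit is scored by the Bayesian information criterion
``BIC = -2 logL + k ln(n_trials)`` with ``k`` counting both players' free
parameters (4 for ``fs``, 8 for ``cox``/``sc``), and compared against the
chance-level baseline that predicts every action at probability one half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .game import DEFAULT_PAYOFFS, GameRecord, PayoffMatrix
from .models import (
    DEFAULT_UPDATE_RULE,
    FS_ALPHA_MAX,
    _MODEL_IDS,
    _loglik_kernel,
    _player_arrays,
    _rule_id,
    ModelParams,
    params_from_array,
)
from .simulate import sample_uniform_params

__all__ = [
    "OptimizerConfig",
    "PlayerFit",
    "FitResult",
    "fit_player",
    "fit_pair",
    "baseline_bic",
    "compare_models",
    "ModelComparison",
]

#: Number of free parameters per dyad (both players).
K_PER_PAIR = {"fs": 4, "cox": 8, "sc": 8}

_EPS = 1e-9
_BOUNDS = {
    # fs is optimized as (alpha, s) with beta = s * min(alpha, 1 - eps), which
    # keeps every iterate inside the joint constraint beta <= alpha, beta < 1.
    "fs": [(0.0, FS_ALPHA_MAX), (0.0, 1.0)],
    "cox": [(1e-6, 1.0), (-1.0, 1.0), (0.0, 1.0), (0.0, 1.0)],
    "sc": [(1e-6, 1.0), (-1.0, 1.0), (0.0, 1.0), (0.0, 1.0)],
}


@dataclass(frozen=True)
class OptimizerConfig:
    """Multi-start bounded optimizer settings.

    ``update_rule`` selects the cox/sc state-update variant the likelihood
    replays (see :mod:`hawkdove.models`); it must match the rule the data
    were generated or modelled under.
    """

    n_starts: int = 20
    seed: int = 0
    maxiter: int = 500
    ftol: float = 1e-9
    update_rule: str = DEFAULT_UPDATE_RULE


def _to_opt_space(model: str, x: np.ndarray) -> np.ndarray:
    if model != "fs":
        return np.asarray(x, dtype=float)
    alpha, beta = x
    cap = min(alpha, 1.0 - _EPS)
    s = beta / cap if cap > 0 else 0.0
    return np.array([alpha, min(max(s, 0.0), 1.0)])


def _from_opt_space(model: str, x: np.ndarray) -> np.ndarray:
    if model != "fs":
        return np.asarray(x, dtype=float)
    alpha, s = x
    return np.array([alpha, s * min(alpha, 1.0 - _EPS)])


@dataclass(frozen=True)
class PlayerFit:
    """One player's fitted parameters and diagnostics."""

    params: ModelParams
    loglik: float
    converged: bool
    at_bounds: bool
    n_starts: int
    start_logliks: Tuple[float, ...]


def fit_player(
    model: str,
    record: GameRecord,
    player: int,
    matrix: PayoffMatrix = DEFAULT_PAYOFFS,
    config: OptimizerConfig = OptimizerConfig(),
    extra_starts: Optional[Sequence[np.ndarray]] = None,
) -> PlayerFit:
    """Maximize one player's sequence log-likelihood over its parameter bounds.

    ``extra_starts`` (natural-space parameter vectors, e.g. a neighbouring
    window's solution) are tried in addition to the random starts.
    """
    arrays = _player_arrays(record, matrix, player)
    model_id = _MODEL_IDS[model]
    rule_id = _rule_id(config.update_rule)

    def negll(x: np.ndarray) -> float:
        p = _from_opt_space(model, x)
        return -float(_loglik_kernel(model_id, rule_id, p, *arrays).sum())

    rng = np.random.default_rng(config.seed)
    raw = sample_uniform_params(model, rng, size=config.n_starts)
    starts = [_to_opt_space(model, raw[i]) for i in range(raw.shape[0])]
    starts += [_to_opt_space(model, np.asarray(x)) for x in (extra_starts or [])]

    bounds = _BOUNDS[model]
    best = None
    start_lls: List[float] = []
    for x0 in starts:
        start_lls.append(-negll(np.asarray(x0, dtype=float)))
        res = optimize.minimize(
            negll,
            np.asarray(x0, dtype=float),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": config.maxiter, "ftol": config.ftol},
        )
        if best is None or res.fun < best.fun - 1e-12:  # ties: first-found wins
            best = res
    natural = _from_opt_space(model, best.x)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    at_bounds = bool(np.any(np.isclose(best.x, lo)) or np.any(np.isclose(best.x, hi)))
    return PlayerFit(
        params=params_from_array(model, natural),
        loglik=-float(best.fun),
        converged=bool(best.success),
        at_bounds=at_bounds,
        n_starts=len(starts),
        start_logliks=tuple(start_lls),
    )


@dataclass(frozen=True)
class FitResult:
    """Joint fit of one dyad under one model.

    ``bic`` always satisfies ``-2 * loglik + k * ln(n_trials)``.
    """

    model: str
    pair_id: str
    player_fits: Tuple[PlayerFit, PlayerFit]
    n_trials: int
    seed: int

    @property
    def params(self) -> Tuple[ModelParams, ModelParams]:
        return (self.player_fits[0].params, self.player_fits[1].params)

    @property
    def loglik(self) -> float:
        return self.player_fits[0].loglik + self.player_fits[1].loglik

    @property
    def k(self) -> int:
        return K_PER_PAIR[self.model]

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.k * math.log(self.n_trials)

    @property
    def converged(self) -> bool:
        return all(pf.converged for pf in self.player_fits)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "pair_id": self.pair_id,
            "n_trials": self.n_trials,
            "loglik": self.loglik,
            "k": self.k,
            "bic": self.bic,
            "seed": self.seed,
            "players": [
                {
                    "params": {n: getattr(pf.params, n) for n in pf.params.names},
                    "loglik": pf.loglik,
                    "converged": pf.converged,
                    "at_bounds": pf.at_bounds,
                    "n_starts": pf.n_starts,
                }
                for pf in self.player_fits
            ],
        }


def fit_pair(
    model: str,
    record: GameRecord,
    matrix: PayoffMatrix = DEFAULT_PAYOFFS,
    config: OptimizerConfig = OptimizerConfig(),
    extra_starts: Optional[Tuple[Sequence, Sequence]] = None,
) -> FitResult:
    """Fit both players of one dyad by multi-start bounded maximum likelihood."""
    if record.n_trials < 2:
        raise ValueError("fitting requires a record with at least 2 trials")
    fits = tuple(
        fit_player(
            model,
            record,
            player,
            matrix,
            config,
            extra_starts=None if extra_starts is None else extra_starts[player],
        )
        for player in (0, 1)
    )
    return FitResult(model, record.pair_id, fits, record.n_trials, config.seed)


def baseline_bic(n_trials: int, n_players: int = 2) -> float:
    """BIC of the zero-parameter chance predictor (every action at p = 0.5).

    ``-2 * n_players * n_trials * ln(0.5)``; 277.26 for a 100-trial dyad.
    """
    if n_trials < 1 or n_players < 1:
        raise ValueError("n_trials and n_players must be positive")
    return -2.0 * n_players * n_trials * math.log(0.5)


def _paired_t(a: np.ndarray, b: np.ndarray) -> Tuple[float, float]:
    """Paired t-test robust to the all-differences-zero degenerate case."""
    diffs = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if np.allclose(diffs, 0.0):
        return 0.0, 1.0
    t, p = stats.ttest_1samp(diffs, 0.0)
    return float(t), float(p)


@dataclass(frozen=True)
class ModelComparison:
    """Comparison tables across dyads grouped by behavioral pattern.

    ``summary`` has one row per (group, model) with mean/SD BIC and the paired
    t-test against the chance baseline; ``pairwise`` holds paired t-tests
    between models within each group.  Groups with a single dyad get
    descriptive rows only (tests reported as NaN).
    """

    summary: pd.DataFrame
    pairwise: pd.DataFrame
    baseline: float


def compare_models(
    results: Dict[str, Dict[str, FitResult]],
    labels: Optional[Dict[str, str]] = None,
) -> ModelComparison:
    """Build BIC comparison tables from per-dyad fits.

    Parameters
    ----------
    results
        ``{pair_id: {model: FitResult}}``; every dyad must be fitted under the
        same set of models and have the same trial count.
    labels
        Optional ``{pair_id: pattern}``; when given, per-pattern groups are
        reported in addition to the overall group.
    """
    if not results:
        raise ValueError("no fit results to compare")
    pair_ids = sorted(results)
    model_names = sorted(results[pair_ids[0]])
    n_trials = results[pair_ids[0]][model_names[0]].n_trials
    base = baseline_bic(n_trials)

    bic = pd.DataFrame(
        {m: [results[p][m].bic for p in pair_ids] for m in model_names},
        index=pair_ids,
    )
    groups: Dict[str, List[str]] = {"overall": pair_ids}
    if labels is not None:
        for p in pair_ids:
            groups.setdefault(labels[p], []).append(p)

    summary_rows = []
    pairwise_rows = []
    for gname, members in groups.items():
        sub = bic.loc[members]
        n = len(members)
        for m in model_names:
            vals = sub[m].to_numpy()
            if n >= 2:
                t, p = _paired_t(vals, np.full(n, base))
            else:
                t, p = (np.nan, np.nan)
            summary_rows.append(
                {
                    "group": gname,
                    "model": m,
                    "n_pairs": n,
                    "bic_mean": float(vals.mean()),
                    "bic_sd": float(vals.std(ddof=1)) if n >= 2 else np.nan,
                    "t_vs_baseline": t,
                    "p_vs_baseline": p,
                }
            )
        for i, ma in enumerate(model_names):
            for mb in model_names[i + 1 :]:
                if n >= 2:
                    t, p = _paired_t(sub[ma].to_numpy(), sub[mb].to_numpy())
                else:
                    t, p = (np.nan, np.nan)
                pairwise_rows.append(
                    {"group": gname, "model_a": ma, "model_b": mb, "n_pairs": n, "t": t, "p": p}
                )
    return ModelComparison(
        summary=pd.DataFrame(summary_rows),
        pairwise=pd.DataFrame(pairwise_rows),
        baseline=base,
    )
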