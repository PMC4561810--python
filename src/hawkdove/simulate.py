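"""Synthetic-data generation: model-driven agents playing iterated chicken games.

Two agents, each governed by one of the trial-level utility models, play a
configurable number of trials.  On every trial each agent computes the utility
of avoiding and of rushing from its current internal state and cumulative
payoffs, samples "avoid" with the sigmoid choice probability, and both agents'
states are then updated from the realized joint action.

The engine is vectorized across simulations, which makes the two large
ensemble jobs practical on one CPU: reproducing published pattern-count means
from fitted parameters (10,000 games) and calibrating classification
thresholds from games with uniformly random parameters (hundreds of thousands
of games).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Union

import numpy as np
from scipy.special import expit

from .game import (
    DEFAULT_PAYOFFS,
    GameRecord,
    PATTERN_NAMES,
    PayoffMatrix,
    Thresholds,
    count_patterns_batch,
)
from .models import (
    DEFAULT_UPDATE_RULE,
    FS_ALPHA_MAX,
    ModelParams,
    PARAM_CLASSES,
    _rule_id,
    params_from_array,
)

__all__ = [
    "SimConfig",
    "EnsembleStats",
    "sample_uniform_params",
    "simulate_batch",
    "simulate_pair",
    "simulate_nonstationary_pair",
    "simulate_ensemble",
    "derive_thresholds",
    "linear_trajectory",
]


def linear_trajectory(start, end, n_trials: int) -> np.ndarray:
    """Per-trial parameter path interpolating linearly from ``start`` to ``end``.

    Returns an ``(n_trials, k)`` array for :func:`simulate_nonstationary_pair`;
    row 0 equals ``start`` and the last row equals ``end``.  Used to emulate a
    player whose decision rule drifts toward a consensus over the session.
    """
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    frac = np.linspace(0.0, 1.0, n_trials)[:, None]
    return start[None, :] * (1.0 - frac) + end[None, :] * frac


@dataclass
class SimConfig:
    """Settings for one simulation job.

    ``params_1`` / ``params_2`` are the two agents' parameter objects (they
    need not be equal); ``n_sims`` only matters for ensemble statistics.
    """

    model: str
    params_1: ModelParams
    params_2: ModelParams
    matrix: PayoffMatrix = field(default_factory=lambda: DEFAULT_PAYOFFS)
    n_trials: int = 100
    n_sims: int = 1
    seed: Optional[int] = None
    update_rule: str = DEFAULT_UPDATE_RULE

    def __post_init__(self) -> None:
        if self.model not in PARAM_CLASSES:
            raise ValueError(f"unknown model {self.model!r}")
        _rule_id(self.update_rule)  # validate
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        for p in (self.params_1, self.params_2):
            if p.model != self.model:
                raise ValueError(
                    f"params are for model {p.model!r}, config says {self.model!r}"
                )


@dataclass(frozen=True)
class EnsembleStats:
    """Per-pattern mean and SD of two-trial window counts across simulations."""

    means: Dict[str, float]
    sds: Dict[str, float]
    n_sims: int
    n_trials: int


def sample_uniform_params(
    model: str, rng: np.random.Generator, size: Optional[int] = None
) -> Union[ModelParams, np.ndarray]:
    """Draw parameters uniformly over their bound intervals.

    For ``fs`` the joint constraint ``beta <= alpha`` (and ``beta < 1``) is
    respected by drawing a fraction ``s ~ U[0, 1)`` and setting
    ``beta = s * min(alpha, 1)``.  With ``size=None`` a single validated
    parameter object is returned; otherwise an array of shape ``(size, k)``.
    """
    n = 1 if size is None else int(size)
    if model == "fs":
        alpha = rng.uniform(0.0, FS_ALPHA_MAX, n)
        beta = rng.random(n) * np.minimum(alpha, 1.0)
        out = np.column_stack([alpha, beta])
    elif model in ("cox", "sc"):
        alpha = 1.0 - rng.random(n)  # uniform on (0, 1]
        beta = rng.uniform(-1.0, 1.0, n)
        gamma = rng.random(n)
        delta = rng.random(n)
        out = np.column_stack([alpha, beta, gamma, delta])
    else:
        raise ValueError(f"unknown model {model!r}")
    return params_from_array(model, out[0]) if size is None else out


def _expected_increments(matrix: PayoffMatrix, player: int):
    """Scaled expected current-trial payoffs (own, other) per own action."""
    table = matrix.scaled()
    if player == 0:
        return table[:, :, 0].mean(axis=1), table[:, :, 1].mean(axis=1)
    return table[:, :, 1].mean(axis=0), table[:, :, 0].mean(axis=0)


def _spow(x: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.abs(x) ** alpha


def _utility_diff(
    model: str,
    p: np.ndarray,
    cum_own: np.ndarray,
    cum_oth: np.ndarray,
    state: Dict[str, np.ndarray],
    e_own: np.ndarray,
    e_oth: np.ndarray,
) -> np.ndarray:
    """u(avoid) - u(rush) for a batch of agents with parameter columns ``p``."""
    alpha = p[:, 0]
    u = []
    for a in (0, 1):
        own = cum_own + e_own[a]
        oth = cum_oth + e_oth[a]
        if model == "fs":
            beta = p[:, 1]
            u.append(
                np.where(
                    own < oth,
                    own - alpha * (oth - own),
                    own - beta * (own - oth),
                )
            )
        else:
            if model == "cox":
                w = state["theta"]
            else:
                delta = p[:, 3]
                w = 2.0 * (delta * state["F_other"] - (1.0 - delta) * state["F_self"])
            u.append((_spow(own, alpha) + w * _spow(oth, alpha)) / alpha)
    return u[0] - u[1]


def simulate_batch(
    model: str,
    params_1: np.ndarray,
    params_2: np.ndarray,
    n_trials: int,
    matrix: PayoffMatrix = DEFAULT_PAYOFFS,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    update_rule: str = DEFAULT_UPDATE_RULE,
) -> np.ndarray:
    """Simulate many games at once; returns actions of shape ``(n_sims, n_trials, 2)``.

    ``params_*`` may be shaped ``(k,)`` (one shared parameter set), ``(n, k)``
    (one set per simulation) or ``(n, n_trials, k)`` (a per-trial trajectory
    per simulation -- the hook for non-stationary agents).  The batch sizes of
    the two players must agree.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    smooth = _rule_id(update_rule) == 0
    params_1 = np.atleast_2d(np.asarray(params_1, dtype=float))
    params_2 = np.atleast_2d(np.asarray(params_2, dtype=float))
    n = max(
        params_1.shape[0] if params_1.ndim >= 2 else 1,
        params_2.shape[0] if params_2.ndim >= 2 else 1,
    )

    def at_trial(p: np.ndarray, t: int) -> np.ndarray:
        q = p[:, t, :] if p.ndim == 3 else p
        return np.broadcast_to(q, (n, q.shape[-1]))

    table = matrix.scaled()
    e_own_1, e_oth_1 = _expected_increments(matrix, 0)
    e_own_2, e_oth_2 = _expected_increments(matrix, 1)

    cum = np.zeros((n, 2))
    state_1 = {"theta": np.zeros(n), "F_self": np.zeros(n), "F_other": np.zeros(n)}
    state_2 = {"theta": np.zeros(n), "F_self": np.zeros(n), "F_other": np.zeros(n)}
    actions = np.empty((n, n_trials, 2), dtype=np.int8)

    for t in range(n_trials):
        p1 = at_trial(params_1, t)
        p2 = at_trial(params_2, t)
        z1 = _utility_diff(model, p1, cum[:, 0], cum[:, 1], state_1, e_own_1, e_oth_1)
        z2 = _utility_diff(model, p2, cum[:, 1], cum[:, 0], state_2, e_own_2, e_oth_2)
        draws = rng.random((n, 2))
        a1 = (draws[:, 0] >= expit(z1)).astype(np.int8)  # avoid iff draw < p(avoid)
        a2 = (draws[:, 1] >= expit(z2)).astype(np.int8)
        actions[:, t, 0] = a1
        actions[:, t, 1] = a2
        cum += table[a1, a2]
        k1 = 1.0 - 2.0 * a1
        k2 = 1.0 - 2.0 * a2
        g1 = (1.0 - p1[:, 2]) if smooth else 1.0
        g2 = (1.0 - p2[:, 2]) if smooth else 1.0
        if model == "cox":
            state_1["theta"] = p1[:, 2] * state_1["theta"] + g1 * p1[:, 3] * k2 + p1[:, 1]
            state_2["theta"] = p2[:, 2] * state_2["theta"] + g2 * p2[:, 3] * k1 + p2[:, 1]
        elif model == "sc":
            state_1["F_self"] = p1[:, 2] * state_1["F_self"] + g1 * k1
            state_1["F_other"] = p1[:, 2] * state_1["F_other"] + g1 * k2 + p1[:, 1]
            state_2["F_self"] = p2[:, 2] * state_2["F_self"] + g2 * k2
            state_2["F_other"] = p2[:, 2] * state_2["F_other"] + g2 * k1 + p2[:, 1]
    return actions


def simulate_pair(config: SimConfig, pair_id: str = "sim") -> GameRecord:
    """Simulate a single dyad's game; fully reproducible given ``config.seed``."""
    actions = simulate_batch(
        config.model,
        config.params_1.to_array(),
        config.params_2.to_array(),
        config.n_trials,
        config.matrix,
        seed=config.seed,
        update_rule=config.update_rule,
    )
    return GameRecord(pair_id, actions[0], matrix=config.matrix)


def simulate_nonstationary_pair(
    model: str,
    trajectory_1: np.ndarray,
    trajectory_2: np.ndarray,
    matrix: PayoffMatrix = DEFAULT_PAYOFFS,
    seed: Optional[int] = None,
    pair_id: str = "sim-ns",
    update_rule: str = DEFAULT_UPDATE_RULE,
) -> GameRecord:
    """Simulate a dyad whose parameters vary over trials.

    ``trajectory_*`` has shape ``(n_trials, k)``; row ``t`` is that player's
    parameter vector on trial ``t + 1``.  This is the generator hook used to
    emulate players whose decision rules drift or converge during a session.
    """
    trajectory_1 = np.asarray(trajectory_1, dtype=float)
    trajectory_2 = np.asarray(trajectory_2, dtype=float)
    if trajectory_1.shape != trajectory_2.shape or trajectory_1.ndim != 2:
        raise ValueError("trajectories must be equal-shape (n_trials, k) arrays")
    n_trials = trajectory_1.shape[0]
    actions = simulate_batch(
        model,
        trajectory_1[None, :, :],
        trajectory_2[None, :, :],
        n_trials,
        matrix,
        seed=seed,
        update_rule=update_rule,
    )
    return GameRecord(pair_id, actions[0], matrix=matrix)


def simulate_ensemble(config: SimConfig) -> EnsembleStats:
    """Run ``config.n_sims`` independent games and summarize pattern counts."""
    if config.n_sims < 2:
        raise ValueError("n_sims must be >= 2 for ensemble standard deviations")
    p1 = config.params_1.to_array()
    p2 = config.params_2.to_array()
    actions = simulate_batch(
        config.model,
        np.broadcast_to(p1, (config.n_sims, p1.shape[0])),
        np.broadcast_to(p2, (config.n_sims, p2.shape[0])),
        config.n_trials,
        config.matrix,
        seed=config.seed,
        update_rule=config.update_rule,
    )
    counts = count_patterns_batch(actions)
    means = {k: float(v.mean()) for k, v in counts.items()}
    sds = {k: float(v.std(ddof=1)) for k, v in counts.items()}
    return EnsembleStats(means, sds, config.n_sims, config.n_trials)


def derive_thresholds(
    n_sims: int,
    quantile: float = 0.95,
    n_trials: int = 100,
    matrix: PayoffMatrix = DEFAULT_PAYOFFS,
    seed: Optional[int] = None,
    batch_size: int = 100_000,
    shared_draw: bool = False,
    update_rule: str = DEFAULT_UPDATE_RULE,
) -> Thresholds:
    """Calibrate pattern-count cutoffs from random-parameter self-concept games.

    Both agents' parameters are drawn uniformly over their bounds for every
    simulated game (independently unless ``shared_draw``), the four pattern
    counts are recorded per game, and each cutoff is the count at the upper
    ``1 - quantile`` order statistic (e.g. the 50,000th largest of 1,000,000
    games at the default 95th percentile).
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    k_top = int(np.floor(n_sims * (1.0 - quantile) + 1e-9))
    if k_top < 1:
        raise ValueError(
            f"n_sims={n_sims} too small for quantile {quantile}; need >= "
            f"{int(np.ceil(1.0 / (1.0 - quantile)))}"
        )
    ss = np.random.SeedSequence(seed)
    counts = {name: [] for name in PATTERN_NAMES}
    done = 0
    while done < n_sims:
        m = min(batch_size, n_sims - done)
        rng = np.random.default_rng(ss.spawn(1)[0])
        p1 = sample_uniform_params("sc", rng, size=m)
        p2 = p1 if shared_draw else sample_uniform_params("sc", rng, size=m)
        actions = simulate_batch(
            "sc", p1, p2, n_trials, matrix, rng=rng, update_rule=update_rule
        )
        for name, arr in count_patterns_batch(actions).items():
            counts[name].append(arr)
        done += m
    cuts = {}
    for name in PATTERN_NAMES:
        arr = np.concatenate(counts[name])
        cuts[name] = int(np.partition(arr, -k_top)[-k_top])
    return Thresholds(**cuts)
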