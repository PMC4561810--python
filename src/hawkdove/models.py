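"""Trial-level utility models for the iterated chicken game.

Three models map a player's game history to the utility of avoiding versus
rushing on the next trial; a shared logistic (sigmoid) choice rule converts
the utility difference into an avoidance probability.

``fs``
    Fehr-Schmidt inequity aversion: utility is the player's expected total
    reward minus a penalty proportional to the payoff gap with the opponent
    (weight ``alpha`` when behind, ``beta`` when ahead).
``cox``
    Reciprocity via an emotional state ``theta`` that decays at retention
    rate ``gamma``, absorbs the opponent's kindness scaled by sensitivity
    ``delta`` and a per-trial benevolence bias ``beta``, and weights the
    opponent's expected total in a CES utility with convexity ``alpha``.
``sc``
    Self-concept: the player tracks both its own accumulated kindness
    (``F_self``) and the opponent's as perceived (``F_other``, biased by
    ``beta``); reciprocity ``r = 2 * (delta * F_other - (1 - delta) * F_self)``
    replaces ``theta`` in the same CES utility.

Kindness of an action is the mean-centered, range-normalized favourability of
that action to the other player; in the chicken game avoiding is worth +1 and
rushing -1.

Two state-update rules are provided for the ``cox`` and ``sc`` states, because
the recursion "retained state plus incoming kindness plus benevolence" admits
two readings that differ sharply at high retention:

``smooth`` (default)
    Incoming kindness is exponentially smoothed, ``theta <- gamma * theta +
    (1 - gamma) * delta * f + beta`` (and likewise ``(1 - gamma) * f`` for the
    two ``sc`` ledgers), so the kindness component of the state stays on the
    +-1 scale of ``f`` at every retention rate while the benevolence bias
    ``beta`` accumulates to ``beta / (1 - gamma)``.  This is the calibrated
    study condition: it reproduces the published pattern statistics far
    better than the raw accumulator (see the methods note).
``accumulate``
    The raw accumulator ``theta <- gamma * theta + delta * f + beta``; at
    ``gamma = 1`` states become running sums of kindness.

Both rules coincide at ``gamma = 0`` (memoryless limit).  All utilities are
computed on payoffs divided by the matrix ``scale`` so that sigmoid arguments
stay in a numerically sensible range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Tuple, Type, Union

import numpy as np
from scipy.special import expit

from .game import Action, DEFAULT_PAYOFFS, GameRecord, PayoffMatrix

try:  # numba accelerates the likelihood replay; the code also runs without it
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap

__all__ = [
    "FSParams",
    "CoxParams",
    "SCParams",
    "CoxState",
    "SCState",
    "MODEL_NAMES",
    "PARAM_CLASSES",
    "UPDATE_RULES",
    "DEFAULT_UPDATE_RULE",
    "params_from_array",
    "kindness",
    "expected_payoffs",
    "fs_utility",
    "ces_utility",
    "signed_power",
    "cox_update",
    "sc_update",
    "sc_reciprocity",
    "action_probability",
    "sequence_loglik",
    "player_loglik",
]

#: Upper bound for the Fehr-Schmidt disadvantageous-inequity weight.
FS_ALPHA_MAX = 10.0

#: State-update rules for the cox/sc models (see module docstring).
UPDATE_RULES = ("smooth", "accumulate")

#: The calibrated study condition.
DEFAULT_UPDATE_RULE = "smooth"
_RULE_IDS = {"smooth": 0, "accumulate": 1}


def _rule_id(update_rule: str) -> int:
    try:
        return _RULE_IDS[update_rule]
    except KeyError:
        raise ValueError(
            f"unknown update rule {update_rule!r}; expected one of {UPDATE_RULES}"
        )


@dataclass(frozen=True)
class FSParams:
    """Fehr-Schmidt weights: ``beta <= alpha``, ``0 <= beta < 1``, ``alpha >= 0``."""

    alpha: float
    beta: float

    names = ("alpha", "beta")
    model = "fs"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= FS_ALPHA_MAX:
            raise ValueError(f"alpha must be in [0, {FS_ALPHA_MAX}]")
        if not 0.0 <= self.beta < 1.0:
            raise ValueError("beta must be in [0, 1)")
        if self.beta > self.alpha:
            raise ValueError("beta must not exceed alpha")

    def to_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta], dtype=float)


@dataclass(frozen=True)
class CoxParams:
    """Reciprocity-model parameters.

    alpha : CES convexity, 0 < alpha <= 1
    beta  : initial benevolence added to the state each trial, -1 <= beta <= 1
    gamma : retention rate of the emotional state, 0 <= gamma <= 1
    delta : sensitivity to the opponent's kindness, 0 <= delta <= 1
    """

    alpha: float
    beta: float
    gamma: float
    delta: float

    names = ("alpha", "beta", "gamma", "delta")
    model = "cox"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if not -1.0 <= self.beta <= 1.0:
            raise ValueError("beta must be in [-1, 1]")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must be in [0, 1]")

    def to_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma, self.delta], dtype=float)


@dataclass(frozen=True)
class SCParams(CoxParams):
    """Self-concept-model parameters; same bounds as :class:`CoxParams`.

    ``delta`` here is the relative weight of the other's kindness against
    one's own in the reciprocity comparison (0.5 = balanced).
    """

    model = "sc"


ModelParams = Union[FSParams, CoxParams, SCParams]

MODEL_NAMES = ("fs", "cox", "sc")
_MODEL_IDS = {"fs": 0, "cox": 1, "sc": 2}
PARAM_CLASSES: Dict[str, Type[ModelParams]] = {
    "fs": FSParams,
    "cox": CoxParams,
    "sc": SCParams,
}


def params_from_array(model: str, values: np.ndarray) -> ModelParams:
    """Build a validated parameter object from a flat array."""
    cls = PARAM_CLASSES[model]
    return cls(*[float(v) for v in np.asarray(values, dtype=float)])


@dataclass
class CoxState:
    """Emotional state of one reciprocity-model agent; 0 before any trial."""

    theta: float = 0.0


@dataclass
class SCState:
    """Kindness ledgers of one self-concept agent; both 0 before any trial."""

    F_self: float = 0.0
    F_other: float = 0.0


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def kindness(matrix: PayoffMatrix, a: Action) -> float:
    """Kindness of action ``a`` toward the other player.

    The other player's best attainable payoff under ``a`` is mean-centered
    over the actor's available actions and normalized by the mean payoff
    range, making the value scale-free.  For any chicken matrix with
    ``crash_cost = 2 * transfer`` this is exactly +1 for avoiding and -1 for
    rushing.
    """
    table = matrix.payoff_table()
    highs = table[:, :, 1].max(axis=1)  # opponent's best payoff per own action
    lows = table[:, :, 1].min(axis=1)
    denom = float(np.mean(highs - lows))
    if denom == 0.0:
        raise ValueError("degenerate payoff matrix: zero mean payoff range")
    return float((highs[a] - highs.mean()) / denom)


def expected_payoffs(
    matrix: PayoffMatrix,
    a: Action,
    history: Tuple[float, float] = (0.0, 0.0),
) -> Tuple[float, float]:
    """Expected total rewards ``(E(Pi_i), E(Pi_j))`` after player i takes ``a``.

    Each total is the player's cumulative realized payoff (``history``, in
    currency units) plus the current trial's payoff averaged uniformly over
    the opponent's two possible actions -- the model holds no belief about the
    opponent beyond that uniform average.
    """
    table = matrix.payoff_table()
    e_own = float(table[a, :, 0].mean())
    e_other = float(table[a, :, 1].mean())
    return (history[0] + e_own, history[1] + e_other)


def fs_utility(params: FSParams, e_own: float, e_other: float) -> float:
    """Fehr-Schmidt utility of an action from the two expected totals."""
    if e_own < e_other:
        return e_own - params.alpha * (e_other - e_own)
    return e_own - params.beta * (e_own - e_other)


def signed_power(x, alpha: float):
    """``sign(x) * |x| ** alpha`` -- the CES power extended to negative bases.

    Cumulative chicken payoffs can be negative, where ``x ** alpha`` is
    undefined for non-integer ``alpha``; the odd (signed) extension keeps the
    utility monotone in the payoff.
    """
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.abs(x) ** alpha
    return float(out) if out.ndim == 0 else out


def ces_utility(alpha: float, weight: float, own_total: float, other_total: float) -> float:
    """Constant-elasticity-of-substitution utility with a signed power.

    ``u = (1/alpha) * (pow*(own, alpha) + weight * pow*(other, alpha))`` where
    ``weight`` is the emotional state (``cox``) or reciprocity (``sc``) and
    ``pow*`` is :func:`signed_power`.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    return (signed_power(own_total, alpha) + weight * signed_power(other_total, alpha)) / alpha


def cox_update(
    state: CoxState,
    params: CoxParams,
    f_opponent: float,
    update_rule: str = DEFAULT_UPDATE_RULE,
) -> CoxState:
    """Advance the emotional state by one trial.

    Under the default ``smooth`` rule the opponent's fresh kindness (scaled by
    the sensitivity ``delta``) is exponentially smoothed into the retained
    state and the benevolence bias is added raw:
    ``theta(t+1) = gamma * theta(t) + (1 - gamma) * delta * f_opponent + beta``.
    Under ``accumulate`` the kindness input enters unsmoothed.
    """
    gain = 1.0 - params.gamma if _rule_id(update_rule) == 0 else 1.0
    return CoxState(
        params.gamma * state.theta + gain * params.delta * f_opponent + params.beta
    )


def sc_update(
    state: SCState,
    params: SCParams,
    f_own: float,
    f_opponent: float,
    update_rule: str = DEFAULT_UPDATE_RULE,
) -> SCState:
    """Advance both kindness ledgers by one trial.

    ``F_self`` absorbs the player's own kindness; ``F_other`` absorbs the
    opponent's kindness plus the benevolence bias ``beta`` (beta enters
    ``F_other`` only).  Under the default ``smooth`` rule the kindness inputs
    are scaled by ``1 - gamma`` (the bias is not); under ``accumulate`` they
    enter raw.
    """
    gain = 1.0 - params.gamma if _rule_id(update_rule) == 0 else 1.0
    return SCState(
        F_self=params.gamma * state.F_self + gain * f_own,
        F_other=params.gamma * state.F_other + gain * f_opponent + params.beta,
    )


def sc_reciprocity(state: SCState, params: SCParams) -> float:
    """``r = 2 * (delta * F_other - (1 - delta) * F_self)``.

    At ``delta = 0.5`` this reduces to the plain ledger difference
    ``F_other - F_self``.
    """
    return 2.0 * (params.delta * state.F_other - (1.0 - params.delta) * state.F_self)


def action_probability(u_avoid: float, u_rush: float):
    """Probability of avoiding: ``sigmoid(u_avoid - u_rush)``.

    Saturates gracefully for large utility differences; ``p(rush)`` is the
    complement.
    """
    return expit(np.asarray(u_avoid, dtype=float) - np.asarray(u_rush, dtype=float))


# ---------------------------------------------------------------------------
# sequence likelihood
# ---------------------------------------------------------------------------


@njit(cache=False)
def _spow(x: float, alpha: float) -> float:
    if x >= 0.0:
        return x ** alpha
    return -((-x) ** alpha)


@njit(cache=False)
def _loglik_kernel(
    model_id: int,
    rule_id: int,
    p: np.ndarray,
    a_self: np.ndarray,
    a_other: np.ndarray,
    pay_self: np.ndarray,
    pay_other: np.ndarray,
    e_own: np.ndarray,
    e_oth: np.ndarray,
) -> np.ndarray:
    """Per-trial log-probabilities of one player's observed actions.

    ``pay_self``/``pay_other`` are the realized scaled payoffs; ``e_own[a]``
    and ``e_oth[a]`` the scaled expected current-trial payoffs of self/other
    given own action ``a``.  States are replayed from the observed history.
    """
    n = a_self.shape[0]
    out = np.empty(n)
    cum_self = 0.0
    cum_other = 0.0
    theta = 0.0  # cox emotional state
    f_slf = 0.0  # sc kindness ledgers
    f_oth = 0.0
    alpha = p[0]
    beta = p[1]
    gamma = p[2] if p.shape[0] > 2 else 0.0
    delta = p[3] if p.shape[0] > 2 else 0.0
    for t in range(n):
        u = np.empty(2)
        for a in range(2):
            e_total_own = cum_self + e_own[a]
            e_total_oth = cum_other + e_oth[a]
            if model_id == 0:  # fehr-schmidt
                if e_total_own < e_total_oth:
                    u[a] = e_total_own - alpha * (e_total_oth - e_total_own)
                else:
                    u[a] = e_total_own - beta * (e_total_own - e_total_oth)
            else:  # CES with state-dependent weight
                if model_id == 1:
                    w = theta
                else:
                    w = 2.0 * (delta * f_oth - (1.0 - delta) * f_slf)
                u[a] = (_spow(e_total_own, alpha) + w * _spow(e_total_oth, alpha)) / alpha
        z = u[0] - u[1]  # avoid minus rush
        if a_self[t] == 0:
            out[t] = -math.log1p(math.exp(-z)) if z > -700.0 else z
        else:
            out[t] = -math.log1p(math.exp(z)) if z < 700.0 else -z
        # state updates from the realized actions
        k_self = 1.0 - 2.0 * a_self[t]
        k_other = 1.0 - 2.0 * a_other[t]
        gain = (1.0 - gamma) if rule_id == 0 else 1.0
        if model_id == 1:
            theta = gamma * theta + gain * delta * k_other + beta
        elif model_id == 2:
            f_slf = gamma * f_slf + gain * k_self
            f_oth = gamma * f_oth + gain * k_other + beta
        cum_self += pay_self[t]
        cum_other += pay_other[t]
    return out


def _player_arrays(record: GameRecord, matrix: PayoffMatrix, player: int):
    """Observed-history arrays for one player (0 or 1), in scaled units."""
    other = 1 - player
    a_self = record.actions[:, player].astype(np.int8)
    a_other = record.actions[:, other].astype(np.int8)
    pay_self = np.ascontiguousarray(record.payoffs[:, player]) / matrix.scale
    pay_other = np.ascontiguousarray(record.payoffs[:, other]) / matrix.scale
    table = matrix.scaled()
    if player == 0:
        e_own = table[:, :, 0].mean(axis=1)
        e_oth = table[:, :, 1].mean(axis=1)
    else:
        e_own = table[:, :, 1].mean(axis=0)
        e_oth = table[:, :, 0].mean(axis=0)
    return a_self, a_other, pay_self, pay_other, e_own, e_oth


def player_loglik(
    model: str,
    params: ModelParams,
    record: GameRecord,
    matrix: PayoffMatrix = DEFAULT_PAYOFFS,
    player: int = 0,
    per_trial: bool = False,
    update_rule: str = DEFAULT_UPDATE_RULE,
):
    """Log-likelihood of one player's observed action sequence under a model.

    The game is replayed trial by trial: the player's internal state (none for
    ``fs``) evolves from the *observed* actions, each trial's avoidance
    probability comes from the sigmoid choice rule, and the log-probability of
    the action actually taken is accumulated.
    """
    if record.n_trials == 0:
        raise ValueError("record must contain at least one trial")
    if params.model != model:
        raise ValueError(f"params are for model {params.model!r}, not {model!r}")
    arrays = _player_arrays(record, matrix, player)
    logp = _loglik_kernel(
        _MODEL_IDS[model], _rule_id(update_rule), params.to_array(), *arrays
    )
    return logp if per_trial else float(logp.sum())


def sequence_loglik(
    model: str,
    params_1: ModelParams,
    params_2: ModelParams,
    record: GameRecord,
    matrix: PayoffMatrix = DEFAULT_PAYOFFS,
    update_rule: str = DEFAULT_UPDATE_RULE,
) -> float:
    """Joint log-likelihood of both players' observed actions (sum over players)."""
    return player_loglik(
        model, params_1, record, matrix, player=0, update_rule=update_rule
    ) + player_loglik(model, params_2, record, matrix, player=1, update_rule=update_rule)
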