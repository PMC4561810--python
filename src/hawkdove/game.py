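"""Chicken-game payoff structure, game records, and two-trial pattern analysis.

The chicken (hawk-dove) game is a two-player anti-coordination game played
here in discrete trials.  Each player either *avoids* (swerves, becoming the
"chicken") or *rushes*.  Mutual avoidance is neutral, a lone avoider transfers
reward to the rusher, and mutual rushing (a crash) costs both players more
than the lone avoider loses.  Over consecutive pairs of trials four symmetric
behavioral patterns can appear -- switching, mutual rush, mutual avoidance and
unfair play -- and a dyad is classified by comparing its pattern counts with
simulation-calibrated thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterator, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Action",
    "PayoffMatrix",
    "DEFAULT_PAYOFFS",
    "TrialRecord",
    "GameRecord",
    "PatternCounts",
    "Thresholds",
    "REFERENCE_THRESHOLDS",
    "PATTERN_NAMES",
    "cumulative_payoffs",
    "count_patterns",
    "count_patterns_batch",
    "classify",
]


class Action(IntEnum):
    """A player's binary choice on one trial."""

    AVOID = 0
    RUSH = 1

    @classmethod
    def from_code(cls, code: str) -> "Action":
        code = code.strip().upper()
        if code in ("A", "AVOID"):
            return cls.AVOID
        if code in ("R", "RUSH"):
            return cls.RUSH
        raise ValueError(f"unknown action code {code!r}; expected 'A' or 'R'")

    @property
    def code(self) -> str:
        return "A" if self is Action.AVOID else "R"


@dataclass(frozen=True)
class PayoffMatrix:
    """The 2x2 chicken-game reward structure, in currency units (KRW).

    Parameters
    ----------
    transfer
        Amount the lone avoider loses to the rusher (must be > 0).
    crash_cost
        Amount each player loses under mutual rush (must exceed ``transfer``).
    mutual_avoid
        Payoff to each player when both avoid (default 0).
    scale
        Currency units per internal model unit.  Utility computations divide
        payoffs by this scale so that sigmoid arguments stay O(1); default one
        internal unit per 1000 KRW.
    """

    transfer: float = 500.0
    crash_cost: float = 1000.0
    mutual_avoid: float = 0.0
    scale: float = 1000.0

    def __post_init__(self) -> None:
        if not self.transfer > 0:
            raise ValueError("transfer must be strictly positive")
        if not self.crash_cost > self.transfer:
            raise ValueError("crash_cost must exceed transfer")
        if not self.scale > 0:
            raise ValueError("scale must be strictly positive")

    def payoff(self, a_i: Action, a_j: Action) -> Tuple[float, float]:
        """Realized payoffs ``(pi_i, pi_j)`` for one trial, in currency units."""
        if a_i == Action.AVOID and a_j == Action.AVOID:
            return (self.mutual_avoid, self.mutual_avoid)
        if a_i == Action.RUSH and a_j == Action.RUSH:
            return (-self.crash_cost, -self.crash_cost)
        if a_i == Action.RUSH:
            return (self.transfer, -self.transfer)
        return (-self.transfer, self.transfer)

    def payoff_table(self) -> np.ndarray:
        """Payoffs as a (2, 2, 2) array indexed [a_i, a_j, player]."""
        out = np.empty((2, 2, 2))
        for ai in Action:
            for aj in Action:
                out[ai, aj] = self.payoff(ai, aj)
        return out

    def scaled(self) -> np.ndarray:
        """``payoff_table() / scale`` -- the units the utility models use."""
        return self.payoff_table() / self.scale

    def to_dict(self) -> dict:
        return {
            "transfer": self.transfer,
            "crash_cost": self.crash_cost,
            "mutual_avoid": self.mutual_avoid,
            "scale": self.scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PayoffMatrix":
        return cls(**{k: float(v) for k, v in d.items()})


#: Default reward structure (KRW).  The crash/transfer ratio of 2 is forced by
#: the kindness normalization (which makes every action worth exactly +/-1 in
#: kindness units only when crash_cost = 2 * transfer); the absolute level and
#: the thousands-of-KRW scale are calibrated so that self-concept simulations
#: at published parameter values reproduce the published pattern-count means.
DEFAULT_PAYOFFS = PayoffMatrix()


@dataclass(frozen=True)
class TrialRecord:
    """One trial of one dyad: 1-based index, both actions, realized payoffs."""

    t: int
    a_1: Action
    a_2: Action
    pi_1: float
    pi_2: float


class GameRecord:
    """Ordered trials of one dyad's iterated chicken game.

    Stores actions as an ``(n_trials, 2)`` integer array (0 = avoid, 1 = rush)
    and realized payoffs as an ``(n_trials, 2)`` float array in currency units.
    """

    def __init__(
        self,
        pair_id: str,
        actions: np.ndarray,
        payoffs: Optional[np.ndarray] = None,
        matrix: Optional[PayoffMatrix] = None,
    ):
        actions = np.asarray(actions, dtype=np.int8)
        if actions.ndim != 2 or actions.shape[1] != 2:
            raise ValueError("actions must have shape (n_trials, 2)")
        if actions.size and not np.isin(actions, (0, 1)).all():
            raise ValueError("actions must be 0 (avoid) or 1 (rush)")
        self.pair_id = str(pair_id)
        self.actions = actions
        if payoffs is None:
            if matrix is None:
                matrix = DEFAULT_PAYOFFS
            table = matrix.payoff_table()
            payoffs = table[actions[:, 0], actions[:, 1]]
        payoffs = np.asarray(payoffs, dtype=float)
        if payoffs.shape != actions.shape:
            raise ValueError("payoffs must have the same shape as actions")
        self.payoffs = payoffs

    @property
    def n_trials(self) -> int:
        return self.actions.shape[0]

    @property
    def trials(self) -> Iterator[TrialRecord]:
        for t in range(self.n_trials):
            yield TrialRecord(
                t + 1,
                Action(int(self.actions[t, 0])),
                Action(int(self.actions[t, 1])),
                float(self.payoffs[t, 0]),
                float(self.payoffs[t, 1]),
            )

    @classmethod
    def from_trials(cls, pair_id: str, trials: Sequence[TrialRecord]) -> "GameRecord":
        ts = [tr.t for tr in trials]
        if ts != list(range(1, len(trials) + 1)):
            raise ValueError("trial indices must be contiguous and 1-based")
        actions = np.array([[tr.a_1, tr.a_2] for tr in trials], dtype=np.int8)
        payoffs = np.array([[tr.pi_1, tr.pi_2] for tr in trials], dtype=float)
        return cls(pair_id, actions, payoffs)

    def payoffs_consistent(self, matrix: PayoffMatrix, atol: float = 1e-9) -> bool:
        """Whether the stored payoffs match ``matrix`` for every trial."""
        table = matrix.payoff_table()
        expect = table[self.actions[:, 0], self.actions[:, 1]]
        return bool(np.allclose(self.payoffs, expect, atol=atol))

    def __len__(self) -> int:
        return self.n_trials

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GameRecord):
            return NotImplemented
        return (
            self.pair_id == other.pair_id
            and np.array_equal(self.actions, other.actions)
            and np.allclose(self.payoffs, other.payoffs)
        )

    def __repr__(self) -> str:
        return f"GameRecord(pair_id={self.pair_id!r}, n_trials={self.n_trials})"


def cumulative_payoffs(record: GameRecord, upto_trial: int) -> Tuple[float, float]:
    """Summed realized payoffs of both players over trials ``1..upto_trial``.

    ``upto_trial = 0`` returns ``(0, 0)`` (the empty prefix before trial 1).
    """
    if not 0 <= upto_trial <= record.n_trials:
        raise IndexError(
            f"upto_trial must be in [0, {record.n_trials}], got {upto_trial}"
        )
    sums = record.payoffs[:upto_trial].sum(axis=0) if upto_trial else np.zeros(2)
    return (float(sums[0]), float(sums[1]))


PATTERN_NAMES = ("switching", "mutual_rush", "mutual_avoid", "unfair")


@dataclass(frozen=True)
class PatternCounts:
    """Counts of the four symmetric patterns over overlapping two-trial windows."""

    switching: int
    mutual_rush: int
    mutual_avoid: int
    unfair: int

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in PATTERN_NAMES}

    @property
    def total(self) -> int:
        return self.switching + self.mutual_rush + self.mutual_avoid + self.unfair


def _pattern_masks(a1: np.ndarray, a2: np.ndarray) -> dict:
    """Boolean window masks for each pattern; arrays may be (n,) or (n_sims, n)."""
    c1, n1 = a1[..., :-1], a1[..., 1:]
    c2, n2 = a2[..., :-1], a2[..., 1:]
    asym_now = c1 != c2
    asym_next = n1 != n2
    return {
        "switching": asym_now & asym_next & (c1 != n1),
        "mutual_rush": (c1 == 1) & (c2 == 1) & (n1 == 1) & (n2 == 1),
        "mutual_avoid": (c1 == 0) & (c2 == 0) & (n1 == 0) & (n2 == 0),
        "unfair": asym_now & asym_next & (c1 == n1) & (c2 == n2),
    }


def count_patterns(record: GameRecord) -> PatternCounts:
    """Count the four two-trial patterns over all ``n_trials - 1`` stride-1 windows.

    A window (t, t+1) is *switching* when exactly one player rushes on each
    trial and the rusher's identity swaps; *mutual rush* / *mutual avoidance*
    when both players rush / avoid on both trials; *unfair* when the same
    single player rushes on both trials while the other avoids on both.
    Windows matching none of the four are left uncounted.
    """
    if record.n_trials < 2:
        raise ValueError("pattern counting requires at least 2 trials")
    masks = _pattern_masks(record.actions[:, 0], record.actions[:, 1])
    return PatternCounts(**{k: int(v.sum()) for k, v in masks.items()})


def count_patterns_batch(actions: np.ndarray) -> dict:
    """Vectorized pattern counts for a batch of games.

    Parameters
    ----------
    actions
        Integer array of shape ``(n_sims, n_trials, 2)``.

    Returns
    -------
    dict mapping pattern name to an ``(n_sims,)`` integer array of counts.
    """
    if actions.shape[1] < 2:
        raise ValueError("pattern counting requires at least 2 trials")
    masks = _pattern_masks(actions[:, :, 0], actions[:, :, 1])
    return {k: v.sum(axis=-1) for k, v in masks.items()}


@dataclass(frozen=True)
class Thresholds:
    """Pattern-count cutoffs: a dyad shows a pattern when its count reaches the cutoff."""

    switching: int
    mutual_avoid: int
    mutual_rush: int
    unfair: int

    def __post_init__(self) -> None:
        for name in PATTERN_NAMES:
            if getattr(self, name) < 1:
                raise ValueError(f"threshold {name} must be >= 1")

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in PATTERN_NAMES}


#: Cutoffs from the published random-parameter calibration (95th percentile of
#: each pattern's count under self-concept play with uniform random parameters,
#: 100-trial games).  ``hawkdove.simulate.derive_thresholds`` recomputes them.
REFERENCE_THRESHOLDS = Thresholds(
    switching=24, mutual_avoid=22, mutual_rush=23, unfair=20
)

#: Tie-break precedence when several counts clear their thresholds by the same excess.
_CLASSIFY_PRECEDENCE = ("switching", "mutual_avoid", "mutual_rush", "unfair")


def classify(counts: PatternCounts, thresholds: Thresholds) -> str:
    """Label a dyad by its dominant pattern, or ``"undefined"`` if none qualifies.

    A pattern qualifies when its count meets or exceeds its threshold.  If
    several qualify, the one with the greatest excess over its threshold wins;
    exact ties fall back to the precedence order switching, mutual_avoid,
    mutual_rush, unfair.
    """
    best: Optional[str] = None
    best_excess = -1
    for name in _CLASSIFY_PRECEDENCE:
        excess = getattr(counts, name) - getattr(thresholds, name)
        if excess >= 0 and excess > best_excess:
            best, best_excess = name, excess
    return best if best is not None else "undefined"
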