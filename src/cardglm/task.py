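"""Probabilistic model of the two-card gambling task.

A trial of the task: the agent bets a fixed stake that a second card drawn
from a deck (default values 1..10, without replacement) will be *higher* or
*lower* than the first. After card 1 the outcome distribution is fully
determined, so every trial yields closed-form decision variables:

- ``p_win``  — probability of winning given bet and card 1,
- ``reward_prediction`` — expected payoff (symmetric ±stake coding),
- ``entropy`` / ``confidence`` — Shannon entropy of the binary outcome in
  bits and its negative,
- ``surprise`` — Shannon information of the observed outcome,
- ``accuracy`` — information gain as a confidence error (certitude, 0,
  minus predicted confidence),
- ``rpe`` — realized minus expected payoff,
- a Dirichlet counting estimate of the win rate, used as a card-counting
  learning control.

All information quantities are in bits (log base 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Bet",
    "Outcome",
    "Deck",
    "Trial",
    "DecisionVariables",
    "LearningState",
    "TaskDataError",
    "win_probability",
    "entropy_bits",
    "confidence",
    "surprise_bits",
    "accuracy_bits",
    "reward_prediction",
    "reward_prediction_error",
    "inverse_variance",
    "dirichlet_update",
    "compute_decision_variables",
    "write_variables_tsv",
]

Bet = Literal["higher", "lower"]
Outcome = Literal["win", "loss"]

HIGHER: Bet = "higher"
LOWER: Bet = "lower"
WIN: Outcome = "win"
LOSS: Outcome = "loss"


class TaskDataError(ValueError):
    """Raised when event data is inconsistent with the task's rules."""


@dataclass(frozen=True)
class Deck:
    """An ordered set of distinct integer card values."""

    values: tuple[int, ...] = tuple(range(1, 11))

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise ValueError("a deck needs at least 2 cards")
        if len(set(self.values)) != len(self.values):
            raise ValueError("card values must be distinct")

    def __len__(self) -> int:
        return len(self.values)

    def __contains__(self, card: int) -> bool:
        return card in self.values


@dataclass
class Trial:
    """One round of the card game.

    ``bet`` and ``outcome`` are ``None`` when the bet was missed (the trial
    is then unresolved: cards are still revealed but no win/loss exists).
    Onsets are in seconds from session start; ``onset_card2 - onset_card1``
    is the task's fixed 5.5 s card gap.
    """

    session: int
    index: int
    card1: int
    card2: int
    bet: Bet | None = None
    outcome: Outcome | None = None
    bet_placed: bool = True
    report_made: bool = True
    report_correct: bool = True
    onset_bet_cue: float = 0.0
    onset_card1: float = 4.0
    onset_card2: float = 9.5
    onset_report_cue: float = 15.0
    rt_bet: float | None = None
    rt_report: float | None = None

    def __post_init__(self) -> None:
        if self.card1 == self.card2:
            raise TaskDataError(
                f"card1 == card2 == {self.card1}: cards are drawn without replacement"
            )
        if self.bet_placed and self.bet is not None and self.outcome is not None:
            if self.outcome != true_outcome(self.card1, self.card2, self.bet):
                raise TaskDataError(
                    f"recorded outcome {self.outcome!r} contradicts cards "
                    f"({self.card1}, {self.card2}) under bet {self.bet!r}"
                )

    @property
    def resolved(self) -> bool:
        return self.bet_placed and self.bet is not None and self.outcome is not None


@dataclass(frozen=True)
class DecisionVariables:
    """Closed-form per-trial decision variables (information terms in bits)."""

    p_win: float
    reward_prediction: float
    entropy: float
    confidence: float
    surprise: float
    accuracy: float
    rpe: float


@dataclass(frozen=True)
class LearningState:
    """Running Dirichlet count of wins used as a card-counting control."""

    wins_so_far: int = 0
    outcomes_so_far: int = 0

    def __post_init__(self) -> None:
        if self.wins_so_far > self.outcomes_so_far:
            raise ValueError("wins cannot exceed outcomes")

    @property
    def p_win_learned(self) -> float:
        return (self.wins_so_far + 1) / (self.outcomes_so_far + 1)


def true_outcome(card1: int, card2: int, bet: Bet) -> Outcome:
    """Outcome implied by the task rules for a resolved bet."""
    if bet not in (HIGHER, LOWER):
        raise ValueError(f"unknown bet {bet!r}")
    won = card2 > card1 if bet == HIGHER else card2 < card1
    return WIN if won else LOSS


def win_probability(card1: int, bet: Bet, deck: Deck = Deck()) -> float:
    """P(win | bet, card1): fraction of the remaining cards that beat card 1."""
    if card1 not in deck:
        raise ValueError(f"card {card1} not in deck {deck.values}")
    if bet not in (HIGHER, LOWER):
        raise ValueError(f"unknown bet {bet!r}")
    others = [v for v in deck.values if v != card1]
    if bet == HIGHER:
        favorable = sum(v > card1 for v in others)
    else:
        favorable = sum(v < card1 for v in others)
    return favorable / len(others)


def entropy_bits(p: float) -> float:
    """Shannon entropy of a Bernoulli(p) outcome in bits, with 0·log2(0) = 0."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    if p in (0.0, 1.0):
        return 0.0
    return -(p * math.log2(p) + (1.0 - p) * math.log2(1.0 - p))


def confidence(p: float) -> float:
    """Confidence as negative entropy: 0 at certitude, −1 bit at p = 0.5."""
    return -entropy_bits(p)


def accuracy_bits(p: float, sign: float = 1.0) -> float:
    """Information gain as a confidence error: certitude (0) minus confidence.

    Numerically the trial's entropy. ``sign=-1`` flips the convention for
    users who prefer to report the gain as a non-positive divergence-style
    quantity; the default follows the literal ``0 - confidence`` definition.
    """
    return sign * (0.0 - confidence(p))


def surprise_bits(trial: Trial, deck: Deck = Deck()) -> float:
    """Shannon surprise of the observed outcome: −log2 p(outcome | bet, card1)."""
    if not trial.resolved:
        raise TaskDataError("surprise is undefined for an unresolved (missed-bet) trial")
    p = win_probability(trial.card1, trial.bet, deck)
    p_obs = p if trial.outcome == WIN else 1.0 - p
    if p_obs <= 0.0:
        raise TaskDataError(
            f"observed outcome {trial.outcome!r} has probability 0 for "
            f"card1={trial.card1}, bet={trial.bet!r}: corrupt event data"
        )
    return -math.log2(p_obs)


def reward_prediction(
    card1: int, bet: Bet, stake: float = 1.0, deck: Deck = Deck()
) -> float:
    """Expected payoff of the bet under symmetric ±stake coding: stake·(2p−1)."""
    if stake <= 0:
        raise ValueError("stake must be positive")
    p = win_probability(card1, bet, deck)
    return stake * (2.0 * p - 1.0)


def reward_prediction_error(
    trial: Trial, stake: float = 1.0, deck: Deck = Deck()
) -> float:
    """Realized payoff (±stake) minus the reward prediction; 0 when certain."""
    if not trial.resolved:
        raise TaskDataError("RPE is undefined for an unresolved (missed-bet) trial")
    realized = stake if trial.outcome == WIN else -stake
    return realized - reward_prediction(trial.card1, trial.bet, stake, deck)


def inverse_variance(p: float, epsilon: float = 0.001) -> float:
    """Precision 1/(q(1−q)) of the win indicator, with q = clip(p, ε, 1−ε).

    Exists to contrast negative entropy with inverse variance as confidence
    measures: at certitude the ε-regularized precision explodes to a value
    that is not ordinal with the rest of the confidence scale, whereas
    negative entropy extends continuously to 0.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    q = min(max(p, epsilon), 1.0 - epsilon)
    return 1.0 / (q * (1.0 - q))


def dirichlet_update(state: LearningState, outcome: Outcome) -> LearningState:
    """Advance the Dirichlet win count by one observed outcome.

    The estimate is (wins + 1)/(outcomes + 1): a single pseudo-count in both
    numerator and denominator, so the empty state predicts p = 1.
    """
    if outcome not in (WIN, LOSS):
        raise ValueError(f"unknown outcome {outcome!r}")
    return LearningState(
        wins_so_far=state.wins_so_far + (outcome == WIN),
        outcomes_so_far=state.outcomes_so_far + 1,
    )


def decision_variables(
    trial: Trial, deck: Deck = Deck(), stake: float = 1.0, accuracy_sign: float = 1.0
) -> DecisionVariables:
    """All closed-form decision variables for one resolved trial."""
    p = win_probability(trial.card1, trial.bet, deck)
    return DecisionVariables(
        p_win=p,
        reward_prediction=reward_prediction(trial.card1, trial.bet, stake, deck),
        entropy=entropy_bits(p),
        confidence=confidence(p),
        surprise=surprise_bits(trial, deck),
        accuracy=accuracy_bits(p, accuracy_sign),
        rpe=reward_prediction_error(trial, stake, deck),
    )


def compute_decision_variables(
    trials: Sequence[Trial],
    deck: Deck = Deck(),
    stake: float = 1.0,
    accuracy_sign: float = 1.0,
    count_unresolved: bool = True,
) -> pd.DataFrame:
    """Per-trial decision-variable table, one row per trial in input order.

    Unresolved (missed-bet) trials get NaN decision variables. The Dirichlet
    learning estimate ``p_win_learned`` restarts at every session and is the
    *prediction held at that trial's card 2*, i.e. the state after counting
    all earlier outcomes of the session. With ``count_unresolved`` the cards
    revealed on a missed-bet trial still advance the outcome (denominator)
    count; no win is ever credited for them.
    """
    rows = []
    states: dict[int, LearningState] = {}
    for t in trials:
        state = states.get(t.session, LearningState())
        row = {
            "session": t.session,
            "index": t.index,
            "bet": t.bet if t.bet is not None else "",
            "card1": t.card1,
            "card2": t.card2,
            "outcome": t.outcome if t.outcome is not None else "",
            "p_win_learned": state.p_win_learned,
        }
        if t.resolved:
            dv = decision_variables(t, deck, stake, accuracy_sign)
            row.update(
                p_win=dv.p_win,
                reward_prediction=dv.reward_prediction,
                confidence=dv.confidence,
                surprise=dv.surprise,
                accuracy=dv.accuracy,
                rpe=dv.rpe,
            )
            state = dirichlet_update(state, t.outcome)
        else:
            row.update(
                p_win=np.nan,
                reward_prediction=np.nan,
                confidence=np.nan,
                surprise=np.nan,
                accuracy=np.nan,
                rpe=np.nan,
            )
            if count_unresolved:
                state = LearningState(state.wins_so_far, state.outcomes_so_far + 1)
        states[t.session] = state
        rows.append(row)
    cols = [
        "session",
        "index",
        "bet",
        "card1",
        "card2",
        "outcome",
        "p_win",
        "reward_prediction",
        "confidence",
        "surprise",
        "accuracy",
        "rpe",
        "p_win_learned",
    ]
    return pd.DataFrame(rows, columns=cols)


def write_variables_tsv(variables: pd.DataFrame, path) -> None:
    """Write the decision-variable table as TSV, floats at 15 significant digits."""
    variables.to_csv(path, sep="\t", index=False, float_format="%.15g")
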