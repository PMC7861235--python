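"""Behavioral quality control and the bet-strategy statistic.

Three per-session quantities: an error rate over response opportunities
(missed bets, missed reports, incorrect reports; sessions above 30% are
flagged for exclusion), a win-stay/lose-shift strategy tally, and the
monetary payout under the task's endowment/stake/penalty scheme.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .task import LOSS, WIN, Bet, Outcome, Trial

__all__ = [
    "SessionSummary",
    "EXCLUSION_ERROR_RATE",
    "error_rate",
    "strategy_tally",
    "payout",
    "summarize_session",
    "summarize_subject",
    "write_summary_tsv",
]

#: Error-rate threshold above which a participant is excluded from analysis.
EXCLUSION_ERROR_RATE = 0.30

#: Task defaults: initial endowment, per-bet stake, per-error penalty (CHF).
ENDOWMENT = 25.0
STAKE = 1.0
PENALTY = 0.25


@dataclass(frozen=True)
class SessionSummary:
    subject: int
    session: int
    n_trials: int
    missed_bets: int
    missed_reports: int
    incorrect_reports: int
    error_rate: float
    excluded: bool
    payout: float
    strategic_count: int
    nonstrategic_count: int
    higher_bet_count: int


def _error_counts(trials: Sequence[Trial]) -> tuple[int, int, int]:
    missed_bets = sum(not t.bet_placed for t in trials)
    missed_reports = sum(t.bet_placed and not t.report_made for t in trials)
    incorrect_reports = sum(
        t.bet_placed and t.report_made and not t.report_correct for t in trials
    )
    return missed_bets, missed_reports, incorrect_reports


def error_rate(trials: Sequence[Trial]) -> float:
    """Errors per response opportunity (one bet + one report per trial)."""
    if not trials:
        raise ValueError("error rate of an empty trial sequence is undefined")
    missed_bets, missed_reports, incorrect_reports = _error_counts(trials)
    return (missed_bets + missed_reports + incorrect_reports) / (2 * len(trials))


def strategy_tally(
    bets: Sequence[Bet | None], outcomes: Sequence[Outcome | None]
) -> tuple[int, int]:
    """Count strategic vs non-strategic bet transitions.

    A transition is *strategic* when the agent switches the bet after a loss
    or repeats it after a win (win-stay/lose-shift). Transitions whose
    predecessor bet or outcome is undefined (missed bet) are dropped.
    """
    if len(bets) != len(outcomes):
        raise ValueError(
            f"bets ({len(bets)}) and outcomes ({len(outcomes)}) differ in length"
        )
    if len(bets) < 2:
        raise ValueError("need at least two trials to tally transitions")
    strategic = nonstrategic = 0
    for t in range(1, len(bets)):
        prev_bet, prev_out, cur_bet = bets[t - 1], outcomes[t - 1], bets[t]
        if prev_bet is None or prev_out is None or cur_bet is None:
            continue
        if prev_out == LOSS:
            is_strategic = cur_bet != prev_bet
        else:
            is_strategic = cur_bet == prev_bet
        if is_strategic:
            strategic += 1
        else:
            nonstrategic += 1
    return strategic, nonstrategic


def payout(
    trials: Sequence[Trial],
    endowment: float = ENDOWMENT,
    stake: float = STAKE,
    penalty: float = PENALTY,
) -> float:
    """Endowment plus ±stake per resolved bet, minus penalties for errors."""
    missed_bets, missed_reports, incorrect_reports = _error_counts(trials)
    gains = sum(
        (stake if t.outcome == WIN else -stake) for t in trials if t.resolved
    )
    return endowment + gains - penalty * (missed_bets + missed_reports + incorrect_reports)


def summarize_session(
    trials: Sequence[Trial], subject: int = 0, session: int | None = None
) -> SessionSummary:
    """Full behavioral summary of one session's trials."""
    if not trials:
        raise ValueError("cannot summarize an empty session")
    missed_bets, missed_reports, incorrect_reports = _error_counts(trials)
    rate = error_rate(trials)
    strategic, nonstrategic = strategy_tally(
        [t.bet for t in trials], [t.outcome for t in trials]
    )
    return SessionSummary(
        subject=subject,
        session=session if session is not None else trials[0].session,
        n_trials=len(trials),
        missed_bets=missed_bets,
        missed_reports=missed_reports,
        incorrect_reports=incorrect_reports,
        error_rate=rate,
        excluded=rate > EXCLUSION_ERROR_RATE,
        payout=payout(trials),
        strategic_count=strategic,
        nonstrategic_count=nonstrategic,
        higher_bet_count=sum(t.bet == "higher" for t in trials),
    )


def summarize_subject(trials: Sequence[Trial], subject: int = 0) -> pd.DataFrame:
    """One summary row per session, in session order."""
    sessions = sorted({t.session for t in trials})
    rows = [
        summarize_session(
            [t for t in trials if t.session == s], subject=subject, session=s
        )
        for s in sessions
    ]
    return pd.DataFrame([r.__dict__ for r in rows])


def write_summary_tsv(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, sep="\t", index=False, float_format="%.15g")
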