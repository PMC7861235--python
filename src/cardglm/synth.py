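"""Synthetic task sequences, agents, and BOLD volumes with known ground truth.

The generator mirrors the study design: ordered card pairs drawn without
replacement from the 90 possible pairs of a 10-card deck (3 sessions of 30
trials use each pair exactly once), 25 s trials with the bet cue at 0 s,
card 1 at 4 s, card 2 at 9.5 s (the fixed 5.5 s gap), the report cue at
15 s, and a uniform 2–5 s inter-trial jitter. Simulated BOLD is the design
matrix times planted voxelwise effect maps plus slow cosine drift (periods
above the 128 s high-pass cutoff) and stationary AR(1) noise, so the whole
analysis chain can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .design import DesignMatrix
from .task import HIGHER, LOSS, LOWER, WIN, Deck, Trial, true_outcome

__all__ = [
    "TimingTemplate",
    "GroundTruth",
    "BoldDataset",
    "generate_trial_sequence",
    "simulate_agent",
    "simulate_bold",
    "write_events_tsv",
    "read_events_tsv",
    "DEFAULT_TR",
]

#: Repetition time of the emulated acquisition (seconds).
DEFAULT_TR = 2.72

Policy = Literal["random", "win_stay_lose_shift", "higher_biased"]


@dataclass(frozen=True)
class TimingTemplate:
    """Within-trial event offsets (seconds from trial start) and trial pacing."""

    bet_cue_offset: float = 0.0
    card1_offset: float = 4.0
    card_gap: float = 5.5
    report_offset_after_card2: float = 5.5
    trial_length: float = 25.0
    jitter_range: tuple[float, float] = (2.0, 5.0)

    def __post_init__(self) -> None:
        needed = self.card1_offset + self.card_gap + self.report_offset_after_card2
        if self.trial_length < needed:
            raise ValueError(
                f"trial_length {self.trial_length} s too short for the event "
                f"offsets (needs ≥ {needed} s)"
            )
        if self.jitter_range[0] > self.jitter_range[1]:
            raise ValueError("jitter_range must be (low, high)")


@dataclass
class GroundTruth:
    """Planted voxelwise effects and noise model for a BOLD simulation.

    ``beta_maps`` maps design column names to 3D amplitude maps (arbitrary
    units); unnamed columns have zero effect. Noise is AR(1) with innovation
    standard deviation ``noise_sd``; drift is a random-phase sum of cosines
    with the given periods (seconds), all above the high-pass cutoff.
    """

    beta_maps: dict[str, np.ndarray] = field(default_factory=dict)
    ar_coefficient: float = 0.2
    noise_sd: float = 1.0
    drift_amplitude: float = 0.0
    drift_periods: tuple[float, ...] = (384.0, 256.0, 160.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.ar_coefficient < 1.0:
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class BoldDataset:
    """4D voxel data (x, y, z, t) with a brain mask and repetition time."""

    data: np.ndarray
    mask: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, t)")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must match the spatial grid")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    def timeseries(self) -> np.ndarray:
        """In-mask time series as a (t, n_voxels) array."""
        return self.data[self.mask].T

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), np.eye(4))
        img.header.set_zooms((1.0, 1.0, 1.0, self.tr))
        return img

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image, mask: np.ndarray) -> "BoldDataset":
        tr = float(img.header.get_zooms()[3])
        return cls(data=np.asarray(img.dataobj, dtype=float), mask=mask, tr=tr)


def generate_trial_sequence(
    n_sessions: int = 3,
    trials_per_session: int = 30,
    deck: Deck = Deck(),
    seed: int = 0,
    template: TimingTemplate = TimingTemplate(),
) -> list[Trial]:
    """Sample ordered card pairs without replacement and lay down onsets.

    The ``n_sessions * trials_per_session`` pairs are drawn without
    replacement from all ``|deck|·(|deck|−1)`` ordered pairs; the default
    3 × 30 on a 10-card deck uses every pair exactly once. Onsets restart at
    0 s in each session; successive trials are separated by the trial length
    plus a uniform jitter. Bets are left unset (see :func:`simulate_agent`).
    """
    n_total = n_sessions * trials_per_session
    pairs = [(a, b) for a in deck.values for b in deck.values if a != b]
    if n_total > len(pairs):
        raise ValueError(
            f"{n_total} trials requested but only {len(pairs)} ordered pairs exist"
        )
    rng = np.random.default_rng(seed)
    chosen = [pairs[i] for i in rng.permutation(len(pairs))[:n_total]]
    trials: list[Trial] = []
    for s in range(n_sessions):
        t0 = 0.0
        for i in range(trials_per_session):
            card1, card2 = chosen[s * trials_per_session + i]
            onset_card1 = t0 + template.card1_offset
            onset_card2 = onset_card1 + template.card_gap
            trials.append(
                Trial(
                    session=s,
                    index=i,
                    card1=card1,
                    card2=card2,
                    bet=None,
                    outcome=None,
                    bet_placed=False,
                    report_made=False,
                    report_correct=False,
                    onset_bet_cue=t0 + template.bet_cue_offset,
                    onset_card1=onset_card1,
                    onset_card2=onset_card2,
                    onset_report_cue=onset_card2 + template.report_offset_after_card2,
                )
            )
            t0 += template.trial_length + rng.uniform(*template.jitter_range)
    return trials


def simulate_agent(
    trials: Sequence[Trial],
    policy: Policy = "random",
    p_miss: float = 0.0,
    seed: int = 0,
    higher_bias: float = 0.7,
) -> list[Trial]:
    """Fill in bets, outcomes, responses and reaction times for an agent.

    Policies: ``random`` (fair coin), ``higher_biased`` (P(higher) =
    ``higher_bias``), ``win_stay_lose_shift`` (repeat the previous bet after
    a win, switch after a loss; random when no predecessor exists). Bets and
    reports are each missed with probability ``p_miss``, and a made report
    is incorrect with the same probability. Reaction times are lognormal
    (median ≈ 0.7 s).
    """
    if not 0.0 <= p_miss < 1.0:
        raise ValueError("p_miss must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    out: list[Trial] = []
    prev_bet: str | None = None
    prev_outcome: str | None = None
    prev_session: int | None = None
    for t in trials:
        if t.session != prev_session:
            prev_bet = prev_outcome = None
            prev_session = t.session
        bet_placed = rng.random() >= p_miss
        if not bet_placed:
            out.append(
                Trial(
                    session=t.session,
                    index=t.index,
                    card1=t.card1,
                    card2=t.card2,
                    bet=None,
                    outcome=None,
                    bet_placed=False,
                    report_made=False,
                    report_correct=False,
                    onset_bet_cue=t.onset_bet_cue,
                    onset_card1=t.onset_card1,
                    onset_card2=t.onset_card2,
                    onset_report_cue=t.onset_report_cue,
                )
            )
            prev_bet = prev_outcome = None
            continue
        if policy == "random":
            bet = HIGHER if rng.random() < 0.5 else LOWER
        elif policy == "higher_biased":
            bet = HIGHER if rng.random() < higher_bias else LOWER
        elif policy == "win_stay_lose_shift":
            if prev_bet is None or prev_outcome is None:
                bet = HIGHER if rng.random() < 0.5 else LOWER
            elif prev_outcome == WIN:
                bet = prev_bet
            else:
                bet = LOWER if prev_bet == HIGHER else HIGHER
        else:
            raise ValueError(f"unknown policy {policy!r}")
        outcome = true_outcome(t.card1, t.card2, bet)
        report_made = rng.random() >= p_miss
        report_correct = bool(report_made and rng.random() >= p_miss)
        out.append(
            Trial(
                session=t.session,
                index=t.index,
                card1=t.card1,
                card2=t.card2,
                bet=bet,
                outcome=outcome,
                bet_placed=True,
                report_made=report_made,
                report_correct=report_correct,
                onset_bet_cue=t.onset_bet_cue,
                onset_card1=t.onset_card1,
                onset_card2=t.onset_card2,
                onset_report_cue=t.onset_report_cue,
                rt_bet=float(rng.lognormal(np.log(0.7), 0.3)),
                rt_report=float(rng.lognormal(np.log(0.7), 0.3))
                if report_made
                else None,
            )
        )
        prev_bet, prev_outcome = bet, outcome
    return out


def _ar1_noise(
    rng: np.random.Generator, phi: float, sd: float, shape: tuple[int, int]
) -> np.ndarray:
    """Stationary AR(1) series, innovations N(0, sd²); shape = (t, voxels)."""
    t, v = shape
    x = np.empty((t, v))
    innov = rng.normal(0.0, sd, size=(t, v))
    x[0] = innov[0] / np.sqrt(1.0 - phi**2) if abs(phi) > 0 else innov[0]
    for i in range(1, t):
        x[i] = phi * x[i - 1] + innov[i]
    return x


def simulate_bold(
    design: DesignMatrix,
    truth: GroundTruth,
    grid: tuple[int, int, int] = (16, 16, 8),
    mask: np.ndarray | None = None,
) -> BoldDataset:
    """Forward-model BOLD: y = X·β(voxel) + drift + AR(1) noise, per voxel."""
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    if mask.shape != grid:
        raise ValueError(f"mask shape {mask.shape} does not match grid {grid}")
    for name, bmap in truth.beta_maps.items():
        if name not in design.column_names:
            raise ValueError(f"beta map {name!r} is not a design column")
        if bmap.shape != grid:
            raise ValueError(f"beta map {name!r} shape {bmap.shape} != grid {grid}")

    t = design.n_frames
    n_vox = int(mask.sum())
    signal = np.zeros((t, n_vox))
    for name, bmap in truth.beta_maps.items():
        signal += np.outer(design.column(name), bmap[mask])

    rng = np.random.default_rng(truth.seed)
    times = design.frame_times
    drift = np.zeros((t, n_vox))
    if truth.drift_amplitude > 0:
        for period in truth.drift_periods:
            phases = rng.uniform(0, 2 * np.pi, size=n_vox)
            drift += truth.drift_amplitude * np.cos(
                2 * np.pi * times[:, None] / period + phases[None, :]
            )
    noise = (
        _ar1_noise(rng, truth.ar_coefficient, truth.noise_sd, (t, n_vox))
        if truth.noise_sd > 0
        else np.zeros((t, n_vox))
    )

    data = np.zeros(grid + (t,))
    data[mask] = (signal + drift + noise).T
    return BoldDataset(data=data, mask=mask, tr=design.tr)


# -- events.tsv I/O ----------------------------------------------------------

_EVENT_COLS = [
    "onset",
    "duration",
    "trial_type",
    "session",
    "trial_index",
    "bet",
    "card1",
    "card2",
    "outcome",
    "bet_placed",
    "report_made",
    "report_correct",
    "response_time",
]


def write_events_tsv(trials: Sequence[Trial], path) -> None:
    """Write trials as a BIDS-style events table (four event rows per trial)."""
    rows = []
    for t in trials:
        common = {
            "session": t.session,
            "trial_index": t.index,
            "bet": t.bet or "n/a",
            "card1": t.card1,
            "card2": t.card2,
            "outcome": t.outcome or "n/a",
            "bet_placed": int(t.bet_placed),
            "report_made": int(t.report_made),
            "report_correct": int(t.report_correct),
        }
        for trial_type, onset, duration, rt in [
            ("bet_cue", t.onset_bet_cue, 0.0, t.rt_bet),
            ("card1", t.onset_card1, 5.5, None),
            ("card2", t.onset_card2, 5.5, None),
            ("report_cue", t.onset_report_cue, 0.0, t.rt_report),
        ]:
            rows.append(
                {
                    "onset": onset,
                    "duration": duration,
                    "trial_type": trial_type,
                    "response_time": rt if rt is not None else "n/a",
                    **common,
                }
            )
    pd.DataFrame(rows, columns=_EVENT_COLS).to_csv(
        path, sep="\t", index=False, float_format="%.15g"
    )


def read_events_tsv(path) -> list[Trial]:
    """Reconstruct trials from a BIDS-style events table written by this package."""
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    trials = []
    for (session, index), grp in df.groupby(["session", "trial_index"], sort=True):
        by_type = grp.set_index("trial_type")
        first = grp.iloc[0]
        bet = first["bet"] if isinstance(first["bet"], str) else None
        outcome = first["outcome"] if isinstance(first["outcome"], str) else None
        rt_bet = by_type.loc["bet_cue", "response_time"]
        rt_report = by_type.loc["report_cue", "response_time"]
        trials.append(
            Trial(
                session=int(session),
                index=int(index),
                card1=int(first["card1"]),
                card2=int(first["card2"]),
                bet=bet,
                outcome=outcome,
                bet_placed=bool(first["bet_placed"]),
                report_made=bool(first["report_made"]),
                report_correct=bool(first["report_correct"]),
                onset_bet_cue=float(by_type.loc["bet_cue", "onset"]),
                onset_card1=float(by_type.loc["card1", "onset"]),
                onset_card2=float(by_type.loc["card2", "onset"]),
                onset_report_cue=float(by_type.loc["report_cue", "onset"]),
                rt_bet=None if pd.isna(rt_bet) else float(rt_bet),
                rt_report=None if pd.isna(rt_report) else float(rt_report),
            )
        )
    trials.sort(key=lambda t: (t.session, t.index))
    return trials
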