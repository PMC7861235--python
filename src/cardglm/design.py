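"""First-level design construction for the card task.

Builds, per session, the time × regressor matrix of the model-based GLM:

- ``sound``: Dirac events at the bet-cue and report-cue onsets,
- ``motor``: Dirac events at the response onsets,
- ``card1`` 5.5 s boxcar, parametrically modulated by reward prediction
  then confidence,
- ``card2`` 5.5 s boxcar, modulated by reward prediction error, then
  stimulus-bound surprise, then accuracy,
- 6 motion nuisance columns, a discrete-cosine high-pass basis
  (128 s cutoff), and a constant.

Modulator amplitudes are mean-centered across the session's trials before
convolution with the canonical double-gamma HRF on an oversampled grid.
Within each onset group the columns are then serially orthogonalized
(boxcar → first modulator → ...) so each modulator carries only variance
unexplained by its predecessors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .task import Trial

__all__ = [
    "RegressorSpec",
    "DesignMatrix",
    "canonical_hrf",
    "build_design",
    "serial_orthogonalize",
    "highpass_dct",
    "CARD_DURATION",
]

#: Duration of the card boxcar regressors (seconds): the card1→card2 gap.
CARD_DURATION = 5.5

#: Canonical HRF shape: response peak, undershoot trough (s), peak:undershoot
#: amplitude ratio, kernel length (s).
HRF_PEAK = 6.0
HRF_UNDERSHOOT = 16.0
HRF_RATIO = 6.0
HRF_LENGTH = 32.0


@dataclass
class RegressorSpec:
    """Event-level description of one onset regressor before convolution."""

    name: str
    onsets: list[float]
    durations: list[float]
    modulators: list[tuple[str, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.onsets) != len(self.durations):
            raise ValueError("onsets and durations must have equal length")
        if sorted(self.onsets) != list(self.onsets):
            raise ValueError("onsets must be sorted")
        for mname, values in self.modulators:
            if len(values) != len(self.onsets):
                raise ValueError(f"modulator {mname!r} length mismatch")
            if not np.all(np.isfinite(values)):
                raise ValueError(f"modulator {mname!r} has non-finite values")


@dataclass
class DesignMatrix:
    """Sampled design with named columns and orthogonalization bookkeeping.

    ``groups`` maps each onset regressor to the ordered column names of its
    serial-orthogonalization group (boxcar first, then modulators).
    """

    matrix: np.ndarray
    column_names: list[str]
    tr: float
    frame_times: np.ndarray
    groups: dict[str, list[str]] = field(default_factory=dict)
    orthogonalized: bool = False

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.column_names):
            raise ValueError("column_names do not match matrix width")
        if self.matrix.shape[0] != len(self.frame_times):
            raise ValueError("frame_times do not match matrix height")

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.column_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.column_names, index=self.frame_times)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.15g")


def _gamma_mode_pdf(t: np.ndarray, mode: float, dispersion: float = 1.0) -> np.ndarray:
    # gamma density parameterized by its mode: shape = mode/dispersion + 1
    return stats.gamma.pdf(t, mode / dispersion + 1.0, scale=dispersion)


def canonical_hrf(tr: float, oversampling: int = 16) -> np.ndarray:
    """Canonical double-gamma HRF sampled at dt = tr / oversampling.

    Difference of two gamma densities with modes at the response peak (6 s)
    and the undershoot trough (16 s), undershoot scaled to 1/6 of the peak;
    the kernel is peak-normalized and truncated at 32 s.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    dt = tr / oversampling
    t = np.arange(0.0, HRF_LENGTH, dt)
    h = _gamma_mode_pdf(t, HRF_PEAK) - _gamma_mode_pdf(t, HRF_UNDERSHOOT) / HRF_RATIO
    return h / h.max()


def _sample_column(
    events: Sequence[tuple[float, float, float]],
    hrf: np.ndarray,
    dt: float,
    frame_times: np.ndarray,
    n_fine: int,
) -> np.ndarray:
    """Convolve (onset, duration, amplitude) events with the HRF; sample at frames."""
    fine = np.zeros(n_fine)
    for onset, duration, amplitude in events:
        i0 = int(round(onset / dt))
        if i0 >= n_fine:
            raise ValueError(f"onset {onset} s beyond session end")
        if duration == 0.0:
            fine[i0] += amplitude
        else:
            i1 = min(int(round((onset + duration) / dt)), n_fine)
            fine[i0:i1] += amplitude
    conv = np.convolve(fine, hrf)[:n_fine]
    idx = np.clip(np.round(frame_times / dt).astype(int), 0, n_fine - 1)
    return conv[idx]


def _trial_regressors(
    trials: Sequence[Trial], variables: pd.DataFrame
) -> list[RegressorSpec]:
    """Onset regressors of one session in the model's canonical order."""
    sound_onsets = sorted(
        [t.onset_bet_cue for t in trials] + [t.onset_report_cue for t in trials]
    )
    motor_onsets = sorted(
        [t.onset_bet_cue + t.rt_bet for t in trials if t.bet_placed and t.rt_bet is not None]
        + [
            t.onset_report_cue + t.rt_report
            for t in trials
            if t.report_made and t.rt_report is not None
        ]
    )
    resolved = [(i, t) for i, t in enumerate(trials) if t.resolved]
    if not resolved:
        raise ValueError("session contains no resolved trials")
    idx = [i for i, _ in resolved]
    card1_onsets = [t.onset_card1 for _, t in resolved]
    card2_onsets = [t.onset_card2 for _, t in resolved]
    v = variables.iloc[idx]

    def centered(col: str) -> np.ndarray:
        x = np.asarray(v[col], dtype=float)
        return x - x.mean()

    specs = [
        RegressorSpec("sound", sound_onsets, [0.0] * len(sound_onsets)),
        RegressorSpec(
            "card1",
            card1_onsets,
            [CARD_DURATION] * len(card1_onsets),
            modulators=[
                ("reward_prediction", centered("reward_prediction")),
                ("confidence", centered("confidence")),
            ],
        ),
        RegressorSpec(
            "card2",
            card2_onsets,
            [CARD_DURATION] * len(card2_onsets),
            modulators=[
                ("rpe", centered("rpe")),
                ("surprise", centered("surprise")),
                ("accuracy", centered("accuracy")),
            ],
        ),
    ]
    if motor_onsets:
        specs.insert(1, RegressorSpec("motor", motor_onsets, [0.0] * len(motor_onsets)))
    return specs


def build_design(
    trials: Sequence[Trial],
    variables: pd.DataFrame,
    tr: float,
    n_frames: int,
    motion: np.ndarray | None = None,
    cutoff: float | None = 128.0,
    oversampling: int = 16,
    orthogonalize: bool = False,
) -> DesignMatrix:
    """Build one session's design matrix.

    ``trials`` and ``variables`` must be row-aligned (as produced by
    :func:`cardglm.task.compute_decision_variables` on the same trials), with
    onsets relative to this session's first frame. ``motion`` is an optional
    (n_frames, 6) nuisance array. ``cutoff`` adds a discrete-cosine high-pass
    basis (None disables it). The constant column comes last.
    """
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (n_frames, 6):
            raise ValueError(f"motion must be ({n_frames}, 6), got {motion.shape}")
    if len(variables) != len(trials):
        raise ValueError("variables table must be row-aligned with trials")

    hrf = canonical_hrf(tr, oversampling)
    dt = tr / oversampling
    frame_times = np.arange(n_frames) * tr
    n_fine = n_frames * oversampling

    columns: list[np.ndarray] = []
    names: list[str] = []
    groups: dict[str, list[str]] = {}
    for spec in _trial_regressors(trials, variables):
        base_events = [(o, d, 1.0) for o, d in zip(spec.onsets, spec.durations)]
        columns.append(_sample_column(base_events, hrf, dt, frame_times, n_fine))
        names.append(spec.name)
        group = [spec.name]
        for mod_name, values in spec.modulators:
            events = [
                (o, d, a)
                for o, d, a in zip(spec.onsets, spec.durations, values)
            ]
            columns.append(_sample_column(events, hrf, dt, frame_times, n_fine))
            col_name = f"{spec.name}x{mod_name}"
            names.append(col_name)
            group.append(col_name)
        if spec.modulators:
            groups[spec.name] = group

    if motion is not None:
        for j in range(6):
            columns.append(motion[:, j])
            names.append(f"motion_{j + 1}")
    if cutoff is not None:
        dct = highpass_dct(n_frames, tr, cutoff)
        for j in range(dct.shape[1]):
            columns.append(dct[:, j])
            names.append(f"drift_{j + 1}")
    columns.append(np.ones(n_frames))
    names.append("constant")

    design = DesignMatrix(
        matrix=np.column_stack(columns),
        column_names=names,
        tr=tr,
        frame_times=frame_times,
        groups=groups,
    )
    return serial_orthogonalize(design) if orthogonalize else design


def serial_orthogonalize(
    design: DesignMatrix, groups: dict[str, list[str]] | None = None
) -> DesignMatrix:
    """Serially orthogonalize modulator columns within each onset group.

    Each column is residualized against all preceding columns of its group,
    in order; earlier columns (the boxcar first) are left untouched. Columns
    outside every group (sound, motor, nuisance, constant) are unchanged.
    """
    groups = design.groups if groups is None else groups
    matrix = design.matrix.copy()
    for group_cols in groups.values():
        idx = [design.column_names.index(c) for c in group_cols]
        for k in range(1, len(idx)):
            preds = matrix[:, idx[:k]]
            y = matrix[:, idx[k]]
            if np.linalg.matrix_rank(preds) < preds.shape[1]:
                warnings.warn(
                    f"rank-deficient predecessors for column "
                    f"{group_cols[k]!r}; skipping its orthogonalization",
                    stacklevel=2,
                )
                continue
            coef, *_ = np.linalg.lstsq(preds, y, rcond=None)
            matrix[:, idx[k]] = y - preds @ coef
    return DesignMatrix(
        matrix=matrix,
        column_names=list(design.column_names),
        tr=design.tr,
        frame_times=design.frame_times,
        groups={k: list(v) for k, v in groups.items()},
        orthogonalized=True,
    )


def highpass_dct(n_frames: int, tr: float, cutoff: float = 128.0) -> np.ndarray:
    """Discrete-cosine high-pass basis: all components with period > cutoff.

    Component k (k ≥ 1) has period 2·n_frames·tr / k; the constant (k = 0)
    is excluded. Columns are unit-norm and mutually orthogonal. Returns an
    (n_frames, K) array, possibly with K = 0.
    """
    if cutoff <= 2 * tr:
        raise ValueError("cutoff must exceed twice the TR")
    span = n_frames * tr
    n = np.arange(n_frames)
    cols = []
    k = 1
    while 2.0 * span / k > cutoff:
        basis = np.cos(np.pi * (2 * n + 1) * k / (2.0 * n_frames))
        cols.append(basis * np.sqrt(2.0 / n_frames))
        k += 1
    if not cols:
        return np.empty((n_frames, 0))
    return np.column_stack(cols)
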