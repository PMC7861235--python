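"""End-to-end simulation and validation pipelines.

Chains the package's stages — trial generation, agent simulation, decision
variables, design construction, BOLD simulation, first-level GLM, group
permutation inference — into parameter-recovery and calibration
experiments. These are the package's own evidence that the analysis chain
is correct: planted effects must be recovered, and null data must produce
false positives at the nominal rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignMatrix, build_design, serial_orthogonalize
from .glm import contrast_t, contrast_vector, fit_first_level, group_permutation
from .synth import (
    DEFAULT_TR,
    BoldDataset,
    GroundTruth,
    TimingTemplate,
    generate_trial_sequence,
    simulate_agent,
    simulate_bold,
)
from .task import Deck, Trial, compute_decision_variables

__all__ = [
    "CohortSpec",
    "default_effect_blocks",
    "simulate_subject",
    "subject_contrast_maps",
    "recovery_experiment",
    "first_level_null_calibration",
    "fwe_calibration",
]

#: Design columns carrying the planted effects of interest.
EFFECT_COLUMNS = ("card1xconfidence", "card2xsurprise", "card2xaccuracy")


@dataclass
class CohortSpec:
    """Study-scale defaults for a synthetic cohort.

    Mirrors the emulated study: 3 sessions of 30 trials (all 90 ordered card
    pairs exactly once), TR 2.72 s, a small response-error rate, AR(1) noise
    and slow drift below the 128 s high-pass cutoff.
    """

    n_subjects: int = 25
    n_sessions: int = 3
    trials_per_session: int = 30
    tr: float = DEFAULT_TR
    grid: tuple[int, int, int] = (16, 16, 8)
    p_miss: float = 0.05
    higher_bias: float = 0.7
    noise_sd: float = 1.0
    ar_coefficient: float = 0.2
    drift_amplitude: float = 1.0
    snr: float = 3.0
    cutoff: float = 128.0
    template: TimingTemplate = field(default_factory=TimingTemplate)
    deck: Deck = field(default_factory=Deck)


def default_effect_blocks(
    grid: tuple[int, int, int],
) -> dict[str, tuple[slice, slice, slice]]:
    """Four disjoint 3×3×3 voxel blocks: one per effect plus a null block."""
    s = (slice(1, 4), slice(5, 8), slice(9, 12), slice(12, 15))
    return {
        "card1xconfidence": (s[0], slice(1, 4), slice(2, 5)),
        "card2xsurprise": (s[1], slice(1, 4), slice(2, 5)),
        "card2xaccuracy": (s[2], slice(1, 4), slice(2, 5)),
        "null": (s[3], slice(5, 8), slice(2, 5)),
    }


def _session_frames(trials: list[Trial], tr: float, tail: float = 20.0) -> int:
    return int(np.ceil((max(t.onset_report_cue for t in trials) + tail) / tr))


def simulate_subject(
    spec: CohortSpec, seed: int, beta_maps: dict[str, np.ndarray] | None = None
) -> list[tuple[BoldDataset, DesignMatrix, DesignMatrix]]:
    """Simulate one subject: per session (BOLD, raw design, orthogonalized design).

    BOLD is generated from the *raw* (un-orthogonalized) design so the data
    follow the natural forward model; fitting uses the serially
    orthogonalized design, exactly as the analysis would on real data.
    """
    rng = np.random.default_rng(seed)
    trials = generate_trial_sequence(
        spec.n_sessions,
        spec.trials_per_session,
        spec.deck,
        seed=int(rng.integers(2**31)),
        template=spec.template,
    )
    trials = simulate_agent(
        trials,
        policy="higher_biased",
        p_miss=spec.p_miss,
        seed=int(rng.integers(2**31)),
        higher_bias=spec.higher_bias,
    )
    variables = compute_decision_variables(trials, spec.deck)
    sessions = []
    for s in range(spec.n_sessions):
        s_idx = [i for i, t in enumerate(trials) if t.session == s]
        s_trials = [trials[i] for i in s_idx]
        s_vars = variables.iloc[s_idx].reset_index(drop=True)
        n_frames = _session_frames(s_trials, spec.tr)
        raw = build_design(
            s_trials, s_vars, spec.tr, n_frames, cutoff=spec.cutoff
        )
        orth = serial_orthogonalize(raw)
        truth = GroundTruth(
            beta_maps=beta_maps or {},
            ar_coefficient=spec.ar_coefficient,
            noise_sd=spec.noise_sd,
            drift_amplitude=spec.drift_amplitude,
            seed=int(rng.integers(2**31)),
        )
        bold = simulate_bold(raw, truth, grid=spec.grid)
        sessions.append((bold, raw, orth))
    return sessions


def subject_contrast_maps(
    sessions: list[tuple[BoldDataset, DesignMatrix, DesignMatrix]],
    columns: tuple[str, ...] = EFFECT_COLUMNS,
) -> dict[str, np.ndarray]:
    """Fit each session and average contrast effect maps across sessions."""
    per_column: dict[str, list[np.ndarray]] = {c: [] for c in columns}
    for bold, _raw, orth in sessions:
        result = fit_first_level(bold, orth)
        for c in columns:
            w = contrast_vector(result.column_names, c)
            per_column[c].append(result.effect_volume(w))
    return {c: np.mean(np.stack(maps), axis=0) for c, maps in per_column.items()}


def recovery_experiment(
    seed: int,
    n_subjects: int = 12,
    spec: CohortSpec | None = None,
    n_permutations: int = 512,
    variance_smoothing_fwhm: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Plant block effects, run the full chain, and score recovery.

    Each effect column gets a disjoint 3×3×3 block of amplitude
    ``snr × noise_sd``; a fourth block stays null. Returns one row per
    effect with the FWE-thresholded sensitivity inside its block and the
    number of significant voxels inside the null block.
    """
    spec = spec or CohortSpec(n_subjects=n_subjects)
    blocks = default_effect_blocks(spec.grid)
    beta_maps = {}
    for name in EFFECT_COLUMNS:
        bmap = np.zeros(spec.grid)
        bmap[blocks[name]] = spec.snr * spec.noise_sd
        beta_maps[name] = bmap

    rng = np.random.default_rng(seed)
    subject_maps: dict[str, list[np.ndarray]] = {c: [] for c in EFFECT_COLUMNS}
    for _ in range(n_subjects):
        sessions = simulate_subject(spec, int(rng.integers(2**31)), beta_maps)
        maps = subject_contrast_maps(sessions)
        for c in EFFECT_COLUMNS:
            subject_maps[c].append(maps[c])

    mask = np.ones(spec.grid, dtype=bool)
    rows = []
    for c in EFFECT_COLUMNS:
        group = group_permutation(
            np.stack(subject_maps[c]),
            mask,
            n_permutations=n_permutations,
            variance_smoothing_fwhm=variance_smoothing_fwhm,
            alpha=alpha,
            seed=int(rng.integers(2**31)),
        )
        sig = np.zeros(spec.grid, dtype=bool)
        sig[mask] = group.significant
        block = np.zeros(spec.grid, dtype=bool)
        block[blocks[c]] = True
        null_block = np.zeros(spec.grid, dtype=bool)
        null_block[blocks["null"]] = True
        rows.append(
            {
                "effect": c,
                "sensitivity": float(sig[block].mean()),
                "null_block_false_positives": int(sig[null_block].sum()),
                "n_block_voxels": int(block.sum()),
                "threshold": group.threshold,
            }
        )
    return pd.DataFrame(rows)


def first_level_null_calibration(
    seed: int,
    n_voxels: int = 1000,
    n_frames: int = 200,
    column: str = "card2xsurprise",
) -> float:
    """Fraction of null voxels whose first-level t exceeds the 0.975 quantile.

    White-noise data with no effects are fitted with a genuine task design;
    under a correct fit and degrees-of-freedom accounting the one-sided
    exceedance rate is 2.5%.
    """
    spec = CohortSpec()
    rng = np.random.default_rng(seed)
    trials = generate_trial_sequence(
        n_sessions=1, trials_per_session=18, seed=int(rng.integers(2**31))
    )
    trials = simulate_agent(trials, policy="random", p_miss=0.0,
                            seed=int(rng.integers(2**31)))
    variables = compute_decision_variables(trials)
    design = serial_orthogonalize(
        build_design(trials, variables, spec.tr, n_frames, cutoff=spec.cutoff)
    )
    grid = (n_voxels, 1, 1)
    mask = np.ones(grid, dtype=bool)
    data = np.zeros(grid + (n_frames,))
    data[mask] = rng.normal(size=(n_voxels, n_frames))
    bold = BoldDataset(data=data, mask=mask, tr=spec.tr)
    result = fit_first_level(bold, design)
    _, t = contrast_t(result, contrast_vector(result.column_names, column))
    crit = stats.t.ppf(0.975, result.dof)
    return float(np.mean(t > crit))


def fwe_calibration(
    seed: int,
    n_cohorts: int = 200,
    n_subjects: int = 8,
    grid: tuple[int, int, int] = (10, 10, 10),
    n_permutations: int = 500,
    variance_smoothing_fwhm: float = 2.0,
    alpha: float = 0.05,
) -> float:
    """Family-wise false-positive rate of the permutation test on null cohorts.

    Each cohort is n_subjects zero-mean Gaussian maps; a cohort counts as a
    family-wise false positive when any voxel is FWE-significant at alpha.
    Should match alpha up to binomial sampling error.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_cohorts):
        maps = rng.normal(size=(n_subjects,) + grid)
        mask = np.ones(grid, dtype=bool)
        group = group_permutation(
            maps,
            mask,
            n_permutations=n_permutations,
            variance_smoothing_fwhm=variance_smoothing_fwhm,
            alpha=alpha,
            seed=int(rng.integers(2**31)),
        )
        hits += bool(np.any(group.significant))
    return hits / n_cohorts
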