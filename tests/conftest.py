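import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def deck():
    from cardglm import Deck

    return Deck()


@pytest.fixture
def small_cohort_trials():
    """One subject's worth of task trials with a plausible agent."""
    from cardglm import generate_trial_sequence, simulate_agent

    trials = generate_trial_sequence(n_sessions=3, trials_per_session=30, seed=42)
    return simulate_agent(trials, policy="higher_biased", p_miss=0.05, seed=43)


@pytest.fixture
def session_design():
    """A single-session (trials, variables, design) triple at task defaults."""
    from cardglm import (
        build_design,
        compute_decision_variables,
        generate_trial_sequence,
        simulate_agent,
    )

    trials = generate_trial_sequence(n_sessions=1, trials_per_session=20, seed=5)
    trials = simulate_agent(trials, policy="random", p_miss=0.0, seed=6)
    variables = compute_decision_variables(trials)
    n_frames = int(np.ceil((trials[-1].onset_report_cue + 20.0) / 2.72))
    design = build_design(trials, variables, tr=2.72, n_frames=n_frames)
    return trials, variables, design
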