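"""First-level GLM on a simulated session.

Simulates one session with a planted surprise effect, fits the AR(1)
prewhitened GLM on the serially orthogonalized design, and prints the
estimated autocorrelation, the recovered effect amplitude, and the t map
peak.
"""

import numpy as np

from cardglm import (
    GroundTruth,
    build_design,
    compute_decision_variables,
    contrast_t,
    contrast_vector,
    fit_first_level,
    generate_trial_sequence,
    serial_orthogonalize,
    simulate_agent,
    simulate_bold,
)

tr = 2.72
trials = generate_trial_sequence(n_sessions=1, trials_per_session=30, seed=20)
trials = simulate_agent(trials, policy="random", p_miss=0.0, seed=21)
variables = compute_decision_variables(trials)
n_frames = int(np.ceil((trials[-1].onset_report_cue + 20.0) / tr))
raw = build_design(trials, variables, tr=tr, n_frames=n_frames)
orth = serial_orthogonalize(raw)

grid = (8, 8, 4)
beta = np.zeros(grid)
beta[2:4, 2:4, 1:3] = 2.0
truth = GroundTruth(beta_maps={"card2xsurprise": beta}, ar_coefficient=0.3,
                    noise_sd=1.0, drift_amplitude=1.0, seed=22)
bold = simulate_bold(raw, truth, grid=grid)

result = fit_first_level(bold, orth)
w = contrast_vector(result.column_names, "card2xsurprise")
effect, t = contrast_t(result, w)

in_block = beta[bold.mask] > 0
print(f"AR(1) coefficient: true 0.30, estimated {result.phi:.3f}")
print(f"Surprise effect in planted voxels: true 2.0, "
      f"mean estimate {effect[in_block].mean():.3f}")
print(f"Mean |effect| outside the block: {np.abs(effect[~in_block]).mean():.3f}")
print(f"Peak t in block: {t[in_block].max():.1f}  (dof = {result.dof})")
print()
print("Prewhitening keeps the t statistics calibrated under AR(1) noise;")
print("the 128 s cosine basis absorbs the simulated slow drift.")
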