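# Methods

## Task model

A trial draws two distinct cards from a deck of 10 (values 1–10) without
replacement; the agent bets a fixed stake that the second is higher or
lower than the first. After card 1 the win probability is
`p = #{remaining cards that beat card 1 under the bet} / 9`, so the
decision variables are closed-form and no fitting is involved:
entropy `H(p)` in bits (with the `0·log₂0 = 0` convention, so `H` extends
continuously to `p ∈ {0, 1}`), confidence `−H(p)`, stimulus-bound surprise
`−log₂ p(observed outcome)`, accuracy `0 − confidence = H(p)`, reward
prediction `stake·(2p − 1)` and its prediction error. Trials are
independent by design: the deck is reshuffled conceptually every trial, so
no learning links one trial to the next.

Three conventions were genuinely open and are fixed as follows:

- **Payoff coding.** Reward prediction uses the symmetric ±stake coding
  (win = +1 CHF, loss = −1 CHF), giving `ER = 2p − 1`. An alternative 0/1
  win-amount coding would rescale and shift the regressor; after
  mean-centering the two differ only by a factor of 2, so the choice does
  not affect orthogonalized inference. `stake` is a parameter throughout.
- **Sign of accuracy.** Accuracy is implemented literally as
  `0 − confidence`, a non-negative quantity in bits. The interpretation of
  information gain as a (non-positive) divergence suggests the opposite
  sign; `accuracy_bits(p, sign=-1)` flips it. Either way the regressor is
  mean-centered before entering the design, so group t statistics only
  change sign.
- **Dirichlet counting.** The card-counting control estimator is
  `(wins + 1)/(outcomes + 1)` — a single pseudo-count in numerator and
  denominator, exactly as specified for the control analysis, even though
  it implies a prior estimate of 1 before any outcome (a Laplace rule
  would use `outcomes + 2`). Missed-bet trials reveal cards but resolve no
  bet; they advance the outcome count (configurable) and never the win
  count.

`inverse_variance` exists only to demonstrate why negative entropy, not
ε-regularized precision `1/(q(1−q))`, is the usable confidence scale: at
certitude the clipped precision jumps to `1/(ε(1−ε))` ≈ 1000, out of scale
with every other confidence level, whereas `−H` extends continuously to 0.

## Behavioral statistics

The error rate counts missed bets, missed reports and incorrect reports
over two response opportunities per trial (one bet, one report — the two
penalized response types); sessions above 30% are flagged for exclusion.
The strategy tally counts win-stay/lose-shift-consistent transitions
("strategic") versus the rest; transitions whose predecessor bet or
outcome is undefined are dropped rather than guessed. Payout is the 25 CHF
endowment ± 1 CHF per resolved bet minus 0.25 CHF per response error.

## Synthetic data

The generator reproduces the design features that matter for the GLM:

- **Card pairs** are sampled without replacement from the 90 ordered pairs;
  the default 3 sessions × 30 trials uses each exactly once. Win
  frequencies per (card 1, bet) cell therefore match the model exactly in
  expectation, which the simulation oracle verifies with binomial bounds.
- **Timing**: bet cue at 0 s, card 1 at 4 s, card 2 at 9.5 s (the fixed
  5.5 s gap), report cue at 15 s, 25 s trials plus uniform 2–5 s
  inter-trial jitter. Only the gap and trial length are fixed by the task;
  the other offsets are package defaults and configurable.
- **Agents**: fair-coin, higher-biased (default 0.7, matching the observed
  preference for higher bets), and win-stay/lose-shift policies; bets and
  reports are each missed with probability `p_miss` (default 0.05 in the
  cohort spec) and a made report is incorrect with the same probability.
  Reaction times are lognormal with ~0.7 s median, giving motor-event
  onsets distinct from the sound cues.
- **BOLD**: `y(voxel) = Σ_r X[:,r]·β_r(voxel) + drift + AR(1) noise` on a
  16×16×8 grid at TR 2.72 s. Noise is stationary AR(1) (default φ = 0.2,
  innovation sd 1). Drift is a random-phase sum of cosines with periods
  384/256/160 s, all above the 128 s high-pass cutoff. Signal is generated
  from the *raw* design; fitting uses the orthogonalized design, as on
  real data.

What the generator does **not** emulate: anatomy and tissue contrast,
spatially correlated or physiological noise, motion, scanner artifacts,
and any nonlinearity of the hemodynamic response. Passing recovery tests
therefore demonstrate the correctness of the estimation chain, not
robustness to those real-data complications.

## Design matrix

Event regressors are built on a 16× oversampled grid (TR/16 ≈ 0.17 s;
onsets with 5.5 s spacing and continuous jitter are never TR-aligned at
TR = 2.72 s), convolved, then sampled at frame times. The HRF is a
difference of gamma densities parameterized by mode — response peak 6 s,
undershoot trough 16 s, dispersion 1 s, undershoot amplitude 1/6 of the
peak, truncated at 32 s, peak-normalized. (Parameterizing by mode keeps
the kernel's peak exactly at its nominal 6 s; shape-parameterized
variants of the canonical kernel peak ~1 s earlier.) No temporal or
dispersion derivatives are included.

Modulator amplitudes are mean-centered across a session's resolved trials
before convolution, so each modulator column is orthogonal to its boxcar
at the event level and the boxcar keeps the mean response. Serial
orthogonalization then residualizes each column of an onset group against
all preceding columns of that group (boxcar → first modulator → …) on the
convolved, sampled columns; sound, motor, drift and constant columns are
never touched. Degenerate (rank-deficient) projections warn and skip. The
resulting coefficient of the k-th modulator provably equals the
coefficient it would receive entered last in a hierarchical regression,
which the tests verify against that oracle directly.

The high-pass basis contains every discrete-cosine component with period
`2·T_session/k` strictly greater than the 128 s cutoff, excluding the
constant. Sessions are modeled separately — each gets its own design,
drift basis and constant, and subject-level contrast maps are the average
of session-level effect maps — avoiding cross-session concatenation
artifacts.

## First-level GLM

OLS fit, then a single AR(1) coefficient pooled over in-mask voxels from
the lag-1 autocorrelation of the residuals, then prewhitening of data and
design by the AR(1) inverse square root and a refit. The pooled residual
autocorrelation is bias-corrected for the degrees of freedom the fit
removes (`E[φ̂] ≈ tr(A·M)/tr(M)` under white noise, with M the
residual-forming matrix and A the symmetrized lag operator — about −0.09
for a 200-frame, 18-column design); without this correction the white
-noise false-positive rate of the first-level t statistics exceeds its
nominal 2.5% tail. φ is clipped to ±0.95 for stationarity. Contrast t
maps use `t = wᵀβ / sqrt(σ̂²·wᵀ(XᵀX)⁻¹w)` with `dof = frames − columns`
on the whitened design.

## Group inference

The one-sample test on n subject contrast maps uses the pseudo-t
`mean / sqrt(smoothed variance / n)`, with the variance image smoothed by
a Gaussian kernel (FWHM in voxel units, default 2; on synthetic grids
millimetres are notional). Smoothing uses normalized (mask-weighted)
convolution so out-of-mask zeros never bias edge voxels, and the smoothed
variance is recomputed for every permutation, keeping the statistic
exchangeable. The simple smoothed-variance form is used rather than a
ratio-of-smoothed-images variant; the calibration tests confirm its
family-wise error rate is nominal.

Sign patterns are fully enumerated when `2^n` does not exceed the
requested permutation count (exact test), otherwise Monte-Carlo sampled
with the identity pattern forced into the null, so p ≥ 1/n_permutations
and p = 0 is impossible. `fwe_p(v)` is the fraction of patterns whose
maximum pseudo-t over the mask is ≥ the observed value at v (ties count
against rejection); the reported threshold is the `1 − α` upper quantile
of the max-statistic null.

## Validation problem sizes

The package's standing evidence, recomputed by the test suite and
`scripts/acceptance.py`, uses these scales: identity checks over all 20
(card 1, bet) cells; a 10⁵-draw win-frequency oracle; 20 random 50-frame
toy designs for the orthogonalization oracle; 1,000 white-noise voxels ×
200 frames for first-level calibration; 200 null cohorts of 8 subjects
(256 enumerated sign patterns) for family-wise error calibration; and
5 cohorts of 12 subjects (3 sessions × 30 trials, effects at 3× noise sd,
512 Monte-Carlo sign flips) for end-to-end recovery. These sizes give
binomial confidence bands tight enough to detect miscalibration of a few
percentage points while keeping a full validation run under a minute.

## Known limitations

- The AR(1) model is global (one φ per dataset/fit); spatially varying
  autocorrelation is not modeled.
- Cluster-extent inference is not implemented; inference is voxelwise via
  the maximum statistic.
- High-pass filtering removes drift only insofar as it projects onto the
  cosine basis; random-phase drift components leak a small residual.
- The Monte-Carlo permutation path is not deterministic under subject
  reordering (the enumerated path is).
- Real-data preprocessing (slice timing, realignment, normalization) is
  out of scope; volumes are assumed analysis-ready.
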