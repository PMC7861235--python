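"""End-to-end parameter recovery: cohort simulation to FWE-corrected maps.

Simulates a 12-subject cohort with confidence, surprise and accuracy
effects planted at 3x the noise standard deviation in disjoint voxel
blocks, fits the prewhitened first-level GLMs on serially orthogonalized
designs, and runs the one-sample sign-flip permutation test with variance
smoothing. Reports per-effect sensitivity inside its block and false
positives in a null block at FWE alpha = 0.05.

Takes about a minute on one CPU.
"""

from cardglm import recovery_experiment

scores = recovery_experiment(seed=0, n_subjects=12, n_permutations=512)
print(scores.to_string(index=False))
print()
print("'sensitivity' is the fraction of each planted 27-voxel block that")
print("survives FWE correction at alpha = 0.05 (max-statistic sign-flip")
print("null, variance smoothing 2 voxels FWHM); the pseudo-t threshold is")
print("the 95th percentile of the permutation maximum. A correct chain")
print("recovers essentially all planted voxels and none in the null block.")
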