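"""Replicate the reference agreement study in silico.

Simulates cohorts at the calibrated defaults and compares the recovered
agreement estimates side by side with the published reference values.
With several replicates, Monte-Carlo standard errors are attached.
(At the study's own size, n=16, sampling noise is substantial; the
parameter-recovery checks in the test suite use 200-subject cohorts.)
"""

from svagree import replicate

table = replicate(n_subjects=16, seed=1, replicates=5)
print(table.round(3).to_string())
# `recovered` is the mean over replicate cohorts, `mc_se` its
# Monte-Carlo standard error, `reference` the published estimate the
# generator calibration is designed to reproduce.
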