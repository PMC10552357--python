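"""Plan a validation study: sample size and reviewer agreement.

Computes the validation-set size needed to pin down a case definition's
sensitivity with a Wald 95% CI of a chosen width, and shows Fleiss's
kappa for a panel of chart reviewers.
"""

import numpy as np

from phenoforge import SampleSizeParams, fleiss_kappa, sample_size

# Expecting ~80% sensitivity, a CI no wider than 10 percentage points,
# and ~19% prevalence of the condition in the sampled charts:
params = SampleSizeParams(
    expected_sensitivity=0.80, ci_full_width=0.10, expected_prevalence=0.19
)
n = sample_size(params)
print(f"validation set size for Sn=0.80, c=0.10, p=0.19: N = {n}")
# N is the number of charts to review so the sensitivity estimate's
# 95% CI spans at most 10 percentage points.

# Reviewer agreement on a subset of charts: rows are charts, columns are
# (case votes, non-case votes) from a 3-reviewer panel.
ratings = np.array([[3, 0], [0, 3], [2, 1], [3, 0], [1, 2], [0, 3]])
result = fleiss_kappa(ratings)
print(f"Fleiss's kappa over {result.n_subjects} charts, "
      f"{result.n_raters} reviewers: {result.kappa:.3f}")
# kappa near 1 means the reviewers agree far beyond chance; near 0,
# agreement is no better than guessing with the marginal frequencies.
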