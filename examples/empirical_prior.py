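"""Estimate the latent-trait distribution of a sample and rescore with it.

When the scored sample is far from the calibration population, an
N(0,1) prior over-shrinks.  The empirical prior re-estimates the normal
mean and variance from the data by EM with all item parameters fixed.
"""

import numpy as np

from irtscore import (
    Prior, estimate_prior_from_data, make_example_bank, score_table,
)
from irtscore.synth import SimulationConfig, simulated_matrix

bank = make_example_bank(seed=20160)
# a clinical-looking sample: one SD above the calibration population
cfg = SimulationConfig(n_respondents=500, theta_mean=1.0, seed=3)
responses, theta_true = simulated_matrix(bank, cfg)

prior = estimate_prior_from_data(responses, bank)
print(f"empirical prior: N({prior.mean:.3f}, {prior.variance:.3f})  "
      f"(truth: N(1, 1))")

for label, p in [("standard N(0,1)", Prior.standard()),
                 ("empirical", prior)]:
    ests = score_table(responses, bank, prior=p)
    theta_hat = np.array([e.theta_hat for e in ests])
    bias = float(np.mean(theta_hat - theta_true))
    rmse = float(np.sqrt(np.mean((theta_hat - theta_true) ** 2)))
    print(f"EAP under {label:16s} prior: bias={bias:+.3f}  rmse={rmse:.3f}")
print("The standard prior drags a shifted sample back toward 0; the "
      "empirical prior removes most of that bias.")
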