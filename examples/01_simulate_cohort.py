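"""Simulate a confounded genotype/exposure/outcome cohort.

Generates a cohort of 5,000 individuals with 300 independent variants, of
which the first 5 drive the exposure (20% of its variance), a causal
effect of 0.05 on the outcome, and correlated error terms inducing
confounding, then prints what the generative ground truth looks like.
"""

import numpy as np

from cfmr import SimulationConfig, calibrate_effect_size, simulate_dataset

config = SimulationConfig(
    n_individuals=5_000,
    n_variants=300,
    n_causal=5,
    maf=0.3,
    h2=0.2,       # causal variants explain 20% of exposure variance
    beta0=0.05,   # true causal effect of exposure on outcome
    sigma_u2=5.0,
    sigma_v2=5.0,
    sigma_uv=0.8,  # error covariance -> confounding
    seed=1,
)
dataset = simulate_dataset(config)

pi = calibrate_effect_size(config.h2, config.n_causal, config.maf,
                           config.sigma_v2)
print(f"calibrated per-variant effect pi = {pi:.6f}")
print(f"cohort: {dataset.n} individuals x {dataset.n_variants} variants")
print(f"exposure variance: {np.var(dataset.exposure):.3f} "
      f"(expected {2.1 * pi**2 + 5.0:.3f})")

# naive regression of Y on X is confounded away from beta0
slope = np.polyfit(dataset.exposure, dataset.outcome, 1)[0]
print(f"naive OLS slope of outcome on exposure: {slope:.4f} "
      f"(true causal effect {config.beta0}; the excess is confounding)")
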