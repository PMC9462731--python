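"""Cross-population estimation with heterogeneous genetic architecture.

Two strata share a causal effect of 1.0 but differ in allele frequency
and heritability.  Each stratum gets its own folds, scans and predictors;
the stratum estimates are pooled by fixed-effect inverse-variance
weighting, with Cochran's Q flagging effect heterogeneity.
"""

from cfmr import (
    SelectionSpec,
    SimulationConfig,
    cross_population_cfmr,
    simulate_two_populations,
)

config_a = SimulationConfig(n_individuals=4_000, n_variants=300, n_causal=5,
                            maf=0.3, h2=0.2, sigma_uv=0.8, seed=20)
config_b = SimulationConfig(n_individuals=3_000, n_variants=300, n_causal=5,
                            maf=0.15, h2=0.1, sigma_uv=0.8, seed=21)
ds_a, ds_b, _ = simulate_two_populations(config_a, config_b, shared_beta0=1.0)

meta = cross_population_cfmr(
    {"pop_A": ds_a, "pop_B": ds_b},
    k=10,
    selection=SelectionSpec(p_threshold=1.0),
    seed=22,
)

for stratum in meta.per_stratum:
    est = stratum.estimate
    print(f"{stratum.label}: beta = {est.beta_hat:+.4f}  se = {est.se:.4f} "
          f"(n = {stratum.n})")
print(f"pooled: beta = {meta.beta_hat:+.4f}  se = {meta.se:.4f}  "
      f"95% CI [{meta.ci_low:+.4f}, {meta.ci_high:+.4f}]")
print(f"Cochran's Q = {meta.heterogeneity_q:.3f} "
      f"(p = {meta.heterogeneity_p:.3f})")
print("\nBoth strata target the shared effect 1.0; the pooled SE is below "
      "either stratum's own SE, and a small Q indicates no detectable "
      "effect heterogeneity.")
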