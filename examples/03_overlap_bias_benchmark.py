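"""Monte-Carlo contrast of cross-fitting against naive one-sample MR.

Reproduces the complete-sample-overlap experiment at desk scale: strong
error covariance (4.9), true effect 0.08, matched seeds across methods.
The naive estimator's mean drifts above the truth; the cross-fitted one
does not.
"""

from cfmr import (
    ScenarioGrid,
    SimulationConfig,
    run_scenario_grid,
    summarize_bias_comparison,
)

grid = ScenarioGrid(
    configs=[
        SimulationConfig(n_individuals=2_000, n_variants=300, n_causal=5,
                         h2=h2, beta0=0.08, sigma_uv=4.9)
        for h2 in (0.1, 0.2)
    ],
    replicates=60,
    methods=("CFMR2", "1SMR"),
    base_seed=10,
)
summary = run_scenario_grid(grid, partition_k=10)
table = summarize_bias_comparison(summary, methods=("1SMR", "CFMR2"))

for _, row in table.iterrows():
    print(f"h2 = {row['h2']:.0%}  (N = {row['n']:.0f}, "
          f"{row['n_matched']:.0f} matched replicates)")
    print(f"  1SMR  mean estimate {row['mean_1SMR']:+.4f} "
          f"(bias {row['bias_1SMR']:+.4f} +/- {row['mc_se_1SMR']:.4f})")
    print(f"  CFMR2 mean estimate {row['mean_CFMR2']:+.4f} "
          f"(bias {row['bias_CFMR2']:+.4f} +/- {row['mc_se_CFMR2']:.4f})")

print("\nTrue effect is 0.08: positive 1SMR bias is endogeneity bias from "
      "training and applying the instrument on the same sample; the "
      "cross-fitted estimator is at worst biased toward zero.")
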