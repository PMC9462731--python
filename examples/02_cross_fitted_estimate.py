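"""Build a cross-fitted instrument and estimate the causal effect.

Runs the full pipeline on one simulated cohort: 10-fold partition,
per-fold exposure GWAS + clumping + penalized predictor, concatenated
out-of-fold predictions as the instrument, then the pooled 2SLS (CFMR2),
the per-fold average (CFMR1), and the naive one-sample baseline for
contrast.
"""

from cfmr import (
    PredictorSpec,
    SelectionSpec,
    SimulationConfig,
    build_cfi,
    cfi_diagnostics,
    cfmr1,
    cfmr2,
    make_folds,
    one_sample_mr,
    simulate_dataset,
)

config = SimulationConfig(
    n_individuals=5_000, n_variants=300, n_causal=5, maf=0.3, h2=0.2,
    beta0=0.05, sigma_uv=4.9, seed=2,   # strong confounding
)
dataset = simulate_dataset(config)

partition = make_folds(dataset.n, k=10, seed=3)
selection = SelectionSpec(p_threshold=1.0)  # independent variants: no filter
predictor = PredictorSpec(seed=4)

cfi = build_cfi(dataset.genotypes, dataset.exposure, partition, selection,
                predictor)
diag = cfi_diagnostics(cfi, dataset.exposure)
print(f"instrument explains {diag.variance_explained_pct:.2f}% of the "
      f"exposure out-of-fold; {cfi.n_degenerate} degenerate folds")

for est in (
    cfmr2(dataset.exposure, dataset.outcome, cfi),
    cfmr1(dataset.exposure, dataset.outcome, cfi),
    one_sample_mr(dataset.exposure, dataset.outcome, dataset.genotypes,
                  selection, predictor),
):
    print(f"{est.method:>5}: beta = {est.beta_hat:+.4f}  se = {est.se:.4f}  "
          f"95% CI [{est.ci_low:+.4f}, {est.ci_high:+.4f}]")

print(f"\ntrue causal effect: {config.beta0}. The cross-fitted estimates "
      "stay near it (at worst shrunk toward zero); the one-sample baseline "
      "is pulled up toward the confounded association.")
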