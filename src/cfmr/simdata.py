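"""Synthetic genotype/phenotype cohorts for instrumental-variable studies.

The generative model is the standard linear IV setup used throughout the
package: for individual ``i`` with dosage row ``Z_i`` (independent biallelic
variants, Hardy-Weinberg ``Binomial(2, maf)`` counts),

    X_i = Z_i . Pi + V_i            (exposure; first-stage)
    Y_i = beta0 * X_i + U_i         (outcome; structural equation)

with ``(U_i, V_i)`` i.i.d. bivariate normal.  A nonzero ``sigma_uv``
covariance induces confounding between exposure and outcome, which is what
makes naive regression of Y on X (and naive one-sample MR) biased.

Effect sizes are calibrated so that the causal variants explain exactly a
requested fraction ``h2`` of the exposure variance; see
:func:`calibrate_effect_size`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "calibrate_effect_size",
    "simulate_genotypes",
    "simulate_dataset",
    "simulate_two_populations",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic cohort.

    Attributes
    ----------
    n_individuals : int
        Cohort size N.
    n_variants : int
        Total number of simulated variants (causal and null).
    n_causal : int
        Number of causal variants; these occupy the *first* ``n_causal``
        genotype columns.
    maf : float
        Minor allele frequency shared by all variants, in (0, 0.5].
    h2 : float
        Fraction of exposure variance explained by the causal variants,
        in [0, 1).
    beta0 : float
        Causal effect of the exposure on the outcome.
    sigma_u2, sigma_v2 : float
        Variances of the outcome-side (U) and exposure-side (V) errors.
    sigma_uv : float
        Covariance of (U, V); nonzero values induce confounding.
    seed : int
        RNG seed; the cohort is bit-for-bit regenerable from it.
    """

    n_individuals: int
    n_variants: int
    n_causal: int = 5
    maf: float = 0.3
    h2: float = 0.2
    beta0: float = 0.0
    sigma_u2: float = 5.0
    sigma_v2: float = 5.0
    sigma_uv: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 1 or self.n_variants < 1:
            raise ConfigurationError("n_individuals and n_variants must be positive")
        if not (0 <= self.maf <= 0.5):
            raise ConfigurationError(f"maf must lie in [0, 0.5], got {self.maf}")
        if not (0 <= self.h2 < 1):
            raise ConfigurationError(f"h2 must lie in [0, 1), got {self.h2}")
        if self.n_causal > self.n_variants:
            raise ConfigurationError("n_causal cannot exceed n_variants")
        if self.h2 > 0 and self.n_causal < 1:
            raise ConfigurationError("n_causal must be >= 1 when h2 > 0")
        if self.sigma_u2 <= 0 or self.sigma_v2 <= 0:
            raise ConfigurationError("error variances must be positive")
        if abs(self.sigma_uv) > np.sqrt(self.sigma_u2 * self.sigma_v2):
            raise ConfigurationError(
                "sigma_uv exceeds sqrt(sigma_u2 * sigma_v2): "
                "(U, V) covariance matrix is not positive semi-definite"
            )

    @property
    def error_cov(self) -> np.ndarray:
        """2x2 covariance matrix of (U, V)."""
        return np.array(
            [[self.sigma_u2, self.sigma_uv], [self.sigma_uv, self.sigma_v2]]
        )


@dataclass
class SimulatedDataset:
    """One generated cohort together with its ground truth."""

    genotypes: np.ndarray  # (N, n_variants) int8 dosages in {0, 1, 2}
    exposure: np.ndarray  # (N,) float
    outcome: np.ndarray  # (N,) float
    true_pi: np.ndarray  # (n_variants,) per-variant effects on the exposure
    true_beta0: float
    seed: int
    config: Optional[SimulationConfig] = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]


def calibrate_effect_size(
    h2: float, n_causal: int, maf: float, sigma_v2: float
) -> float:
    """Per-variant effect size pinning the causal variance share to ``h2``.

    With ``n_causal`` independent Binomial(2, maf) variants of common effect
    ``pi`` and residual exposure variance ``sigma_v2``, the genetic variance
    is ``n_causal * pi^2 * 2 * maf * (1 - maf)``.  Solving

        genetic / (genetic + sigma_v2) = h2

    gives ``pi = sqrt(h2 * sigma_v2 / ((1 - h2) * n_causal * 2 maf (1-maf)))``.
    """
    if not (0 <= h2 < 1):
        raise ConfigurationError(f"h2 must lie in [0, 1), got {h2}")
    if h2 == 0:
        return 0.0
    if n_causal < 1:
        raise ConfigurationError("n_causal must be >= 1 when h2 > 0")
    if not (0 < maf <= 0.5):
        raise ConfigurationError("maf must lie in (0, 0.5] when h2 > 0")
    if sigma_v2 <= 0:
        raise ConfigurationError("sigma_v2 must be positive")
    dosage_var = 2.0 * maf * (1.0 - maf)
    return float(np.sqrt(h2 * sigma_v2 / ((1.0 - h2) * n_causal * dosage_var)))


def simulate_genotypes(
    n_individuals: int, n_variants: int, maf: float, seed: int
) -> np.ndarray:
    """Independent Binomial(2, maf) dosage matrix, dtype int8."""
    if n_individuals < 1 or n_variants < 1:
        raise ConfigurationError("counts must be positive")
    if not (0 <= maf <= 0.5):
        raise ConfigurationError(f"maf must lie in [0, 0.5], got {maf}")
    rng = np.random.default_rng(seed)
    return rng.binomial(2, maf, size=(n_individuals, n_variants)).astype(np.int8)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw one cohort from the structural model.

    The causal variants occupy the first ``n_causal`` columns; all causal
    effects equal the calibrated ``pi``.  Genotypes, then errors, are drawn
    from a single ``default_rng(config.seed)`` stream, so the dataset is
    regenerable bit-for-bit.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genotypes = rng.binomial(
        2, cfg.maf, size=(cfg.n_individuals, cfg.n_variants)
    ).astype(np.int8)

    pi = calibrate_effect_size(cfg.h2, cfg.n_causal, cfg.maf, cfg.sigma_v2)
    true_pi = np.zeros(cfg.n_variants)
    true_pi[: cfg.n_causal] = pi

    errors = rng.multivariate_normal(
        mean=[0.0, 0.0], cov=cfg.error_cov, size=cfg.n_individuals
    )
    u, v = errors[:, 0], errors[:, 1]

    if cfg.h2 > 0:
        genetic = genotypes[:, : cfg.n_causal].astype(np.float64) @ true_pi[: cfg.n_causal]
    else:
        genetic = np.zeros(cfg.n_individuals)
    exposure = genetic + v
    outcome = cfg.beta0 * exposure + u
    return SimulatedDataset(
        genotypes=genotypes,
        exposure=exposure,
        outcome=outcome,
        true_pi=true_pi,
        true_beta0=cfg.beta0,
        seed=cfg.seed,
        config=cfg,
    )


def simulate_two_populations(
    config_a: SimulationConfig,
    config_b: SimulationConfig,
    shared_beta0: float,
):
    """Two independent cohorts with a common causal effect.

    Population-specific MAF, heritability, effect vectors and error
    covariances come from the respective configs; ``shared_beta0``
    overrides both configs' ``beta0``.  Returns ``(dataset_a, dataset_b,
    labels)`` where ``labels`` concatenates ``"A"`` / ``"B"`` in the stable
    order (all of A, then all of B).
    """
    ds_a = simulate_dataset(replace(config_a, beta0=shared_beta0))
    ds_b = simulate_dataset(replace(config_b, beta0=shared_beta0))
    labels = np.array(["A"] * ds_a.n + ["B"] * ds_b.n)
    return ds_a, ds_b, labels
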