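"""Cross-population estimation: per-stratum cross-fitting plus meta-analysis.

When a sample contains genetically distinct sub-populations (different
allele frequencies, heritabilities, or causal architectures), one shared
exposure predictor is a poor instrument for everyone.  The stratified
estimator runs the full cross-fitting pipeline independently within each
population stratum — its own folds, scans and predictors — and pools the
per-stratum causal estimates with fixed-effect inverse-variance weights.
Cochran's Q across strata is reported so effect heterogeneity (a violated
shared-effect assumption) is visible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .cfi import PredictorSpec, SelectionSpec, build_cfi, make_folds
from .errors import CfmrError, ConfigurationError, DegenerateInstrumentError
from .estimators import IVEstimate, cfmr2

__all__ = [
    "StratumEstimate",
    "MetaEstimate",
    "inverse_variance_meta",
    "cross_population_cfmr",
]

logger = logging.getLogger(__name__)


@dataclass
class StratumEstimate:
    label: str
    estimate: IVEstimate
    n: int


@dataclass
class MetaEstimate:
    """Fixed-effect pooled estimate across strata."""

    beta_hat: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    per_stratum: List[StratumEstimate]
    heterogeneity_q: float

    @property
    def heterogeneity_p(self) -> float:
        df = len(self.per_stratum) - 1
        if df < 1:
            return float("nan")
        return float(stats.chi2.sf(self.heterogeneity_q, df))


def inverse_variance_meta(
    estimates: Sequence[Union[IVEstimate, Tuple[float, float]]],
    labels: Optional[Sequence[str]] = None,
    ns: Optional[Sequence[int]] = None,
) -> MetaEstimate:
    """Fixed-effect pooling: weights 1/se^2, pooled se 1/sqrt(sum w)."""
    if len(estimates) == 0:
        raise ConfigurationError("no estimates to meta-analyze")
    betas, ses, strata = [], [], []
    for i, est in enumerate(estimates):
        if isinstance(est, IVEstimate):
            b, s, n_i = est.beta_hat, est.se, est.n
            stratum = StratumEstimate(
                label=str(labels[i]) if labels is not None else str(i),
                estimate=est,
                n=n_i,
            )
        else:
            b, s = float(est[0]), float(est[1])
            n_i = int(ns[i]) if ns is not None else 0
            stratum = StratumEstimate(
                label=str(labels[i]) if labels is not None else str(i),
                estimate=IVEstimate(
                    beta_hat=b, se=s, ci_low=b - 1.959964 * s,
                    ci_high=b + 1.959964 * s,
                    pvalue=2.0 * stats.norm.sf(abs(b / s)) if s > 0 else float("nan"),
                    method="stratum", n=n_i,
                ),
                n=n_i,
            )
        if s <= 0:
            raise ConfigurationError(f"stratum {stratum.label}: se must be > 0")
        betas.append(b)
        ses.append(s)
        strata.append(stratum)
    w = 1.0 / np.asarray(ses) ** 2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (np.asarray(betas) - beta) ** 2))
    z = beta / se
    z975 = float(stats.norm.ppf(0.975))
    return MetaEstimate(
        beta_hat=beta,
        se=se,
        ci_low=beta - z975 * se,
        ci_high=beta + z975 * se,
        pvalue=float(2.0 * stats.norm.sf(abs(z))),
        per_stratum=strata,
        heterogeneity_q=q,
    )


def _cohort_arrays(cohort):
    """Accept (genotypes, exposure, outcome) tuples or dataset objects."""
    if hasattr(cohort, "genotypes"):
        return cohort.genotypes, cohort.exposure, cohort.outcome
    g, x, y = cohort
    return g, x, y


def cross_population_cfmr(
    cohorts: Mapping[str, object],
    k: int = 10,
    selection: Optional[SelectionSpec] = None,
    predictor: Optional[PredictorSpec] = None,
    seed: int = 0,
    min_stratum_size: int = 100,
    robust: bool = False,
) -> MetaEstimate:
    """Full cross-fitted pipeline per stratum, then inverse-variance pooling.

    Strata below ``min_stratum_size`` (or whose instrument degenerates) are
    excluded with a warning; an error is raised only when no stratum
    survives.  Per-stratum fold seeds derive deterministically from
    ``seed`` and the stratum position.
    """
    estimates: List[IVEstimate] = []
    labels: List[str] = []
    for idx, (label, cohort) in enumerate(cohorts.items()):
        genotypes, exposure, outcome = _cohort_arrays(cohort)
        n = np.asarray(genotypes).shape[0]
        if n < min_stratum_size:
            logger.warning(
                "stratum %s: size %d below floor %d, excluded",
                label, n, min_stratum_size,
            )
            continue
        stratum_seed = int(
            np.random.SeedSequence([seed, idx]).generate_state(1)[0] & 0x7FFFFFFF
        )
        partition = make_folds(n, k, seed=stratum_seed)
        try:
            cfi = build_cfi(genotypes, exposure, partition, selection, predictor)
            est = cfmr2(exposure, outcome, cfi, robust=robust)
        except (DegenerateInstrumentError, CfmrError) as exc:
            logger.warning("stratum %s: estimation failed (%s), excluded",
                           label, exc)
            continue
        estimates.append(est)
        labels.append(str(label))
    if not estimates:
        raise DegenerateInstrumentError(
            "every stratum was excluded or degenerate"
        )
    return inverse_variance_meta(estimates, labels=labels)
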