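"""Exposure GWAS, variant selection, and exposure-predictor training.

This module implements the instrument-building half of the pipeline: a
marginal association scan of the exposure on each dosage column, greedy
LD clumping so retained variants are approximately uncorrelated, a strict
P-value filter, and a predictor of the exposure from the retained dosages
(L1-penalized regression with cross-validated penalty, an unpenalized
least-squares fit, or a fixed-weight allele score).

None of these operations reads the outcome: the predictor is a function of
genotypes and exposure only, which is what allows cross-fitting to break
the correlation between instrument construction and outcome noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _lasso
from ._moments import Moments, moments
from .errors import ConfigurationError

__all__ = [
    "AssociationScan",
    "FittedPredictor",
    "marginal_scan",
    "greedy_clump",
    "select_by_pvalue",
    "fit_predictor",
]


@dataclass
class AssociationScan:
    """Marginal per-variant regression results for one index set."""

    variant_ids: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    pvalue: np.ndarray
    n_used: int
    indices: np.ndarray = field(repr=False)  # rows the scan was run on
    zero_variance: np.ndarray = field(repr=False)  # flagged columns

    @property
    def n_variants(self) -> int:
        return len(self.beta)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "variant": self.variant_ids,
                "beta": self.beta,
                "se": self.se,
                "pvalue": self.pvalue,
            }
        )

    def to_tsv(self, path):
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class FittedPredictor:
    """A trained per-fold exposure predictor.

    The prediction is the affine map ``intercept + Z[:, selected] @ weights``
    — a function of the selected dosages only.
    """

    selected_ids: np.ndarray  # variant column indices entering the predictor
    weights: np.ndarray
    intercept: float
    training_indices: np.ndarray = field(repr=False)
    method: str = "penalized-regression"
    training_r2: float = 0.0
    degenerate: bool = False
    alpha: Optional[float] = None  # chosen L1 penalty, when applicable

    def predict(self, genotypes: np.ndarray, indices=None) -> np.ndarray:
        Z = genotypes if indices is None else genotypes[np.asarray(indices)]
        if len(self.selected_ids) == 0:
            return np.full(Z.shape[0], self.intercept)
        cols = np.asarray(Z[:, np.asarray(self.selected_ids)], dtype=np.float64)
        return cols @ self.weights + self.intercept


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Residuals of v (vector or matrix columns) on a design matrix."""
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ coef


def marginal_scan(
    genotypes: np.ndarray,
    exposure: np.ndarray,
    indices=None,
    covariates: Optional[np.ndarray] = None,
    variant_ids=None,
) -> AssociationScan:
    """Simple linear regression of the exposure on each dosage column.

    Restricted to ``indices`` (default: all rows).  With covariates, both
    exposure and dosages are residualized on ``[1, covariates]`` first and
    the t test uses ``n - 2 - q`` degrees of freedom.  Zero-variance columns
    are flagged and reported with ``p = 1``.
    """
    if indices is None:
        indices = np.arange(np.asarray(genotypes).shape[0])
    indices = np.asarray(indices)
    if len(indices) == 0:
        raise ConfigurationError("marginal_scan requires a non-empty index set")
    x = np.asarray(exposure, dtype=np.float64)
    if len(x) != np.asarray(genotypes).shape[0]:
        raise ConfigurationError("exposure length does not match genotype rows")

    n_cov = 0
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
        if C.shape[0] != len(x):
            C = C.T
        n_cov = C.shape[1]
        design = np.column_stack([np.ones(len(indices)), C[indices]])
        Zr = _residualize(
            np.asarray(genotypes[indices], dtype=np.float64), design
        )
        xr = _residualize(x[indices], design)
        m = moments(Zr, xr)
    else:
        m = moments(np.asarray(genotypes), x, indices)

    beta, se, pvalue, zero = m.marginal_scan(n_covariates=n_cov)
    if variant_ids is None:
        variant_ids = np.arange(len(beta))
    return AssociationScan(
        variant_ids=np.asarray(variant_ids),
        beta=beta,
        se=se,
        pvalue=pvalue,
        n_used=len(indices),
        indices=indices,
        zero_variance=zero,
    )


def clump_from_correlation(
    r2: np.ndarray,
    pvalue: np.ndarray,
    r2_threshold: float,
    positions: Optional[np.ndarray] = None,
    window_bp: Optional[float] = None,
) -> np.ndarray:
    """Greedy clumping given a squared-correlation matrix.

    Variants are processed in ascending p-value (ties broken by variant
    index); a variant is retained iff its r-squared with every
    already-retained variant inside the window is below the threshold.
    Returns retained variant indices in ascending variant order.
    """
    p = len(pvalue)
    order = np.lexsort((np.arange(p), pvalue))
    retained = np.empty(p, dtype=np.intp)
    n_ret = 0
    for j in order:
        prior = retained[:n_ret]
        if n_ret:
            r2_row = r2[j, prior]
            if window_bp is not None:
                in_window = np.abs(positions[prior] - positions[j]) <= window_bp
                blocked = np.any(r2_row[in_window] >= r2_threshold)
            else:
                blocked = np.any(r2_row >= r2_threshold)
            if blocked:
                continue
        retained[n_ret] = j
        n_ret += 1
    return np.sort(retained[:n_ret])


def greedy_clump(
    scan: AssociationScan,
    genotypes: np.ndarray,
    r2_threshold: float = 0.1,
    window_bp: Optional[float] = None,
    positions: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Greedy LD thinning of the scanned variants.

    r-squared is the squared sample correlation of dosage columns over the
    scan's index set.  Without positions the window is infinite (every pair
    is compared); a finite ``window_bp`` requires ``positions``.
    """
    if not (0 < r2_threshold <= 1):
        raise ConfigurationError("r2_threshold must lie in (0, 1]")
    if window_bp is not None and positions is None:
        raise ConfigurationError("positions are required with a finite window")
    m = moments(np.asarray(genotypes), np.zeros(np.asarray(genotypes).shape[0]),
                scan.indices)
    r2 = m.corr() ** 2
    return clump_from_correlation(
        r2, scan.pvalue, r2_threshold, positions=positions, window_bp=window_bp
    )


def select_by_pvalue(scan: AssociationScan, threshold: float) -> np.ndarray:
    """Variant indices with p strictly below the threshold, stable order."""
    if not (0 < threshold <= 1):
        raise ConfigurationError("threshold must lie in (0, 1]")
    return np.flatnonzero(scan.pvalue < threshold)


def fit_predictor(
    genotypes: np.ndarray,
    exposure: np.ndarray,
    train_indices,
    selected,
    method: str = "penalized-regression",
    cv_folds: int = 10,
    seed: int = 0,
    scan: Optional[AssociationScan] = None,
    alpha: Optional[float] = None,
    n_alphas: int = 100,
    eps: float = 1e-3,
    tol: float = 1e-6,
) -> FittedPredictor:
    """Train an exposure predictor on the selected dosage columns.

    ``penalized-regression`` fits an L1-penalized linear model with the
    penalty chosen by ``cv_folds``-fold cross-validated prediction error
    (``alpha`` overrides the search; ``inf`` forces the intercept-only
    fit).  ``least-squares`` is the unpenalized fit.  ``allele-score``
    re-uses the marginal scan slopes as fixed weights (no refit; requires
    ``scan``).  An empty selection returns an intercept-only predictor
    flagged degenerate.
    """
    train_indices = np.asarray(train_indices)
    if len(train_indices) == 0:
        raise ConfigurationError("train_indices must be non-empty")
    selected = np.asarray(selected, dtype=np.intp)
    x = np.asarray(exposure, dtype=np.float64)
    Z = np.asarray(genotypes)

    if len(selected) == 0:
        return FittedPredictor(
            selected_ids=selected,
            weights=np.zeros(0),
            intercept=float(x[train_indices].mean()),
            training_indices=train_indices,
            method=method,
            training_r2=0.0,
            degenerate=True,
        )

    Zsel = Z[:, selected]
    total = moments(Zsel, x, train_indices)

    if method in ("penalized-regression", "lasso"):
        fit = _lasso.lasso_cv(
            Zsel, x, rows=train_indices, cv_folds=cv_folds, seed=seed,
            alpha=alpha, n_alphas=n_alphas, eps=eps, tol=tol,
        )
        weights, intercept, chosen = fit.coef, fit.intercept, fit.alpha
    elif method in ("least-squares", "ols"):
        weights, intercept = total.ols()
        chosen = None
    elif method == "allele-score":
        if scan is None:
            raise ConfigurationError("allele-score requires the marginal scan")
        weights = np.nan_to_num(scan.beta[selected], nan=0.0)
        intercept = float(total.xbar - weights @ total.center)
        chosen = None
    else:
        raise ConfigurationError(f"unknown predictor method: {method!r}")

    degenerate = not np.any(weights != 0.0)
    syy = total.syy
    r2 = 0.0
    if syy > 0 and not degenerate:
        r2 = float(max(0.0, 1.0 - total.rss(weights) / syy))
    return FittedPredictor(
        selected_ids=selected,
        weights=np.asarray(weights, dtype=np.float64),
        intercept=float(intercept),
        training_indices=train_indices,
        method=method,
        training_r2=r2,
        degenerate=degenerate,
        alpha=chosen,
    )
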