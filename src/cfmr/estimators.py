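"""Instrumental-variable estimators of the causal exposure->outcome effect.

The core is the textbook two-stage least-squares (2SLS) estimator

    beta_hat = [X'Z (Z'Z)^-1 Z'X]^-1 X'Z (Z'Z)^-1 Z'Y

after residualizing X, Y and Z on an intercept (plus covariates when
supplied — Frisch-Waugh, equivalent to carrying the covariates through
both stages).  On top of it sit the two cross-fitted variants:

* ``cfmr1`` — per-fold 2SLS on the fold's own out-of-fold prediction,
  averaged with equal weights across non-degenerate folds;
* ``cfmr2`` — a single 2SLS of the full data on the concatenated
  cross-fitted instrument (the recommended estimator);

plus the naive one-sample MR baseline (predictor trained and applied on
the same data, which inherits endogeneity bias) and the Nagar
approximation of that bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .cfi import (
    CrossFittedInstrument,
    PredictorSpec,
    SelectionSpec,
)
from .errors import (
    ConfigurationError,
    DegenerateInstrumentError,
    RankDeficiencyError,
)
from .gwas_instrument import fit_predictor, greedy_clump, marginal_scan, select_by_pvalue

__all__ = [
    "IVEstimate",
    "tsls",
    "cfmr1",
    "cfmr2",
    "one_sample_mr",
    "nagar_bias_term",
]

logger = logging.getLogger(__name__)

_Z975 = 1.959964  # conventional 97.5% normal quantile used for Wald CIs


@dataclass
class IVEstimate:
    """Point estimate with Wald inference."""

    beta_hat: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    method: str
    n: int
    k: Optional[int] = None
    n_instruments: int = 1
    degenerate_folds: int = 0

    def to_row(self) -> dict:
        return {
            "method": self.method,
            "estimate": self.beta_hat,
            "se": self.se,
            "pvalue": self.pvalue,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n": self.n,
            "k": self.k,
            "n_instruments": self.n_instruments,
            "degenerate_folds": self.degenerate_folds,
        }


def _wald(beta: float, se: float, method: str, n: int, **kw) -> IVEstimate:
    if se > 0:
        z = beta / se
        pvalue = 2.0 * stats.norm.sf(abs(z))
    else:
        pvalue = float("nan")
    return IVEstimate(
        beta_hat=float(beta),
        se=float(se),
        ci_low=float(beta - _Z975 * se),
        ci_high=float(beta + _Z975 * se),
        pvalue=float(pvalue),
        method=method,
        n=n,
        **kw,
    )


def _residual_frame(x, y, Zmat, covariates):
    """Residualize everything on [1, covariates]; returns (xr, yr, Zr, q)."""
    n = len(x)
    if covariates is None:
        design = np.ones((n, 1))
        q = 0
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
        if C.shape[0] != n:
            C = C.T
        design = np.column_stack([np.ones(n), C])
        q = C.shape[1]

    def res(v):
        coef, *_ = np.linalg.lstsq(design, v, rcond=None)
        return v - design @ coef

    return res(x), res(y), res(Zmat), q


def tsls(
    exposure: np.ndarray,
    outcome: np.ndarray,
    instrument: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    robust: bool = False,
    method_label: str = "2SLS",
    k: Optional[int] = None,
    degenerate_folds: int = 0,
) -> IVEstimate:
    """Two-stage least squares with homoskedastic (or sandwich) SEs.

    The reported SE uses the second-stage residuals ``e = Y - X beta_hat``
    in the residualized frame, ``sigma2 = e'e / (n - q - 2)`` and
    ``Var(beta_hat) = sigma2 * [X'Z (Z'Z)^-1 Z'X]^-1``; ``robust=True``
    switches to the heteroskedasticity-consistent sandwich form.
    """
    x = np.asarray(exposure, dtype=np.float64)
    y = np.asarray(outcome, dtype=np.float64)
    Zmat = np.asarray(instrument, dtype=np.float64)
    if Zmat.ndim == 1:
        Zmat = Zmat[:, None]
    n, m = Zmat.shape
    if len(x) != n or len(y) != n:
        raise ConfigurationError("exposure/outcome/instrument rows misaligned")

    col_sd = Zmat.std(axis=0)
    if np.all(col_sd <= 0):
        raise DegenerateInstrumentError(
            "every instrument column has zero variance"
        )

    xr, yr, Zr, q = _residual_frame(x, y, Zmat, covariates)

    ZtZ = Zr.T @ Zr
    rank = np.linalg.matrix_rank(ZtZ)
    if rank < m:
        # name columns outside a maximal independent set via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(Zr, mode="economic", pivoting=True)
        offending = sorted(int(j) for j in piv[rank:])
        raise RankDeficiencyError(
            f"instrument cross-product matrix is singular; offending "
            f"columns: {offending}",
            columns=offending,
        )

    ZtX = Zr.T @ xr
    ZtY = Zr.T @ yr
    sol_x = np.linalg.solve(ZtZ, ZtX)
    denom = float(ZtX @ sol_x)  # X'Z (Z'Z)^-1 Z'X
    if denom <= 0:
        raise DegenerateInstrumentError(
            "instrument carries no exposure variation (X'PzX <= 0)"
        )
    beta = float(ZtY @ sol_x) / denom

    e = yr - xr * beta
    dof = n - q - 2
    if robust:
        xhat = Zr @ sol_x
        meat = float(np.sum((xhat * e) ** 2))
        var = meat / denom**2
    else:
        sigma2 = float(e @ e) / dof
        var = sigma2 / denom
    return _wald(
        beta,
        np.sqrt(var),
        method_label,
        n,
        k=k,
        n_instruments=m,
        degenerate_folds=degenerate_folds,
    )


def cfmr1(
    exposure: np.ndarray,
    outcome: np.ndarray,
    cfi: CrossFittedInstrument,
    covariates: Optional[np.ndarray] = None,
    robust: bool = False,
) -> IVEstimate:
    """Equal-weight average of the per-fold 2SLS estimates.

    Each non-degenerate fold contributes the 2SLS of its own exposure and
    outcome on its out-of-fold prediction; degenerate folds are dropped
    with a warning.  The variance treats folds as independent, which is
    approximate (training complements overlap).
    """
    x = np.asarray(exposure, dtype=np.float64)
    y = np.asarray(outcome, dtype=np.float64)
    cov = None
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
        if cov.shape[0] != len(x):
            cov = cov.T

    betas, variances = [], []
    for ki, fold in enumerate(cfi.partition.folds):
        if ki in cfi.degenerate_folds:
            logger.debug("cfmr1: dropping degenerate fold %d", ki)
            continue
        inst = cfi.values[fold]
        if inst.std() <= 0:
            logger.debug("cfmr1: dropping zero-variance fold %d", ki)
            continue
        est = tsls(
            x[fold],
            y[fold],
            inst,
            covariates=None if cov is None else cov[fold],
            robust=robust,
        )
        betas.append(est.beta_hat)
        variances.append(est.se**2)
    if not betas:
        raise DegenerateInstrumentError("all folds are degenerate: no identification")
    kk = len(betas)
    beta = float(np.mean(betas))
    var = float(np.sum(variances)) / kk**2
    return _wald(
        beta,
        np.sqrt(var),
        "CFMR1",
        len(x),
        k=cfi.k,
        n_instruments=1,
        degenerate_folds=cfi.n_degenerate,
    )


def cfmr2(
    exposure: np.ndarray,
    outcome: np.ndarray,
    cfi: CrossFittedInstrument,
    covariates: Optional[np.ndarray] = None,
    robust: bool = False,
) -> IVEstimate:
    """Single 2SLS of the full data on the concatenated instrument.

    Uses the cross-fitted instrument as-is (no per-fold re-centering);
    degenerate folds are reported in the output but do not remove data.
    """
    if np.std(cfi.values) <= 0:
        raise DegenerateInstrumentError(
            "cross-fitted instrument has zero variance"
        )
    return tsls(
        exposure,
        outcome,
        cfi.values,
        covariates=covariates,
        robust=robust,
        method_label="CFMR2",
        k=cfi.k,
        degenerate_folds=cfi.n_degenerate,
    )


def in_sample_instrument(
    exposure: np.ndarray,
    genotypes: np.ndarray,
    selection: Optional[SelectionSpec] = None,
    predictor: Optional[PredictorSpec] = None,
    covariates: Optional[np.ndarray] = None,
) -> np.ndarray:
    """In-sample predicted exposure: the naive one-sample-MR instrument.

    Scans, clumps and thresholds on the *full* sample, trains the predictor
    on the full sample, and returns its prediction on the same rows — the
    construction whose correlation with the outcome noise produces
    endogeneity bias.
    """
    selection = selection or SelectionSpec()
    predictor = predictor or PredictorSpec()
    Z = np.asarray(genotypes)
    all_rows = np.arange(Z.shape[0])

    scan = marginal_scan(Z, exposure, all_rows, covariates=covariates)
    if selection.fixed_variants is not None:
        sel = np.asarray(selection.fixed_variants, dtype=np.intp)
    else:
        clumped = greedy_clump(
            scan,
            Z,
            r2_threshold=selection.clump_r2,
            window_bp=selection.clump_window_bp,
            positions=selection.positions,
        )
        sel = clumped[scan.pvalue[clumped] < selection.p_threshold]
    method = (
        "penalized-regression"
        if predictor.method == "fixed"
        else predictor.method
    )
    fp = fit_predictor(
        Z,
        exposure,
        all_rows,
        sel,
        method=method,
        cv_folds=predictor.cv_folds,
        seed=predictor.seed,
        scan=scan,
        alpha=predictor.alpha,
        n_alphas=predictor.n_alphas,
        eps=predictor.eps,
        tol=predictor.tol,
    )
    if fp.degenerate:
        raise DegenerateInstrumentError(
            "one-sample MR predictor is degenerate (no selected variants "
            "or fully shrunk fit)"
        )
    return fp.predict(Z)


def one_sample_mr(
    exposure: np.ndarray,
    outcome: np.ndarray,
    genotypes: np.ndarray,
    selection: Optional[SelectionSpec] = None,
    predictor: Optional[PredictorSpec] = None,
    covariates: Optional[np.ndarray] = None,
    robust: bool = False,
) -> IVEstimate:
    """Naive one-sample MR: train and apply the predictor on the same data.

    This is the biased baseline — with correlated first- and second-stage
    errors its estimate is pulled toward the confounded association.
    """
    inst = in_sample_instrument(
        exposure, genotypes, selection, predictor, covariates
    )
    return tsls(
        exposure,
        outcome,
        inst,
        covariates=covariates,
        robust=robust,
        method_label="1SMR",
    )


def nagar_bias_term(n_instruments: int, n: int, sigma_uv: float) -> float:
    """Leading endogeneity-bias term of many-instrument 2SLS.

    Proportional to (number of instruments / sample size) times the
    covariance of the first- and second-stage errors.
    """
    if n <= 0:
        raise ConfigurationError("n must be positive")
    return n_instruments / n * sigma_uv
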