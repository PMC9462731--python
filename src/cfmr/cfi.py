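"""K-fold partitioning and cross-fitted instrument assembly.

A cross-fitted instrument (CFI) replaces the usual fitted first stage of
two-stage least squares with out-of-fold predictions: the data are split
into K folds; for each fold k an exposure predictor is trained on the
fold's complement (GWAS scan -> clumping -> P-value filter -> penalized
fit), and the instrument value of every individual in fold k is the
prediction of that individual's exposure by the model that never saw
them.  Concatenating the per-fold predictions gives a length-N instrument
whose construction noise is independent of each individual's outcome
error — the property that removes endogeneity bias from one-sample MR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from . import _lasso
from ._moments import Moments, moments
from .errors import ConfigurationError
from .gwas_instrument import (
    AssociationScan,
    FittedPredictor,
    clump_from_correlation,
    marginal_scan,
)

__all__ = [
    "FoldPartition",
    "SelectionSpec",
    "PredictorSpec",
    "CrossFittedInstrument",
    "make_folds",
    "build_cfi",
    "cfi_diagnostics",
    "CFIDiagnostics",
]

logger = logging.getLogger(__name__)


@dataclass
class FoldPartition:
    """A uniformly random K-fold partition of {0..n-1}."""

    n: int
    k: int
    folds: List[np.ndarray]
    seed: int

    def complement(self, fold_index: int) -> np.ndarray:
        return np.concatenate(
            [f for j, f in enumerate(self.folds) if j != fold_index]
        )

    @property
    def fold_of(self) -> np.ndarray:
        out = np.empty(self.n, dtype=np.intp)
        for j, f in enumerate(self.folds):
            out[f] = j
        return out


def make_folds(n: int, k: int, seed: int) -> FoldPartition:
    """Random partition into K folds whose sizes differ by at most one.

    When K does not divide n, the first ``n mod K`` folds receive one extra
    element.  Deterministic under a fixed seed.
    """
    if k < 2 or k > n:
        raise ConfigurationError(f"k must satisfy 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    base, extra = divmod(n, k)
    folds, start = [], 0
    for j in range(k):
        size = base + (1 if j < extra else 0)
        folds.append(np.sort(perm[start : start + size]))
        start += size
    return FoldPartition(n=n, k=k, folds=folds, seed=seed)


@dataclass
class SelectionSpec:
    """Variant-selection settings for each per-fold scan.

    ``p_threshold`` is the strict P-value cutoff applied after clumping;
    ``1.0`` lets every (clumped) variant through to the predictor, which is
    the convention for simulated cohorts of independent variants.
    ``fixed_variants`` bypasses scan-based selection entirely (a testing
    and oracle-analysis hook).
    """

    p_threshold: float = 1e-6
    clump_r2: float = 0.1
    clump_window_bp: Optional[float] = None
    positions: Optional[np.ndarray] = None
    fixed_variants: Optional[np.ndarray] = None


@dataclass
class PredictorSpec:
    """Predictor-training settings.

    ``cv_folds`` controls the penalty search when ``method`` is
    ``penalized-regression``; inside :func:`build_cfi` the K-1 co-folds of
    the partition are reused as CV splits whenever there are between 2 and
    20 of them (deterministic and cheap), otherwise ``cv_folds`` random
    splits of the training set are drawn from ``seed``.  ``alpha`` pins the
    penalty (``inf`` = intercept-only).  ``method="fixed"`` evaluates the
    supplied affine map in every fold without training (oracle hook).
    """

    method: str = "penalized-regression"
    cv_folds: int = 10
    n_alphas: int = 30
    eps: float = 2e-2  # penalty floor as a fraction of the null penalty
    tol: float = 1e-4
    seed: int = 0
    alpha: Optional[float] = None
    fixed_weights: Optional[np.ndarray] = None
    fixed_intercept: float = 0.0


@dataclass
class CrossFittedInstrument:
    """The concatenated out-of-fold exposure predictions with diagnostics."""

    values: np.ndarray  # (n,) instrument
    fold_of: np.ndarray  # individual -> fold index
    per_fold_predictors: List[FittedPredictor]
    heldout_r2: np.ndarray  # per-fold squared correlation with the exposure
    degenerate_folds: List[int]
    partition: FoldPartition = field(repr=False)

    @property
    def k(self) -> int:
        return self.partition.k

    @property
    def n_degenerate(self) -> int:
        return len(self.degenerate_folds)

    def to_frame(self, individual_ids=None):
        import pandas as pd

        ids = (
            np.arange(len(self.values)) if individual_ids is None else individual_ids
        )
        return pd.DataFrame(
            {"individual": ids, "fold": self.fold_of, "instrument": self.values}
        )

    def to_tsv(self, path, individual_ids=None):
        self.to_frame(individual_ids).to_csv(path, sep="\t", index=False)


def _fold_scan(
    mc: Moments,
    genotypes,
    exposure,
    complement,
    covariates,
) -> AssociationScan:
    if covariates is None:
        beta, se, p, zero = mc.marginal_scan()
        return AssociationScan(
            variant_ids=np.arange(len(beta)),
            beta=beta,
            se=se,
            pvalue=p,
            n_used=mc.n,
            indices=complement,
            zero_variance=zero,
        )
    return marginal_scan(genotypes, exposure, complement, covariates)


def _select_variants(spec: SelectionSpec, scan: AssociationScan, mc: Moments):
    if spec.fixed_variants is not None:
        return np.asarray(spec.fixed_variants, dtype=np.intp)
    r2 = mc.corr() ** 2
    clumped = clump_from_correlation(
        r2,
        scan.pvalue,
        spec.clump_r2,
        positions=spec.positions,
        window_bp=spec.clump_window_bp,
    )
    return clumped[scan.pvalue[clumped] < spec.p_threshold]


def build_cfi(
    genotypes: np.ndarray,
    exposure: np.ndarray,
    partition: FoldPartition,
    selection: Optional[SelectionSpec] = None,
    predictor: Optional[PredictorSpec] = None,
    covariates: Optional[np.ndarray] = None,
) -> CrossFittedInstrument:
    """Assemble the K-fold cross-fitted instrument.

    For each fold: scan the complement, clump, filter by P-value, train the
    predictor on the complement, and predict the fold.  Folds whose
    selection is empty (or whose penalized fit shrinks every coefficient to
    zero) yield intercept-only predictions and are flagged degenerate; the
    estimators downstream decide whether identification survives.
    """
    selection = selection or SelectionSpec()
    predictor = predictor or PredictorSpec()
    Z = np.asarray(genotypes)
    x = np.asarray(exposure, dtype=np.float64)
    if Z.shape[0] != partition.n or len(x) != partition.n:
        raise ConfigurationError("partition does not match the data dimensions")
    n, p = Z.shape

    if predictor.method == "fixed":
        if predictor.fixed_weights is None:
            raise ConfigurationError("method='fixed' requires fixed_weights")
        w = np.asarray(predictor.fixed_weights, dtype=np.float64)
        values = np.asarray(Z, dtype=np.float64) @ w + predictor.fixed_intercept
        preds, heldout, degenerate = [], [], []
        for ki in range(partition.k):
            fp = FittedPredictor(
                selected_ids=np.flatnonzero(w != 0.0),
                weights=w[w != 0.0],
                intercept=float(predictor.fixed_intercept),
                training_indices=partition.complement(ki),
                method="fixed",
                degenerate=not np.any(w != 0.0),
            )
            preds.append(fp)
            heldout.append(_squared_corr(values[partition.folds[ki]],
                                         x[partition.folds[ki]]))
            if fp.degenerate:
                degenerate.append(ki)
        return CrossFittedInstrument(
            values, partition.fold_of, preds, np.array(heldout), degenerate,
            partition,
        )

    fold_moms = [moments(Z, x, f) for f in partition.folds]

    # Complement statistics are assembled from the *other* folds' sums
    # (prefix + suffix), never by subtracting fold k from the grand total:
    # that keeps predictor k bitwise independent of fold k's data, which is
    # the no-leakage contract.  For very large K x p the prefix store is
    # traded for plain subtraction (identical up to rounding).
    k_total = partition.k
    exact = k_total * p * p <= 5_000_000
    if exact:
        zero = Moments(0, np.zeros(p), 0.0, 0.0, np.zeros((p, p)), np.zeros(p))
        prefix = [zero]
        for m in fold_moms:
            prefix.append(prefix[-1] + m)
        suffix = [zero]
        for m in reversed(fold_moms):
            suffix.append(suffix[-1] + m)
        suffix = suffix[::-1]
        complements = [prefix[ki] + suffix[ki + 1] for ki in range(k_total)]
    else:
        total = fold_moms[0]
        for m in fold_moms[1:]:
            total = total + m
        complements = [total - fold_moms[ki] for ki in range(k_total)]

    values = np.empty(n, dtype=np.float64)
    preds: List[FittedPredictor] = []
    heldout: List[float] = []
    degenerate: List[int] = []

    for ki in range(partition.k):
        fold = partition.folds[ki]
        complement = partition.complement(ki)
        mc = complements[ki]
        if selection.fixed_variants is not None and predictor.method != "allele-score":
            scan = None  # selection is pinned; the scan would be unused
            sel = np.asarray(selection.fixed_variants, dtype=np.intp)
        else:
            scan = _fold_scan(mc, Z, x, complement, covariates)
            sel = _select_variants(selection, scan, mc)

        fp = _train_fold_predictor(
            Z, x, mc, fold_moms, partition, ki, sel, scan, predictor, complement
        )
        preds.append(fp)
        pred_k = fp.predict(Z, fold)
        values[fold] = pred_k
        heldout.append(_squared_corr(pred_k, x[fold]))
        if fp.degenerate:
            degenerate.append(ki)
            logger.debug("fold %d: degenerate (intercept-only) predictor", ki)

    return CrossFittedInstrument(
        values=values,
        fold_of=partition.fold_of,
        per_fold_predictors=preds,
        heldout_r2=np.array(heldout),
        degenerate_folds=degenerate,
        partition=partition,
    )


def _train_fold_predictor(
    Z, x, mc, fold_moms, partition, ki, sel, scan, spec: PredictorSpec,
    complement,
) -> FittedPredictor:
    if len(sel) == 0:
        return FittedPredictor(
            selected_ids=sel,
            weights=np.zeros(0),
            intercept=float(mc.xbar),
            training_indices=complement,
            method=spec.method,
            training_r2=0.0,
            degenerate=True,
        )
    mc_sel = mc.select(sel)
    chosen_alpha = None
    if spec.method in ("penalized-regression", "lasso"):
        Zsel = Z if len(sel) == Z.shape[1] else Z[:, sel]
        co_folds = partition.k - 1
        if spec.alpha is None and 2 <= co_folds <= 20:
            chunk_moms = [
                fold_moms[j].select(sel)
                for j in range(partition.k)
                if j != ki
            ]
            chunk_rows = [
                partition.folds[j] for j in range(partition.k) if j != ki
            ]
            fit = _lasso.lasso_cv_moments(
                mc_sel, chunk_moms, chunk_rows, Zsel, x,
                n_alphas=spec.n_alphas, eps=spec.eps, tol=spec.tol,
            )
        else:
            fit = _lasso.lasso_cv(
                Zsel, x, rows=complement, cv_folds=spec.cv_folds,
                seed=spec.seed + ki, alpha=spec.alpha, n_alphas=spec.n_alphas,
                eps=spec.eps, tol=spec.tol,
            )
        weights, intercept, chosen_alpha = fit.coef, fit.intercept, fit.alpha
    elif spec.method in ("least-squares", "ols"):
        weights, intercept = mc_sel.ols()
    elif spec.method == "allele-score":
        weights = np.nan_to_num(scan.beta[sel], nan=0.0)
        intercept = float(mc_sel.xbar - weights @ mc_sel.center)
    else:
        raise ConfigurationError(f"unknown predictor method: {spec.method!r}")

    degenerate = not np.any(weights != 0.0)
    syy = mc_sel.syy
    r2 = 0.0
    if syy > 0 and not degenerate:
        r2 = float(max(0.0, 1.0 - mc_sel.rss(np.asarray(weights)) / syy))
    return FittedPredictor(
        selected_ids=sel,
        weights=np.asarray(weights, dtype=np.float64),
        intercept=float(intercept),
        training_indices=complement,
        method=spec.method,
        training_r2=r2,
        degenerate=degenerate,
        alpha=chosen_alpha,
    )


def _squared_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation; nan when either side is constant."""
    if len(a) < 2:
        return float("nan")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    r = float(np.corrcoef(a, b)[0, 1])
    return r * r


@dataclass
class CFIDiagnostics:
    """Held-out variance explained and confounder-association checks."""

    variance_explained_pct: float
    zero_variance: bool
    confounders: "object"  # pandas DataFrame: confounder, slope, se, pvalue


def cfi_diagnostics(
    cfi: CrossFittedInstrument,
    exposure: np.ndarray,
    candidate_confounders: Optional[np.ndarray] = None,
    confounder_names: Optional[Sequence[str]] = None,
) -> CFIDiagnostics:
    """Overall instrument quality and confounder-association screen.

    Variance explained is the squared correlation of the instrument with
    the exposure, as a percentage.  Each candidate confounder is regressed
    on the instrument (simple regression; slope, SE, two-sided p).
    """
    import pandas as pd
    from scipy import stats as sps

    x = np.asarray(exposure, dtype=np.float64)
    v = cfi.values
    zero = v.std() <= 0
    if zero:
        pct = float("nan")
    else:
        pct = 100.0 * _squared_corr(v, x)

    rows = []
    if candidate_confounders is not None and not zero:
        C = np.atleast_2d(np.asarray(candidate_confounders, dtype=np.float64))
        if C.shape[0] != len(v):
            C = C.T
        names = (
            list(confounder_names)
            if confounder_names is not None
            else [f"confounder_{j}" for j in range(C.shape[1])]
        )
        vc = v - v.mean()
        sxx = float(vc @ vc)
        n = len(v)
        for j, name in enumerate(names):
            c = C[:, j]
            slope = float(vc @ (c - c.mean())) / sxx
            resid = (c - c.mean()) - slope * vc
            sigma2 = float(resid @ resid) / (n - 2)
            se = np.sqrt(sigma2 / sxx)
            t = slope / se if se > 0 else np.inf
            pv = 2.0 * sps.t.sf(abs(t), n - 2)
            rows.append({"confounder": name, "slope": slope, "se": se,
                         "pvalue": pv})
    table = pd.DataFrame(rows, columns=["confounder", "slope", "se", "pvalue"])
    return CFIDiagnostics(
        variance_explained_pct=pct, zero_variance=bool(zero), confounders=table
    )
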