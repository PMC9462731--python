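"""Raw cross-product accumulators for genotype/phenotype blocks.

Everything the per-fold GWAS scan, the greedy clumping rule, the ordinary
least-squares predictor and the penalized path need from a set of rows can
be expressed through the raw sums

    n, sum(Z), sum(x), x'x, Z'Z, Z'x.

Accumulating these once per fold and forming fold *complements* by
subtraction avoids re-reading the dosage matrix for every training set,
which is what makes K-fold cross-fitting affordable at Monte-Carlo scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg.blas import dsyrk
from scipy import stats

__all__ = ["Moments", "moments"]

_EPS_VAR = 1e-12


def _gram(a: np.ndarray) -> np.ndarray:
    """Symmetric a'a via BLAS syrk (a must be Fortran-ordered float64)."""
    upper = dsyrk(1.0, a, trans=1, lower=0)
    return upper + np.triu(upper, 1).T


@dataclass
class Moments:
    """Raw sufficient statistics of (Z, x) over one row block."""

    n: int
    zsum: np.ndarray  # (p,)
    xsum: float
    xss: float  # x'x
    G: np.ndarray  # (p, p) raw Z'Z
    b: np.ndarray  # (p,) raw Z'x

    def __sub__(self, other: "Moments") -> "Moments":
        return Moments(
            n=self.n - other.n,
            zsum=self.zsum - other.zsum,
            xsum=self.xsum - other.xsum,
            xss=self.xss - other.xss,
            G=self.G - other.G,
            b=self.b - other.b,
        )

    def __add__(self, other: "Moments") -> "Moments":
        return Moments(
            n=self.n + other.n,
            zsum=self.zsum + other.zsum,
            xsum=self.xsum + other.xsum,
            xss=self.xss + other.xss,
            G=self.G + other.G,
            b=self.b + other.b,
        )

    # -- derived, centered quantities -------------------------------------

    @property
    def center(self) -> np.ndarray:
        return self.zsum / self.n

    @property
    def xbar(self) -> float:
        return self.xsum / self.n

    def centered_gram(self) -> np.ndarray:
        c = self.center
        return self.G - self.n * np.outer(c, c)

    def centered_cross(self) -> np.ndarray:
        return self.b - self.center * self.xsum

    @property
    def syy(self) -> float:
        return float(self.xss - self.xsum**2 / self.n)

    def column_sd(self) -> np.ndarray:
        var = np.diag(self.centered_gram()) / self.n
        return np.sqrt(np.clip(var, 0.0, None))

    def corr(self) -> np.ndarray:
        """Sample correlation matrix of the columns (zero-variance -> 0)."""
        gc = self.centered_gram()
        sd = np.sqrt(np.clip(np.diag(gc), 0.0, None))
        safe = np.where(sd > _EPS_VAR, sd, 1.0)
        r = gc / np.outer(safe, safe)
        bad = sd <= _EPS_VAR
        if bad.any():
            r[bad, :] = 0.0
            r[:, bad] = 0.0
        np.fill_diagonal(r, 1.0)
        return np.clip(r, -1.0, 1.0)

    def select(self, cols: np.ndarray) -> "Moments":
        """Restrict the statistics to a subset of columns."""
        cols = np.asarray(cols)
        if len(cols) == self.G.shape[0] and np.array_equal(
            cols, np.arange(self.G.shape[0])
        ):
            return self
        return Moments(
            n=self.n,
            zsum=self.zsum[cols],
            xsum=self.xsum,
            xss=self.xss,
            G=self.G[np.ix_(cols, cols)],
            b=self.b[cols],
        )

    # -- closed-form fits --------------------------------------------------

    def marginal_scan(self, n_covariates: int = 0):
        """Per-column simple regression of x on the column.

        Returns ``(beta, se, pvalue, zero_variance)`` arrays; columns with
        (numerically) zero dosage variance get ``beta = se = nan`` and
        ``p = 1`` with the flag set.
        """
        sxx = np.diag(self.centered_gram()).astype(float)
        sxy = self.centered_cross()
        syy = self.syy
        zero = sxx <= _EPS_VAR * max(1.0, self.n)
        sxx_safe = np.where(zero, 1.0, sxx)
        beta = sxy / sxx_safe
        df = self.n - 2 - n_covariates
        sse = np.clip(syy - beta * sxy, 0.0, None)
        sigma2 = sse / df
        se = np.sqrt(sigma2 / sxx_safe)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(
                se > 0,
                beta / np.where(se > 0, se, 1.0),
                np.where(beta == 0.0, 0.0, np.inf),
            )
        pvalue = 2.0 * stats.t.sf(np.abs(t), df)
        beta = np.where(zero, np.nan, beta)
        se = np.where(zero, np.nan, se)
        pvalue = np.where(zero, 1.0, pvalue)
        return beta, se, pvalue, zero

    def ols(self):
        """Least-squares fit of x on all columns plus intercept.

        Returns ``(coef, intercept)``; rank-deficient Grams fall back to the
        pseudoinverse solution.
        """
        gc = self.centered_gram()
        bc = self.centered_cross()
        try:
            coef = np.linalg.solve(gc, bc)
        except np.linalg.LinAlgError:
            coef = np.linalg.lstsq(gc, bc, rcond=None)[0]
        intercept = self.xbar - coef @ self.center
        return coef, float(intercept)

    def rss(self, coef: np.ndarray, cols=None) -> float:
        """Residual sum of squares of the affine fit with these weights."""
        m = self if cols is None else self.select(np.asarray(cols))
        gc = m.centered_gram()
        bc = m.centered_cross()
        return float(m.syy - 2.0 * coef @ bc + coef @ gc @ coef)


def moments(Z: np.ndarray, x: np.ndarray, rows=None) -> Moments:
    """Accumulate raw sufficient statistics over ``rows`` (default: all)."""
    if rows is not None:
        Zb = Z[np.asarray(rows)]
        xb = np.asarray(x, dtype=np.float64)[np.asarray(rows)]
    else:
        Zb = Z
        xb = np.asarray(x, dtype=np.float64)
    Zb = np.asfortranarray(Zb, dtype=np.float64)
    return Moments(
        n=Zb.shape[0],
        zsum=Zb.sum(axis=0),
        xsum=float(xb.sum()),
        xss=float(xb @ xb),
        G=_gram(Zb),
        b=Zb.T @ xb,
    )
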