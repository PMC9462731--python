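"""Monte-Carlo evaluation of the estimators over scenario grids.

Drives the full pipeline — simulate a cohort, build the cross-fitted
instrument, run the requested estimators — over a grid of scenario cells
(sample size x effect size x heritability x confounding), recording
per-replicate estimates so that type-I error, power, bias, empirical SD
and SE calibration can all be summarized afterwards.  Replicate r of every
cell uses data seed ``base_seed + r``, so cells with matching generative
parameters share genotype draws and method contrasts are within-replicate.

Also provides the closed-form asymptotic power of two-sample MR that the
cross-fitted estimator is benchmarked against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .cfi import PredictorSpec, SelectionSpec, build_cfi, make_folds
from .errors import CfmrError, ConfigurationError
from .estimators import cfmr1, cfmr2, in_sample_instrument, tsls
from .simdata import SimulationConfig, simulate_dataset

__all__ = [
    "ScenarioGrid",
    "SimulationSummary",
    "run_scenario_grid",
    "theoretical_power_2smr",
    "summarize_bias_comparison",
]

logger = logging.getLogger(__name__)

_METHODS = ("CFMR1", "CFMR2", "1SMR")


@dataclass
class ScenarioGrid:
    """A list of scenario cells plus the Monte-Carlo settings."""

    configs: Sequence[SimulationConfig]
    replicates: int = 200
    methods: Tuple[str, ...] = ("CFMR2",)
    alpha_levels: Tuple[float, ...] = (0.05,)
    base_seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        for a in self.alpha_levels:
            if not (0 < a < 1):
                raise ConfigurationError("alpha levels must lie in (0, 1)")
        for m in self.methods:
            if m not in _METHODS:
                raise ConfigurationError(
                    f"unknown method {m!r}; choose from {_METHODS}"
                )


@dataclass
class SimulationSummary:
    """Per-replicate estimates plus the per-cell summary table."""

    estimates: pd.DataFrame
    alpha_levels: Tuple[float, ...] = (0.05,)
    table: pd.DataFrame = field(init=False)

    def __post_init__(self):
        self.table = self._summarize()

    def _summarize(self) -> pd.DataFrame:
        rows = []
        keys = ["method", "n", "h2", "beta0", "sigma_uv"]
        for key, grp in self.estimates.groupby(keys, sort=True):
            ok = grp[~grp["failed"]]
            row = dict(zip(keys, key))
            row["replicates"] = len(grp)
            row["n_failed"] = int(grp["failed"].sum())
            row["mean_estimate"] = ok["estimate"].mean() if len(ok) else np.nan
            row["empirical_sd"] = (
                ok["estimate"].std(ddof=1) if len(ok) > 1 else np.nan
            )
            row["mean_se"] = ok["se"].mean() if len(ok) else np.nan
            for a in self.alpha_levels:
                row[f"reject_at_{a:g}"] = (
                    float((ok["pvalue"] < a).mean()) if len(ok) else np.nan
                )
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path):
        self.table.to_csv(path, sep="\t", index=False)


def _replicate_seeds(base_seed: int, r: int) -> Tuple[int, int, int]:
    """Data seed is base+r (regenerable); partition/CV seeds derive from it
    through an independent stream so fold draws never reuse genotype draws."""
    data_seed = base_seed + r
    aux = np.random.SeedSequence([data_seed, 7]).generate_state(2)
    return data_seed, int(aux[0] & 0x7FFFFFFF), int(aux[1] & 0x7FFFFFFF)


def run_scenario_grid(
    grid: ScenarioGrid,
    partition_k: int = 10,
    selection: Optional[SelectionSpec] = None,
    predictor: Optional[PredictorSpec] = None,
) -> SimulationSummary:
    """Execute every cell x replicate and collect the estimates.

    Simulated cohorts of independent variants default to selection with
    ``p_threshold = 1.0`` (every clumped variant enters the penalized
    fit).  Replicates whose instrument degenerates are recorded as failed
    rows, not dropped.
    """
    selection = selection or SelectionSpec(p_threshold=1.0)
    base_predictor = predictor or PredictorSpec()

    # Cells that differ only in beta0 share every draw under matched seeds:
    # genotypes, exposure and the error pair (U, V) are beta0-free, and
    # Y = beta0 * X + U.  Instruments depend on (Z, X) only, so they are
    # built once per replicate and reused across the beta0 grid.
    groups: dict = {}
    for cfg in grid.configs:
        key = replace(cfg, beta0=0.0, seed=0)
        groups.setdefault(key, []).append(cfg.beta0)

    rows = []
    for key_cfg, beta0s in groups.items():
        for r in range(grid.replicates):
            data_seed, part_seed, cv_seed = _replicate_seeds(grid.base_seed, r)
            ds = simulate_dataset(replace(key_cfg, seed=data_seed))
            u = ds.outcome  # beta0 = 0, so the outcome is the U draw
            pred_spec = replace(base_predictor, seed=cv_seed)

            cfi = cfi_error = None
            if any(m in grid.methods for m in ("CFMR1", "CFMR2")):
                partition = make_folds(ds.n, partition_k, seed=part_seed)
                try:
                    cfi = build_cfi(
                        ds.genotypes, ds.exposure, partition, selection,
                        pred_spec,
                    )
                except CfmrError as exc:
                    cfi_error = exc
            smr_inst = smr_error = None
            if "1SMR" in grid.methods:
                try:
                    smr_inst = in_sample_instrument(
                        ds.exposure, ds.genotypes, selection, pred_spec
                    )
                except CfmrError as exc:
                    smr_error = exc

            for beta0 in beta0s:
                y = beta0 * ds.exposure + u
                for m in grid.methods:
                    base = {
                        "method": m,
                        "n": key_cfg.n_individuals,
                        "h2": key_cfg.h2,
                        "beta0": beta0,
                        "sigma_uv": key_cfg.sigma_uv,
                        "replicate": r,
                        "seed": data_seed,
                    }
                    try:
                        if m == "CFMR1":
                            if cfi_error is not None:
                                raise cfi_error
                            est = cfmr1(ds.exposure, y, cfi)
                        elif m == "CFMR2":
                            if cfi_error is not None:
                                raise cfi_error
                            est = cfmr2(ds.exposure, y, cfi)
                        else:
                            if smr_error is not None:
                                raise smr_error
                            est = tsls(ds.exposure, y, smr_inst,
                                       method_label="1SMR")
                        rows.append(
                            {
                                **base,
                                "estimate": est.beta_hat,
                                "se": est.se,
                                "pvalue": est.pvalue,
                                "failed": False,
                                "error": "",
                            }
                        )
                    except CfmrError as exc:
                        logger.debug(
                            "cell %s rep %d method %s failed: %s",
                            key_cfg, r, m, exc,
                        )
                        rows.append(
                            {
                                **base,
                                "estimate": np.nan,
                                "se": np.nan,
                                "pvalue": np.nan,
                                "failed": True,
                                "error": type(exc).__name__,
                            }
                        )
    return SimulationSummary(
        estimates=pd.DataFrame(rows), alpha_levels=grid.alpha_levels
    )


def theoretical_power_2smr(
    beta0: float,
    n: int,
    h2: float,
    var_x: float,
    sigma_u2: float,
    alpha: float = 0.05,
) -> float:
    """Asymptotic power of two-sample MR at nominal level alpha.

    Uses the asymptotic standard error ``SE = sqrt(sigma_u2 / (n h2
    var_x))`` of an IV estimate whose instrument explains fraction ``h2``
    of an exposure with variance ``var_x``; power is the two-sided normal
    rejection probability.  ``h2 = 0`` carries no information: power equals
    the nominal level.
    """
    if not (0 < alpha < 1):
        raise ConfigurationError("alpha must lie in (0, 1)")
    if n <= 0 or var_x <= 0 or sigma_u2 <= 0:
        raise ConfigurationError("n, var_x and sigma_u2 must be positive")
    if h2 <= 0:
        return float(alpha)
    se_inf = np.sqrt(sigma_u2 / (n * h2 * var_x))
    z = stats.norm.ppf(1 - alpha / 2)
    shift = abs(beta0) / se_inf
    return float(stats.norm.cdf(-z + shift) + stats.norm.cdf(-z - shift))


def summarize_bias_comparison(
    summary: SimulationSummary,
    methods: Tuple[str, str] = ("1SMR", "CFMR2"),
) -> pd.DataFrame:
    """Matched-seed bias contrast between two methods, per (n, h2) cell.

    Requires both methods to be present on identical replicate seeds in
    every cell; the contrast column is the within-replicate difference of
    estimates, so Monte-Carlo noise common to both methods cancels.
    """
    est = summary.estimates
    m_a, m_b = methods
    rows = []
    for (n, h2, beta0, suv), grp in est.groupby(
        ["n", "h2", "beta0", "sigma_uv"], sort=True
    ):
        a = grp[(grp["method"] == m_a) & ~grp["failed"]].set_index("seed")
        b = grp[(grp["method"] == m_b) & ~grp["failed"]].set_index("seed")
        if len(a) == 0 or len(b) == 0:
            raise ConfigurationError(
                f"cell (n={n}, h2={h2}) lacks estimates for both methods"
            )
        common = a.index.intersection(b.index)
        if len(common) == 0:
            raise ConfigurationError(
                f"cell (n={n}, h2={h2}): no matched seeds between methods"
            )
        diff = a.loc[common, "estimate"] - b.loc[common, "estimate"]
        row = {"n": n, "h2": h2, "beta0": beta0, "sigma_uv": suv,
               "n_matched": len(common)}
        for label, sub in ((m_a, a), (m_b, b)):
            est_vals = sub["estimate"]
            row[f"mean_{label}"] = est_vals.mean()
            row[f"bias_{label}"] = est_vals.mean() - beta0
            row[f"mc_se_{label}"] = est_vals.std(ddof=1) / np.sqrt(len(est_vals))
        row["contrast_mean"] = diff.mean()
        row["contrast_mc_se"] = (
            diff.std(ddof=1) / np.sqrt(len(diff)) if len(diff) > 1 else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)


def plot_power_curves(summary: SimulationSummary, sigma_u2: float,
                      var_x: float, alpha: float = 0.05, path=None):
    """Empirical power per cell against the closed-form two-sample curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = summary.table
    fig, ax = plt.subplots(figsize=(6, 4))
    for (method, h2), grp in table.groupby(["method", "h2"]):
        grp = grp.sort_values("beta0")
        ax.plot(grp["beta0"], grp[f"reject_at_{alpha:g}"], "o--",
                label=f"{method}, h2={h2:g} (empirical)")
        theo = [
            theoretical_power_2smr(b, n, h2, var_x, sigma_u2, alpha)
            for b, n in zip(grp["beta0"], grp["n"])
        ]
        ax.plot(grp["beta0"], theo, "-", label=f"2SMR closed form, h2={h2:g}")
    ax.set_xlabel("causal effect")
    ax.set_ylabel(f"power at alpha={alpha:g}")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_bias_boxplots(summary: SimulationSummary, path=None):
    """Box plots of per-replicate estimates by method and sample size."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    est = summary.estimates
    ok = est[~est["failed"]]
    fig, ax = plt.subplots(figsize=(7, 4))
    groups, labels = [], []
    for (method, n), grp in ok.groupby(["method", "n"]):
        groups.append(grp["estimate"].to_numpy())
        labels.append(f"{method}\nN={n}")
    ax.boxplot(groups, tick_labels=labels)
    beta0 = est["beta0"].iloc[0]
    ax.axhline(beta0, color="black", lw=1)
    ax.set_ylabel("estimated effect")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
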