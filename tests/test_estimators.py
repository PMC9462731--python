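"""2SLS and its cross-fitted variants against brute-force matrix oracles,
algebraic identities, and the Jackknife-IV special case."""

import numpy as np
import pytest

from cfmr import (
    DegenerateInstrumentError,
    PredictorSpec,
    RankDeficiencyError,
    SelectionSpec,
    SimulationConfig,
    build_cfi,
    cfmr1,
    cfmr2,
    make_folds,
    nagar_bias_term,
    one_sample_mr,
    simulate_dataset,
    tsls,
)


def _tsls_oracle(x, y, Z):
    """Direct evaluation of the 2SLS matrix expression (demeaned frame)."""
    xr = x - x.mean()
    yr = y - y.mean()
    Zr = Z - Z.mean(axis=0)
    P = Zr @ np.linalg.inv(Zr.T @ Zr) @ Zr.T
    return float((xr @ P @ yr) / (xr @ P @ xr))


class TestTsls:
    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            n = int(rng.integers(30, 201))
            m = int(rng.integers(1, 6))
            Z = rng.normal(size=(n, m))
            x = Z @ rng.normal(size=m) + rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            est = tsls(x, y, Z)
            assert est.beta_hat == pytest.approx(_tsls_oracle(x, y, Z),
                                                 abs=1e-10)

    def test_single_instrument_equals_wald_ratio(self, rng):
        n = 500
        z = rng.binomial(2, 0.3, n).astype(float)
        x = 0.5 * z + rng.normal(size=n)
        y = 2.0 * x + rng.normal(size=n)
        est = tsls(x, y, z)
        wald = np.cov(z, y, ddof=1)[0, 1] / np.cov(z, x, ddof=1)[0, 1]
        assert est.beta_hat == pytest.approx(wald, abs=1e-10)

    def test_self_instrument_collapses_to_ols(self, rng):
        n = 400
        x = rng.normal(size=n)
        y = 3.0 * x + rng.normal(size=n)
        est = tsls(x, y, x)
        ols = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert est.beta_hat == pytest.approx(ols, abs=1e-10)
        assert est.beta_hat == pytest.approx(3.0, abs=0.2)

    def test_scale_equivariance(self, rng):
        n = 300
        Z = rng.normal(size=(n, 2))
        x = Z @ [1.0, 0.5] + rng.normal(size=n)
        y = 0.7 * x + rng.normal(size=n)
        base = tsls(x, y, Z)
        out_scaled = tsls(x, 10.0 * y, Z)
        assert out_scaled.beta_hat == pytest.approx(10 * base.beta_hat,
                                                    rel=1e-12)
        assert out_scaled.se == pytest.approx(10 * base.se, rel=1e-12)
        exp_scaled = tsls(4.0 * x, y, Z)
        assert exp_scaled.beta_hat == pytest.approx(base.beta_hat / 4,
                                                    rel=1e-12)
        assert exp_scaled.se == pytest.approx(base.se / 4, rel=1e-12)

    def test_instrument_rescaling_is_irrelevant(self, rng):
        n = 300
        z = rng.normal(size=n)
        x = z + rng.normal(size=n)
        y = x + rng.normal(size=n)
        a = tsls(x, y, z)
        b = tsls(x, y, 1000.0 * z)
        assert a.beta_hat == pytest.approx(b.beta_hat, abs=1e-10)
        assert a.se == pytest.approx(b.se, rel=1e-10)

    def test_ci_is_symmetric_wald(self, rng):
        n = 200
        z = rng.normal(size=n)
        x = z + rng.normal(size=n)
        y = x + rng.normal(size=n)
        est = tsls(x, y, z)
        assert est.ci_low == pytest.approx(est.beta_hat - 1.959964 * est.se,
                                           abs=1e-9)
        assert est.ci_high == pytest.approx(est.beta_hat + 1.959964 * est.se,
                                            abs=1e-9)
        assert est.ci_low <= est.beta_hat <= est.ci_high

    def test_covariate_residualization_matches_two_stage(self, rng):
        """Frisch-Waugh residualization equals carrying the covariates in
        both stages (statsmodels IV-style manual check)."""
        n = 500
        c = rng.normal(size=(n, 2))
        z = rng.normal(size=n) + c @ [0.5, 0.2]
        x = z + c @ [1.0, -1.0] + rng.normal(size=n)
        y = 0.5 * x + c @ [0.3, 0.7] + rng.normal(size=n)
        est = tsls(x, y, z, covariates=c)
        # manual two-stage with covariates in both stages
        D = np.column_stack([np.ones(n), c])
        stage1 = np.column_stack([z, D])
        coef1, *_ = np.linalg.lstsq(stage1, x, rcond=None)
        xhat = stage1 @ coef1
        stage2 = np.column_stack([xhat, D])
        coef2, *_ = np.linalg.lstsq(stage2, y, rcond=None)
        assert est.beta_hat == pytest.approx(coef2[0], abs=1e-8)

    def test_rank_deficiency_names_columns(self, rng):
        n = 100
        z = rng.normal(size=n)
        Z = np.column_stack([z, z, rng.normal(size=n)])
        x = z + rng.normal(size=n)
        y = x + rng.normal(size=n)
        with pytest.raises(RankDeficiencyError) as err:
            tsls(x, y, Z)
        assert len(err.value.columns) == 1

    def test_zero_variance_instrument_rejected(self, rng):
        n = 50
        x = rng.normal(size=n)
        with pytest.raises(DegenerateInstrumentError):
            tsls(x, x, np.ones(n))


class TestCfmrEstimators:
    def test_cfmr1_equals_mean_of_fold_wald_ratios(self, small_cohort):
        ds = small_cohort
        part = make_folds(ds.n, 2, seed=1)
        cfi = build_cfi(ds.genotypes, ds.exposure, part,
                        SelectionSpec(p_threshold=1.0))
        est = cfmr1(ds.exposure, ds.outcome, cfi)
        walds = []
        for k in range(2):
            f = part.folds[k]
            z, x, y = cfi.values[f], ds.exposure[f], ds.outcome[f]
            walds.append(np.cov(z, y, ddof=1)[0, 1] / np.cov(z, x, ddof=1)[0, 1])
        assert est.beta_hat == pytest.approx(np.mean(walds), abs=1e-10)
        assert est.k == 2

    def test_cfmr1_constant_folds_returns_common_value(self, small_cohort):
        """Duplicated data in both folds forces identical per-fold estimates."""
        ds = small_cohort
        half = ds.n // 2
        g = np.vstack([ds.genotypes[:half], ds.genotypes[:half]])
        x = np.concatenate([ds.exposure[:half], ds.exposure[:half]])
        y = np.concatenate([ds.outcome[:half], ds.outcome[:half]])
        from cfmr.cfi import CrossFittedInstrument, FoldPartition

        folds = [np.arange(0, half), np.arange(half, 2 * half)]
        part = FoldPartition(n=2 * half, k=2, folds=folds, seed=0)
        vals = g.astype(float) @ ds.true_pi
        cfi = CrossFittedInstrument(
            values=vals, fold_of=part.fold_of, per_fold_predictors=[],
            heldout_r2=np.array([np.nan, np.nan]), degenerate_folds=[],
            partition=part,
        )
        est = cfmr1(x, y, cfi)
        single = tsls(x[folds[0]], y[folds[0]], vals[folds[0]])
        assert est.beta_hat == pytest.approx(single.beta_hat, abs=1e-12)

    def test_cfmr2_with_global_affine_map_equals_tsls(self, small_cohort):
        ds = small_cohort
        part = make_folds(ds.n, 5, seed=2)
        w = ds.true_pi
        cfi = build_cfi(
            ds.genotypes, ds.exposure, part,
            predictor=PredictorSpec(method="fixed", fixed_weights=w,
                                    fixed_intercept=1.5),
        )
        est = cfmr2(ds.exposure, ds.outcome, cfi)
        ref = tsls(ds.exposure, ds.outcome,
                   ds.genotypes.astype(float) @ w + 1.5)
        assert est.beta_hat == pytest.approx(ref.beta_hat, abs=1e-12)
        assert est.se == pytest.approx(ref.se, rel=1e-12)

    def test_jackknife_iv_special_case(self):
        """K = N with leave-one-out least-squares predictors equals an
        independently coded Jackknife IV estimator."""
        cfg = SimulationConfig(
            n_individuals=200, n_variants=2, n_causal=2, maf=0.3, h2=0.3,
            beta0=0.4, sigma_uv=0.8, seed=33,
        )
        ds = simulate_dataset(cfg)
        part = make_folds(ds.n, ds.n, seed=0)
        cfi = build_cfi(
            ds.genotypes, ds.exposure, part,
            selection=SelectionSpec(fixed_variants=np.array([0, 1])),
            predictor=PredictorSpec(method="least-squares"),
        )
        est = cfmr2(ds.exposure, ds.outcome, cfi)

        # oracle: explicit leave-one-out first stages
        Z = np.column_stack([np.ones(ds.n), ds.genotypes.astype(float)])
        jive_inst = np.empty(ds.n)
        for i in range(ds.n):
            mask = np.ones(ds.n, bool)
            mask[i] = False
            coef, *_ = np.linalg.lstsq(Z[mask], ds.exposure[mask], rcond=None)
            jive_inst[i] = Z[i] @ coef
        ref = tsls(ds.exposure, ds.outcome, jive_inst)
        assert est.beta_hat == pytest.approx(ref.beta_hat, abs=1e-8)

    def test_cfmr1_all_degenerate_raises(self, small_cohort):
        ds = small_cohort
        part = make_folds(ds.n, 3, seed=5)
        cfi = build_cfi(ds.genotypes, ds.exposure, part,
                        predictor=PredictorSpec(alpha=np.inf))
        with pytest.raises(DegenerateInstrumentError):
            cfmr1(ds.exposure, ds.outcome, cfi)

    def test_cfmr_variants_asymptotically_agree(self):
        """Averaged per-fold and pooled estimates coincide up to MC noise."""
        d1, d2 = [], []
        sel = SelectionSpec(p_threshold=1.0)
        for r in range(40):
            cfg = SimulationConfig(
                n_individuals=3000, n_variants=100, h2=0.2, beta0=0.05,
                sigma_uv=0.8, seed=5000 + r,
            )
            ds = simulate_dataset(cfg)
            part = make_folds(ds.n, 10, seed=r)
            cfi = build_cfi(ds.genotypes, ds.exposure, part, sel)
            d1.append(cfmr1(ds.exposure, ds.outcome, cfi).beta_hat)
            d2.append(cfmr2(ds.exposure, ds.outcome, cfi).beta_hat)
        diff = np.array(d1) - np.array(d2)
        mc_se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) < 2 * max(mc_se, 1e-4)


class TestOneSampleMr:
    def test_unbiased_without_confounding(self):
        ests = []
        sel = SelectionSpec(p_threshold=1.0)
        for r in range(40):
            cfg = SimulationConfig(
                n_individuals=2000, n_variants=50, h2=0.3, beta0=0.3,
                sigma_uv=0.0, seed=300 + r,
            )
            ds = simulate_dataset(cfg)
            ests.append(
                one_sample_mr(ds.exposure, ds.outcome, ds.genotypes,
                              sel, PredictorSpec(seed=r)).beta_hat
            )
        mc_se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert np.mean(ests) == pytest.approx(0.3, abs=2.5 * mc_se)

    def test_pure_noise_instrument_pulled_toward_confounding(self):
        """With h2 = 0 and strong confounding the in-sample instrument
        inherits the confounded association."""
        ests, failures = [], 0
        sel = SelectionSpec(p_threshold=1.0)
        for r in range(60):
            cfg = SimulationConfig(
                n_individuals=800, n_variants=300, h2=0.0, beta0=0.08,
                sigma_uv=4.9, seed=700 + r,
            )
            ds = simulate_dataset(cfg)
            try:
                ests.append(
                    one_sample_mr(ds.exposure, ds.outcome, ds.genotypes,
                                  sel, PredictorSpec(seed=r)).beta_hat
                )
            except DegenerateInstrumentError:
                failures += 1
        assert len(ests) >= 20
        mc_se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert np.mean(ests) > 0.08 + 2 * mc_se

    def test_deterministic(self, small_cohort):
        ds = small_cohort
        sel = SelectionSpec(p_threshold=1.0)
        a = one_sample_mr(ds.exposure, ds.outcome, ds.genotypes, sel,
                          PredictorSpec(seed=9))
        b = one_sample_mr(ds.exposure, ds.outcome, ds.genotypes, sel,
                          PredictorSpec(seed=9))
        assert a.beta_hat == b.beta_hat
        assert a.se == b.se


@pytest.mark.parametrize(
    "m, n, suv, expected",
    [(300, 1000, 4.9, 1.47), (300, 1000, 0.8, 0.24), (300, 1000, 0.0, 0.0)],
)
def test_nagar_bias_term(m, n, suv, expected):
    assert nagar_bias_term(m, n, suv) == pytest.approx(expected, abs=1e-12)
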