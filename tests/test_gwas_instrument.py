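"""Association scan, clumping and predictor training, each checked against
an independent closed-form or brute-force oracle."""

import numpy as np
import pytest

from cfmr import (
    ConfigurationError,
    SimulationConfig,
    fit_predictor,
    greedy_clump,
    marginal_scan,
    select_by_pvalue,
    simulate_dataset,
    simulate_genotypes,
)


class TestMarginalScan:
    def test_exact_linear_relation(self):
        g = simulate_genotypes(200, 5, maf=0.3, seed=1)
        exposure = 2.0 * g[:, 2].astype(float)
        scan = marginal_scan(g, exposure)
        assert scan.beta[2] == pytest.approx(2.0, abs=1e-10)
        assert scan.pvalue[2] < 1e-100

    def test_simple_regression_identity_small_n(self):
        """Slope equals cov(dosage, exposure)/var(dosage) computed longhand."""
        rng = np.random.default_rng(4)
        g = rng.binomial(2, 0.4, (20, 1))
        x = 0.7 * g[:, 0] + rng.normal(0, 1, 20)
        scan = marginal_scan(g, x)
        z = g[:, 0].astype(float)
        slope_oracle = np.cov(z, x, ddof=1)[0, 1] / np.var(z, ddof=1)
        assert scan.beta[0] == pytest.approx(slope_oracle, abs=1e-10)
        # textbook SE of the simple-regression slope
        resid = (x - x.mean()) - slope_oracle * (z - z.mean())
        se_oracle = np.sqrt(
            (resid @ resid) / 18 / ((z - z.mean()) @ (z - z.mean()))
        )
        assert scan.se[0] == pytest.approx(se_oracle, abs=1e-10)

    def test_null_pvalues_are_uniform(self):
        rng = np.random.default_rng(8)
        g = rng.binomial(2, 0.3, (5000, 1000)).astype(np.int8)
        x = rng.normal(0, 1, 5000)
        scan = marginal_scan(g, x)
        frac = float((scan.pvalue < 0.05).mean())
        mc_se = np.sqrt(0.05 * 0.95 / 1000)
        assert abs(frac - 0.05) < 3 * mc_se

    def test_zero_variance_variant_flagged(self):
        g = np.column_stack([np.full(50, 1), np.arange(50) % 3]).astype(np.int8)
        x = np.random.default_rng(0).normal(size=50)
        scan = marginal_scan(g, x)
        assert scan.zero_variance[0]
        assert scan.pvalue[0] == 1.0
        assert not scan.zero_variance[1]

    def test_covariate_adjustment_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(12)
        n = 300
        g = rng.binomial(2, 0.3, (n, 3)).astype(float)
        c = rng.normal(size=(n, 2))
        x = 0.5 * g[:, 0] + c @ [1.0, -0.5] + rng.normal(0, 1, n)
        scan = marginal_scan(g, x, covariates=c)
        for j in range(3):
            design = sm.add_constant(np.column_stack([g[:, j], c]))
            fit = sm.OLS(x, design).fit()
            assert scan.beta[j] == pytest.approx(fit.params[1], abs=1e-8)
            assert scan.pvalue[j] == pytest.approx(fit.pvalues[1], abs=1e-8)


def _brute_force_clump(r2, pvalue, thr):
    """Literal greedy replay, independently coded."""
    order = sorted(range(len(pvalue)), key=lambda j: (pvalue[j], j))
    kept = []
    for j in order:
        if all(r2[j, i] < thr for i in kept):
            kept.append(j)
    return sorted(kept)


class TestClumping:
    def test_independent_variants_all_retained(self):
        g = simulate_genotypes(2000, 12, maf=0.3, seed=5)
        x = np.random.default_rng(5).normal(size=2000)
        scan = marginal_scan(g, x)
        kept = greedy_clump(scan, g, r2_threshold=0.5)
        np.testing.assert_array_equal(kept, np.arange(12))

    def test_duplicate_column_keeps_smaller_p(self):
        rng = np.random.default_rng(6)
        base = rng.binomial(2, 0.3, 500).astype(np.int8)
        other = rng.binomial(2, 0.3, 500).astype(np.int8)
        g = np.column_stack([base, base, other])
        # exposure driven by the duplicated variant
        x = 0.5 * base + rng.normal(0, 1, 500)
        scan = marginal_scan(g, x)
        kept = greedy_clump(scan, g, r2_threshold=0.1)
        winner = 0 if scan.pvalue[0] <= scan.pvalue[1] else 1
        assert winner in kept
        assert {0, 1} - set(kept.tolist())  # the twin was removed

    def test_matches_brute_force_on_correlated_toy(self):
        rng = np.random.default_rng(7)
        n = 800
        a = rng.binomial(2, 0.3, n)
        # correlated block around `a` plus independent columns
        g = np.column_stack([
            a,
            np.where(rng.random(n) < 0.9, a, rng.binomial(2, 0.3, n)),
            np.where(rng.random(n) < 0.8, a, rng.binomial(2, 0.3, n)),
            rng.binomial(2, 0.3, n),
            rng.binomial(2, 0.3, n),
        ]).astype(np.int8)
        x = 0.4 * a + rng.normal(0, 1, n)
        scan = marginal_scan(g, x)
        gc = g.astype(float)
        r2 = np.corrcoef(gc.T) ** 2
        for thr in (0.05, 0.3, 0.9):
            kept = greedy_clump(scan, g, r2_threshold=thr)
            assert kept.tolist() == _brute_force_clump(r2, scan.pvalue, thr)

    def test_clumping_is_idempotent(self):
        rng = np.random.default_rng(9)
        g = rng.binomial(2, 0.3, (600, 30)).astype(np.int8)
        g[:, 1] = g[:, 0]  # one duplicated pair
        x = rng.normal(size=600)
        scan = marginal_scan(g, x)
        kept = greedy_clump(scan, g, r2_threshold=0.2)
        sub = g[:, kept]
        scan2 = marginal_scan(sub, x)
        kept2 = greedy_clump(scan2, sub, r2_threshold=0.2)
        np.testing.assert_array_equal(kept2, np.arange(len(kept)))

    def test_window_requires_positions(self):
        g = simulate_genotypes(100, 5, maf=0.3, seed=0)
        scan = marginal_scan(g, np.random.default_rng(0).normal(size=100))
        with pytest.raises(ConfigurationError):
            greedy_clump(scan, g, r2_threshold=0.1, window_bp=500_000)

    def test_far_apart_duplicates_both_kept_with_window(self):
        rng = np.random.default_rng(10)
        base = rng.binomial(2, 0.3, 300).astype(np.int8)
        g = np.column_stack([base, base])
        x = 0.5 * base + rng.normal(0, 1, 300)
        scan = marginal_scan(g, x)
        pos = np.array([0.0, 2_000_000.0])
        kept = greedy_clump(scan, g, r2_threshold=0.1, window_bp=500_000,
                            positions=pos)
        np.testing.assert_array_equal(kept, [0, 1])


class TestSelectByPvalue:
    def test_threshold_behavior(self):
        g = simulate_genotypes(100, 3, maf=0.3, seed=0)
        scan = marginal_scan(g, np.random.default_rng(1).normal(size=100))
        scan.pvalue[:] = [1e-7, 1e-5, 0.2]
        np.testing.assert_array_equal(select_by_pvalue(scan, 1e-6), [0])
        np.testing.assert_array_equal(select_by_pvalue(scan, 1.0), [0, 1, 2])
        scan.pvalue[:] = 0.5
        assert len(select_by_pvalue(scan, 1e-6)) == 0


class TestFitPredictor:
    def test_infinite_penalty_intercept_only(self, small_cohort):
        ds = small_cohort
        train = np.arange(0, 600)
        fp = fit_predictor(
            ds.genotypes, ds.exposure, train, np.arange(10), alpha=np.inf
        )
        assert fp.degenerate
        assert fp.intercept == pytest.approx(ds.exposure[train].mean())
        assert np.all(fp.predict(ds.genotypes) == fp.intercept)

    def test_strong_signal_recovers_generative_effect(self):
        cfg = SimulationConfig(
            n_individuals=20_000, n_variants=20, n_causal=1, maf=0.3,
            h2=0.3, seed=21,
        )
        ds = simulate_dataset(cfg)
        train = np.arange(ds.n)
        fp = fit_predictor(ds.genotypes, ds.exposure, train, np.arange(20),
                           cv_folds=5, seed=0)
        pi = ds.true_pi[0]
        assert 0 in fp.selected_ids[fp.weights != 0].tolist() or fp.weights[0] != 0
        assert fp.weights[0] == pytest.approx(pi, rel=0.10)
        # against an unpenalized refit oracle on the causal column
        z = ds.genotypes[:, 0].astype(float)
        ols = np.cov(z, ds.exposure, ddof=1)[0, 1] / np.var(z, ddof=1)
        assert fp.weights[0] == pytest.approx(ols, rel=0.10)

    def test_training_fit_is_optimistic(self):
        """In-sample R^2 exceeds held-out R^2 on average (overfitting)."""
        deltas = []
        for r in range(50):
            cfg = SimulationConfig(
                n_individuals=400, n_variants=30, n_causal=3, maf=0.3,
                h2=0.08, seed=1000 + r,
            )
            ds = simulate_dataset(cfg)
            train, test = np.arange(0, 200), np.arange(200, 400)
            fp = fit_predictor(ds.genotypes, ds.exposure, train,
                               np.arange(30), cv_folds=5, seed=r)
            if fp.degenerate:
                continue
            pred = fp.predict(ds.genotypes, test)
            ss_res = np.sum((ds.exposure[test] - pred) ** 2)
            ss_tot = np.sum(
                (ds.exposure[test] - ds.exposure[test].mean()) ** 2
            )
            deltas.append(fp.training_r2 - (1 - ss_res / ss_tot))
        assert len(deltas) > 20
        assert np.mean(deltas) > 0

    def test_allele_score_uses_scan_slopes(self, small_cohort):
        ds = small_cohort
        train = np.arange(0, 600)
        scan = marginal_scan(ds.genotypes, ds.exposure, train)
        sel = np.array([0, 1, 2])
        fp = fit_predictor(ds.genotypes, ds.exposure, train, sel,
                           method="allele-score", scan=scan)
        np.testing.assert_allclose(fp.weights, scan.beta[sel])
        # centered on the training exposure mean
        assert fp.predict(ds.genotypes, train).mean() == pytest.approx(
            ds.exposure[train].mean()
        )

    def test_empty_selection_flagged_degenerate(self, small_cohort):
        ds = small_cohort
        fp = fit_predictor(ds.genotypes, ds.exposure, np.arange(100),
                           np.array([], dtype=int))
        assert fp.degenerate
        assert fp.training_r2 == 0.0

    def test_least_squares_matches_numpy(self, small_cohort):
        ds = small_cohort
        train = np.arange(0, 500)
        sel = np.arange(5)
        fp = fit_predictor(ds.genotypes, ds.exposure, train, sel,
                           method="least-squares")
        design = np.column_stack([
            np.ones(len(train)), ds.genotypes[train][:, sel].astype(float)
        ])
        coef, *_ = np.linalg.lstsq(design, ds.exposure[train], rcond=None)
        assert fp.intercept == pytest.approx(coef[0], abs=1e-8)
        np.testing.assert_allclose(fp.weights, coef[1:], atol=1e-8)
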