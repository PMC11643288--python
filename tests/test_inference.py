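"""Joint SVI fit, per-gene LRTs, screening, and multiple-testing correction."""

import numpy as np
import pandas as pd
import pytest
from conftest import nr_logistic
from scipy import stats

from gruyere.datatypes import CohortData, GeneVariantSet
from gruyere.inference import (
    PriorConfig,
    bonferroni,
    burden_screen,
    fit_joint,
    fit_per_gene,
    lrt_pvalue,
    screen_genes,
)
from gruyere.model import maf_weight
from gruyere.simulation import (
    SyntheticCohortSpec,
    generate_cohort,
    recovery_metrics,
    simulate_phenotypes,
)


class TestScreening:
    def test_threshold_comparison(self):
        pv = {"A": 0.005, "B": 0.02, "C": 0.5}
        assert screen_genes(pv, 0.01) == ["A"]
        assert sorted(screen_genes(pv, 1.0)) == ["A", "B", "C"]

    def test_empty_survivors_error(self):
        with pytest.raises(ValueError, match="loosen"):
            screen_genes({"A": 0.9}, 0.01)

    def test_builtin_burden_screen_null_calibration(self):
        # independent phenotypes: ~1% of genes pass at p < 0.01
        rng = np.random.default_rng(5)
        n, m = 400, 250
        cohort = CohortData(
            [f"S{i}" for i in range(n)], rng.integers(0, 2, n),
            np.column_stack([np.ones(n), rng.random((n, 2))]), ["icpt", "c1", "c2"],
        )
        gene_sets = {}
        for g in range(m):
            maf = rng.uniform(0.005, 0.05, 15)
            G = rng.binomial(2, maf, size=(n, 15)).astype(float)
            gene_sets[f"G{g}"] = GeneVariantSet(f"G{g}", G, maf, rng.random((15, 2)))
        pv = burden_screen(cohort, gene_sets, split=None)
        n_pass = (pv < 0.01).sum()
        hi = stats.binom.ppf(0.999, m, 0.01)
        assert n_pass <= hi  # 99.9% binomial upper bound


class TestPerGeneFit:
    def _random_problem(self, rng, n=300, p=12, c=3, q=2):
        maf = rng.uniform(0.005, 0.05, p)
        G = rng.binomial(2, maf, size=(n, p)).astype(float)
        Z = rng.random((p, q))
        X = np.column_stack([np.ones(n), rng.random((n, c - 1))])
        y = rng.integers(0, 2, n)
        cohort = CohortData([f"S{i}" for i in range(n)], y, X,
                            [f"c{j}" for j in range(c)])
        tau = rng.dirichlet(np.ones(q + 1))
        return GeneVariantSet("G", G, maf, Z), cohort, tau

    def test_coefficients_match_newton_raphson_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            gvs, cohort, tau = self._random_problem(rng)
            res = fit_per_gene(gvs, cohort, tau, split=None)
            b = maf_weight(gvs.maf) * (tau[0] + gvs.Z @ tau[1:])
            design = np.column_stack([cohort.X, gvs.G @ b])
            beta_oracle, ll_oracle = nr_logistic(design, cohort.Y)
            assert np.allclose(
                np.append(res.alpha_hat, res.w_hat), beta_oracle, atol=1e-6
            )
            assert res.loglik_combined == pytest.approx(ll_oracle, abs=1e-6)

    def test_matches_statsmodels_on_one_fixture(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        gvs, cohort, tau = self._random_problem(rng)
        res = fit_per_gene(gvs, cohort, tau, split=None)
        b = maf_weight(gvs.maf) * (tau[0] + gvs.Z @ tau[1:])
        design = np.column_stack([cohort.X, gvs.G @ b])
        fit = sm.Logit(cohort.Y, design).fit(disp=0)
        assert np.allclose(np.append(res.alpha_hat, res.w_hat), fit.params, atol=1e-5)

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(11)
        spec = SyntheticCohortSpec(n_samples=2000, n_genes=2, variants_per_gene=80,
                                   n_covariates=3, n_annotations=3)
        cohort, gs = generate_cohort(spec, seed=12)
        tau = np.array([0.4, 0.2, 0.2, 0.2])
        truth = simulate_phenotypes(
            cohort, gs, seed=13, tau=tau, w_fixed=np.array([0.08, 0.0]),
            alpha=np.zeros((2, 3)),
        )
        gene = truth.genes[0]
        c2 = CohortData(cohort.sample_ids, truth.Y_sim[:, 0], cohort.X,
                        cohort.covariate_names)
        res = fit_per_gene(gs[gene], c2, tau, split=None)
        # crude SE from the LR statistic: |w|/sqrt(LR) ~ SE under H1
        se = abs(res.w_hat) / max(np.sqrt(res.lr_stat), 1e-9)
        assert abs(res.w_hat - 0.08) < 3 * se

    def test_null_gene_lr_near_zero(self):
        rng = np.random.default_rng(23)
        gvs, cohort, tau = self._random_problem(rng, n=500)
        res = fit_per_gene(gvs, cohort, tau, split=None)
        assert res.lr_stat < stats.chi2.ppf(0.999, 1)

    def test_no_variants_errors(self):
        rng = np.random.default_rng(1)
        gvs, cohort, tau = self._random_problem(rng)
        empty = GeneVariantSet("E", np.empty((300, 0)), np.empty(0), np.empty((0, 2)))
        with pytest.raises(ValueError):
            fit_per_gene(empty, cohort, tau, split=None)


class TestLrt:
    @pytest.mark.parametrize(
        "lr, expected, tol",
        [(0.0, 1.0, 1e-12), (3.841, 0.050, 5e-4), (6.635, 0.010, 2e-4)],
    )
    def test_chi2_quantiles(self, lr, expected, tol):
        assert lrt_pvalue(lr / 2.0, 0.0) == pytest.approx(expected, abs=tol)

    def test_nested_model_violation(self):
        with pytest.raises(ValueError, match="nested"):
            lrt_pvalue(-1.0, 0.0)

    def test_tiny_negative_clipped(self):
        assert lrt_pvalue(-1e-10, 0.0) == 1.0


class TestBonferroni:
    def _res(self, gene, p, ct="mg"):
        from gruyere.datatypes import GeneTestResult

        return GeneTestResult(gene, 0.0, np.zeros(1), 0, 0, 0.0, p, 1, ct)

    def test_five_genes(self):
        rs = [self._res(f"G{i}", 0.5) for i in range(5)]
        thr = bonferroni(rs, 0.05)
        assert thr["mg"] == pytest.approx(0.01)

    def test_genome_wide_threshold(self):
        rs = [self._res(f"G{i}", 0.5) for i in range(17361)]
        thr = bonferroni(rs, 0.05)
        assert thr["mg"] == pytest.approx(2.88e-6, rel=5e-3)

    def test_boundary_is_strict(self):
        rs = [self._res(f"G{i}", 0.01) for i in range(5)]
        bonferroni(rs, 0.05)
        assert all(r.significant is False for r in rs)


class TestJointFit:
    def test_deterministic_under_fixed_seed(self, tiny_cohort):
        cohort, gs = tiny_cohort
        truth = simulate_phenotypes(cohort, gs, seed=7, include_intercept_tau=False)
        kw = dict(phenotypes=truth.Y_sim, split=None, include_intercept_tau=False,
                  epochs=60)
        f1 = fit_joint(cohort, gs, seed=42, **kw)
        f2 = fit_joint(cohort, gs, seed=42, **kw)
        assert np.array_equal(f1.tau_hat.tau, f2.tau_hat.tau)
        assert np.array_equal(f1.w_mean, f2.w_mean)

    def test_requires_two_genes(self, tiny_cohort):
        cohort, gs = tiny_cohort
        one = {next(iter(gs)): gs[next(iter(gs))]}
        with pytest.raises(ValueError, match="at least 2"):
            fit_joint(cohort, one)

    def test_tau_recovery_high_heritability(self, tiny_cohort):
        cohort, gs = tiny_cohort
        truth = simulate_phenotypes(
            cohort, gs, seed=5, include_intercept_tau=False,
            heritability_range=(0.15, 0.30),
        )
        fit = fit_joint(cohort, gs, seed=6, phenotypes=truth.Y_sim, split=None,
                        include_intercept_tau=False)
        rec = recovery_metrics(truth, fit, gs).set_index("block")["pearson_r"]
        assert rec["tau"] >= 0.9
        assert rec["w"] >= 0.9

    def test_irrelevant_annotation_shrinks(self, tiny_cohort):
        cohort, gs = tiny_cohort
        q = next(iter(gs.values())).n_annotations
        # simulate with all tau mass off the last annotation, then fit
        tau_true = np.zeros(q)
        tau_true[0] = 1.0
        truth = simulate_phenotypes(cohort, gs, seed=9, include_intercept_tau=False,
                                    tau=tau_true)
        fit = fit_joint(cohort, gs, seed=10, phenotypes=truth.Y_sim, split=None,
                        include_intercept_tau=False)
        assert fit.tau_hat.tau[-1] < 1.0 / q

    def test_elbo_trace_improves(self, tiny_cohort):
        cohort, gs = tiny_cohort
        truth = simulate_phenotypes(cohort, gs, seed=3, include_intercept_tau=False)
        fit = fit_joint(cohort, gs, seed=4, phenotypes=truth.Y_sim, split=None,
                        include_intercept_tau=False, epochs=150)
        first, last = fit.elbo_trace[:10].mean(), fit.elbo_trace[-10:].mean()
        assert last > first

    def test_joint_and_per_gene_agree(self, tiny_cohort):
        cohort, gs = tiny_cohort
        truth = simulate_phenotypes(cohort, gs, seed=21, include_intercept_tau=False,
                                    heritability_range=(0.1, 0.3))
        fit = fit_joint(cohort, gs, seed=22, phenotypes=truth.Y_sim, split=None,
                        include_intercept_tau=False)
        for m, gene in enumerate(fit.genes):
            c2 = CohortData(cohort.sample_ids, truth.Y_sim[:, m], cohort.X,
                            cohort.covariate_names)
            res = fit_per_gene(gs[gene], c2, fit.tau_hat.tau, split=None)
            assert abs(res.w_hat - fit.w_mean[m]) < max(4 * fit.w_sd[m], 0.05)
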