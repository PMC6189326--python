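"""Multi-trait mixed model: REML, Gibbs sampler, scan, fit statistics."""

import numpy as np
import pytest

import semgwas as sg
from semgwas.kinship import KinshipMatrix
from semgwas.mtm import geweke_z
from semgwas.qc_io import GenotypeMatrix, PhenotypeTable, SnpRecord


def _identity_k(n):
    return KinshipMatrix([f"s{i}" for i in range(n)], np.eye(n), "pedigree_A")


def _pheno(values, traits=None):
    values = np.atleast_2d(np.asarray(values, float))
    if values.shape[0] == 1:
        values = values.T
    traits = traits or [f"y{k+1}" for k in range(values.shape[1])]
    return PhenotypeTable([f"s{i}" for i in range(values.shape[0])], traits,
                          values)


class TestREML:
    def test_single_trait_variance_partition(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(300)
        fit = sg.fit_mtm_reml(_pheno(y), _identity_k(300))
        total = fit.vc.sigma_g[0, 0] + fit.vc.sigma_e[0, 0]
        assert total == pytest.approx(np.var(y, ddof=1), rel=0.05)

    def test_null_genetic_covariance_recovered(self):
        rng = np.random.default_rng(1)
        n, t = 500, 3
        cov = np.array([[1.0, 0.3, 0.1], [0.3, 1.0, 0.2], [0.1, 0.2, 1.0]])
        y = rng.multivariate_normal(np.zeros(t), cov, size=n)
        # K with family blocks so sigma_g is identifiable
        fam = np.kron(np.eye(n // 5), np.full((5, 5), 0.5)) + 0.5 * np.eye(n)
        k = KinshipMatrix([f"s{i}" for i in range(n)], fam, "pedigree_A")
        fit = sg.fit_mtm_reml(_pheno(y), k)
        # truth sigma_g = 0: estimates should be near zero, residuals near cov
        assert np.abs(fit.vc.sigma_g).max() < 0.35
        np.testing.assert_allclose(fit.vc.sigma_g + fit.vc.sigma_e, cov,
                                   atol=0.35)

    def test_em_trace_monotone_and_multistart_determinism(self):
        rng = np.random.default_rng(2)
        n = 200
        fam = np.kron(np.eye(n // 4), np.full((4, 4), 0.5)) + 0.5 * np.eye(n)
        k = KinshipMatrix([f"s{i}" for i in range(n)], fam, "pedigree_A")
        y = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 2]], size=n)
        fit1 = sg.fit_mtm_reml(_pheno(y), k)
        em_trace = fit1.logl_trace
        assert np.all(np.diff(em_trace) >= -1e-7)
        fit2 = sg.fit_mtm_reml(_pheno(y), k,
                               init=(0.1 * np.eye(2), 2.0 * np.eye(2)))
        assert abs(fit1.logl - fit2.logl) < 1e-6


class TestGibbs:
    def test_chain_bookkeeping(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal((60, 2))
        draws = sg.fit_mtm_gibbs(_pheno(y), _identity_k(60), iterations=1000,
                                 burn_in=200, thin=10, seed=1)
        assert draws.n_draws == (1000 - 200) // 10 == 80

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(4)
        y = rng.standard_normal((50, 2))
        a = sg.fit_mtm_gibbs(_pheno(y), _identity_k(50), iterations=300,
                             burn_in=100, thin=2, seed=99)
        b = sg.fit_mtm_gibbs(_pheno(y), _identity_k(50), iterations=300,
                             burn_in=100, thin=2, seed=99)
        np.testing.assert_array_equal(a.sigma_e, b.sigma_e)
        np.testing.assert_array_equal(a.sigma_g, b.sigma_g)

    def test_posterior_recovers_truth_and_mixes(self):
        sim = sg.simulate(sg.SimulationConfig(
            n_individuals=500, family_size=5, n_snps=10,
            sigma_g=np.array([[0.5, 0.25, 0.25], [0.25, 0.5, 0.25],
                              [0.25, 0.25, 0.5]]), seed=11))
        draws = sg.fit_mtm_gibbs(sim.phenotypes, sim.kinship,
                                 iterations=24000, burn_in=8000, thin=10,
                                 seed=11)
        truth_g = sim.truth["sigma_g"]
        truth_e = np.diag(sim.truth["psi"])
        for a in range(3):
            for b in range(a, 3):
                for stack, truth in ((draws.sigma_g, truth_g),
                                     (draws.sigma_e, truth_e)):
                    x = stack[:, a, b]
                    assert abs(x.mean() - truth[a, b]) < 3 * x.std() + 0.05
                assert abs(geweke_z(draws.sigma_g[:, a, b])) < 3.0

    def test_invalid_chain_settings(self):
        y = np.zeros((30, 1))
        with pytest.raises(ValueError):
            sg.fit_mtm_gibbs(_pheno(y), _identity_k(30), iterations=100,
                             burn_in=100)


class TestScan:
    def test_matches_ols_when_no_polygenics(self):
        # single trait, sigma_g = 0, K = I: GLS collapses to OLS
        dose = np.array([0.0, 1.0, 2.0, 1.0, 0.0])
        y = np.array([0.1, 1.2, 2.3, 0.9, 0.2])
        geno = GenotypeMatrix([f"s{i}" for i in range(5)],
                              [SnpRecord(id="m0")], dose[:, None])
        vc = sg.VarianceComponents(np.zeros((1, 1)), np.eye(1), ["y1"])
        scan = sg.mtm_snp_scan(_pheno(y), geno, _identity_k(5), vc)
        x = np.column_stack([np.ones(5), dose])
        beta = np.linalg.lstsq(x, y, rcond=None)[0]
        assert scan.table.estimate[0] == pytest.approx(beta[1], abs=1e-10)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(5)
        n = 120
        dose = rng.binomial(2, 0.4, size=(n, 3)).astype(float)
        y = rng.standard_normal((n, 2))
        geno = GenotypeMatrix([f"s{i}" for i in range(n)],
                              [SnpRecord(id=f"m{j}") for j in range(3)], dose)
        vc = sg.VarianceComponents(0.2 * np.eye(2), np.eye(2), ["y1", "y2"])
        base = sg.mtm_snp_scan(_pheno(y), geno, _identity_k(n), vc).table
        vc2 = sg.VarianceComponents(4 * 0.2 * np.eye(2), 4 * np.eye(2),
                                    ["y1", "y2"])
        doubled = sg.mtm_snp_scan(_pheno(2 * y), geno, _identity_k(n),
                                  vc2).table
        np.testing.assert_allclose(doubled.estimate, 2 * base.estimate,
                                   rtol=1e-8)
        np.testing.assert_allclose(doubled.se, 2 * base.se, rtol=1e-8)
        np.testing.assert_allclose(doubled.t, base.t, rtol=1e-8)
        np.testing.assert_allclose(doubled.p, base.p, rtol=1e-6)

    def test_zero_variance_snp_flagged_not_raised(self):
        n = 40
        dose = np.column_stack([np.ones(n), np.random.default_rng(6)
                                .binomial(2, 0.5, n)]).astype(float)
        geno = GenotypeMatrix([f"s{i}" for i in range(n)],
                              [SnpRecord(id="const"), SnpRecord(id="ok")], dose)
        y = np.random.default_rng(7).standard_normal(n)
        vc = sg.VarianceComponents(np.zeros((1, 1)), np.eye(1), ["y1"])
        scan = sg.mtm_snp_scan(_pheno(y), geno, _identity_k(n), vc).table
        assert np.isnan(scan[scan.snp == "const"].estimate).all()
        assert np.isfinite(scan[scan.snp == "ok"].estimate).all()


class TestFitStats:
    def test_half_criteria_arithmetic(self):
        fit = sg.MixedModelFit(
            sg.VarianceComponents(np.eye(3), np.eye(3), ["a", "b", "c"]),
            logl=-100.0, k=12, n_records=100)
        logl, aic2, bic2 = sg.model_fit_stats(fit)
        assert (logl, aic2) == (-100.0, -112.0)
        assert bic2 == pytest.approx(-100 - 6 * np.log(100), abs=1e-9)

    def test_twelve_parameter_offset_matches_reported_convention(self):
        # a three-trait model with two free covariance matrices has
        # k = t(t+1) = 12, so -AIC/2 sits exactly 12 below logL
        fit = sg.MixedModelFit(
            sg.VarianceComponents(np.eye(3), np.eye(3), ["a", "b", "c"]),
            logl=-7093.480, k=12, n_records=1351)
        _, aic2, _ = sg.model_fit_stats(fit)
        assert aic2 == pytest.approx(-7105.48, abs=1e-6)
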