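"""SEM fit, scan, path decomposition, FDR and model comparison."""

import numpy as np
import pandas as pd
import pytest

import semgwas as sg
from semgwas.kinship import KinshipMatrix
from semgwas.netsearch import CausalStructure
from semgwas.qc_io import PhenotypeTable
from semgwas.sem import ConfigurationError
from semgwas.simulate import FULLY_RECURSIVE_LAMBDA


def _random_recursive_system(rng, t):
    """Random DAG on t ordered traits with random coefficients and directs."""
    names = [f"y{i+1}" for i in range(t)]
    lam = np.zeros((t, t))
    edges = set()
    for i in range(t):
        for j in range(i):
            if rng.random() < 0.6:
                lam[i, j] = rng.uniform(-2, 2)
                edges.add((names[j], names[i]))
    dag = CausalStructure(names, set(), edges, {}, status="dag")
    direct = rng.uniform(-1, 1, t)
    return dag, lam, direct


class TestReducedForm:
    def test_identity_when_no_network(self):
        d = np.array([0.3, -0.2, 1.1])
        np.testing.assert_allclose(
            sg.total_effect_reduced_form(np.zeros((3, 3)), d), d)

    def test_hand_arithmetic(self):
        lam = np.array([[0, 0, 0], [2.0, 0, 0], [-0.2, -0.3, 0.0]])
        total = sg.total_effect_reduced_form(lam, [1.0, 0.5, 0.1])
        np.testing.assert_allclose(total, [1.0, 2.5, -0.85], atol=1e-12)

    def test_symbolic_four_path_formula(self):
        # total on y3 = l32*l21*d1 + l32*d2 + l31*d1 + d3
        rng = np.random.default_rng(0)
        l21, l31, l32 = rng.uniform(-1, 1, 3)
        d = rng.uniform(-1, 1, 3)
        lam = np.array([[0, 0, 0], [l21, 0, 0], [l31, l32, 0]])
        total = sg.total_effect_reduced_form(lam, d)
        assert total[2] == pytest.approx(
            l32 * l21 * d[0] + l32 * d[1] + l31 * d[0] + d[2], abs=1e-12)


class TestPathEnumeration:
    def test_fully_recursive_three_paths_to_y3(self):
        names = ["y1", "y2", "y3"]
        dag = CausalStructure(names, set(), {("y1", "y2"), ("y1", "y3"),
                                             ("y2", "y3")}, {}, status="dag")
        lam = FULLY_RECURSIVE_LAMBDA
        d = np.array([1.0, 0.5, 0.1])
        paths = dict(sg.enumerate_indirect_paths(dag, lam, d, "y3"))
        assert set(paths) == {("y1", "y3"), ("y1", "y2", "y3"), ("y2", "y3")}
        assert paths[("y1", "y2", "y3")] == pytest.approx(-0.27 * 2.13 * 1.0)
        assert paths[("y2", "y3")] == pytest.approx(-0.27 * 0.5)
        assert paths[("y1", "y3")] == pytest.approx(-0.17 * 1.0)

    def test_no_edges_no_paths(self):
        dag = CausalStructure(["a", "b"], set(), set(), {}, status="dag")
        assert sg.enumerate_indirect_paths(dag, np.zeros((2, 2)),
                                           np.ones(2), "b") == []

    def test_chain_single_path(self):
        dag = CausalStructure(["y1", "y2", "y3"], set(),
                              {("y1", "y2"), ("y2", "y3")}, {}, status="dag")
        lam = np.array([[0, 0, 0], [2.0, 0, 0], [0, -0.3, 0.0]])
        paths = sg.enumerate_indirect_paths(dag, lam, np.array([1.0, 0, 0]),
                                            "y3")
        assert paths == [(("y1", "y2", "y3"), pytest.approx(-0.6))]


class TestDecomposition:
    def test_matches_reduced_form_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            t = rng.integers(3, 7)
            dag, lam, direct = _random_recursive_system(rng, t)
            dec = sg.decompose_snp_effect(dag, lam, direct)
            totals = dec[dec.effect_type == "total"].set_index("trait").estimate
            oracle = sg.total_effect_reduced_form(lam, direct)
            for i, name in enumerate(dag.nodes):
                assert abs(totals[name] - oracle[i]) <= 1e-12

    def test_total_is_direct_plus_paths_exactly(self):
        rng = np.random.default_rng(43)
        dag, lam, direct = _random_recursive_system(rng, 4)
        dec = sg.decompose_snp_effect(dag, lam, direct)
        for trait, grp in dec.groupby("trait"):
            d = grp[grp.effect_type == "direct"].estimate.iloc[0]
            tot = grp[grp.effect_type == "total"].estimate.iloc[0]
            path_sum = grp[grp.effect_type == "path"].estimate.sum()
            assert tot == pytest.approx(d + path_sum, abs=1e-12)

    def test_no_network_collapses_to_direct(self):
        dag = CausalStructure(["a", "b"], set(), set(), {}, status="dag")
        cov_d = np.diag([0.04, 0.09])
        dec = sg.decompose_snp_effect(dag, np.zeros((2, 2)),
                                      np.array([1.0, -2.0]), cov_d)
        ind = dec[dec.effect_type == "indirect"]
        tot = dec[dec.effect_type == "total"].set_index("trait")
        assert (ind.estimate == 0).all()
        assert tot.loc["a", "estimate"] == 1.0
        assert tot.loc["a", "se"] == pytest.approx(0.2)

    def test_indirect_can_flip_total_sign(self):
        # d > 0 on y2 but a strongly negative mediated path flips the total
        dag = CausalStructure(["y1", "y2"], set(), {("y1", "y2")}, {},
                              status="dag")
        lam = np.array([[0.0, 0.0], [-3.0, 0.0]])
        dec = sg.decompose_snp_effect(dag, lam, np.array([1.0, 0.5]))
        d = dec[(dec.trait == "y2") & (dec.effect_type == "direct")].estimate.iloc[0]
        tot = dec[(dec.trait == "y2") & (dec.effect_type == "total")].estimate.iloc[0]
        assert d > 0 > tot


class TestBHFDR:
    def test_all_ones_no_rejection(self):
        q, cutoff = sg.bh_fdr(np.ones(10))
        assert cutoff is None and (q == 1.0).all()

    def test_step_up_by_hand(self):
        p = np.array([0.001, 0.02, 0.03, 0.5])
        q, cutoff = sg.bh_fdr(p, q=0.05)
        # 0.03 <= 3 * 0.05 / 4, so the first three are rejected
        assert cutoff == pytest.approx(-np.log10(0.03))
        assert (q[:3] <= 0.05).all() and q[3] > 0.05

    def test_invalid_pvalues(self):
        with pytest.raises(ValueError):
            sg.bh_fdr([0.0, 0.5])


class TestFit:
    def test_identifiability_guard(self, paper_sim, saturated_dag):
        with pytest.raises(ConfigurationError, match="identifiable"):
            sg.fit_sem(paper_sim.phenotypes, paper_sim.kinship, saturated_dag,
                       psi_diagonal=False)

    def test_requires_dag_status(self, paper_sim):
        pdag = CausalStructure(["y1", "y2", "y3"],
                               undirected={frozenset(("y1", "y2"))})
        with pytest.raises(ValueError, match="directed"):
            sg.fit_sem(paper_sim.phenotypes, paper_sim.kinship, pdag)

    def test_lambda_recovery_and_signs(self, sem_fit):
        lam, se = sem_fit.coefficients.lam, sem_fit.coefficients.se
        assert lam[1, 0] > 0 and lam[2, 0] < 0 and lam[2, 1] < 0
        for (i, j), truth in [((1, 0), 2.13), ((2, 0), -0.17), ((2, 1), -0.27)]:
            assert abs(lam[i, j] - truth) < 3 * se[i, j]

    def test_parameter_count(self, sem_fit):
        assert sem_fit.k == 3 + 6 + 3

    def test_empty_dag_factorizes_into_single_trait_fits(self):
        rng = np.random.default_rng(21)
        n = 300
        fam = np.kron(np.eye(n // 5), np.full((5, 5), 0.5)) + 0.5 * np.eye(n)
        k = KinshipMatrix([f"s{i}" for i in range(n)], fam, "pedigree_A")
        y = rng.standard_normal((n, 3)) + \
            np.linalg.cholesky(fam) @ rng.standard_normal((n, 3)) * 0.7
        pheno = PhenotypeTable([f"s{i}" for i in range(n)],
                               ["y1", "y2", "y3"], y)
        empty = CausalStructure(["y1", "y2", "y3"], set(), set(), {},
                                status="dag")
        fit = sg.fit_sem(pheno, k, empty, diag_sigma_g=True)
        single_sum = 0.0
        for j, name in enumerate(pheno.traits):
            sub = PhenotypeTable(list(pheno.samples), [name], y[:, [j]])
            single_sum += sg.fit_mtm_reml(sub, k).logl
        assert fit.logl == pytest.approx(single_sum, abs=1e-4)


class TestScanAndEquivalence:
    def test_mtm_equals_sem_totals(self, paper_sim, mtm_fit, sem_fit):
        mscan = sg.mtm_snp_scan(paper_sim.phenotypes, paper_sim.genotypes,
                                paper_sim.kinship, mtm_fit.vc)
        _, est, _ = sg.sem_snp_scan(paper_sim.phenotypes, paper_sim.genotypes,
                                    paper_sim.kinship, sem_fit, return_cov=True)
        totals = est @ sem_fit.coefficients.gamma().T
        order = [s.id for s in paper_sim.genotypes.snps]
        m = mscan.table.pivot(index="snp", columns="trait", values="estimate")
        m = m.loc[order, ["y1", "y2", "y3"]].to_numpy()
        assert np.abs(m - totals).max() < 0.05

    def test_direct_effects_localize_to_target_trait(self, paper_sim, sem_fit):
        # the QTL at snp00050 acts on y1 only; its direct effect on y2/y3
        # should be small relative to its y1 effect
        scan = sg.sem_snp_scan(paper_sim.phenotypes, paper_sim.genotypes,
                               paper_sim.kinship, sem_fit).table
        row = scan[scan.snp == "snp00050"].set_index("trait")
        assert abs(row.loc["y1", "t"]) > 3.0
        assert abs(row.loc["y2", "estimate"]) < abs(row.loc["y1", "estimate"])

    def test_decomposition_scan_table_shape(self, paper_sim, mtm_fit, sem_fit):
        geno = paper_sim.genotypes.subset_snps(np.arange(40))
        table = sg.decomposition_scan(paper_sim.phenotypes, geno,
                                      paper_sim.kinship, sem_fit,
                                      mtm_vc=mtm_fit.vc)
        assert set(table.effect_type) == {"direct", "indirect", "total", "mtm"}
        assert {"snp", "chrom", "pos", "trait", "estimate", "se", "t", "p",
                "q", "paths"} <= set(table.columns)
        tot = table[table.effect_type == "total"]
        d = table[table.effect_type == "direct"].set_index(["snp", "trait"])
        ind = table[table.effect_type == "indirect"].set_index(["snp", "trait"])
        for _, r in tot.iterrows():
            assert r.estimate == pytest.approx(
                d.loc[(r.snp, r.trait)].estimate
                + ind.loc[(r.snp, r.trait)].estimate, abs=1e-10)


class TestCompareModels:
    def test_single_fit_row(self, mtm_fit):
        table = sg.compare_models([mtm_fit])
        row = table.iloc[0]
        assert row.half_neg_aic == pytest.approx(mtm_fit.logl - mtm_fit.k)
        assert row.half_neg_bic == pytest.approx(
            mtm_fit.logl - 0.5 * mtm_fit.k * np.log(mtm_fit.n_records))

    def test_saturated_sem_matches_mtm_likelihood(self, mtm_fit, sem_fit):
        assert abs(mtm_fit.logl - sem_fit.logl) < 1e-4

    def test_k_differs_between_model_classes(self, mtm_fit, sem_fit):
        table = sg.compare_models([mtm_fit, sem_fit])
        assert table.k.tolist() == [12, 12]  # saturated SEM: 3 edges + 6 + 3

    def test_mismatched_records_rejected(self, mtm_fit):
        other = sg.MixedModelFit(mtm_fit.vc, -10.0, 12, mtm_fit.n_records + 5)
        with pytest.raises(ValueError, match="different record counts"):
            sg.compare_models([mtm_fit, other])
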