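"""Shared fixtures: synthetic datasets and fitted models reused across files.

Model fits are session-scoped because REML/Gibbs runs dominate test time;
all fixtures are generated from fixed seeds so every run sees identical data.
"""

import numpy as np
import pytest

import semgwas as sg
from semgwas.netsearch import CausalStructure

SATURATED_EDGES = {("y1", "y2"), ("y1", "y3"), ("y2", "y3")}


@pytest.fixture(scope="session")
def saturated_dag():
    return CausalStructure(["y1", "y2", "y3"], set(), set(SATURATED_EDGES),
                           {}, status="dag")


@pytest.fixture(scope="session")
def paper_sim():
    """1000 full-sib individuals, 500 SNPs, fully recursive trait network."""
    return sg.make_fixture("paper_like", seed=sg.DEFAULT_SEED)


@pytest.fixture(scope="session")
def mtm_fit(paper_sim):
    return sg.fit_mtm_reml(paper_sim.phenotypes, paper_sim.kinship, label="MTM")


@pytest.fixture(scope="session")
def sem_fit(paper_sim, saturated_dag):
    return sg.fit_sem(paper_sim.phenotypes, paper_sim.kinship, saturated_dag,
                      label="SEM")


@pytest.fixture(scope="session")
def chain_draws():
    """Short Gibbs chain on chain-structured data (y1 -> y2 -> y3)."""
    sim = sg.make_fixture("chain", seed=sg.DEFAULT_SEED)
    # subsample individuals to keep the unit-test chain cheap
    keep = sim.phenotypes.samples[:800]
    pheno = sg.PhenotypeTable(keep, list(sim.phenotypes.traits),
                              sim.phenotypes.values[:800])
    kin = sim.kinship.subset(keep)
    return sg.fit_mtm_gibbs(pheno, kin, iterations=1500, burn_in=500,
                            thin=5, seed=sg.DEFAULT_SEED)
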