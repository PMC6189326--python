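"""Synthetic datasets with the generative structure the method assumes.

Phenotypes follow the recursive system used throughout the package: QTL
direct effects, polygenic values with covariance Sigma_g (x) K, and
independent trait residuals Psi feed the reduced form
y = (I - Lambda)^-1 (W s + g + e).  Genotypes are simulated either for
unrelated individuals (binomial dosages under Hardy-Weinberg proportions)
or for full-sib families with Mendelian transmission from founder parents,
mirroring the family structure of commercial broiler populations.  Every
fixture records its ground truth so tests can score recovery.

Effect sizes are expressed in residual-standard-deviation units (residual
variances default to 1); the ``paper_like`` fixture uses the structural
coefficients (2.13, -0.17, -0.27) of a fully recursive three-trait broiler
network as its truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinship import KinshipMatrix, nrm_from_pedigree
from .mtm import DEFAULT_SEED
from .netsearch import CausalStructure
from .qc_io import GenotypeMatrix, PedigreeTable, PhenotypeTable, SnpRecord


@dataclass
class SimulationConfig:
    n_individuals: int = 1000
    family_size: int = 0        # 0 = unrelated founders only
    n_snps: int = 500
    maf_bounds: tuple[float, float] = (0.1, 0.5)
    trait_names: tuple[str, ...] = ("y1", "y2", "y3")
    lam: np.ndarray | None = None           # strictly lower-triangular in trait order
    sigma_g: np.ndarray | None = None
    psi: np.ndarray | None = None           # diagonal residual variances, (t,)
    qtl: dict[int, dict[str, float]] = field(default_factory=dict)
    ld_block_size: int = 1      # >1 correlates founder alleles within blocks
    ld_strength: float = 0.8    # probability an allele copies the block anchor
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        t = len(self.trait_names)
        self.lam = np.zeros((t, t)) if self.lam is None else np.asarray(self.lam, float)
        if np.any(np.triu(self.lam) != 0):
            raise ValueError("Lambda must be strictly lower-triangular in "
                             "the given trait order")
        self.sigma_g = (0.5 * np.eye(t) if self.sigma_g is None
                        else np.asarray(self.sigma_g, float))
        if np.linalg.eigvalsh((self.sigma_g + self.sigma_g.T) / 2).min() < -1e-10:
            raise ValueError("Sigma_g must be positive semi-definite")
        self.psi = np.ones(t) if self.psi is None else np.asarray(self.psi, float)
        if (self.psi <= 0).any():
            raise ValueError("Psi must be positive")
        if any(j >= self.n_snps or j < 0 for j in self.qtl):
            raise ValueError("QTL indices must lie below n_snps")
        if self.family_size:
            if self.n_individuals % self.family_size:
                raise ValueError("n_individuals must be a multiple of family_size")

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    pedigree: PedigreeTable
    kinship: KinshipMatrix
    truth: dict


def simulate_genotypes(cfg: SimulationConfig,
                       rng: np.random.Generator | None = None
                       ) -> tuple[GenotypeMatrix, PedigreeTable]:
    """Dosages for unrelated founders or full-sib families.

    Per-SNP allele frequencies are drawn uniformly from ``maf_bounds``.
    In family mode each family has an unrelated sire and dam whose gametes
    are transmitted by Mendelian sampling (an allele is passed with
    probability dosage / 2)."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    p = rng.uniform(*cfg.maf_bounds, size=cfg.n_snps)
    snps = [SnpRecord(id=f"snp{j:05d}", chromosome=str(1 + j % 5),
                      position=1000 * (j + 1)) for j in range(cfg.n_snps)]

    if not cfg.family_size:
        dos = _founder_dosages(rng, cfg, p, cfg.n_individuals).astype(float)
        ids = [f"id{i:05d}" for i in range(cfg.n_individuals)]
        ped = PedigreeTable(ids, ["0"] * len(ids), ["0"] * len(ids))
        return GenotypeMatrix(ids, snps, dos), ped

    n_fam = cfg.n_individuals // cfg.family_size
    sires = _founder_dosages(rng, cfg, p, n_fam)
    dams = _founder_dosages(rng, cfg, p, n_fam)
    ids, sire_col, dam_col, rows = [], [], [], []
    for f in range(n_fam):
        for c in range(cfg.family_size):
            ids.append(f"f{f:04d}c{c}")
            sire_col.append(f"s{f:04d}")
            dam_col.append(f"d{f:04d}")
            dose = (rng.binomial(1, sires[f] / 2.0)
                    + rng.binomial(1, dams[f] / 2.0))
            rows.append(dose)
    founders = [f"s{f:04d}" for f in range(n_fam)] + [f"d{f:04d}" for f in range(n_fam)]
    ped = PedigreeTable(founders + ids,
                        ["0"] * len(founders) + sire_col,
                        ["0"] * len(founders) + dam_col)
    return GenotypeMatrix(ids, snps, np.array(rows, float)), ped


def _founder_dosages(rng: np.random.Generator, cfg: SimulationConfig,
                     p: np.ndarray, n: int) -> np.ndarray:
    """Founder dosages, independent SNPs by default.

    With ``ld_block_size > 1`` consecutive SNPs form blocks sharing one
    allele frequency, and each founder haplotype allele copies the block's
    anchor allele with probability ``ld_strength`` (pairwise r^2 within a
    block is about ld_strength^4 in founders; Mendelian transmission to
    offspring treats SNPs independently, so this emulates founder haplotype
    structure, not linkage).
    """
    if cfg.ld_block_size <= 1:
        return rng.binomial(2, p, size=(n, cfg.n_snps))
    block = np.arange(cfg.n_snps) // cfg.ld_block_size
    p[:] = p[block * cfg.ld_block_size]  # one frequency per block
    n_blocks = int(block.max()) + 1
    p_block = p[np.arange(n_blocks) * cfg.ld_block_size]
    dos = np.zeros((n, cfg.n_snps), dtype=np.int64)
    for _ in range(2):  # two haplotypes
        anchor = rng.binomial(1, p_block, size=(n, n_blocks))[:, block]
        fresh = rng.binomial(1, p, size=(n, cfg.n_snps))
        copy = rng.random((n, cfg.n_snps)) < cfg.ld_strength
        dos += np.where(copy, anchor, fresh)
    return dos


def _qtl_effect_matrix(cfg: SimulationConfig) -> np.ndarray:
    """(n_snps, t) matrix of direct QTL effects (zero rows for non-QTL)."""
    s = np.zeros((cfg.n_snps, cfg.n_traits))
    name_idx = {x: i for i, x in enumerate(cfg.trait_names)}
    for j, effects in cfg.qtl.items():
        for trait, size in effects.items():
            s[j, name_idx[trait]] = size
    return s


def simulate_phenotypes(cfg: SimulationConfig, geno: GenotypeMatrix,
                        kinship: KinshipMatrix,
                        rng: np.random.Generator | None = None
                        ) -> tuple[PhenotypeTable, dict]:
    """Phenotypes from the reduced form y = (I - Lambda)^-1 (W s + g + e)."""
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    n, t = geno.n_samples, cfg.n_traits
    s = _qtl_effect_matrix(cfg)
    w = geno.mean_imputed()
    qtl_part = w @ s

    eig_d, eig_u = kinship.eigendecomposition()
    root_k = eig_u * np.sqrt(eig_d)
    lg = np.linalg.cholesky(cfg.sigma_g + 1e-10 * np.eye(t))
    g = root_k @ rng.standard_normal((n, t)) @ lg.T
    e = rng.standard_normal((n, t)) * np.sqrt(cfg.psi)

    gamma = np.linalg.inv(np.eye(t) - cfg.lam)
    y = (qtl_part + g + e) @ gamma.T
    truth = {
        "lam": cfg.lam.copy(), "sigma_g": cfg.sigma_g.copy(),
        "psi": cfg.psi.copy(), "qtl_direct": s, "polygenic": g,
        "seed": cfg.seed,
        "qtl_total": s @ gamma.T,
    }
    return PhenotypeTable(list(geno.samples), list(cfg.trait_names), y), truth


def simulate(cfg: SimulationConfig) -> SimulatedDataset:
    rng = np.random.default_rng(cfg.seed)
    geno, ped = simulate_genotypes(cfg, rng)
    kin = nrm_from_pedigree(ped).subset(geno.samples)
    pheno, truth = simulate_phenotypes(cfg, geno, kin, rng)
    return SimulatedDataset(geno, pheno, ped, kin, truth)


def true_structure(cfg: SimulationConfig) -> CausalStructure:
    """The generating DAG as a CausalStructure (for oracle-style tests)."""
    t = cfg.n_traits
    edges = {(cfg.trait_names[j], cfg.trait_names[i])
             for i in range(t) for j in range(t) if cfg.lam[i, j] != 0}
    return CausalStructure(list(cfg.trait_names), set(), edges, {}, status="dag",
                           lam=cfg.lam)


FULLY_RECURSIVE_LAMBDA = np.array([[0.0, 0.0, 0.0],
                                   [2.13, 0.0, 0.0],
                                   [-0.17, -0.27, 0.0]])
CHAIN_LAMBDA = np.array([[0.0, 0.0, 0.0],
                         [2.14, 0.0, 0.0],
                         [0.0, -0.31, 0.0]])
_SIGMA_G = np.array([[0.5, 0.25, 0.25],
                     [0.25, 0.5, 0.25],
                     [0.25, 0.25, 0.5]])


def make_fixture(name: str, seed: int = DEFAULT_SEED) -> SimulatedDataset:
    """Named deterministic datasets used across the test suites.

    - ``null``: no QTL, no trait network, unrelated individuals.
    - ``chain``: y1 -> y2 -> y3 with coefficients (2.14, -0.31), n = 2000
      full-sib families, no QTL; the structure-recovery workload.
    - ``collider``: y1 -> y2 <- y3, generated in the order (y1, y3, y2) and
      reported as (y1, y2, y3) to exercise ordering logic.
    - ``fully_recursive``: the three-trait saturated DAG with coefficients
      (2.13, -0.17, -0.27), a single QTL on y1.
    - ``paper_like``: n = 1000 in 200 full-sib families of 5, 500 SNPs, the
      fully recursive coefficients, and 5 QTL with mixed direct targets.
    """
    if name == "null":
        cfg = SimulationConfig(n_individuals=1000, family_size=0, n_snps=200,
                               seed=seed, sigma_g=_SIGMA_G)
    elif name == "chain":
        cfg = SimulationConfig(n_individuals=2000, family_size=5, n_snps=50,
                               lam=CHAIN_LAMBDA, sigma_g=_SIGMA_G, seed=seed)
    elif name == "collider":
        # generative order (y1, y3, y2): y2 <- y1 and y2 <- y3
        lam = np.array([[0.0, 0.0, 0.0],
                        [0.0, 0.0, 0.0],
                        [1.0, 0.8, 0.0]])
        cfg = SimulationConfig(n_individuals=2000, family_size=5, n_snps=50,
                               trait_names=("y1", "y3", "y2"), lam=lam,
                               sigma_g=_SIGMA_G, seed=seed)
        sim = simulate(cfg)
        ph = sim.phenotypes
        perm = [ph.traits.index(x) for x in ("y1", "y2", "y3")]
        sim.phenotypes = PhenotypeTable(list(ph.samples), ["y1", "y2", "y3"],
                                        ph.values[:, perm])
        return sim
    elif name == "fully_recursive":
        cfg = SimulationConfig(n_individuals=1000, family_size=5, n_snps=100,
                               lam=FULLY_RECURSIVE_LAMBDA, sigma_g=_SIGMA_G,
                               qtl={3: {"y1": 0.8}}, seed=seed)
    elif name == "paper_like":
        cfg = SimulationConfig(
            n_individuals=1000, family_size=5, n_snps=500,
            lam=FULLY_RECURSIVE_LAMBDA, sigma_g=_SIGMA_G,
            qtl={50: {"y1": 0.7}, 150: {"y2": 0.7}, 250: {"y3": 0.7},
                 350: {"y1": -0.5}, 450: {"y1": 0.4, "y3": 0.4}},
            seed=seed)
    else:
        raise ValueError(f"unknown fixture {name!r}")
    return simulate(cfg)
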