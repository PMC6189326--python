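# Methods

## The model

`semgwas` implements association mapping for a set of t quantitative traits
measured on n related individuals, in two nested model classes.

**Multi-trait mixed model (MTM).** For trait vectors stacked as the n x t
matrix Y,

    Y = 1 mu' + g + e,   vec(g') ~ N(0, K ⊗ Sigma_g),  vec(e') ~ N(0, I ⊗ Sigma_e),

where K is a relationship matrix — pedigree expectation (A, tabular method)
or marker-based realization (G, VanRaden: G = MM'/(2 Σ p_j q_j) with M the
dosage matrix centred by twice the allele frequency) — Sigma_g is the t x t
genetic covariance and Sigma_e the t x t residual covariance.  Each SNP is
tested by entering its dosage (0/1/2 copies of the A allele) as one fixed
covariate per trait.

**Structural equation mixed model (SEM).**  Phenotypes may affect each
other.  Given a directed acyclic graph over the traits with structural
coefficients Lambda (lambda_ij ≠ 0 only on the edge j -> i),

    Y = Lambda Y + W s + g + e,

with the same polygenic term and with a *diagonal* residual covariance Psi.
The diagonality restriction is what makes Lambda likelihood-identifiable:
the reduced-form residual covariance (I - Lambda)^-1 Psi (I - Lambda)^-T is
an LDL-style factorization, unique once Psi is diagonal.  The reduced form

    y = (I - Lambda)^-1 (W s + g + e)

shows that a saturated SEM and the MTM parameterize the same marginal
distribution, so their maximized likelihoods coincide; the SEM's value is
interpretive: the SNP coefficient s_jt is the *direct* effect of SNP j on
trait t, and effects transmitted through the trait network are recovered by
path tracing.

**Effect decomposition.**  For a target trait, every directed path from an
upstream trait to the target contributes (product of lambdas along the
path) x (direct SNP effect on the path's head); the indirect effect is the
sum over paths, and total = direct + indirect = (I - Lambda)^-1 d.  The
matrix identity is used as an independent oracle for the path enumeration
in the tests.  Standard errors of indirect and total effects use a
first-order delta method over the direct-effect estimates (full per-SNP
covariance block from the scan) and the structural coefficients (observed
information), treated as independent blocks; p-values use the standard
normal reference, and q-values are Benjamini-Hochberg within each effect
type.

## Fitting

All fitting works in the eigenbasis of K = U D U'.  Rotating Y by U' makes
rows independent with covariance V_i = d_i Sigma_g + Sigma_e, reducing
every likelihood evaluation, Gibbs update, and GLS solve to batched t x t
operations; n in the thousands costs milliseconds per pass.

- **REML (MTM):** EM iterations (monotone in the restricted likelihood;
  the trace is stored and asserted monotone in tests) followed by an
  L-BFGS polish on the log-Cholesky scale so different model classes can
  be compared at tight likelihood tolerances.  Convergence: relative logL
  change < 1e-8 or 500 EM iterations.  Missing phenotype rows are dropped
  listwise.
- **REML (SEM):** (I - Lambda) Y is again an MTM with residual covariance
  Psi, so the same restricted likelihood is maximized jointly over the
  lambda entries, Sigma_g (log-Cholesky), and log Psi by L-BFGS.  Since
  (I - Lambda) is unit-triangular the Jacobian is 1 and the two model
  classes' REML values are directly comparable.  Lambda standard errors
  come from the observed information (central-difference Hessian).
- **Gibbs (MTM):** normal full conditionals for the intercepts and the
  rotated polygenic values, inverse-Wishart full conditionals for both
  covariance matrices.  Priors are weakly informative inverse-Wisharts
  with df = t + 2 and scale 0.5 I (the model offers no default better
  grounded in these data; the scale is small relative to any n used here).
  The chain starts at EM-REML estimates — this leaves the posterior
  untouched and removes initialization transients, which otherwise
  dominate the Geweke diagnostic at practical chain lengths.  Stored
  draws: (iterations - burn_in)/thin.
- **Scan ("SNP Snappy" strategy):** variance components (and Lambda, for
  the SEM) are estimated once on the no-SNP model and held fixed; each SNP
  then costs one 2t x 2t GLS solve, with estimates and standard errors
  from the inverse coefficient matrix, T = estimate/se, and two-sided
  p-values from the standard normal (the scans are used at n where the
  t and normal references are indistinguishable).

## Network search

The trait network is learned from the *residual* covariance of the MTM:
conditioning on the polygenic effects removes confounding by genetic
correlation.  For every trait pair and conditioning subset (enumerated
exhaustively; t is small), the residual partial correlation is computed
from each stored Sigma_e draw via the precision of the relevant submatrix,
and the pair is declared conditionally dependent when the highest-
posterior-density interval at the chosen coverage (0.75 / 0.85 / 0.95)
excludes zero.  The HPD interval is the shortest contiguous window of the
sorted draws containing ceil(coverage x S) of them, ties resolved to the
lowest start.  Wider coverage can only turn dependent calls into
independent ones, so discovered edge sets shrink as coverage grows.

The IC algorithm then builds the skeleton (an edge is absent iff some
conditioning subset renders the pair independent, with the separating set
recorded), orients colliders a -> c <- b for non-adjacent pairs whose
separating set excludes c, and applies the three standard propagation
rules (no new colliders, no cycles, forced chains) to closure.  The output
is a PDAG; a three-trait complete skeleton, in particular, cannot be
oriented from conditional independence alone.  Completion to a DAG
therefore takes an explicit, logged causal order (default: trait order in
the phenotype file), applied only to the edges left undirected.

## Synthetic data

The generator draws per-SNP allele frequencies uniformly from configurable
bounds, simulates founder genotypes as binomial dosages, and produces
full-sib families by Mendelian gamete sampling (an allele is transmitted
with probability dosage/2), mirroring the sire-dam-family design of
commercial broiler populations.  Phenotypes follow the reduced form
exactly: QTL direct effects W s, polygenic effects drawn through the
matrix square roots of Sigma_g and K, residuals with diagonal Psi.  Trait
scales are residual-SD units (Psi = I by default) since no real-data
scales are assumed; the default genetic covariance (0.5 diagonal, 0.25
off-diagonal) gives heritability 1/3 and genetic correlation 0.5, typical
of production traits.  The `paper_like` fixture uses the fully recursive
three-trait coefficients (2.13, -0.17, -0.27) as ground truth with
n = 1000 in 200 families of 5, 500 SNPs, and 5 QTL with mixed targets;
the `chain` fixture uses (2.14, -0.31) with n = 2000.

What the generator does *not* emulate: linkage disequilibrium between
markers (SNPs are independent, so scan calibration results do not speak to
LD-induced multiplicity), selection, genotyping error, non-Gaussian
residuals, or latent confounders between traits.  Passing tests therefore
demonstrate correctness of the estimators and of the discovery machinery
under the model's own assumptions, not robustness to their violation.

## Numerical choices and workload sizes

- Kinship matrices are validated symmetric; eigenvalues are computed once
  at construction (diagonal matrices short-circuit), clipped at zero for
  the rotation, and a 1e-8 diagonal jitter is logged if the smallest
  eigenvalue falls below -1e-8.
- Monomorphic markers contribute nothing to the VanRaden numerator and are
  excluded from its denominator; a fully monomorphic panel is an error.
- Allele frequencies for GRM centring are observed post-QC frequencies.
- QC filters attribute each removed SNP to the first failed filter in the
  fixed order MAF -> call rate -> HWE, so report counts are conserved and
  deterministic; MAF and call rate are computed on observed (non-missing)
  calls, and dosages surviving QC are mean-imputed per SNP before
  modelling.
- The HWE test is the plain 1-df chi-square without continuity
  correction; monomorphic counts return p = 1.
- Zero-variance SNPs yield NaN scan rows rather than exceptions.
- Model comparison reports -AIC/2 = logL - k and -BIC/2 = logL -
  (k/2) ln n.  Parameter counts are explicit: k = t(t+1) for the MTM
  (two free covariance matrices) and k = #edges + t(t+1)/2 + t for the
  SEM, so a restricted SEM has smaller k than the MTM even at equal logL.
- Test and acceptance workloads are sized for a single CPU: the
  equivalence/recovery studies use the paper_like fixture (n = 1000, 500
  SNPs), structure-discovery replication uses 50 seeded replicates of
  n = 2000 with 2000-iteration chains, and the null-calibration scan uses
  2000 SNPs at n = 1000.  The Gibbs recovery check uses 100 families of 5
  (n = 500): with fewer, larger families the data themselves (REML
  included) can place a genetic variance component several posterior SDs
  from truth, which tests the design, not the sampler.

## Known limitations

- Structure discovery conditions on point decisions per edge; no
  multiplicity control is applied across the (few) independence queries.
- The per-replicate probability that the HPD-0.85 decision correctly
  drops the absent chain edge is intrinsically about 85-90% (the HPD test
  behaves like a 15%-level two-sided test under the null), so skeleton
  recovery rates plateau near that level regardless of chain length.
- The delta-method standard errors ignore the (small) covariance between
  Lambda estimates and per-SNP direct effects.
- Non-recursive (cyclic) systems, latent variables, and more than ~10
  traits (exhaustive conditioning subsets) are out of scope.
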