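# Methods

## The model

`vblup` fits the standard animal-model family used in genetic evaluation:

    y = X b + R r + sum_i Z_i u_i + e,

with `y` the n phenotypic records, `X` the fixed-effect design (intercept,
reference-coded factors, covariates), `r ~ N(0, I sigma_r^2)` per
environmental random factor, `u_i ~ N(0, K_i sigma_i^2)` for each genetic
kernel `K_i` (pedigree `A`, genomic `G`, single-step `H`, or dominance
`D`), and `e ~ N(0, I sigma_e^2)`.  For t traits with complete records the
system is stacked trait-major and every variance component becomes an
unstructured t x t covariance matrix on a shared relationship structure,
so the phenotypic covariance is

    V = sum_c Sigma0_c (x) S_c,

with `S_c` in {R R', Z_i K_i Z_i', I} and `(x)` the Kronecker product.

## Variance components

Restricted maximum likelihood is computed entirely on the V scale:

    lnL = -1/2 ( ln|V| + ln|X'V^-1 X| + y'Py ),
    P   = V^-1 - V^-1 X (X'V^-1 X)^-1 X'V^-1.

Gradients are `-1/2 [tr(P dV_c) - y'P dV_c P y]` and the curvature is the
average-information matrix `1/2 y'P dV_c P dV_d P y`.  The update ascends
(theta + AI^-1 grad), with up to five step halvings if the likelihood
would decrease and an expectation-maximisation fallback whenever a step is
rejected or the AI matrix is singular.  The EM update used for fallback
(and for the pure `EM` schedule) is, per component,

    Sigma_c <- Sigma_c + (1/q_c) Sigma_c M_c Sigma_c,
    (M_c)_ab = y'P (E_ab (x) S_c) P y - tr(P (E_ab (x) S_c)),

which reduces to the classical scalar EM-REML step for one trait and is
monotone in lnL.  No relationship matrix is ever inverted on this path;
all solves go through one factorisation of V (or a preconditioned
conjugate-gradient solve of `V [phi1 phi2] = [X y]`).

Schedules: `AI` and `AIEM` (AI with EM fallback -- operationally the same
safeguarded loop), `EM`, `EMAI` (three EM warm-up steps, then AI), `HE`
(Haseman-Elston only) and `HI` (AI started from Haseman-Elston
estimates).  Convergence requires both the largest relative parameter
change and the absolute likelihood change to fall below the tolerance
(default 1e-8, maximum 100 iterations).

A dense reference engine assembles Henderson's mixed-model equations with
kernel-inverse shifts and recomputes the same likelihood, AI matrix,
gradients and solutions from `C`, its inverse blocks and the residuals.
Every quantity must agree with its V-based twin to at least 1e-6 on
randomized instances; this equivalence is the package's central
correctness argument and is enforced in the acceptance suite.  Two details
of the MME likelihood are worth noting for anyone comparing with textbook
forms: with `C` assembled as `W'W` plus `sigma_e^2`-scaled shifts, the
genetic count term must use the number of levels of each effect and the
residual count must be `n - n_b - n_r - sum(n_i)` for the MME form to be
identical (not merely proportional) to the V-based likelihood; and the
`tr(C^rr)`, `tr(K^-1 C^uu)` gradient terms carry an explicit `sigma_e^2`
factor because `C^-1` is the prediction-error variance divided by
`sigma_e^2`.

### Boundary handling

Variance components are floored at `1e-6 x var(y)` (per-trait average).
A component whose estimate sits below ten times the floor on two
consecutive iterations is pinned at the floor, removed from subsequent
updates and reported in `REMLResults.floored`.  Without pinning, an
optimum on the boundary (a truly absent component) makes EM decay
geometrically forever and the relative-change criterion can never fire.
Multi-trait component matrices are kept valid by clipping eigenvalues at
the floor after every EM or clamped AI step.

### Haseman-Elston regression

After OLS adjustment for fixed effects and per-trait standardisation,
the product of a pair's phenotypes is regressed on the pair's entries in
each relationship structure (intercept included, i = j pairs excluded);
coefficients are variance ratios and implied variances are
`var(yhat) * beta`.  The squared pair difference is available as the
alternative response; its coefficients estimate `-2 h^2` and are rescaled
before reporting.  Cross-trait products over ordered pairs give
covariances, hence the genetic correlation.  The normal equations are
accumulated with whole-matrix algebra (O(n^2) per regressor pair), so no
pair enumeration is materialised.  The default response is the cross
product; it is unbiased for the covariance under the centering used,
whereas the squared difference relies on the pair's diagonal entries being
absorbed by the intercept.

### Traces at large scale

Up to a system size of 25,000 the projection matrix is formed explicitly
from one Cholesky factorisation (LAPACK `potri`) and every trace is an
O(n^2) Hadamard sum.  Above the cap, traces switch to seeded Rademacher
(Hutchinson) probes through factor solves; the Monte-Carlo error of the
worst trace is recorded on the state.  The cap is configurable per
`REMLState`; all analyses in this repository run below it.

## Solving

Given variance components, `V [phi1 phi2] = [X y]` is solved by Cholesky
(LU fallback), LU, or Jacobi-preconditioned conjugate gradients (relative
residual < 1e-8 by default).  Then `Py = phi2 - phi1 (X'phi1)^-1 X'phi2`,
BLUEs are `(X'phi1)^-1 X'phi2` with covariance `(X'phi1)^-1` (per-
coefficient Wald z tests and per-factor joint chi-square tests),
environmental effects are `sigma_r^2 R'Py`, and EBVs are
`sigma_i^2 K_i Z_i'Py` over every kernel ID -- individuals without
phenotypes are predicted through the columns of `K_i`, never imputed into
`y`.  Marker effects are back-solved as `alpha = Zc' G^- u / c` with a
minimum-norm solve, because the sample-frequency VanRaden GRM is rank
deficient by construction (column centering places the ones vector in its
null space); since EBVs lie in the range of `G`, `Zc alpha` reproduces
them exactly.

## Relationship matrices

* `A` by the tabular recursion; `A^-1` by Henderson's rules with
  Mendelian-sampling variances from pedigree inbreeding (one-known-parent
  case uses `d = 0.75 - F_known/4`); inbreeding by a Meuwissen-Luo-style
  ancestor recursion that never materialises `A`.  Unknown parents are
  unrelated non-inbred founders, and any individual with an unknown parent
  has `F = 0`.
* `G` by VanRaden's first method, accumulated over marker blocks
  (`--step`) so the peak working set is O(n x block + n^2); missing
  genotypes contribute zero after centering (mean imputation).  Dominance
  coding `{-2p^2, 2p(1-p), -2(1-p)^2}` with denominator
  `sum (2p(1-p))^2`.
* `H` by the joint-distribution block formula with
  `G* = (1-w) G_tuned + w A22` (default blend `w = 0.05`, tuning on:
  an affine rescale matching the mean diagonal and off-diagonal of `A22`);
  `H^-1 = A^-1 + [0 0; 0 G*^-1 - A22^-1]`.  With everyone genotyped,
  blend 0 and tuning off, `H = G` exactly and single-step evaluation
  reproduces GBLUP.
* Inverses are Cholesky-based with escalating diagonal jitter
  (0, 1e-8, 1e-6, 1e-4 times the mean diagonal); the product `K K^-1`
  must reproduce the identity to 1e-6 against the *original* matrix, so a
  rank-deficient sample GRM raises an error advising blending rather than
  returning a meaningless inverse.

## Storage and genotype decoding

Relationship matrices are stored as a lower triangle (row-major) in a
self-describing binary format (magic, version, precision flag, dimension)
with a plain-text `.id` sidecar; single or double precision.  A block
reader returns any (rows x columns) sub-block reading only the triangle
rows it needs -- the contract that replaces OS-level memory mapping.
PLINK 1 `.bed` files (SNP-major v1.00 only) decode through a 256-entry
lookup table, four individuals per byte; additive codes count copies of
the `.bim` allele 1, missing is a reserved sentinel distinct from
{0, 1, 2}, and imputation is deferred to GRM construction.

## The simulator

The generator mirrors a classical benchmark design: a base population of
unrelated individuals (default 500 males + 500 females) drawn marker-wise
from Hardy-Weinberg proportions at frequencies uniform on (0.05, 0.95),
then discrete generations (default nine) of random male-female pairing
restricted to the immediately preceding generation, each pair producing a
fixed litter (default two: one male, one female) -- 10,000 individuals in
total under the defaults.  Markers (default 100,000) segregate
independently; there is no linkage map, selection, or mutation.  Two
traits share a random QTL set (default 600) with effects drawn bivariate
normal, zero mean, unit variance and correlation 0.3; per trait the
breeding values are rescaled so the genetic share of the unit total
variance equals the configured heritability (defaults 0.1 and 0.3).  Two
environmental random factors (20 uniformly assigned levels each, 10% of
variance each -- the level counts and shares are this package's choices,
as the benchmark specifies only "two environmental random effects") and
two fixed factors (2 and 4 levels, evenly spaced constants up to 0.5
standard deviations; the first factor reuses the simulated sexes) complete
the phenotype, with residual variance filling the budget.  Environmental
and residual effects are independent across traits, so the genetic
correlation is the only cross-trait signal.

The genetic correlation is induced at the QTL-effect level and then
verified empirically rather than calibrated exactly per replicate;
realised values vary by roughly `1/sqrt(n_qtl)` around the target, which
is real sampling variation of the design, and recovery checks therefore
compare means over replicate seeds against Monte-Carlo standard errors.

What the simulator does *not* emulate: linkage disequilibrium beyond
family co-segregation, minor-allele-frequency spectra from real SNP
arrays, genotyping error or missingness, selection and assortative
mating, and genotype-environment correlation.  Passing recovery tests
therefore show estimator correctness under the model's own assumptions,
not robustness to violations of them.

## Problem sizes used in the checked analyses

Routine tests run a scaled-down configuration of the same design
(200 + 200 base individuals, three generations -> 1,600 individuals,
5,000 markers, 120 QTL); recovery of the generating heritabilities and
genetic correlation is assessed as the mean over 20 replicate seeds
against two Monte-Carlo standard errors.  Bivariate AI-REML is started
from Haseman-Elston estimates (the `HI` schedule), which typically
reaches the 1e-8 tolerance in 7-11 iterations.  The strategy-equivalence
suite uses 100 randomized instances with up to 50 records, one or two
genetic kernels and one environmental factor.

## Design choices where the design was open

* Additive genotype codes count allele 1 (the `.bim` fifth column); the
  convention is asserted by fixture, since nothing downstream is invariant
  to flipping it.
* GRM: VanRaden method 1 only, frequencies always from the observed
  sample; the method tag and denominator travel in the matrix metadata and
  are required for marker-effect back-solving.
* Reference-level (treatment) coding with an intercept; estimable
  functions, not raw coefficients, are the contract, and rank-deficient
  designs are repaired by dropping dependent columns with a logged report.
* Multi-trait analyses require complete records across traits (v1).
* AI updates ascend; the EM safeguard and boundary pinning above are the
  concrete negative-variance policy.
* Default REML starts: half the phenotypic variance to the residual, the
  rest split equally (deterministic, reproducible); `HI` replaces this
  with HE estimates.
* Jacobi preconditioning for PCG: the diagonal of V is cheap and
  effective for kernels whose diagonal dominates, as relationship
  matrices' do.
* Eigen-decomposition acceleration for single-kernel models and GRM
  sparsification are documented hooks, not implemented paths.

## Known limitations

* The MME reference engine is single-trait, dense and size-capped at
  2,000 equations -- it is an oracle, not a production path.
* Multi-trait missing-data patterns (trait-specific record sets) are not
  supported; records missing any selected trait are dropped.
* No APY-style core/non-core GRM inversion, no sparse supernodal
  factorisation, no interaction (G x G, G x E) kernels, no PCA or mating
  tools.
* `--threads` is passed to the BLAS layer best-effort; results are
  thread-count invariant but speed-ups depend on the linked library.
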