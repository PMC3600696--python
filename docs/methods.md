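# Methods

`f2quant` implements the quantitative-genetic analysis of a three-generation
F2 resource population: pedigree construction and additive relationships,
restricted-maximum-likelihood (REML) estimation of variance components under
the animal model, BLUP prediction of breeding values, derived obesity
phenotypes, QTL-detection power, and a synthetic-population generator that
reproduces the experimental design so every stage can be validated by
parameter recovery.

## The animal model

For a trait `y` measured on F2 animals the model is

    y = mu + SEX + SOB + b_k * AGE [+ b_l * LENGTH] + a + e

with sex (2 classes) and season-of-birth batch (3 classes) as categorical
fixed effects, age in days at measurement as a covariate (and body length in
cm for mass traits), a random additive genetic effect `a ~ N(0, A sigma2_a)`
structured by the pedigree relationship matrix `A`, and residual
`e ~ N(0, I sigma2_e)`.  Heritability is `h2 = sigma2_a / (sigma2_a +
sigma2_e)`.  The bivariate extension stacks two such models; the genetic
covariance of the stacked animal effects is `G (x) A` and the residual
covariance is carried only by animals recording both traits.  Genetic and
phenotypic correlations follow from the estimated components:
`rg = g12 / sqrt(g11 g22)`, `rp = (g12 + r12) / sqrt((g11+r11)(g22+r22))`.

Fixed-effect coding is reference-level on the first sorted label with
centred covariates; variance-component estimates are invariant to this
choice.  Records missing the response or a required covariate are dropped
per trait, so a bivariate system may hold different record sets per trait.

## Relationship matrices

`A` is built by the tabular recursion (`a_ij = (a_{j,s} + a_{j,d}) / 2`,
`a_ii = 1 + F_i`) and stored dense — populations here are a few hundred
animals; a configurable ceiling (default 5000) guards against accidental
huge allocations.  The sparse inverse is assembled directly by Henderson's
rules with inbreeding: each animal contributes `(1/d_i) w w'` on the pattern
{animal, sire, dam} with weights {1, -1/2, -1/2} and Mendelian-sampling
variance `d_i = 1/2 - (F_s + F_d)/4` (both parents known), `3/4 - F_p/4`
(one), 1 (none).  Inbreeding comes from the tabular diagonal by default; the
Meuwissen–Luo recursion is available where the dense matrix is unwanted.
Founders are assumed unrelated and non-inbred: the founder breeds are
purebred lines, and line structure is modelled (in the simulator) as mean
divergence, not as relationship.

The test suite checks `A` entrywise against an independent path-counting
(Wright) oracle and `A^-1 A = I` to 1e-8 on ~200-animal random pedigrees.

## REML estimation

Estimation maximises the REML log-likelihood
`-[log|V| + log|X'V^-1 X| + y'Py] / 2`.  Because the model has a single
structured random effect, rotating the records by the eigenvectors of the
relationship submatrix among phenotyped animals makes `V` diagonal
(univariate) or block-diagonal with 2x2 per-animal blocks (bivariate with
identical record sets), so each iteration costs O(n) after one
eigendecomposition.  When the two traits are recorded on different animal
sets the engine falls back to dense-matrix algebra.

The optimiser is EM-REML for the first 5 iterations (monotone, safe start
at `sigma2_a = sigma2_e = ` half the OLS residual variance, covariances at a
quarter of the sample phenotypic covariance), then average-information (AI)
updates.  An AI step that would decrease the likelihood or leave the
feasible region is halved up to 10 times and then replaced by one monotone
EM step (exact matrix EM in the rotated engines; an ascent-guaranteed
backtracking gradient step in the dense engine).  Convergence requires a
relative log-likelihood change below 1e-9 and a relative parameter change
below 1e-6 (default cap 200 iterations); non-convergence and boundary
solutions are flagged on the result object, never raised.  Near-degenerate
datasets (a genetic correlation pinned at its clip, or a variance at the
floor) legitimately end flagged: estimates are still reported.

Constraints: variances are floored at 1e-6 times the phenotypic variance;
covariances are kept inside the positive-semi-definite region of `G` and
`R` (which bounds all correlations by 1) with a hard clip at |r| = 0.999.
The AI updates act on the six (co)variance parameters directly with
PSD-feasibility step-halving rather than on Cholesky factors: the AI matrix
at the optimum is then already on the reported scale, and its inverse is
the sampling covariance used for all standard errors.  When fewer than 10
animals record both traits the residual covariance is inestimable and fixed
at zero with a warning.

Standard errors of h2, rg and rp are first-order delta-method propagations
of the inverse-AI sampling covariance; tests verify them against numeric
central-difference propagation to 1e-8.  Following the selection rule of the reference analysis,
the reported heritability per trait is the candidate (univariate or any
bivariate fit involving the trait) with the smallest standard error, ties
going to the univariate fit.

BLUP breeding values for every pedigree animal — including unphenotyped
founders and parents — come from Henderson's mixed-model equations at the
REML estimates, using the sparse `A^-1`; prediction-error variances are the
corresponding diagonal of the inverted coefficient matrix times the
residual variance.

## The synthetic population generator

The generator reproduces the design of the resource population: 14 founder
boars of an obesity-prone minipig line each mated to one of 14 production
sows (7 + 7 from two lean maternal breeds) giving 28 F0 animals and 14
full-sib F1 families totalling 127 animals (60 male); 81 F1 are selected as
parents (15 boars + 29 gilts in one cross, 13 + 24 in the other), each boar
mated once or twice to non-litter-mate gilts; 474 F2 are born in 53 litters
of 2–12 piglets (mean ~8.9) across three season-of-birth batches of
approximately 250/125/100; 5 die early and 15 are removed, leaving 454
retained animals.  Two managed constraints mirror practice in a resource
population and make the analysis pedigree exactly 28 + 81 + 454 = 563
animals: parent selection covers every founder family, and losses never
wipe out a whole litter.

Ages at the six measurement points are truncated normal at the recorded
spreads (e.g. 64 ± 11 days at the two-month scan), clipped at ±2 SD and
forced strictly increasing per animal.  Breeding values are gene-dropped:
founders `N(0, G)`, descendants midparent plus a Mendelian-sampling deviate
with covariance `(1 - (F_s + F_d)/2) G / 2`.  Phenotypes add the configured
fixed effects, an optional founder-line mean offset transmitted additively
by expectation (F1 midparent, F2 midparent of F1 — deliberately absent from
the analysis model, so switching it on inflates apparent genetic variance
exactly as line divergence does in the real design), a realised length
covariate when requested, and correlated residuals.  Missingness is
missing-at-random within the retained set: a trait may be restricted to an
exact observed count (e.g. 146 for fasting glucose).

Default fixed-effect sizes, in phenotypic-SD units, are moderate values
typical of a growing-pig experiment: sex 0.25, season batches 0 / 0.4 / 0.8,
age slope 0.03 per day; traits default to unit phenotypic variance.  The
three-trait default architecture places heritabilities at the reference
point estimates (fat percentage 0.57, weight at two months 0.78, fasting
glucose 0.49 on 146 animals) with a genetic correlation of 0.90 between the
fat and weight traits.

What the generator does not emulate: marker genotypes and linkage (no SNP
simulation), selection between generations, non-additive genetic effects,
maternal/litter environmental effects, and non-normal residuals.  Parameter
recovery on these simulations therefore demonstrates the correctness of the
estimation machinery under the assumed model, not robustness of the model
on real data.

One global integer seed drives everything; per-stage streams are derived by
hashing stage names, so the same seed gives bit-identical populations and
pipeline output bundles.

## Power calculations

A QTL explaining a fraction `p` of phenotypic variance in an F2 of size `n`
gives a likelihood-ratio noncentrality `lambda = n p / (1 - p)` (chi-square,
1 df additive or 2 df with dominance).  A fraction of *genetic* variance is
converted by multiplying with the trait heritability.  With markers spaced
`s` cM apart the worst-case QTL sits mid-interval; under the Haldane map
the signal attenuates by `(1 - 2r)^2 = exp(-2s/100)`.  Genome-wide control
uses a Sidak correction over `genome_length / spacing` effective tests —
defaults 0.05 over a 2300 cM, 18-autosome map at 1 cM, printed into every
report.  Binary traits convert observed-scale heritability to the liability
scale by the Dempster–Lerner factor `p(1-p)/z^2`.  The analytic power is
validated against Monte-Carlo rejection rates of the single-locus
likelihood-ratio test at interior operating points (the comparison is
uninformative where power saturates, since the binomial error collapses
faster than the asymptotic approximation error).  Sample-size queries invert
the power function by bisection, so round trips are exact by construction.

## Validation problem sizes

The recovery experiments the package ships run at the design scale: 50
replicate populations for the univariate heritability check (true h2 0.57,
454 records each), 100 replicates for the subset trait (true h2 0.49, 146
records), and 30 replicates for the bivariate genetic-correlation check
(true rg 0.90, heritabilities 0.43/0.78, residual correlation 0.5).  With
the rotated REML engines the full set completes in a few minutes on one
CPU.  Smaller cousins of the same checks run in the test suite.

## Known limitations

- Multi-trait (>2) models are out of scope; full multi-trait
  systems of this size are prone to singular covariance estimates, which is
  why the pairwise-bivariate strategy exists.
- The dense bivariate engine inverts `V` explicitly each iteration; it is
  intended for the few-hundred-record scale, not large field datasets.
- Boundary solutions (h2 near 0 or 1, |rg| near 1) converge slowly along the
  constraint and are flagged rather than polished.
- Delta-method standard errors are first-order and understate uncertainty
  near parameter boundaries.
- No maternal, litter-environment, or dominance components: estimates from
  real F2 data would absorb such effects into `sigma2_a`.
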