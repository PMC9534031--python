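# Methods

This note records the model, the defaults, and the numerical and design
choices behind `cloverqg`, in enough detail that a user can judge what the
package's tests do — and do not — establish about real trials.

## The trial and its model

The design emulated throughout is a two-room (environmental replicate)
randomised split-plot seedling trial: containers are plots, the four
quadrants within a container are sub-plots, and each quadrant holds one
half-sib family's seedlings at 16 plants per quadrant.  Three arms are
distinguished: `TA1` (inoculated with a *Rhizobium leguminosarum* bv.
*trifolii* strain, nitrogen from symbiosis), `NPLUS` (mineral-N positive
control), and `NEG` (no N, no *Rhizobium* — an unlabelled balanced bulk of
all families that measures seed-reserve growth and flags contamination).

Analysis operates on plot observations, i.e. family × replicate quadrant
means, under the all-random linear model

y_ijkl = μ + f_i + R_j + (fR)_ij + r_kj + c_lj + ε_ijkl,

every term drawn from a zero-mean normal with its own variance.  Sub-plot
terms are excluded by design (in this trial type they contribute nothing
once quadrant means are taken).  Row and column effects are nested within
replicate.  The only fixed effect is the intercept: treating replicates as
fixed changes nothing material, and the all-random form keeps the REML
machinery uniform.

**Analysis scale.**  Variances are defined at the plot-mean scale.  This is
a substantive choice: the family-mean heritability formula
h² = σ²f/(σ²f + σ²fR/nR + σ²ε/nR) divides the interaction and residual by
the number of replicates only, which is coherent exactly when σ²ε is the
plot-level error.  A consequence is that with one plot per family ×
replicate cell the interaction (fR) and the plot error are confounded; the
engine drops the interaction term with a warning and the fitted "residual"
estimates their sum.  Heritability computed from such a fit,
σ²f/(σ²f + σ²resid/nR), is identical to the three-term formula evaluated on
the summed components.

## REML engine

The restricted log-likelihood is maximised over the component vector by an
expectation-maximisation warm start (15 iterations) followed by Fisher
scoring on log-variances with step halving; convergence requires the
relative log-likelihood change below 1e-8 and a gradient norm below 1e-6,
with an L-BFGS-B polish as fallback and a diagnostic error (carrying the
trajectory) if everything fails.  Log-parameterisation enforces
non-negativity; a component that collapses below 1e-10 × the phenotypic
variance is pinned to exactly zero and reports no standard error.  Standard
errors come from the inverse expected information at the optimum; component
significance is a one-sided Wald test at α = 0.05 (a boundary-corrected
likelihood-ratio alternative, 0.5·χ²₀ + 0.5·χ²₁, is exposed as
`likelihood_ratio_test`).  BLUPs are σ²f Z'f P y at the estimated
components; family adjusted means are μ̂ + BLUP.

Degenerate terms are dropped, not errored: a term with a single level is
inestimable, and a term with one observation per level is confounded with
the residual.  Terms whose grouping columns are absent from the data are
likewise dropped with a warning, so the same model specification runs on
reduced layouts.

On balanced toy designs the engine reproduces the closed-form ANOVA-REML
estimators to 1e-6 relative and the one-way BLUP shrinkage closed form
exactly; an independent cross-check against a standard mixed-model
implementation (statsmodels MixedLM, random-intercept case) agrees to 1e-3.

**Unconstrained auxiliary fits.**  Covariance-component estimation (below)
fits synthetic sum/difference responses whose "family variance" encodes a
covariance and may legitimately be negative.  For those fits only, the
engine estimates the family component on the raw scale (the total covariance
must merely remain positive definite).  Ordinary fits never return a
negative component.

## Trait derivation

RSR is the plot mean of per-plant root:shoot ratios — deliberately not the
ratio of plot means — and is computed only over plants with positive shoot
weight.  Symbiotic potential uses a family-specific positive-control mean
(the same family grown with mineral N, averaged over all its plants) and a
global negative-control mean (the bulk carries no family labels).  SP is
linear in the plant's own dry weight, so the per-plant and plot-mean bases
coincide on complete plots; both are exposed, default per-plant.  Negative
SP (a plant below the seed-reserve baseline) and SP above 100% (root growth
under symbiosis exceeding the mineral-N control) are retained untruncated.

## Synthetic trials

The generator draws every effect of the model above at configurable
variances, assigns families to container/quadrant slots by a seeded
permutation per replicate, lays containers on a near-square bench grid
(quadrants 2×2 within a container, giving the row/column indices), and
emits plant-level records; output is a pure function of the configuration
including its seed.  Family deviates are drawn once per family and reused
across replicates and treatment arms — shared genetics — with a
configurable shoot–root correlation (default 0.97, the strength typical of
strongly pleiotropic biomass traits in such trials).  The negative-control
bulk is simulated as mean ± sd with no family structure.  Missingness is
completely at random and defaults to zero.

Defaults are the study conditions this package emulates: 120 families × 2
replicates × 16 plants per quadrant, 30 containers per replicate per arm,
treatment means 11.4/5.03 mg (shoot/root, inoculated) and 25.1/9.0 mg
(mineral N), and the published variance components at the plot scale (e.g.
13.5/4.7/49.6 for inoculated shoot DM).  Replicate, row and column
variances are not published; they default to small values relative to the
residual (1.0/0.5/0.5 mg² for inoculated shoot DM, scaled analogously for
the other trait/arm combinations) — large enough to exercise the spatial
terms, small enough not to distort the family-mean variance.  The
negative-control bulk sd defaults to ~25% CV of the bulk means.

**What the generator does not emulate.**  Effects are exactly normal and
additive.  At realistic variance scales (plot sd ≈ 7 mg on an 11.4 mg mean)
this occasionally produces non-positive dry weights (~5% of inoculated
plots); they are retained, because truncation would bias the
variance-component recovery tests that are the generator's purpose, and the
ratio traits guard against them downstream.  Real dry weights are positive
and right-skewed; real spatial correlation is not purely row+column; plant
loss is not random.  Passing recovery tests therefore establishes
correctness of the estimators under the stated model, not robustness to
these departures.

A second consequence of the additive-normal model at study-scale variances:
the mineral-N family mean that forms the SP denominator has a coefficient
of variation near 0.5, so simulated SP is heavy-tailed (a family whose
mineral-N mean lands near the bulk baseline gets an exploding SP, which
inflates the SP family variance).  This is the simulation exposing a real
fragility of baseline-ratio traits with noisy family-specific denominators;
it is also why SP-derived quantities are checked through the formulas
applied to published summary components rather than through simulation.

## Heritability, correlations

The family variance component under a half-sib structure equals ¼ of the
total additive genetic variance; the heritability and gain formulas use the
component as-is (no ×4 rescaling), which is what makes the published
component arithmetic reproduce.  A delta-method standard error for h² is
provided from the component covariance matrix; no published SE method
exists to validate it against, so treat it as indicative.

Genetic covariance between traits X and Y uses the polarization identity
covA = [σ²f(X'+Y') − σ²f(X'−Y')]/4 on unit-scaled traits, rescaled back to
original units.  For quadratic (balanced-ANOVA) estimators this equals the
direct cross-product estimator exactly; it keeps the engine univariate; and
unlike the three-fit sum trick it is exactly antisymmetric under a sign
flip of either trait.  The sum/difference fits use the unconstrained family
component described above — with a constrained fit, a strongly correlated
pair makes the difference trait's family variance collapse to the boundary
and biases covA toward zero.  Genetic correlations are covA over the
geometric mean of the family variances; small-sample estimates can
overshoot ±1 and are clamped with a flag in matrix output (the scalar
function returns the raw value).  No standard errors are attached to
genetic correlations.

Phenotypic correlations are plain Pearson r with two-sided t-test p-values
on the family × trait matrix of BLUP-adjusted means, without multiplicity
adjustment.

## Selection theory

Selection intensity uses the infinite-population truncated-normal formula
k = φ(z)/p, giving 2.0627, 1.7550, 1.3998 at p = 0.05, 0.10, 0.20.  (The
breeding literature's two-decimal table values 2.06/1.76/1.40 arise from
rounding classical three-decimal tables; note 1.7550 itself rounds to 1.75.)
A Burrows finite-population correction is available and off by default.
Predicted gain is ΔG = k·c·σ²f/σPF with c = 0.5 for half-sib families and
σPF the phenotypic sd among family means; percent gain is relative to the
absolute trait mean.  The Smith-Hazel system P b = A w is solved by Cholesky
factorisation with a positive-definiteness check and a 1e-8 relative
residual guard; P is assembled from among-family phenotypic (co)variances
(σ²f + σ²fR/nR + σ²ε/nR on the diagonal, analogous term-wise covariances
off-diagonal) and A from the family (co)variances, with weights defaulting
to (1, 1) (desired-gain weights are supplied through the same vector).
Correlated response is k·c·hX·hY·rA·σPY, signed.  Top-fraction selection
takes ⌈p·n⌉ families with deterministic tie-break by family ID and a
warning when a tie spans the cut.

## Pattern analysis

Trait columns are standardized (zero mean, unit variance) before clustering
and PCA because the traits mix mg, percent and ratio units; constant
columns are excluded with a warning.  Clustering is Ward's minimum-variance
agglomeration — the natural companion of squared-Euclidean dissimilarity;
the linkage choice is otherwise open and Ward is this package's choice.
The group count uses the Hartigan stopping rule, smallest k with
H(k) = (n−k−1)(W_k/W_{k+1} − 1) ≤ 10 (threshold configurable).  Note a
known property of the threshold-10 rule: splitting even a single
standardized Gaussian reduces within-SS by roughly (2/π)/d in d trait
dimensions, so for n ≈ 100 entries and d ≤ 5 traits the rule tends to
over-partition unclustered data; with many traits (d ≈ 10) it behaves as
intended.  Interpret small-d group counts with this in mind.  PCA is an
eigendecomposition of the trait correlation matrix; scores are standardized
data projected on eigenvectors, loadings are eigenvectors scaled by root
eigenvalues (so the angle between loading vectors reflects the sign of the
trait correlation), variance proportions are eigenvalues over their sum,
and eigenvector signs are fixed (largest-magnitude loading positive) for
reproducible output across BLAS builds.

## Pipeline sizes and determinism

All randomness flows through `numpy.random.default_rng` seeded from the
configuration; identical configurations produce byte-identical CSV output.
The Monte-Carlo checks in the test suite use 200 simulated trials of 120
families × 2 replicates (the study's own scale) for variance and
heritability recovery, and 200 trials per correlation strength for genetic
correlation recovery, aggregated as ratio-of-means with delta-method
Monte-Carlo standard errors (per-seed correlation ratios carry a Jensen
bias of order cv² and are unstable when a weak family variance lands near
zero).  These sizes keep the whole suite to a few minutes while leaving the
Monte-Carlo error well below the effects being checked.

## Known limitations

- Single-trait REML throughout; the multivariate structure enters only via
  the polarization covariances, exact for balanced designs and approximate
  under strong imbalance.
- No spatial modelling beyond row/column effects; no pedigree beyond the
  half-sib family structure; no genomic information.
- h² standard errors are delta-method approximations; component significance
  by a Wald test is crude near the boundary (the LRT option is preferable
  there).
- The gain equations are single-cycle deterministic predictions; no
  multi-cycle recurrent-selection simulation, no economic weighting model.
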