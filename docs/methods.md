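# Methods

## The quantities

A species record summarises mature social groups by the mean number of
breeding females *B* and the mean total number of females *N* (both
real-valued species averages, so `B = 1.3` is legal).  Three derived
quantities drive everything else:

* the proportion of breeders *P = B/N* ∈ (0, 1];
* the monopolization-of-breeding-positions index
  *M = (1 − B/N)/(1 − 1/N)*.  The denominator rescales 1 − *P* by the
  largest value it can take at group size *N* (attained at *B* = 1), so
  *M* = 1 exactly when a single female monopolizes breeding — at any
  group size — and *M* = 0 when all females breed.  *M* is undefined at
  *N* ≤ 1 (the denominator vanishes); such records are accepted by the
  data layer but flagged, and all index summaries exclude them with an
  explicit count.
* the social category: `single_breeder` when |*B* − 1| ≤ tolerance,
  `multi_breeder` when *B* > 1 + tolerance.  The tolerance defaults to
  1e−9 — "a mean of one breeding female" is treated as exact — and is
  configurable because real compilations sometimes code 1.0 with
  rounding noise.  Classification depends on *B* only, never on *N*.

Single-breeder species carry no variation in breeder number, so only
multi-breeder species enter the regressions; this exclusion is built
into the pipeline, not left to the caller.

## The regression model

For each taxon, the model is a linear regression of the transformed
breeder proportion on log group size with phylogenetically correlated
residuals:

    y = α + β x + u + e,   u ~ N(0, σ²ᵤ R),   e ~ N(0, σ²ₑ I)

The default response transform is log *P* (natural log), making β the
elasticity of the breeder proportion with respect to group size; logit
and identity transforms are available (the logit pulls proportions of
exactly 1 just inside the boundary before transforming).  Base-10
logs are available for plotting parity; they rescale both axes and
leave the log–log slope unchanged.

R is the Brownian-motion tip correlation of the taxon's ultrametric
tree: entry (*i*, *j*) is the depth of the most recent common ancestor
divided by total tree depth — shared evolutionary history as a fraction
of total history.  R is unit-diagonal, positive semi-definite by
construction, and handles multifurcations natively.

Two estimators fit this model:

**Profile-likelihood GLS** writes the residual covariance as
σ²·(h·R + (1 − h)·I) and estimates the mixing proportion h by maximum
profile likelihood on a 41-point grid refined by bounded local search,
working in the eigenbasis of R so each candidate h costs O(n).  With
h = 0 (or R absent) the fit reduces exactly to ordinary least squares.
Intervals are normal-approximation ±1.96 SE; a saturated two-point fit
is flagged rather than reported with fictitious uncertainty.

**Bayesian mixed model (Gibbs).**  Priors are deliberately diffuse:
fixed effects N(0, 1e8), both variances inverse-gamma(0.001, 0.001).
Each sweep draws (α, β, u) from their exact joint multivariate-normal
full conditional — the fixed effects from their marginal via a Schur
complement, then the random effects conditionally; in the eigenbasis
of R the random-effect precision is diagonal, so a sweep costs O(n) —
followed by the two inverse-gamma variance draws.  The sampler is
bit-reproducible given the chain seed.  The chain defaults (500 000
iterations, 200 000 burn-in, thinning 100) mirror the published
analysis; tests and desk-scale runs use shorter chains passed
explicitly (typically 20 000 / 5 000 / 10, or less for replicated
simulation studies), chosen so the full suite runs in minutes while
retaining ≥ 1000 draws per chain.  The sampler refuses configurations
retaining fewer than 100 draws.

Summaries per fixed effect: posterior mean, equal-tailed 95% credible
interval (order-statistic exact, rather than HPD), and the MCMC
*p*-value 2·max(min(frac > 0, frac < 0), 1/n) capped at 1 — floored at
2/n because an MCMC tail probability cannot resolve below one draw.
Convergence diagnostics per parameter: the Geweke z-score (first 10%
vs last 50%, segment variances estimated by a Bartlett lag-window
spectral estimator at frequency zero with bandwidth √n) and the
effective sample size n/(1 + 2Σρ) with the autocorrelation sum
truncated at the first non-positive paired sum (Geyer's initial
positive sequence).  Heidelberg–Welch diagnostics are not implemented;
Geweke plus ESS cover stationarity and mixing for these conjugate
chains.

The estimators agree closely but not identically: the posterior mean
integrates over variance-component uncertainty where profile-ML GLS
plugs in the likelihood mode, a systematic finite-sample (Jensen) gap
of order 1/n — about 0.003 on a slope with standard error 0.035 at
n = 100.  The sampler itself is verified against exact two-dimensional
numerical integration of the marginal variance posterior at n = 30.

**Pooled model.**  No single phylogeny spans wasps, ants, birds and
mammals, so the across-taxa model replaces the phylogenetic effect
with a random intercept on taxonomic class (the same Gibbs machinery
with an indicator random-effect design).  The pipeline also exports a
plain GLS pooled fit, since a figure's regression line may come from
either.

## Tree preparation

Trees are Newick phylograms or chronograms (dendropy handles parsing,
serialisation and pruning; path-length and MRCA-depth matrices are
computed here).  Operations preserve the tip–tip path-length matrix
exactly under write/read round trips and pruning.

**Congeneric polytomy grafting** expands a genus-level tip into a
polytomy of congeneric species: the tip becomes an internal node whose
children (the renamed original plus the new species) sit on pendant
branches, and the stem above is shortened by the pendant length so
every root-to-tip depth — and hence ultrametricity — is preserved.
The pendant length defaults to half the average congeneric patristic
distance: a patristic distance between two ultrametric tips is twice
the pendant branch, so halving preserves the tree's timescale.  Using
the distance directly, or the min/max congeneric distances for
sensitivity variants, is a caller option via
`average_congeneric_distance`.

**Nonparametric rate smoothing** converts a phylogram to relative
time.  Node ages (tips at 0, root fixed at a required, explicit
`root_age`) minimise the sum of squared differences between the
substitution rates of adjacent branches, where a branch's rate is its
input length divided by its time duration; the root term is the squared
deviation of the root's child rates from their mean.  Ages are
parameterised as logistic fractions of the parent's age, which enforces
parent-older-than-child by construction and leaves an unconstrained
problem for L-BFGS.  Initial ages come from the input depths, so a
clock-like phylogram starts (and finishes) at penalty ≈ 0.  The
objective depends only on relative rates, so rescaling all input branch
lengths leaves the smoothed ages unchanged (verified by test).  The
root age is not identifiable from the data and must be supplied; for
correlation matrices only relative ages matter.

## The synthetic-data generator

The generator exists so the discrete-vs-continuum inference can be
exercised and validated without the original compilation.  It emulates:

* **phylogenies** — pure-birth (Yule) trees conditioned on tip count,
  built lineage-by-lineage with exponential waiting times (expected
  depth Σ_{k=2..n} 1/(k·rate), verified against that closed form);
* **phylogenetic signal** — Brownian motion along branches, with
  `sigma2_phylo` specified as the *tip-level* variance (the diffusion
  rate is scaled by tree depth), so scenarios are comparable across
  trees;
* **group sizes** — log-normal *N* with half of the log-scale variance
  phylogenetically correlated by default, floored at `n_min` ≥ 2;
* **the discrete scenario** — log *P* = α + β log *N* + Brownian +
  noise, then *B* = clamp(*P*·*N*, 1, *N*) (continuous species means by
  default; integer rounding optional).  The clamp embodies the
  constraint that a mature group holds at least one breeder; it
  truncates the generative model deliberately so the tests measure the
  recovery bias it introduces instead of assuming it away.  The default
  intercept α = 0 encodes that a group of one female necessarily has
  *P* = 1;
* **the continuum scenario** — log *P* drawn independently of *N* from
  a normal censored at *P* = 1.  The atom at 1 is intentional: real
  compilations contain many species in which every female breeds;
* **monogyny** — a configurable fraction of species set to *B* = 1
  exactly.

Taxon presets encode the contrast the comparative data show: insect-like
scenarios with wide colony-size ranges (up to ~10⁶) and steep declines
(slopes −0.4 to −0.7), vertebrate-like scenarios with groups of ~2–30
females and shallow declines (~−0.2).  The four named presets (wasp,
ant, bird, mammal) use the published per-taxon slope estimates
(−0.378, −0.672, −0.404, −0.206) as generating values, with group-size
distributions and monogynous fractions chosen once to resemble each
taxon's compilation (e.g. most ants monogynous, most wasps not).

What passing tests do *not* show about real data: the generator is
log-linear by construction, its trees are clean Yule chronograms, and
species are sampled completely at random — real compilations have
taxonomically biased sampling, measurement error in *B* and *N*, and
trees with calibration uncertainty, none of which are emulated.

### A note on null calibration at the feasibility boundary

Under *any* continuum generator respecting 1 ≤ *B* ≤ *N*, a species is
observable as multi-breeder only when *P* > 1/*N* — a group-size-
dependent truncation.  When the continuum *P* distribution places
appreciable mass below 1/*N* for the smaller groups in the sample, the
retained multi-breeder data carry a genuine weak negative *P*–*N*
dependence even though *P* was drawn independently of *N*.  Under the
default study conditions the measured false-positive rate of the slope
test is therefore ~11% rather than the nominal 5%; with the identical
tree and signal structure but an exactly Gaussian (boundary-free) null
response, the measured rate is 3–4%.  The inflation is a property of
the boundary-constrained data-generating process — the test is
correctly rejecting a null that is not exactly null — not of the
estimators.  Both measurements are encoded as tests.

## Numerical choices

* Ultrametricity tolerance: relative depth spread ≤ 1e−6 by default,
  configurable everywhere it is checked.
* Correlation matrices get a jitter of 1e−10 × mean diagonal before
  factorisation; eigenvalues are clipped at zero (PSD is verified to
  −1e−8 before clipping and rejected beyond that).
* Equal-tailed intervals use empirical 2.5/97.5 percentiles.
* Degenerate inputs error loudly: constant predictors, zero-variance
  chains, chains under 100 draws, non-ultrametric trees passed to the
  correlation conversion (the error points to the rate smoother), and
  trait rows violating *B* ≤ *N* are all reported with the offending
  species or line numbers; no silent dropping anywhere.
* Multiple candidate trees per taxon: fits are repeated per tree and
  the posterior means, interval endpoints and p-values averaged
  arithmetically.

## Problem sizes

The replicated simulation studies in the test suite and acceptance
script use 100–300 species per replicate, 100–200 replicates, and
chains of 3 000–50 000 iterations — sizes at which the Monte-Carlo
error of each summary is comfortably below the tolerances being
asserted, and the whole suite completes in a few minutes on one CPU.

## Known limitations

* Gaussian responses only; no binomial/Poisson families for counts.
* The pooled model's random intercept treats taxa as exchangeable; with
  four levels the group-variance posterior is weakly identified (its
  diagnostics are reported so this is visible).
* NPRS uses numerical optimisation with finite-difference gradients;
  trees beyond a few hundred tips will be slow to smooth.
* Tree uncertainty is handled only by averaging fits over a supplied
  tree list, not by joint inference.
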