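# Methods

This note documents the statistical procedures implemented in `altinull`,
the conventions chosen where several defensible options exist, and what
the synthetic generator does and does not emulate.

## Data model and occupancy filter

A *site table* holds one lake per row with altitude (m a.s.l.) and up to a
few dozen environmental variables, each tagged with a measurement kind
(`concentration`, `percentage`, `ph`, `nominal`) that drives preprocessing.
A *community matrix* holds non-negative integer counts of species per lake
for one taxonomic group. Occurrence is defined as count > 0 throughout; no
detection threshold is applied. Every analysis operates on the matrix
filtered to species present in at least `min_sites` lakes (default 4),
applied per group independently; the filter is idempotent and never
changes the site set.

## Species-level altitudinal tests

**Bias test.** For each species, altitudes of occupied lakes are compared
with those of unoccupied lakes by a two-tailed Welch *t*-test
(Welch–Satterthwaite fractional degrees of freedom; no equal-variance
assumption; *p* from the continuous *t* distribution). Species leaving
fewer than two lakes on either side are reported untestable rather than
forced through the test. The direction of a significant bias (`low` /
`high`) is the sign of the occupied-minus-unoccupied mean altitude; exact
ties map to `none`. No multiple-testing correction is applied across
species — the per-species *p*-values are descriptive screens whose group
proportions are what is compared; this is a deliberate caveat, not an
oversight.

**Range-given-occupancy null.** A species present in *k* of the *N*
surveyed lakes has a null altitudinal-range distribution defined by
drawing *k* altitudes without replacement from the survey. The Monte-Carlo
route draws `n_rep` = 9,999 replicates; envelope bounds are the
inverse-ECDF (type-1 order statistic) quantiles at α/2 and 1 − α/2
(two-sided 95% by default; a one-tailed variant is a matter of setting α).
*Narrow-ranging* means the observed range falls strictly below the lower
bound. One envelope is computed per distinct *k* and shared across
species, since the null depends on *k* only. The exact route
(`exhaustive_null_range`) exploits the fact that a subset's range depends
only on its extreme members: the number of *k*-subsets with sorted-altitude
extremes (i, j) is C(j − i − 1, k − 2), giving the full pmf in O(N²)
operations. It serves as the oracle for the Monte-Carlo envelope in the
tests and is exposed for small-survey use; the default enumeration cap
keeps survey-sized problems on the Monte-Carlo path, matching how such
envelopes are conventionally computed, and can be disabled.

**Group contrasts.** Proportions of significant species are compared
pairwise with two-sided Fisher exact tests under the minimum-likelihood
rule (sum of hypergeometric probabilities of tables no more probable than
the observed one, with a ~1e−7 relative tolerance guarding float ties —
the convention of the standard implementations). Zero margins give *p* = 1.
The Welch and Fisher primitives are delegated to scipy, which implements
exactly these conventions; the test suite verifies both against
independent oracles (an incomplete-beta *t* CDF; full table enumeration).

## Constrained ordination

**Preprocessing.** Community counts are Hellinger-transformed,
√(y_ij / y_i·), so Euclidean distances between transformed rows equal
Hellinger distances and double zeros carry no weight; all-zero rows map to
zero. Environmental variables failing a normality check are
log(x + 1)-transformed, except percentages, pH (already a log scale) and
0/1 nominal variables; zeros and negative values are first replaced by a
per-variable constant one order of magnitude below the smallest positive
measurement. The normality check is a KS test with estimated mean/SD; the
default uses Lilliefors-corrected critical values (the plain KS reference
distribution is markedly conservative when parameters are estimated — the
suite demonstrates this), with the plain variant available as an option.
Predictors are standardized before ordination because the variable bank
mixes units; this affects reported coordinates, not R² or *p*.

**RDA.** Y is column-centered; fitted values Ŷ come from least squares of
Y on the centered/standardized design; constrained axes are the principal
axes of Ŷ. R² = SS(Ŷ)/SS(Y); adjusted R² uses the Ezekiel formula with
*m* = design rank (collinear designs are fit on the column space with a
warning). Eigenvalues are s²/(n − 1) and sum to SS(Ŷ)/(n − 1). Scaling is
a correlation biplot: unit site scores, species scores carrying the
singular values. R², adjusted R² and eigenvalues were cross-checked
against vegan 2.7 on a fixed fixture (frozen in the test suite, agreement
to 7 significant digits), as was vector fitting against `envfit`.

**Permutation tests.** The pseudo-*F* is (SS(Ŷ)/m)/(SS_res/(n − m − 1));
rows of the centered response are permuted freely (unrestricted
permutation — the simplest exchangeability assumption and the common
default) and *p* = (1 + #{F* ≥ F})/(n_perm + 1), so *p* is never below
1/(n_perm + 1).

**Forward selection (double stopping).** Selection begins only if the
global model with all candidates passes the permutation test at α.
At each step the candidate contributing the largest additional fitted
variance — computed on the response and candidate residualized for the
variables already selected — enters if its partial permutation *p* < α
and the cumulative adjusted R² does not exceed the global model's
adjusted R². The stop reason (`alpha`, `adj_r2_ceiling`, `exhausted`) is
recorded in the trace. Under pure noise the global gate leaves the model
empty in ≈ 95% of runs, which the acceptance suite verifies.

**Vector fitting.** An external variable (altitude) is regressed on the
site scores of the first two constrained axes (or the single axis when
only one exists); the squared correlation is the regression R², tested by
permuting the variable. Direction cosines are the normalized coefficients.

## Richness models

Per-site richness is regressed on altitude, linearly and quadratically
(ordinary least squares on raw altitude powers). Model choice is by AICc
with the Gaussian parameter count including the residual variance (p = 3
and 4), i.e. AICc = −2ℓ + 2p + 2p(p + 1)/(n − p − 1) with the full
log-likelihood constant retained — the convention of standard AICc tooling
for linear models, verified against an R oracle frozen in the tests. The
nested pair is also compared by a deviance χ²(1) test with dispersion from
the richer model. Absolute AICc values are convention-dependent; only
differences and the selection decision are meaningful. A peak altitude is
reported only when the quadratic is selected, curvature is negative and
the vertex −b₁/(2b₂) lies inside the observed altitude span; otherwise the
reason (`u_shaped`, `extrapolated`, `flat`) is recorded.

## Synthetic districts and communities

The generator's defaults mirror the survey geometry the analysis chain is
designed for: 82 lakes spanning 1,620–2,990 m a.s.l., with lake density
concentrated at mid elevations — implemented as a symmetric Beta(c, c)
profile rescaled to the altitude span, c = 2 by default, chosen as the
simplest unimodal density with one interpretable knob (no quantitative
density-vs-altitude curve exists to fit, so the hump is qualitative by
design). Environmental variables are monotone functions of altitude plus
Gaussian noise, with per-variable correlation and kind-specific output
maps (log-normal for concentrations, logistic for percentages, affine for
pH-like variables, thresholded for fish presence); default correlations
(|ρ| ≈ 0.3–0.85) span the weak-to-strong collinearity with altitude that
lake surveys report.

Species come in three archetypes. *Filtered* species draw a Gaussian
niche optimum uniformly on the gradient (breadth σ = 150 m by default, the
scale at which detection power is high but not trivial) and occupy an
exact target occupancy *k* by weighted sampling without replacement with
weights ∝ exp(−(alt − μ)²/2σ²) — conditioning on exact *k* keeps the range
null's *k*-conditioning honest. *Range-cohesive* species occupy every lake
inside a window of width drawn uniformly (200–900 m by default) placed
uniformly within the domain — the classic mid-domain construction whose
overlapping ranges produce a central richness hump. *Neutral* species
occupy a uniformly random *k*-subset. Abundances on occupied lakes are
geometric with mean 3 — any right-skewed integer law suffices, since
abundance matters only through the Hellinger transform. Occupancy targets
default to 4–40 lakes, the post-filter range observed in practice.

What the generator does **not** emulate: spatial (x, y) structure,
between-valley dispersal limitation, temporal dynamics, species
interactions, or detection error. Passing tests therefore demonstrate the
statistical machinery's calibration and power under the stated generating
models, not robustness to those real-data complications.

## Problem sizes and numerical choices

Calibration experiments use 1,000 synthetic species for the species-level
type-I rates, 200 replicates for the ordination null (with 199
permutations per selection test) and 100 replicates for mid-domain
recovery — sizes at which the binomial confidence bands are a few
percentage points wide and the whole suite runs in seconds. Permutation
and randomization counts default to 9,999 in the user-facing API.
Reproducibility is by a single run seed with per-stage substreams derived
from (seed, CRC32 of the stage name). Quantiles of simulated null
distributions use the inverse-ECDF rule; fitted-variance comparisons use
a 1e−10 tolerance when testing the adjusted-R² ceiling; zero-residual
designs are guarded so exact linear relationships yield the floor
*p*-value rather than a division error.

## Known limitations

- The bias test treats lakes as independent samples of altitude; spatial
  autocorrelation between neighboring lakes is not modeled.
- Forward selection *p*-values are conditional on the selection path;
  only the double-stopping rule, not a full selective-inference
  correction, guards their optimism.
- Gaussian OLS on richness counts can in principle predict negative
  richness outside the observed range; count-model alternatives (Poisson,
  negative binomial) are deliberately out of scope.
- The exact range-null enumeration assumes exchangeable lakes; surveys
  with strongly duplicated altitudes produce discrete null support where
  the strict-inequality narrow call is conservative.
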