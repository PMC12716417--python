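# Methods

This note records the models implemented in `streamisd`, the defaults and
why they were chosen, the numerical details, and what the synthetic-data
generator does and does not emulate.

## Bounded power-law ISD (`streamisd.isd`)

The individual size distribution is modelled as a bounded power law (PLB)
on body mass *x* ∈ [*x*min, *x*max] with density
(b+1)·x^b / (x_max^(b+1) − x_min^(b+1)) for b ≠ −1 and the log-uniform
limit x⁻¹/ln(x_max/x_min) at b = −1. The likelihood branch switches when
|b + 1| < 10⁻⁸; the negative log-likelihood is continuous across the
switch (unit tested).

* **Bounds**: set to the observed sample minimum and maximum. The
  estimation literature's default; sensitive only when n is small.
* **Optimization**: bounded 1-D minimisation (Brent) of the analytic
  negative log-likelihood on b ∈ [−10, 5], `xatol = 1e-8`. The likelihood
  is unimodal in b, so a grid oracle is a cheap independent check and is
  asserted in the acceptance tests.
* **Confidence interval**: 95% profile likelihood, the set
  {b : nll(b) ≤ nll(b̂) + 1.92}, endpoints located by root bracketing
  (`brentq`, xtol 10⁻⁶) on each side; if the profile never rises 1.92
  units before the optimisation box, the box edge is reported.
* **Degenerate inputs**: fewer than two fish, or all masses identical,
  raise — a one-point ISD has no exponent.
* **Masses, not lengths**, are the modelled variable; length-only records
  are excluded upstream by the QC stage. No small-size truncation is
  applied by default (gear selectivity correction is out of scope).

The canonical spectrum relation b = λ + log(TTE)/log(PPMR) is provided for
reference predictions; the log-ratio is base invariant.

## Record QC and community means (`streamisd.prep`)

* Repeat samples: only the most recent sample per site is kept; ties on
  date go to the larger sample, then input order.
* Length–weight QC: per species with ≥ `min_n` (default 10) paired
  records, OLS of log₁₀ mass on log₁₀ length; records with |standardized
  residual| > `z_thresh` (default 3) are removed. Conventional allometric
  screening; both knobs are configurable. Flagging is scale equivariant.
  Flagged records are removed *before* both ISD fitting and abundance
  tallies, and abundance is the count of retained individuals.
* Community-weighted means are individual-count weighted (not biomass).

## Life-history affinities (`streamisd.life_history`)

Reproductive mode is recoded to ordinal parental care (nonguarder = 1,
brood hider = 2, substrate chooser = 3, guarders/bearers = 4) and treated
as interval-scaled thereafter. The Gower dissimilarity over age at
maturity, log₁₀ fecundity, spawning-season duration and parental care is
the mean range-scaled absolute difference. Fecundity enters on the log₁₀
scale: annual egg output spans orders of magnitude, and raw range scaling
would let the largest spawners dominate the matrix. Spawning season is
encoded as duration in months.

The matrix is embedded in 2-D by nonmetric MDS (isotonic regression on
dissimilarity ranks, SMACOF majorisation, stress-1 reported; 20 random
starts, ≤ 500 iterations, eps 10⁻⁸ — tight enough that stress is invariant
to monotone transforms of the input to ~10⁻³). Archetypal analysis with
k = 3 (the trilateral life-history model; no model selection over k) is
run on the ordination scores, not on the Gower matrix directly.
The alternating least squares solves each simplex-constrained subproblem
by non-negative least squares with a sum-to-one penalty row; archetypes
are kept inside the convex hull of the data by projection. Initialisation
is greedy farthest-point plus 10 random restarts, best residual wins.

Archetypes are labelled from affinity-weighted trait means: top fecundity
→ periodic, top parental care among the rest → equilibrium, remainder →
opportunistic; a fecundity/care tie at one archetype is ambiguous and
raises. Missing continuous traits are imputed genus-mean-then-global-mean
with a report (phylogenetic imputation is out of scope). Community
affinity axes with pairwise |r| above the collinearity threshold (default
0.7) are reduced, preferring to keep the periodic and opportunistic axes,
which carry the life-history hypotheses; the path model uses at most those
two affinity axes.

## Flow alteration (`streamisd.flow`)

The package consumes precomputed annual observed/expected flow metrics
with a per-year model-error band [expected_lo, expected_hi]; constructing
expected (natural) flows is upstream and out of scope. A year is inflated
(magnitude/frequency/duration metrics) or later (timing metrics) when the
observation exceeds the band, diminished/earlier below it, indeterminate
inside it. Severity per gage × metric × direction is the proportion of
years with that designation — indeterminate years count in the denominator
only — and gages with fewer than 10 years of record are excluded. High/low
events are defined upstream as the 90th/10th percentile nonexceedance
flows; that is metadata here.

Sites pair to the gage with the smallest relative drainage-area
difference within ±10%, provided no major discontinuity (dam or large
tributary) intervenes; ties break lexicographically on gage id. Duration
metrics are removed before modelling (annually, frequency and duration
are mechanically inverse); then, while any severity-column pair exceeds
|r| > 0.7, the member with the larger mean absolute correlation is
dropped. When the three standard covariates (diminished low-flow
magnitude, inflated high-flow frequency, later high-flow timing) are all
present they are used directly as the default retained set. Severities
use all available years, not only years overlapping the fish sample.

## Piecewise path model (`streamisd.sem`)

Numeric columns with |skewness| > 1 are log-transformed (log(x+1) when
zeros are present) and every numeric column is z-scored, so path
coefficients are standardized. Ecoregion enters as dummy contrasts
(reference level first alphabetically); dummy coefficients are reported
unstandardized and ecoregion never appears as a standardized edge.

Submodels are selected in three stages — exponent on traits + flow + land
use, each trait on flow + land use, each flow variable on land use — all
with drainage area and ecoregion forced. All four trait submodels are
always fit. Selection is bidirectional stepwise on the Gaussian profile
AIC, n·ln(RSS/n) + 2p with p counting the coefficients (intercept
included) plus the error variance, a constant convention across compared
models. The greedy walk runs from both the full and the forced-only
starting models and keeps the lower-AIC endpoint; a single start can lodge
in a single-move local optimum when two correlated noise terms must leave
together, and the two-start walk matches the exhaustive all-subsets
minimum on every test fixture. Exactly collinear candidate sets get
infinite AIC rather than an error, which makes noiseless (zero-residual)
data selectable. Selection and the final submodels use the identical
standardized frame; there is no data splitting.

Correlated-error edges connect every pair of endogenous trait and flow
variables (within-trait and within-flow pairs included, not only
trait × flow pairs): community-weighted traits are computed from shared
abundance weights, and flow severities from shared gage records, so their
residuals covary for reasons outside the modelled paths; a global fit test
that punished those pairs would be testing the bookkeeping, not the causal
structure.

Directed separation: one claim per ordered non-adjacent pair whose later
member (in the causal layer order) is endogenous, excluding
correlated-error pairs; pairs of exogenous variables are not claims
because the model places no constraint on exogenous covariance. Each
claim's p-value is the t-test on the earlier variable's coefficient in a
regression of the later variable on that variable plus its selected
parents (partial F-test for categorical terms); this is the local-Markov
form of the claim and is exactly calibrated under Gaussian errors.
P-values are floored at the smallest positive float before pooling.
Fisher's C = −2Σln p with 2k degrees of freedom; an empty basis set is
the saturated case, reported as C = 0, df = 0, p = 1. No multiplicity
correction is applied to claim p-values — C is the aggregate.

Effects on the exponent: direct = the edge coefficient; indirect = sum
over all directed paths of length ≥ 2 of the edge-coefficient products
(computed by memoised dynamic programming over the DAG; correlated-error
edges are never traversed); total = direct + indirect, an identity that
holds to 10⁻¹⁰ by construction and is asserted.

## Synthetic studies (`streamisd.synthetic`)

The generator plants a 15-edge causal diagram — land use (crop, developed)
→ flow severities (diminished low-flow magnitude, inflated high-flow
frequency, later high-flow timing) → community traits (periodic and
opportunistic affinity, trophic level, CTmax) → exponent — with
coefficient magnitudes drawn uniformly from [0.2, 0.4] and signs fixed by
the layered hypotheses (periodic → b positive, opportunistic → b negative,
trophic → b positive, CTmax → b negative; flow and land use reach b only
through traits). All latents are kept at unit variance by setting each
residual SD to √(1 − explained variance); a configuration whose implied
explained variance reaches 1 raises as infeasible (unless noise is
disabled, which is supported for noiseless diagnostics). Planted
coefficients are therefore directly comparable to the standardized
coefficients the pipeline estimates.

Observables are constructed so the pipeline's own transformations invert
the generator: land-use percentages and drainage areas are lognormal (the
skewness gate logs them back to the planted latents); severities are
quantized to whole altered years out of 40 (1980–2019) and expanded into
annual records whose classify → proportion round trip is exact, with the
post-quantization severity used downstream so the planted and
recomputed values agree exactly. The species pool (default 120 species)
is built from Dirichlet(0.8) mixtures of three archetype trait profiles,
with reproductive traits jittered at 10% of the archetype range and
trophic level / CTmax given larger independent spreads (SD 0.4 levels and
3 °C) — within a life-history strategy those traits genuinely vary, and
the independent variation is what lets four community trait axes move
separately. Site abundance weights follow a Gaussian kernel (width 0.5)
on standardized species trait axes around each site's target trait
vector, scaled by 0.7 into the densely occupied region of trait space;
abundances are one multinomial draw (default 500 individuals), and the
planted exponent is the planted linear function of the *realized*
(abundance-weighted, z-scored) traits — the exponent responds to the
community that actually assembled, not to the unrealised target. Masses
are inverse-CDF draws from the PLB on [1, 1000] g with the site's
exponent, centred at b = −1.43 (SD 0.30) to match a plausible temperate
stream study; lengths follow the cube-law allometry W = 10⁻⁵L³ with 2%
length noise, which exercises the QC stage at a ~0.3% false-flag rate.
Three sites also receive an older duplicate sample that the
most-recent-sample rule must discard.

What the generator does **not** emulate: species-dependent body-mass
distributions (masses are drawn ataxically, independent of the species
label), gear selectivity, hydrologically realistic discharge series,
spatial autocorrelation among sites, intraspecific trait variation, and
real effects of the control variables (drainage area and ecoregion are
planted with zero effect and act purely as forced controls). Passing
recovery tests therefore demonstrates the estimators and the inferential
chain, not robustness to those real-data complications.

## Problem sizes

Defaults are the study conditions: 500 sites, 120 species, 500 measured
individuals per site, 40 years of annual flow records. The replicated
model-fit check (Fisher's C non-significant in ≥ 90% of generated studies)
runs 20 replicates at 150 individuals per site with 4 NMDS starts; the
calibration simulations use 200–500 replicates as stated in the tests.
The acceptance script runs the full default study once.

## Known limitations

* The stepwise search explores single-term moves from two starts; it is
  not guaranteed to find the global AIC optimum on adversarial designs.
* Standardized effects are reported for numeric predictors only;
  ecoregion contrasts are controls, not decomposed effects.
* The d-sep basis set conditions on the response's parents only (local
  Markov), which is valid under the fitted DAG but differs from basis-set
  constructions that condition on both members' parents.
* Profile intervals assume a unimodal likelihood; for n < ~20 fish the
  interval can hit the optimisation box.
* No mixed/random effects, latent variables, interactions or spatial
  error structure in the path model.
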