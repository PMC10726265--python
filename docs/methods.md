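# Methods

## The model

`streamocc` fits a single-season, multispecies site-occupancy model to
repeat-visit stream-survey data with two gears.  For species *i* at site *j*
the true occurrence state is latent,

    z_ij ~ Bernoulli(psi_ij),

and each survey *k* conditions on it,

    y_ijk ~ Bernoulli(z_ij * p_ijk),

so an observed zero is ambiguous between absence and missed detection.  Both
probabilities are logistic regressions:

    logit(psi_ij) = x'_occ(j) beta_i + u_{r(j), i}
    logit(p_ijk)  = x'_det(j,k) alpha_i + x'_shared(j,k) gamma

* **Community structure.**  Species coefficients are deflections around a
  community hypermean: `alpha_ic ~ Normal(mu_alpha_c, sigma_alpha_c)` and
  likewise `beta`.  Each species can therefore be read as its own model while
  borrowing strength across the (small) assemblage.
* **Shared gear responses.**  The gear x covariate detection columns carry a
  single community-level coefficient vector `gamma` — how a gear's
  efficiency changes with, say, water depth is assumed common to all species,
  while each species keeps its own gear intercept offset.
* **Nesting.**  Sites are riffle-run-pool complexes nested in stream
  reaches; a reach random intercept `u_{r,i} ~ Normal(0, sigma_u)` (per
  species; each reach lies in exactly one ecoregion) absorbs the spatial
  correlation of sites within a reach and unexplained reach-level variation.
* **Multiscale covariates.**  Detection covariates live at the survey level
  (wood, coarse substrate, vegetation, velocity, depth plus a depth² term,
  clarity, temperature, plus gear and ecoregion indicators).  Occurrence
  covariates mix site scale (fine substrate, pool %, residual pool depth,
  seepage, vegetation, wood) and reach scale (two-week mean temperature,
  drainage area, agriculture %), with temperature x RPD, vegetation x RPD
  and vegetation x pool interactions and ecoregion-varying main effects
  coded as main + (ecoregion x main) offset columns.

### Marginalized likelihood

Rather than sampling the latent `z`, the likelihood marginalizes it exactly
per species x site:

    L_ij = psi_ij * prod_k p^y (1-p)^(1-y)  +  (1 - psi_ij) * 1[all y = 0]

over *conducted* surveys only; missing (site, gear, occasion) combinations
are masked and contribute nothing.  Marginalization is exact, removes a few
hundred discrete parameters from the sampler, and improves mixing;
`conditional_occupancy` recovers Pr(z=1 | data) whenever a posterior
occupancy state is needed.  Probabilities are clipped to
[1e-12, 1 - 1e-12] inside log terms and the two-component marginal uses
log-sum-exp.

### Priors

The main-text model description leaves hyperprior families open, so the
package sets weakly informative defaults on the logit scale, all
configurable through `PriorConfig`:

| parameter | prior | default |
| --- | --- | --- |
| hypermeans `mu_alpha`, `mu_beta` | Normal(0, s) | s = 2 |
| hyper-SDs `sigma_alpha`, `sigma_beta` | half-Normal(s) | s = 1 |
| shared gear x covariate `gamma` | Normal(0, s) | s = 2 |
| reach-intercept SD `sigma_u` | half-Normal(s) | s = 1 |

Normal(0, 2) on a logit intercept keeps the implied probability prior
roughly flat over (0.05, 0.95); half-Normal(1) keeps hyper-SDs in the range
where logit-scale deflections stay interpretable.

## Covariate treatment

Continuous covariates are standardized (mean 0, SD 1, sample SD) on the
pooled both-ecoregion data so coefficients are comparable across ecoregions
on one scale.  Drainage area spans roughly 1-544 km² and is natural-log
transformed before standardizing; every other covariate uses the identity
transform.  Percents are stored 0-100 in files and standardized like any
other continuous column inside design matrices.  The depth² column is the
square of the standardized depth (not re-standardized), interaction columns
are products of standardized mains and never re-centred — both choices make
every non-main column vanish when covariates sit at their means, which is
exactly the conditioning used for marginal-effect curves.  Indicators are
0/1: gear (0 seining, 1 snorkeling), ecoregion (0 Arbuckle Uplift, 1 Ozark
Highlands), year (0 2018, 1 2019).  Each `StandardizationRecord` keeps the
transform, moments and the observed natural-scale range so curves can be
drawn back on natural units.

Derived field covariates follow their field definitions: residual pool depth
= max pool depth − riffle-crest depth, clamped at 0 for degenerate
measurements (RPD is a residual depth by definition); seepage = downstream −
upstream discharge, rounded to 0.01 m³/s, sign positive for gaining
(groundwater-fed) sites; channel-unit area = mean wetted width x unit
length.  Water clarity is measured once per reach and broadcast to nested
sites.

## Sampler

Posterior exploration uses component-wise adaptive random-walk Metropolis:

* scalar random-walk updates for every species coefficient, shared
  coefficient and reach intercept, with per-parameter step sizes adapted in
  batches of 50 warmup iterations toward a 0.35 acceptance rate (inside the
  0.23-0.44 band that is near-optimal for scalar updates);
* conjugate Gibbs draws for the hypermeans given deflections and hyper-SDs;
* log-scale random-walk updates (with Jacobian) for hyper-SDs and the
  reach-intercept SD.

The marginal site likelihood factorizes into a detection part (per-site sums
of Bernoulli log-terms, a function of `eta_det` only) and an occupancy part
(`psi`, a function of `eta_occ` only).  Both are cached, so an occurrence
update reuses the detection sums and a reach-intercept update touches only
that reach's sites; a full sweep is O(parameters x surveys).  The sampler is
dependency-free and adequate at this dimension (a few hundred parameters);
the `run_mcmc` interface would equally front a gradient-based sampler.

Defaults are 3 chains x 4000 iterations with 2000 warmup.  Convergence is
monitored with split R-hat — floored at 1.0 so that exactly-replicated
chains report 1.0 rather than the (n-1)/n artifact — with a 1.1 warning
threshold, and a Geyer initial-positive-sequence effective sample size.
Chains are seeded through `numpy.random.SeedSequence(seed).spawn`, making
runs bit-reproducible.

Point and interval summaries follow the reporting convention for this model
class: the posterior *mode* ("most likely value") from a Gaussian-kernel
density estimate with Silverman bandwidth evaluated on a fixed 512-point
grid over the pooled chains, and 95% *highest density intervals* — the
shortest interval containing ⌈0.95 n⌉ sorted draws.

## Backward selection

The full occurrence model is simplified one term at a time.  A term is
retained when its community hypermean 95% HDI excludes zero **or** any
single species coefficient's 95% HDI excludes zero; among non-retained
terms the one with the smallest |hypermean median| / HDI-width ratio is
dropped and the model refit.  Interactions and ecoregion offsets are
droppable immediately; a main effect only once nothing above it depends on
it, so the final spec always respects the hierarchy principle and is a
sub-spec of the input.  Detection covariates are exempt from selection by
default.  The exact drop rule used in the original analysis is not published
in the main text; this rule is the package's deterministic
operationalization of "effect size and uncertainty of species
relationships", and its behavior is validated by recovery simulations
(strong single-covariate truths are recovered exactly, null truths collapse
to intercept-only) rather than by matching any published selection trace.
A non-convergent intermediate fit is retried once with doubled chain length,
then selection aborts with the partial trace.

## Effect summaries

All derived quantities hold non-focal covariates at their means
(standardized 0), apply a mean year effect (0.5 x the year coefficient — the
literal average over the two study years), and set the reach intercept to 0
for population-level curves.  `integrate_reach=True` instead integrates over
Normal(0, sigma_u) draws by Monte Carlo, reproducing the wider band that
includes reach-to-reach variation; both modes exist because published
uncertainty bands of this kind are ambiguous about which is shown.
Curves are computed per posterior draw through the inverse-logit and
summarized afterwards (median, KDE mode, 2.5%/97.5% bounds) on a 100-point
grid spanning the covariate's observed range; standardization and log
transforms are inverted through the stored records, so curves are invariant
to the scaling used during fitting.

## Synthetic data

The generator reproduces the study design: 153 sites in 61 reaches, 64
Arbuckle / 89 Ozark (42%/58%), 25/36 reaches per ecoregion assigned
round-robin, about half the reaches in each year, up to 2 gears x 2
occasions per site with one gear dropped at a site with probability 0.2
(neither gear works everywhere), and five taxa.  Covariates are truncated
Normals matched to the per-ecoregion field means/SDs/ranges; drainage area
is log-normal moment-matched and rejection-truncated to its range; percent
covariates stay in [0, 100] and seepage may be negative.  Two obvious
misprints in the source covariate table are corrected here: the Ozark pool
row is read as 54 ± 26 % (not 0.54 ± 0.26 with a 0-96 range) and the Ozark
detection-temperature range as 17.0-28.8 °C (a mean of 23.84 cannot exceed
its upper bound).  Raw field measurements are generated consistently with
the derived covariates (max pool depth = riffle-crest depth + RPD,
downstream discharge = upstream + seepage).  Detections are then the model
run forward with known hypermeans, deflection SDs and reach-intercept SD;
the default detection intercept is 0 on the logit scale (the average
detection probability of .50 the survey design anticipated) and the default
gear effect +1 (snorkeling more efficient).  Covariates are drawn
independently across columns; real field covariates are correlated (RPD
with pool %, temperature with drainage area), the design is perfectly
balanced apart from the gear-missingness mechanism, and there is no residual
species correlation beyond the shared hyperparameters — so passing recovery
tests demonstrate correctness of the machinery under the model's own
assumptions, not robustness to the messiness of real survey data.

## Problem sizes used in the automated checks

The likelihood is verified against full latent-state enumeration on toys up
to 2 species x 3 sites x 4 surveys (|difference| < 1e-12) and by summing
exp(log-likelihood) to 1 over all encounter arrays of a 1-species 2-site
2-survey design.  Hypermean recovery runs 10 replicate generate-fit cycles
with 2 species and a reduced covariate set on the full 153-site/61-reach
design (3 chains x 1200 iterations), scoring 95%-HDI coverage over
parameter x replicate cells.  Selection recovery runs 10 strong-effect
(|logit coefficient| = 1.5) and 10 null simulations with all 5 taxa on an
80-site/40-reach design with a 4-covariate candidate set; the full species
complement matters here because the hierarchical shrinkage that keeps
species-level intervals honest weakens sharply below ~5 species.  These
sizes are the package's own balance between
statistical resolution and a test suite that runs in minutes; the generator
defaults themselves always remain the full study design.

## Known limitations

* The random-walk sampler mixes slowly for weakly identified hyper-SDs with
  few species; long chains or more species are needed for tight hyper-SD
  inference.
* HDIs from short chains are themselves noisy; selection decisions near the
  retention boundary can flip between seeds.
* The any-species retention clause is a multiple-comparison surface: with
  5 species and several candidate terms, a fit tests ~20+ intervals, so on
  data where no covariate matters the procedure keeps one spurious term in
  a nontrivial fraction of datasets even though each interval is
  individually conservative.  This is inherent to the rule (which is kept
  because single-species relationships are scientifically meaningful
  here), not a sampling artifact; treat a final model whose only support
  is one species' interval barely excluding zero with caution.
* The generator draws covariates independently; an optional correlation
  hook is not implemented.
* Single-season only: no occupancy dynamics, no abundance extension.
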