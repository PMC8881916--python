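# Methods

`fishdyn` implements an analysis workflow for long-term electrofishing
monitoring data of stream fish: split individuals into two size classes from
length-frequency histograms, model the joint dynamics of the two classes
with a hierarchical Bayesian state model, measure each parameter's
contribution to projected abundance by numerical elasticity, and test
whether those contributions follow spatial gradients.  This note records the
model, the defaults, and the design choices made where the design was
genuinely open.

## Size-class discrimination

Per sampling event, body lengths (mm) are modelled as a two-component
normal mixture fit by EM (`sklearn.mixture.GaussianMixture`, spherical
components, k-means initialization so fits are deterministic given a seed).
The class boundary is the length where the weighted component densities
cross, solved in closed form (the log-density equality is quadratic in
length) with a bracketed numeric fallback; with equal SDs the boundary is
`midpoint + sd^2 * ln(w1/w2) / (m2 - m1)`.  Because mixtures are unreliable
on weakly bimodal events, a random-forest classifier is calibrated on ~20
clearly bimodal events, with three features per individual: length, the
event's total catch (a density proxy), and annual degree-days above 12 °C —
the threshold below which growth is assumed inhibited.  Degree-days are the
sum of daily exceedances `max(0, T - 12)`, the standard growth-accumulation
definition, over the year preceding sampling.  Classifier skill is measured
by repeated split-sample cross-validation (default 100 splits, 30% holdout —
the holdout fraction is a free parameter since no convention exists) scored
with Cohen's kappa.

## Population dynamics model

Let `X0[i,t]`, `X1[i,t]` be log-abundances of 0+ (young-of-the-year) and
>0+ fish at site `i`, year `t`, and `S[i,t]` the sampled area (m²).  Both
are normal around expected values:

    lam0[i,t] = a0[i] + b0[i] * X1[i,t] / log S[i,t]
                + sum_j g0[i,j] * U[j,i,t] + log S[i,t]

    lam1[i,t] = a1[i] + X1[i,t-1] + b1[i] * X1[i,t-1] / log S[i,t-1]
                + d1[i] * X0[i,t-1] / log S[i,t-1]
                + sum_j g1[i,j] * U[j,i,t] + log(S[i,t] / S[i,t-1])

The >0+ equation is a modified stochastic Gompertz model: `a1` is the
productivity rate, `b1` density dependence, `d1` the apparent 0+→>0+
survival (transition) rate; `b0` is the apparent recruitment rate.  `U` holds
the z-scored annual mean and intra-annual SD of water temperature between
consecutive sampling occasions plus their squares (squares of the z-scores,
so quadratic responses are expressed on the standardized scale); J = 4 per
size class, giving 13 coefficient families in total.  Standardization is
pooled across sites and years within a species run so site coefficients are
comparable — a requirement of the downstream spatial stage.

Each site coefficient is exchangeable: `coef[i] ~ Normal(mu_fam,
sigma_fam)`.  Priors: `mu_fam ~ Normal(0, 10)`; all SD scales (family SDs
and the two process SDs) get half-Cauchy priors with scale 2.5, the
weakly-informative convention.  Log-abundance is defined as `log(count + 1)`
when ingesting counts, since zero catches occur and the offset convention
must be stated somewhere.

Eligibility filters before fitting: a site-year series is retained iff it
has ≥ 15 observed years, ≥ 50% non-null captures among observed years
(both classes confounded), and no more than 3 consecutive missing years.

### Inference

Sampling is by a blocked Gibbs sampler written in numpy.  Every conditional
except the SD scales is conjugate normal: the per-site coefficient vectors
(6 and 7 dimensional batched ridge-style updates), the hyper means, and the
latent log-abundances of missing site-years, which enter the joint density
linearly (as response, as same-year recruitment predictor, and in the next
year's Gompertz terms) and are treated as latent nodes sampled jointly with
the parameters.  The half-Cauchy SD scales are updated by univariate slice
sampling on the log scale.  Default chain geometry: 3 chains of 11,000
total iterations, 1,000 burn-in, thinned by 10 (1,000 retained draws per
chain).  `iterations` is interpreted as the total pre-thinning chain length.

Initial values: chains start from per-site ridge estimates perturbed by a
chain-specific overdispersed jitter (SD 0.5 on coefficients, log-normal on
scales).  Drawing initial scales from the half-Cauchy prior itself routinely
initializes the latent recursion in numerically absurd regions; the jittered
ridge start preserves "different regions of parameter space" while keeping
the first latent-state updates finite.  Missing areas at unobserved years
are carried at the site's mean log-area; a latent first-year >0+ state,
which has no autoregressive predecessor, gets a diffuse Normal(site mean,
10) anchor.  The expected value for a year whose predecessor lies outside
the series contributes no likelihood.

Diagnostics: classic potential scale reduction factor per hyper-level
scalar (flagging > 1.1); HPD intervals as the shortest empirical interval
at 95%; between-group comparisons by the overlap coefficient of posterior
samples on a shared 512-bin histogram grid (deterministic and
resolution-insensitive at MCMC sample sizes), with < 5% overlap read as a
difference; chi-square-discrepancy posterior predictive checks whose
p-value should be near 0.5 under a well-specified model.

## Elasticity analysis

Posterior medians of the site coefficients drive a deterministic projection
of both classes over the study period, started at the first observed >0+
value.  The projection is fully iterative — the projected >0+ state feeds
back into the carryover term (a one-step-ahead mode using observed states
is available behind `mode="one-step"`).  For each focal parameter family
the family's own predictor takes observed values while every other
predictor is held at its site-level time average; site-level (not pooled)
averaging preserves the between-site contrasts the spatial stage analyses.
Area offsets are not parameters and always take observed values.

Elasticity: `e = ((theta_per - theta_ori) / theta_ori) / delta` per
site-year, with `delta = 0.10` by default; coefficients are scaled
multiplicatively by `1 + delta` (a negative coefficient grows in
magnitude), and the linear and quadratic coefficients of a temperature
variable move together.  Points with `|theta_ori| < 1e-6` on the log scale
are excluded and logged rather than allowed to blow up the ratio.  Site
means are taken over years within the size class the parameter acts on;
the species mean pools all site-years used.  Species are compared per
family by Wilcoxon signed-rank tests on shared sites (rank-sum when site
sets are disjoint) with Bonferroni adjustment.

## Spatial model selection

Per parameter family, four OLS models of the site-mean elasticities are
compared by AIC: intercept-only, and quadratic models in elevation,
latitude, and great-circle (haversine, Earth radius fixed at 6371 km for
bit-reproducibility) distance to the supplied range center.  Covariates are
z-scored before squaring to avoid collinearity between the linear and
quadratic terms.  AIC counts the residual variance as a parameter
(`k = slopes + intercept + 1`), matching R's `AIC` so tables are comparable
with that toolchain; exact ties break toward the simpler model.  The best
model gets an adjusted R² and a likelihood-ratio test against the null with
chi-square df = extra parameters.  Elevation or latitude wins count toward
the range-shift hypothesis, distance wins toward the abundant-center one.

A caveat worth knowing: with three quadratic alternatives, each has
P(chi2_2 > 4) ≈ 13.5% of beating a true null by AIC, so the null is the
four-way arg-min in only ≈ 65% of null replicates even though it beats any
*single* alternative ≈ 86.5% of the time.  The acceptance suite tests the
pairwise comparison, whose operating characteristic is well defined.

## Synthetic data generator

The generator emulates the structure the analysis assumes: sites with
coordinates and elevations in a France-like window; water-temperature
summaries whose mean cools with elevation (5.5 °C/km lapse) and whose
variability grows with it, giving realistic covariate-elevation
correlation; site coefficients drawn from the normal hyper-distributions,
optionally with an injected spatial gradient on a z-scored site covariate;
abundances simulated exactly from the two dynamic equations; two-normal
length mixtures (defaults 60 ± 10 mm vs 180 ± 30 mm, a typical 0+/adult
separation for mid-sized cyprinids); and interior missing years with runs
capped at 3 so the default panels pass the eligibility filters.  Default
hyper means are of the magnitude reported for such populations
(productivity ≈ 1.5, recruitment ≈ 1.5, density dependence ≈ −4.5,
survival ≈ 0.5, temperature coefficients ≈ ±0.03–0.2) with moderate
between-site SDs and process SDs of 0.4 (0+) and 0.3 (>0+).  Sampled areas
are generated > 1 m² so the `log S` density denominator is positive — the
equations are undefined at S ≤ 1 and real electrofished stretches are far
larger.  Observed zero catches can be treated as true zeros (`log(0+1)`)
or censored to missing behind a flag; true zeros are the default.

What the generator does *not* emulate: detection error (no N-mixture
layer), river-network topology and flow directionality, multi-species
interactions, growth within the season, or non-normal length components.
Passing tests therefore demonstrate correctness of the estimation and
selection machinery under the model's own assumptions, not robustness to
their violation on field data.

## Problem sizes and numerical choices

Test and acceptance runs use 30 sites × 20 years (the published series
average ≈ 17 years), which the sampler fits at the full chain geometry in
under a minute; smaller 8–10-site panels with shortened chains back the
unit tests.  EM uses `reg_covar = 1e-10` and flags component collapse
(SD < 0.1 mm) as a degenerate fit rather than returning it.  The slice
sampler uses unit step width with stepping-out and shrinkage.  Zero-variance
covariates, constant spatial covariates, single-class training data,
infeasible missingness requests and misaligned panels are rejected with
specific exceptions rather than propagating NaNs.

## Known limitations

Posterior medians are plugged into the elasticity projection without
propagating posterior uncertainty, and elasticities are first-order local
measures around a 10% perturbation.  The Gibbs sampler exploits the
linear-Gaussian structure; a structurally different observation layer
(e.g. negative-binomial counts) would need a different kernel.  The RData
importer discovers variables heuristically by shape and name and reports
what it found when the mapping is ambiguous, rather than guessing.
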