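# Methods

## The estimation problem

Waterfowl harvest pressure is monitored through banding: birds are marked
on the breeding grounds before the hunting season, and hunters who shoot a
banded bird may report the band. The *direct recovery probability* f — the
chance that a bird alive at the start of the season is shot **and** its
band reported in that same season — understates the *harvest probability*
h because not every recovered band is reported. With a band-reporting
probability λ (estimated externally from reward-band studies),
h = f / λ. When reporting differs between jurisdictions, the correction
must be weighted by where the bird would be recovered: with P_CAN the
probability that a recovery occurs in Canada,

    h = f · ( P_CAN / λ_CAN + (1 − P_CAN) / λ_USA ).

Both f and P_CAN vary in space (hunting pressure concentrates along
settled corridors) and in time (hunter numbers, regulations, and
band-inscription technology all changed over the study period). This
package estimates both quantities on a 1° × 1° grid of banding blocks with
hierarchical Bayesian binomial models sharing one spatial machinery, then
derives h and late/early *risk ratios* per block.

## Data model

Releases and recoveries are aggregated to a dense count cube over
(block i, year t, age class a ∈ {juvenile, adult}, band type
b ∈ {avise, zip, toll-free, web}):

* N[i,t,a,b] — releases (preseason, July–September, 42–57° N, Ontario /
  Quebec / Atlantic-province banding regions; reward and mail-solicited
  bands excluded);
* y[i,t,a,b] — *direct* recoveries: shot and reported between September of
  the release year and the end of February of the following year, keyed by
  the **release** block. Restricting to direct recoveries avoids any
  assumption about annual survival or site fidelity;
* x[i,t,a,b] — the subset of y recovered in Canada.

Band type is taken from the inscription code when present and otherwise
imputed from the deployment era (before 1993 → avise; 1993–1995 → zip
code; 1996–2006 → toll-free; 2007 on → web address), with imputations
counted in the rejection report. Releases with unknown age are rejected
and counted; the handling of such records in historical data sets is not
standardized, and rejection keeps the cube unambiguous.

## The two submodels

One spatially correlated binomial-logit model serves both responses:

    y[i,t,a,b] ~ Binomial(N[i,t,a,b], f[i,t,a,b])        (recovery)
    x[i,t,a,b] ~ Binomial(y[i,t,a,b], P_CAN[i,t,a,b])    (Canada proportion)

    logit p[i,t,a,b] = α[a,b] + Σ_k β[k,a]·X[t,k] + Z[i] + ε[i,t]

* **α[a,b]** — intercepts per age × band type. The four (juvenile, adult)
  pairs are draws from one bivariate normal with mean zero, half-Cauchy(0, 5)
  scale priors and a uniform prior on the correlation (the separation /
  C-vine strategy), pooling information across band types.
* **β[k,a]** — age-specific slopes on three annual covariates: a hunting
  effort index (permit and duck-stamp sales analogue), a regulation-era
  indicator with a change point (1983 in the real calendar), and total
  banding effort. Priors Normal(0, 5) truncated to (−20, 20). Covariates
  are z-scored before fitting — vague slope priors on raw permit counts
  (~10⁵–10⁶) would be meaningless — and the stored means/SDs support
  back-transformation.
* **Z[i]** — a zero-mean Gaussian spatial field over block centroids with
  exponential correlation ρ(d) = exp(−θ d), d the great-circle distance in
  km. Because the field is shared between age classes, hierarchical
  centering is unavailable, so identifiability against the intercepts is
  restored by constraining Σ_i Z_i = 0. σ_Z has a half-Cauchy(0, 1) prior
  truncated to (0, 20); θ is uniform between −ln(0.99)/d_max and
  −ln(0.01)/d_min, the decay rates at which the most distant pair of
  blocks correlates at 0.99 and the closest pair at 0.01.
* **ε[i,t]** — block-year heterogeneity, Normal(0, σ_e), shared across age
  and band type within a block-year; same prior as σ_Z. Cells with zero
  trials stay in the index but contribute nothing to the likelihood and
  their ε is not sampled.

The *effective range* −ln(0.05)/θ (the distance at which correlation drops
below 0.05) is reported instead of θ; the common 3/θ approximation is also
exposed, labelled approximate. σ_Z and θ are not separately identifiable
in this model family — tests and reported diagnostics treat them jointly
(via the implied covariance / field magnitude), never individually.

## Posterior computation

The posterior is sampled with a No-U-Turn HMC sampler implemented in this
package (tree doubling with the slice acceptance rule, dual-averaging step
size targeting 0.8 acceptance, diagonal mass matrix estimated in expanding
warmup windows). Gradients of the log posterior are analytic.

Parameterization choices matter more than sampler bells:

* the sum-to-zero constraint is **hard**: the field is sampled in an
  orthonormal (n−1)-dimensional basis of the constraint subspace
  (Helmert), so every retained draw sums to zero at machine precision;
* intercepts and the spatial field are **centered** (sampled on their
  natural scale) because the counts inform them strongly; the block-year
  heterogeneity is **non-centered** (ε = σ_e·e, e ~ N(0,1)) because single
  block-years are weakly informed. This combination removed the deep
  trajectories (tree depth 8 → 5) seen with a fully non-centered
  parameterization;
* scales and θ use bounded-sigmoid transforms with exact log-Jacobians;
  K(θ) gets a 1e−9 diagonal jitter before factorization, as 1° grids are
  near-singular at small θ.

Defaults mirror a 6-chain run with 250 warmup and 1250 retained
iterations; the test suite and analysis scripts use 4 chains × (250
warmup + 300–500 retained), which keeps a desk-scale fit to one or two
minutes on one CPU while leaving split-R̂ of all fixed effects below 1.05.
Convergence is assessed with the classic split potential scale reduction
factor (each chain halved; no rank normalization). A divergent-transition
fraction above 10% triggers a prominent warning. When the true σ_Z is
zero the centered field has a funnel at σ_Z → 0; a few divergences there
are expected and the posterior median of σ_Z (the quantity the tests use)
is robust to them.

Prediction at unfitted blocks uses standard Gaussian-field conditioning
(kriging) per posterior draw with the unconstrained exponential
covariance; at a fitted block this reproduces the fitted Z exactly.
Population-level predictions set ε = 0; an option integrates it by
drawing ε ~ N(0, σ_e) per draw. Annual summaries can weight band types by
their observed share of releases in each year.

## Harvest derivation

The early reference year uses h = f/λ_pre with a single reporting rate
(default 0.43); P_CAN cancels there, so the early surface is computed from
f alone. The late year uses the jurisdiction-weighted form with λ_CAN =
0.50 and λ_USA = 0.73 by default. f and P_CAN come from two independently
fitted posteriors; their draws are paired by index — pairing is arbitrary
between independent posteriors and preserves each marginal uncertainty.
Risk ratios h_late/h_early are computed per draw and summarized with 95%
intervals. h > 1 is reported, not clipped, with a warning: it diagnoses λ
inputs inconsistent with the recovery probabilities. λ values are always
configuration inputs, never estimated.

## The synthetic study

The real banding records sit in a restricted registry, so the package
ships a generator that reproduces exactly the structure the models assume,
and the analysis is validated by parameter recovery. Defaults (the
reference study): 50 blocks sampled from a 10 × 17 block window spanning
44–54° N, 62–79° W; 20 years; two band types with a mid-study rollout
(each new type takes over linearly across 3 years); recovery intercepts
near logit(0.07)/logit(0.05) for juveniles/adults, matching typical
direct-recovery levels for the species; juvenile effort slope 0.2; σ_Z =
0.5 with a 500 km effective range; σ_e = 0.3. The Canada submodel field
is stronger and longer-ranged (σ_Z = 1.0, 1200 km), mirroring the
expectation that *where* birds are recovered is more spatially structured
than *whether* they are recovered. Releases are negative-binomial
(dispersion 1.5) around 30 juveniles and 8 adults per block-year, so
sparse, poorly informed blocks occur as they do in the north of the real
grid. The full-scale configuration (105 blocks × 41 years × 4 band types)
is available by config.

What the generator does **not** emulate: record-level banding (it draws
counts directly), age misclassification, spatial variation in λ within an
era, non-exponential correlation, and temporal drift in the spatial
field. Passing recovery tests therefore demonstrate that the estimation
machinery is correct and calibrated under the model's own assumptions,
not that the model is adequate for any particular real data set.

## Numerical and design notes

* Block assignment floors coordinates (half-open 1° cells), deterministic
  at boundaries; the direct-recovery window is calendar months September 1
  through the end of February, closed on both ends.
* Great-circle (haversine, R = 6371 km) centroid distances by default; the
  study area spans enough longitude that planar distance distorts.
* Sex is ignored throughout: the species is sexually monomorphic in
  flight, so hunters cannot select by sex.
* The Canada submodel blocks its intercepts identically to the recovery
  submodel.
* Risk-ratio draws with zero early-era harvest are dropped with a warning
  (cannot occur with a positive-definite posterior; guards degenerate
  inputs).
* Empty inputs: an all-zero cube is rejected at model construction
  ("nothing to fit"); an empty record list aggregates to an all-zero cube
  over a degenerate grid.

## Known limitations

* The sampler is single-threaded; chains run sequentially.
* ESS shown in summary tables is a lag-1 autocorrelation proxy, not the
  full autocorrelation-sum estimator.
* The coverage study in the default test run uses 5 replicates (the
  20-replicate version is `scripts/coverage_extended.py`); at 5 × 10
  parameters the 85% threshold has non-trivial Monte-Carlo slack.
* Kriging to unfitted blocks conditions on the unconstrained covariance;
  the sum-to-zero projection's effect on predictive covariance is ignored
  (negligible away from the grid-mean direction).
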