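# Methods

This note records the models occudyn implements, the choices that were
genuinely open, and what the synthetic-data tests do and do not establish.

## Dynamic occupancy model

The observation unit is a site × season × secondary-period binary record
y(i,t,k) (here 4 periods of 5 days per 20-day season), with NaN where a
station was not operative. The latent state z(i,t) ∈ {0,1} is true
occupancy; the model is

- z(i,1) ~ Bernoulli(ψ1(i)),
- z(i,t) | z(i,t−1) ~ Bernoulli(z(i,t−1)·(1−ε(i)) + (1−z(i,t−1))·γ(i)),
- y(i,t,k) | z(i,t) ~ Bernoulli(z(i,t)·p(i)),

with logit links on all four probabilities. Covariates are site-level and
standardized (mean 0, sample SD with ddof=1 — recorded in
`CovariateScaling` so response curves can be drawn on the raw scale);
squared terms are squares of the standardized covariate. Detection
covariates are site-level, so p is constant over seasons and periods; the
assumptions are the usual ones (closure within a season, no false
positives, independence across sites given covariates).

Colonization/extinction may include the spatiotemporal auto-covariate
D(i,t) = (1/n_i) Σ_{j∈N_i} z(j,t), the mean latent state of i's neighbors.
The transition t−1 → t uses D evaluated at t−1 (the conditioning state of
the transition); an isolated site takes D = 0 with a logged warning.
Neighbor sets are sites within a planar Euclidean radius, default 1,500 m
— chosen between the typical inland (~800 m) and coastal (~2,000 m)
station spacings because nothing in the survey fixes a biological
neighborhood; the radius is a parameter, not a finding.

### Likelihood and samplers

Without the auto-covariate the sites are independent and the latent chain
is marginalized exactly: per site, a scaled two-state forward recursion
with season emissions p^s1 (1−p)^s0 for z=1 and the all-zeros indicator
for z=0 (missing observations contribute emission 1). The recursion is
validated against brute-force enumeration of all 2^(sites×seasons) latent
configurations on random toys to 1e-10. Latent-state draws (for PAO) come
from forward-filter backward-sampling at a thinned subset of posterior
draws (default 900).

Coefficients get independent Normal(0, sd 31.6) priors — the precision
0.001 "non-informative" convention of standard JAGS occupancy code;
configurable. Sampling is adaptive random-walk Metropolis, 3 chains:
during burn-in the proposal scale chases a 0.35 acceptance rate and the
proposal covariance is re-estimated from the chain history at 50% and 100%
of burn-in; adaptation then stops. Chains start near the posterior mode
(Nelder-Mead + BFGS polish) with jitter. Defaults are test-scale — 500
burn-in, 2,000 kept per chain — and `MCMCConfig.paper_scale()` switches to
the field-study settings (20,000 / 100,000). Convergence is the classic
split Gelman-Rubin R-hat (verified against arviz's split method), flagged
— not fatal — above 1.1.

With the auto-covariate, neighbor states couple the sites and the forward
recursion no longer applies; the sampler is Metropolis-within-Gibbs with
explicit z: a Metropolis block for the coefficients conditional on z, then
one full sweep of single-site Gibbs updates of z(i,t), whose full
conditional includes the site's emission, its transitions in and out, and
its neighbors' t → t+1 transitions (through D). The sweep is a numba
kernel over a CSR adjacency. Sites with a detection have z pinned at 1.
Data augmentation mixes more slowly than the marginal sampler; at
test-scale chains the auto models are the usual source of R-hat flags.

### Derived quantities

PAO(t) = Σ_i z(i,t)/n from the latent draws (finite-sample, not the
ψ parameter), overall or restricted to coast/inland station groups.
Response curves are the inverse-logit of the linear predictor over a
covariate grid with all other terms at 0 (their standardized mean),
back-transformed to raw units via the stored scaling.

## DIC and staged forward selection

Deviance is −2 × marginal log-likelihood for marginalizable models. DIC
uses the Spiegelhalter penalty pD = mean(deviance) − deviance(posterior
mean coefficients). For auto-covariate models the deviance is conditional
on z (the observation layer only, as JAGS monitors it) and the plug-in
uses posterior means of both coefficients and z (emission rate z̄·p);
conditional and marginal DICs are therefore *not* strictly comparable and
the selection table records which models carry the caveat implicitly via
their spec. On a large-n normal toy pD reproduces the free-parameter count
within 20%.

Selection proceeds in stages — detection, initial occupancy, dynamics —
each stage fitting the stage null (the running winner) plus every
single-term candidate; a candidate is informative iff DIC < null DIC, and
if any is, terms are added forward-stepwise while DIC strictly decreases
(ties keep the simpler model). Candidates that fail the collinearity
screen (|Spearman rho| ≥ 0.7 by default; the generator deliberately makes
elevation × distance-to-coast such a pair) or the R-hat check are excluded
from the competition but stay in the audit table with a reason. The table,
not just the winner, is the product: DIC differences between hierarchical
models are suggestive, and a close competitor may be preferred on
subject-matter grounds — hence the `base_spec`/override hooks rather than
any automated judgment.

A statistical note that shapes the tests: a pure-noise candidate beats the
null by DIC with probability ≈ P(χ²₁ > 2) ≈ 0.16 (ΔDIC = 2 − χ²₁ for one
useless parameter), so the probability that the all-intercept model
survives a staged search decays like 0.84^m in the number of noise
candidates (measured: 15/20 replicates with one candidate per stage, 9/20
with two). Null-retention checks therefore use one candidate per stage and
assert a majority; with more candidates the "retain the null" property is
simply not a property DIC has.

## Diel activity

Clock time of the camera timestamp is the circular coordinate (not solar
time); sun times enter only through the seasonal partition. Sunrise and
sunset are circular means over the days cameras were operative. Periods:
dawn [sr−2, sr+2), day [sr+2, ss−2), dusk [ss−2, ss+2), night the
remainder — dawn and dusk exactly 4 h, availabilities summing to 1; a day
length outside (4 h, 20 h) makes day or night empty and is an error.

The activity density is a von Mises kernel mixture on the 24-h circle,
normalized per hour (grid of 512 points; circle integrals by the periodic
rectangle rule, interval integrals by the trapezoid rule on per-segment
grids, renormalized to proportions). `concentration="auto"` maximizes the
leave-one-out cross-validated log-likelihood of κ over a log-spaced grid
(subsampling to 1,500 points for the search only), divided by adjust².

Selection ratios follow Manly's design I (individuals not identified):
w_i = o_i/π_i, SE = sqrt(o_i(1−o_i)/(n π_i²)), simultaneous Bonferroni
intervals at z_{1−α/(2I)} with lower bounds clipped at 0; selected iff the
interval lies above 1, avoided iff below. By default the "use" o_i is the
KDE's per-period density mass (the study computed density proportions),
with n = number of independent detections supplying the SE; a raw-count
mode exists because the original procedure is ambiguous on this point.
Caveat worth knowing: with raw multinomial use the Wald-type intervals'
simultaneous coverage measures 0.93–0.95 at n = 100–800 — the
normal-approximation error erodes the nominal Bonferroni slack — while the
smoothed default is strongly conservative (≈0.998 at n=200). Repeat
detections of unidentifiable individuals are pseudoreplication; no
correction is applied because none is defined for this design.

## Synthetic studies

The generator is first-class, tested code. It emulates: ~93 stations in
the study's habitat mix (20 coastal shrubland / 40 forest / 33 meadow);
coastal stations along the shore at ~2 km spacing, inland stations in a
0.4–4.2 km band at ~900 m spacing; elevation generated as
0.12 × dist_coast + Normal(0, 95 m) noise (floored at ground level), which
reproduces the elevation/coast collinearity at Spearman rho ≈ 0.87 — the
95 m noise scale was calibrated once against that target; distance
covariates with plausible scales; logit-scale occupancy/detection
coefficients applied to standardized covariates (defaults give season-1
occupancy near 0.6, colonization 0.2, extinction 0.3, detection 0.5,
echoing the study's reported magnitudes); optional auto-covariate dynamics
using the previous season's z; winter restricted to 47 stations; and diel
times uniform in summer versus a night-centred von Mises + uniform
mixture (85/15, centre 02:00, κ 2.5) in winter/spring. For each detected
period the event count is geometric (support ≥ 1), days uniform in the
period — no within-period event model exists to copy, so this is a
convenience. The generating truth is serialized beside the data.

What it does not emulate: animal movement or home ranges, spatially
autocorrelated covariate fields beyond the elevation–coast link,
season-varying detection, camera failures within an operative season, or
observer/EXIF errors. Passing recovery tests therefore show the estimators
are correct for data meeting the model's assumptions, not that the model
is adequate for any particular field dataset.

## Numerical details and degenerate inputs

Probabilities are clipped at 1e-12 inside logs; the forward recursion is
renormalized each season. Detection-history periods are half-open 5-day
intervals aligned to each station's deployment start (stations may carry
start offsets, as cameras ran in sequential groups). The >60-min
independence filter is a greedy forward pass per station anchored on kept
events, strict at exactly 60 min, idempotent by construction. Distance
bins are half-open and left-closed; zero-effort bins report an undefined
(NaN) rate rather than 0. Zero-variance covariates, unknown stations,
events outside every operative window, single chains, and empty deviance
draws are errors, not warnings. Sampler seeds derive from one root seed
per fit; selection seeds increment a fit counter, so identical configs
reproduce identical tables byte-for-byte.

Problem sizes in the test and acceptance runs (300 sites × 3 seasons for
recovery, 100 sites for selection replicates, 2,000 activity replicates,
test-scale chains) were chosen as the smallest sizes at which the checked
statistical properties are comfortably resolved.

## Limitations

- Detection covariates are site-level; survey- or season-varying p would
  need design-matrix plumbing the spec of this study never exercises.
- Per-transition (season-specific) colonization/extinction coefficients
  are not implemented; covariate effects on dynamics are shared across
  transitions.
- Habitat class enters as the coast/inland PAO split, not as model dummy
  covariates (add indicator columns to the station table to include it).
- Conditional-DIC vs marginal-DIC comparability, Wald-interval coverage,
  and DIC's ~16% false-inclusion rate per noise candidate are inherited
  properties of the original toolchain, documented rather than repaired.
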