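# occudyn

Dynamic occupancy models and diel-activity analysis for camera-trap
surveys of an elusive carnivore — built around the study design used to
track the American mink (*Neovison vison*) invasion of a sub-Antarctic
island: ~93 baited camera stations across coastal shrubland, forest and
meadow, surveyed in seasonal bouts of 20 days split into four 5-day
secondary periods.

The package answers two questions a wildlife ecologist asks of such data:

1. **Where is the species, and how does that change between seasons?**
   A Bayesian hierarchical multi-season (dynamic) occupancy model with
   imperfect detection: the latent occupancy state of site *i* evolves as

   ```
   z(i,1) ~ Bernoulli(psi1_i)
   z(i,t) | z(i,t-1) ~ Bernoulli( z(i,t-1) (1 - eps_i) + (1 - z(i,t-1)) gamma_i )
   y(i,t,k) | z(i,t) ~ Bernoulli( z(i,t) p_i )
   ```

   with initial occupancy psi1, colonization gamma, extinction eps and
   per-period detection p all taking site covariates (elevation, slope,
   distances to water, ground cover) through a logit link. Colonization and
   extinction may additionally depend on the spatiotemporal auto-covariate
   `D(i,t) = mean z of i's neighbors`, which captures spread from occupied
   neighborhoods. Model structure is chosen by a staged forward DIC search
   (detection, then initial occupancy, then dynamics), and the headline
   derived quantity is the PAO — the proportion of sites occupied per
   season, overall and split coast vs. inland. Single-season variants fit
   each season's inland stations alone with distance to fresh water on psi.

2. **When is it active?** Detection clock-times are smoothed with a von
   Mises kernel density on the 24-h circle; the day is partitioned into
   dawn/day/dusk/night from seasonal mean sun times (dawn and dusk are the
   4 h around sunrise and sunset); and Manly design-I selection ratios
   `w = use / availability` with simultaneous Bonferroni intervals classify
   each period as selected, avoided, or used as expected.

Inference is MCMC (3 chains of adaptive random-walk Metropolis; split
Gelman-Rubin diagnostics). Models without the auto-covariate use the exact
marginal likelihood (a two-state forward recursion per site, verified
against brute-force enumeration); auto-covariate models sample the latent
states explicitly by Gibbs. Because no raw data from the original survey
are public, the package ships a first-class synthetic-study generator that
reproduces the design — including the elevation/distance-to-coast
collinearity (Spearman rho ≈ 0.87), winter access to only 47 of 93
stations, and night-concentrated winter activity — and keeps the
generating truth for recovery testing.

## Worked example

The whole analysis is config-driven:

```sh
occudyn simulate --config examples/demo_config.yaml
occudyn fit      --config examples/demo_config.yaml
occudyn report   --config examples/demo_config.yaml
```

`simulate` writes a synthetic 93-station study (stations, timestamped
detections, design, sun times, and the generating truth). `fit` filters
detections to >60-min independence, builds the detection history, screens
collinear covariates, runs the staged DIC selection on the three
non-winter seasons, fits per-season inland single-season models, and runs
the distance-binned detection rates and the diel-activity analysis. With
seed 1 the run (about half a minute) reports capture rates per 100
trap-nights of

```
summer_2014  11.72      winter_2014  8.40
spring_2014   8.23      summer_2015  6.56
```

a summer-2014 PAO of 0.649 (95% CrI 0.581-0.720) against a realized
simulated truth of 0.634, and a winter selection-ratio table

```
period  ratio   CI             class
night   1.63    [1.49, 1.77]   selected
dawn    0.41    [0.00, 0.83]   avoided
day     0.15    [0.00, 0.47]   avoided
dusk    0.03    [0.00, 0.15]   avoided
```

mirroring the nocturnal winter pattern the generator encodes. Every output
CSV carries the config hash and seed in its header; `report` collates them
into a single markdown document.

The same machinery is importable as sklearn-style estimators:

```python
import occudyn as od

stations = od.simulate_landscape(93, seed=1)
std, scaling = od.standardize(stations, ["elevation", "ground_cover"])
truth = od.default_truth(1)
latent, history, events = od.simulate_dynamics(truth, stations, od.default_design())

model = od.DynamicOccupancyModel(spec={"psi1": ["elevation"], "p": ["ground_cover"]})
model.fit(std, history.subset_seasons(["summer_2014", "spring_2014", "summer_2015"]))
model.summary_          # coefficient posterior means, CrIs, R-hat
model.pao("summer_2014")
model.response_curve("psi1", "elevation", scaling=scaling)
```

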