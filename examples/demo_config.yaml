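# End-to-end synthetic-study demo: simulate -> fit -> report.
seed: 1
output_dir: occudyn_out
n_stations: 93

design:
  seasons:
    - {label: summer_2014, start: 2014-02-10}
    - {label: winter_2014, start: 2014-06-20}
    - {label: spring_2014, start: 2014-09-20}
    - {label: summer_2015, start: 2015-02-10}

# winter access was limited: only 47 of 93 stations operative
season_station_counts:
  winter_2014: 47

truth:
  psi1: {intercept: 0.4, elevation: -1.0}
  gamma: {intercept: -1.4, dist_any_water: -0.7}
  eps: {intercept: -0.85, dist_any_water: 0.7}
  p: {intercept: 0.0, ground_cover: 0.8, dist_any_water: -0.8}
  diel:
    summer_2014: [{family: uniform, weight: 1.0}]
    winter_2014: &night
      - {family: vonmises, weight: 0.85, loc_hours: 2.0, kappa: 2.5}
      - {family: uniform, weight: 0.15}
    spring_2014: *night
    summer_2015: [{family: uniform, weight: 1.0}]

mcmc:
  n_chains: 3
  n_burn: 500
  n_keep: 2000
  # paper_scale: true   # 3 x 100,000 kept after 20,000 burn-in

dynamic_exclude_seasons: [winter_2014]

activity:
  concentration: auto
  use_mode: kde
  alpha: 0.05
  min_detections: 10
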