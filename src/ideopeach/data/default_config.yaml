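# ideopeach default configuration (version 0.1.0).
# Every key is optional; omitted keys fall back to these same values.
# Units and rationale: docs/methods.md.

growth:
  DM0: 13.0          # g, fruit dry mass at start_dab
  dj0: null          # GDD; null = read off the weather series at start_dab
  start_dab: 87      # days after bloom
  end_dab: 150
  alpha: 0.08        # gC/gDM, growth respiration
  beta: 0.44         # gC/gDM, biomass carbon content
  ksugar: 0.05       # 1/day, sugar-carbon consumption
  sigma_ts: 0.42     # gC/g sugar
  dmc: 0.15          # flesh dry-matter content
  f0: 0.5            # initial sugar fraction of flesh carbon
  step: 1.0          # days, sugar ODE step
  asymptote_mode: power   # 'power' = A*DM0^B, 'product' = A*DM0*B
  sla_ref: null      # m^2/g; null disables source limitation

weather:
  kind: constant     # or 'csv' with a 'path' key (columns day,tmean[,gdd])
  tmean: 22.0        # degrees C
  base_temp: 7.0     # degrees C, thermal-time base
  start: 0
  end: 160

nsga:
  population_size: 100
  max_generations: 250
  crossover_prob: 0.9
  mutation_prob: null     # null = 0.1 continuous / 0.01 binary
  eta_crossover: 20.0
  eta_mutation: 10.0
  seed: 0
  constraint_mode: block_encoding   # or constraint_domination
  archive_mode: all_nondominated    # or final_population

progeny:
  n_individuals: 159
  wild_allele_freq: 0.25
  variance_explained: {A: 0.30, B: 0.30, RGRini: 0.30, P3: 0.30,
                       kstone: 0.30, Wstone: 0.30, SLA: 0.30}
  kinetics_noise: {DM: 0.5, SR: 0.01, SU: 0.3}
  sla_noise_sd: 0.0005
  fruits_per_individual: 3
  fruit_size_factors: [0.8, 1.0, 1.2]
  observation_interval: 7
  n_starts: 8
  seed: 0
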