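# Example configuration for `thermoresil run-all --config examples/sim_config.yaml`
# Any omitted key keeps its default (see thermoresil.simulate.SimConfig and
# thermoresil.pipeline.PipelineConfig).
sim:
  seed: 7
  generation_sizes: [150, 300, 450]   # founders, generation 1, generation 2
  n_sires: 12                         # sires used per generation
  n_flocks: 5
  n_stations: 3
  start_year: 2014
  n_years: 4
  t_mean: 16.5                        # annual mean air temperature, degC
  t_amplitude: 10.0                   # seasonal half-range, degC
covariates: [tavg, tavg_lag7]
temperatures: [10.0, 25.0]            # cold- and heat-stress slope queries
slope_mode: total                     # or: deviation
analyses: [h2, lifetime, between_seasons, daily_vs_lag7]
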