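# Demo configuration for the end-to-end pipeline:
#   boarheat run --config examples/run_config.yaml --out-dir scratch/demo
seed: 1
n_animals: 3
start: "2019-06-01"
end: "2019-08-31"
site_lat: 50.0
site_lon: 14.8
tz_offset: 2.0
heatwave_threshold_c: 24.0
heatwave_min_hours: 23
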