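# Full synthetic study: 50x50 grid (~1 km cells) over the south-west
# highlands, three emission-scenario analogues x three future dates.
# Run:  arabica-sdm run-all examples/config.yaml
output_dir: demo
seed: 1

grid:
  n_rows: 50
  n_cols: 50
  cell_size: 0.02        # degrees (~2 km)
  origin_lon: 35.0       # north-west corner
  origin_lat: 8.0

n_layers: 4
autocorrelation_length: 5.0   # cells

# ground-truth niche used by the simulator (layer units)
niche:
  optima:
    temp_seasonality: 42.5
    temp_warmest_quarter: 16.2
    precip_driest_month: 60.0
    temp_wettest_quarter: 13.2
  tolerances:
    temp_seasonality: 3.6
    temp_warmest_quarter: 1.08
    precip_driest_month: 7.2
    temp_wettest_quarter: 1.08
  max_suitability: 1.0

n_records: 719        # raw occurrence records to simulate
clustering: 4.0       # expected records per survey cluster
frac_bad: 0.01        # fraction of rejectable records

# modelling
beta: 1.0             # global regularisation scale
hinge_knots: 5
background_size: 10000
test_fraction: 0.2
threshold_levels: [0.68, 0.95, 1.00]
ratchet: false        # no-gain rule only; set true to forbid class recovery
core_fraction: 0.1
dedup_precision: 4
max_confidence_km: 5.0
thin_min_sep: 0.0     # degrees; 0 disables thinning in the main analysis
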