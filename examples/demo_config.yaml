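# Demo configuration for `hazegrid run --config examples/demo_config.yaml --out <dir>`
# The `lut` block is mandatory; "default" uses the standard node set
# (zeniths 0..60 step 12, azimuths 0..180 step 24 plus the 180 endpoint,
# tau nodes 0/0.25/0.5/1.0/1.5/1.95, bands 470/660/2100 nm).
lut: default

n_rows: 40
n_cols: 40
seed: 7
dates_per_season: 12
noise_cv: 0.05

solar_zenith: 33.0
satellite_zenith: 21.0
relative_azimuth: 50.0
surface_swir_mean: 0.12
surface_swir_std: 0.04
cloud_fraction: 0.08

n_aod_stations: 2
n_pm25_stations: 41
station_clustering: 0.7
pop_centers: 5
pop_peak_density: 8000.0
pop_decay_km: 6.0

dark_limit: 0.25
cloud_brightness: 0.4
normalize_x: false
build_fraction: 0.7
outlier_rule: resid3

weights_scheme: queen
alpha: 0.05
n_perm: 199
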